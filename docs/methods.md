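# Methods

This note records the statistical models, algorithmic conventions and design
choices behind `gba`, in the spirit of a package reference manual: enough
detail to reproduce every number the code prints, and an honest account of
what the synthetic benchmarks do and do not demonstrate.

## Expression model and normalization

Counts are taken as given (quantification is upstream).  Abundance is
expressed as transcripts per million,
`TPM_gs = (c_gs / l_g) / sum_j (c_js / l_j) * 1e6`, with lengths in
nucleotides; every sample column sums to 1e6 by construction (relative
tolerance 1e-6 in the contract tests).  The low-expression filter keeps
transcripts whose **maximum** TPM over samples is **strictly greater** than
the threshold (default 5 TPM).  The max rule is the default because in a
merged multi-tissue assembly a transcript well expressed in any one organ is
informative; `mean` and `all` rules are provided.  Filtering does not
renormalize by default — retained values keep their original meaning — and a
`renormalize` flag rescales columns to 1e6 when closed TPM values are wanted.

All correlation work uses `log2(TPM + 1)`.  The pseudocount of 1 TPM keeps
zeros finite and compresses Poisson noise at low abundance; it is
configurable.  Replicate QC reports Spearman (default) and Pearson
correlations for every within-tissue replicate pair and flags pairs at
`rho > min_rho` (default 0.9, matching the replicate-agreement bar of the
emulated study design).  Spearman ties get average ranks; a constant column
makes the coefficient undefined and is reported as a failed pair with a
reason rather than an exception.

## Differential expression

The test statistic is the classic conditional exact test under a
negative-binomial model with a **common dispersion** phi shared across genes
(`BCV = sqrt(phi)`; the default phi = 0.168531 corresponds to BCV 0.41, a
typical bulk value for the emulated 4-tissue x 2-replicate design).  With
equal per-sample library sizes, the sum of a group's counts is
NB(n_g * mu, phi / n_g).  Conditional on the observed total t, the law of
the group-A sum is `P(A = a | t) ∝ f_A(a) f_B(t - a)` enumerated over
a = 0..t (log space, normalized by logsumexp); the two-sided p-value sums
the probabilities of all outcomes no more likely than the observed one, with
a 1e-10 log-tolerance absorbing floating-point ties.  At phi = 0 the model
degenerates to Poisson and the conditional law is exactly
Binomial(t, n_A / (n_A + n_B)); the code dispatches to that closed form, and
the tests verify agreement with an independent exact binomial test to 1e-9
over totals up to 200.  A total of zero returns p = 1 (no information).
Libraries are equalized upstream by rescaling each column to the
geometric-mean library size and rounding.

The common dispersion can be estimated by pooled method of moments: for
every (gene, group) cell with >= 2 replicates and positive mean, form
`(s^2 - m) / m^2`; phi-hat is the median over cells, floored at 0.  With few
replicates this estimator is deliberately simple and biased low (the median
of a chi-square-shaped moment estimate); at 4 replicates/group its sampling
interval around phi = 0.168531 is roughly [0.10, 0.24], which the tests
assert.  It is adequate for fixture-scale work; when a trusted dispersion
exists it should be passed explicitly (the default does exactly that).

Calls use the strict decision rule: up iff p < 0.01 and log2FC > 2, down iff
p < 0.01 and log2FC < -2.  log2FC = log2((mean_B + 0.5) / (mean_A + 0.5));
the 0.5 prior keeps zero counts finite.  No multiple-testing correction is
applied by default (the decision rule thresholds the raw p); BH correction
is a flag away in the API.  DEG set overlaps are exclusive (UpSet-style)
intersection counts.  Keyword enrichment is the upper-tail hypergeometric
probability P(X >= k), summed term by term in log space; it matches exact
enumeration to machine precision for all universes up to 15 in the tests.

## Homology search and conservation tiers

Alignment is optimal affine-gap dynamic programming (Gotoh) in nucleotide
space, via Bio.Align.PairwiseAligner: match +2, mismatch -3, gap open -5,
gap extend -2, where a length-L gap scores `open + (L-1) * extend`.  These
are blastn-flavoured defaults; ranking by raw DP score under a fixed scheme
is order-equivalent to a bit score.  `N` matches nothing — it scores and
counts as a mismatch against every base including itself.  Percent identity
is identities / alignment columns (matches + mismatches + internal gap
columns); coverage is the aligned span over the sequence length.  Best hits
align both strands (assembled transcripts have arbitrary orientation) and
break score ties by higher identity, then lexicographic subject id; hits
under a minimum score (default 50, i.e. 25 matched bases) are reported as
"no hit" rather than dropped.  An optional minimum alignment length filter
exists for screening spuriously short best hits, with no default cutoff.

Best-hit identities are banded into four conservation tiers: tier 1 >= 85 %,
tier 2 in [78, 85), tier 3 in [70, 78), tier 4 < 70 %.  The 85/70 anchors
follow the qualitative conservation groups this kind of pathway analysis
reports; 78 is this package's interior boundary between the "slightly
diverged" and "around 75 %" bands.  Branch summaries average best-hit
identity per pathway branch, excluding and counting no-hit baits.

## Redundancy compaction

Greedy incremental clustering in the CD-HIT style: sequences sorted by
decreasing length (ties lexicographic), each joining the first existing
representative it matches at identity >= 0.9 over an alignment covering
>= 0.8 of the **shorter** sequence, else founding a new cluster.  A
candidate pre-screen requires at least one shared exact 11-mer before any
DP alignment; true redundancy partners (fragments, near-copies) share long
exact stretches, so the screen only prunes hopeless comparisons.  Consensus
selection takes the longest member, breaking ties by highest max TPM then
lexicographic id.  The full pipeline is: TPM filter, cluster, select; it is
idempotent, and raising either threshold can only increase cluster counts
(asserted over a threshold grid).

## HRR co-expression network and communities

For each gene, neighbours are sorted by decreasing Pearson correlation of
log2(TPM+1) profiles over **all** samples; ordinal ranks 1..(n-1) with ties
broken by ascending gene id (average ranks would make the statistic
non-integral).  The highest reciprocal rank is
`HRR(i, j) = max(rank_i(j), rank_j(i))` — symmetric, integer, >= 1, equal to
1 exactly for mutually top-ranked pairs.  The network captures, for each
bait, every partner with HRR **strictly** below tau (default 100).  The
default capture keeps only bait-incident edges; `all-pairs` mode also
connects captured genes to each other under the same threshold, which is
the right input for community detection (communities are defined among
candidates, not only through baits).

Communities come from Clauset–Newman–Moore greedy modularity agglomeration,
implemented here to be fully deterministic: starting from singletons, the
connected community pair with maximal dQ = e_between - 2 a_i a_j is merged,
ties broken by the lexicographically smallest pair of community labels (a
community is labelled by its smallest member id); the partition with the
highest unweighted modularity `Q = sum_c (e_c - a_c^2)` along the merge path
is returned.  Edges are unweighted for modularity; PCC and HRR ride along as
edge attributes only.  Tests pin the implementation to exhaustive partition
search on small graphs (never above the optimum; exact on disconnected
cliques) and to networkx's modularity formula.

Candidate reports list each bait's non-bait neighbours sorted by ascending
HRR, then descending PCC, then id, with community membership and keywords;
the profile filter keeps candidates whose tissue-mean TPM peaks in a stated
tissue set (default the young aerial parts, YL/YS — the expression pattern
expected of the pathway of interest in the emulated design).

## The synthetic study design

`SimConfig()` defaults describe the reference conditions all recovery
benchmarks use: 2000 genes, 5 planted modules of 50 genes, 4 tissues
(YL, YS, OL, AR) x 2 replicates, library size 5e6, NB dispersion 0.168531,
module fold 8, baseline proportions log-normal(0, 1), seed 42.

* **Planted modules** take distinct two-tissue activity patterns, module 0
  being the pathway-like module active in the young aerial parts {YL, YS};
  the remaining modules cover {OL,AR}, {YL,OL}, {YS,OL}, {YL,AR}.  Inside an
  active tissue a module gene's baseline proportion is multiplied by the
  module fold before per-sample renormalization.
* **Background structure.** Every non-module gene belongs to one of the
  binary tissue-activity archetypes over the subsets *not* used by modules
  (organ-specific expression programs), with per-gene fold drawn
  log-normal(ln 8, 0.2).  This reflects how bulk transcriptomes over a
  handful of organs behave — expression is pervasively organ-regulated and
  effectively low-dimensional, so thousands of genes share each archetype.
  The alternative, an unstructured i.i.d.-noise background, is the single
  most adversarial case for a mutual-rank statistic at this problem size:
  with 8 samples and 2000 genes each bait's top-99 neighbour list fills up
  with chance-correlated background whose own neighbour lists are equally
  arbitrary, so their reciprocal ranks survive and edge precision is capped
  near 0.5 no matter how clean the planted modules are.  Genes embedded in
  real co-expression programs instead have their top ranks occupied by their
  own program, which breaks spurious reciprocity.  Passing the recovery
  benchmarks therefore demonstrates correct behaviour on modular expression
  data; it does not certify performance on data dominated by unregulated,
  pattern-free genes.
* **Planted DEGs** are exactly the module genes whose activity differs
  between a tissue pair, direction "up" meaning higher in the second tissue;
  with module fold 1 nothing is planted.  Background genes also respond to
  tissue (their programs), so planted-DEG benchmarks measure recall of the
  labelled truth, not a false-discovery rate.
* **Sequence fixtures** assign roles to background gene ids in order:
  redundancy groups (a representative plus fragments covering >= 85 % of it
  at ~1 % substitutions and occasionally a 3-nt deletion; the representative
  stays longest), bait-homolog carriers (substitution-only mutation at
  1 - target identity, targets 0.95/0.85/0.75 by default), then unrelated
  random ACGT background.  Mutations are substitutions only so realized
  global-alignment identity concentrates within ~±0.01 of the target;
  indels live only in the redundancy fragments.
* **Annotations** give the planted keyword to 80 % of the designated
  module's genes and 5 % of the rest; ten generic keywords are sprinkled at
  the background rate.
* **Determinism.** Each generator draws from its own stream derived from
  `(seed, stream-id)`, so outputs are byte-identical across runs and
  independent of call order.

What the generator does **not** emulate: read-level artefacts (quality,
mapping multi-hits, positional bias), library-size imbalance and
compositional effects beyond renormalization, correlated dispersion across
genes, ambiguity codes, unregulated "flat" genes, and alternative splicing.
Benchmarks passing here say the algorithms are implemented correctly and
behave as designed under the stated statistical model — not that the same
thresholds are optimal for any particular real dataset.

## Benchmark metric conventions

On the reference conditions, with three baits per planted module:

* **Precision** is the fraction of bait-incident edges (HRR < 100,
  bait-anchored capture) whose two endpoints share a planted module;
  **recall** is the fraction of (bait, same-module partner) pairs captured.
  Both are ~0.85–0.95 at seed 42 and asserted >= 0.8.
* **Community ARI** compares fast-greedy communities of the all-pairs
  captured subgraph with the planted module labels, over captured genes that
  *have* a module label — the standard treatment of partial ground truth.
  Captured background genes belong to no planted community; conventions
  that force them into one pseudo-class ("all background") or into their
  generative archetypes score the attachment of interlopers rather than the
  recovery of the planted structure (they measure 0.6–0.7 here while the
  module/community cross-tabulation is exactly diagonal).
* **Keyword check**: the planted keyword must be the top enrichment hit of
  the community containing the module-0 baits.

## Numerical and convention details worth knowing

* Tie-breaks are deterministic everywhere: neighbour ranks by ascending gene
  id; cluster membership by (length, id) insertion order; best hits by
  (score, identity, id, strand); CNM merges by smallest label pair.
* The exact test uses a relative log-tolerance of 1e-10 when collecting
  outcomes "no more likely than observed", so symmetric totals return
  exactly 1.0 despite floating rounding.
* Hypergeometric tails and NB conditional laws are computed in log space;
  enumerated conditional probabilities normalize to 1 within 1e-10 for
  totals up to 5000.
* Zero-variance genes are excluded (with a warning) before correlation;
  fewer than 3 samples is an error.
* The empty local alignment (nothing scores positively) is returned as a
  zero-score, zero-length result instead of an error.
* Degenerate inputs fail loudly and name the offender: zero-length
  transcripts, all-zero sample columns, module overcommit, identity targets
  outside (0, 1], unknown tissues in a profile pattern.

## Problem sizes used by tests and the acceptance script

Simulation-heavy checks run at deliberately modest sizes chosen to keep the
whole suite comfortable on a single CPU while leaving the conclusions
unchanged: the reference study itself (2000 x 8) for network recovery, 1000
genes for null calibration of the exact test, 2000 genes for
dispersion-estimator intervals, 100-gene fixtures for compaction, 200 seeds
for the enrichment-uniformity check, 300-gene runs for byte-level
determinism, and <= 12-nt sequences for exhaustive alignment oracles.

## Known limitations

* The dispersion estimator is a floor-at-zero moment median, not qCML or
  quasi-likelihood; it under-estimates phi at low replication by design
  simplicity.
* The exact test plugs the conditioned-total mean into the NB conditional
  law; with very unequal (unequalized) libraries it is not exact.
* Greedy compaction is order-dependent by specification (longest first); it
  does not re-assign members after better representatives appear later, and
  it is not a reimplementation of any particular external clustering tool's
  heuristics.
* CNM is O(n^2)-ish per merge in this implementation — fine for captured
  subgraphs (hundreds of nodes), not meant for genome-scale graphs.
* Alignment is nucleotide-only, no E-values, no seed-and-extend heuristics;
  all-vs-all bait searches scale as baits x transcripts full DP.
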