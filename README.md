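# gba — guilt-by-association candidate-gene discovery from multi-tissue RNA-seq

Plant specialized metabolism (for example monoterpene indole alkaloid
biosynthesis) is encoded by pathways whose genes are tightly co-regulated
across organs.  When only some pathway genes are known, the remaining steps
can be nominated by *guilt by association*: genes whose expression profiles
track the known ("bait") genes across tissues are strong candidates.  `gba`
is a tested, reusable implementation of that computational chain for bulk
multi-tissue RNA-seq — from raw transcript counts to ranked candidate
reports — together with a synthetic-data generator that plants every signal
the chain is supposed to find, so the whole pipeline is testable without any
sequencing download.

## What it computes

Given a transcript × sample count matrix with transcript lengths, sample
metadata (tissue, replicate), transcript and bait sequences, and a
transcript → keyword annotation table:

1. **Normalization & QC** (`gba.exprmat`) — transcripts per million,
   TPM<sub>gs</sub> = (c<sub>gs</sub>/ℓ<sub>g</sub>) / Σ<sub>j</sub>
   (c<sub>js</sub>/ℓ<sub>j</sub>) · 10⁶; strict low-expression filtering
   (max-over-samples TPM > 5 by default); log₂(TPM+1); within-tissue
   replicate agreement (Spearman ρ > 0.9).
2. **Redundancy compaction** (`gba.compact`) — greedy incremental clustering
   of the (merged-assembly style) transcript set, longest first, joining a
   representative at ≥ 90 % identity with ≥ 80 % coverage of the shorter
   sequence; one consensus transcript per cluster.
3. **Differential expression** (`gba.dge`) — the conditional exact test under
   a common-dispersion negative-binomial model (φ defaults to 0.168531,
   BCV = √φ ≈ 0.41): given the total of the two group sums, the two-sided p
   sums all conditional outcome probabilities no larger than the observed
   one; calls are made at p < 0.01 and |log₂FC| > 2 (strict).  UpSet-style
   exclusive intersections of DEG sets and upper-tail hypergeometric keyword
   enrichment, P(X ≥ k) for X ~ Hypergeom(N, K, n).
4. **Homology tiers** (`gba.homology`) — optimal affine-gap DP alignment of
   baits against transcripts (both strands), best hit per bait by raw score,
   and conservation bands of percent identity (≥ 85, [78, 85), [70, 78),
   < 70) summarized per pathway branch.
5. **HRR network & communities** (`gba.coexnet`) — pairwise Pearson
   correlation r<sub>ij</sub> of log₂(TPM+1) profiles, ordinal neighbour
   ranks, and the highest reciprocal rank

   HRR(i, j) = max(rank<sub>i</sub>(j), rank<sub>j</sub>(i)),

   capturing every pair with HRR < 100 around the baits; fast-greedy
   (Clauset–Newman–Moore) modularity communities,
   Q = Σ<sub>c</sub> (e<sub>c</sub> − a<sub>c</sub>²); per-bait candidate
   tables and an expression-profile filter (for example "maximum in the
   young aerial parts").
6. **Synthetic studies** (`gba.synthio`) — seeded datasets emulating a
   4-tissue × 2-replicate design with NB counts, planted co-expression
   modules, planted DEGs, redundant transcript variants, bait homologs at
   controlled identity, and a keyword enriched in one module, all recorded
   as ground truth.

## Worked example

```python
from gba import synthio, exprmat, coexnet, dge

dataset = synthio.simulate_dataset(synthio.SimConfig())  # 2000 genes, seed 42
tpm = exprmat.compute_tpm(dataset.counts)
qc = exprmat.replicate_qc(tpm, dataset.meta, min_rho=0.9)
print(f"replicate QC: {'PASS' if qc.all_pass else 'FAIL'} "
      f"(min Spearman rho = {qc.pairs['spearman'].min():.3f})")

expr = exprmat.log_transform(exprmat.filter_low_expression(tpm, 5.0))
corr = coexnet.pcc_matrix(expr)
hrr = coexnet.hrr(coexnet.rank_neighbors(corr))

truth = dataset.truth
baits, seen = [], {}
for g, m in sorted(truth.module_of.items()):  # three known genes per branch
    if m is not None and seen.get(m, 0) < 3:
        baits.append(g); seen[m] = seen.get(m, 0) + 1

net = coexnet.build_network(hrr, baits, tau=100, capture="all-pairs", pcc=corr)
part = coexnet.fast_greedy_communities(net)
print(f"network: {net.number_of_nodes()} genes, {net.number_of_edges()} edges, "
      f"{len(part.members())} communities (Q = {part.modularity:.3f})")

report = coexnet.candidate_report(net, part, annotations=dataset.keywords)
print(report.candidates.head(3).to_string(index=False))

members = {g for g, c in part.communities.items()
           if c == part.communities[baits[0]]}
enr = dge.keyword_enrichment(members, set(hrr.index), dataset.keywords)
print(f"top keyword: {enr.iloc[0]['keyword']!r} "
      f"(k={enr.iloc[0]['k']}/{enr.iloc[0]['n']}, p = {enr.iloc[0]['p']:.2e})")
```

prints

```
replicate QC: PASS (min Spearman rho = 0.917)
network: 327 genes, 6768 edges, 5 communities (Q = 0.797)
 bait  gene  hrr      pcc  community  shared_community                   keywords
g0000 g0037    2 0.979215          0              True alkaloid biosynthesis;kw04
g0000 g0008    4 0.974503          0              True alkaloid biosynthesis;kw09
g0000 g0024    5 0.977365          0              True alkaloid biosynthesis;kw08
top keyword: 'alkaloid biosynthesis' (k=40/73, p = 2.26e-30)
```

Replicates agree well above the ρ > 0.9 bar; the bait-anchored HRR network
resolves exactly the five planted co-expression modules as communities; the
top-ranked candidates of bait `g0000` are fellow members of its planted
pathway module (HRR 2–5, PCC ≈ 0.97); and the keyword planted on that module
is the community's top enrichment hit by twenty-odd orders of magnitude.

The same chain is available from the shell:

```sh
gba simulate --out fixture --seed 42
gba normalize --counts fixture/counts.tsv --lengths fixture/lengths.tsv --out tpm.tsv
gba filter --tpm tpm.tsv --threshold 5 --out kept.tsv
gba network --tpm kept.tsv --baits baits.txt --tau 100 --out-edges edges.tsv
gba report  --tpm kept.tsv --baits baits.txt --keywords fixture/keywords.tsv --out report.tsv
```

## Layout

```
src/gba/       exprmat, compact, dge, homology, coexnet, synthio, io, cli
tests/         pytest suite with independent oracles (tests/oracles.py)
docs/methods.md   model, assumptions, parameter choices, limitations
```
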