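"""Two-group differential expression and keyword enrichment for count data.

The test statistic is the classic conditional exact test under a common-
dispersion negative-binomial model: with equal library sizes, the sum of each
group's counts for a gene is NB distributed (group A: mean ``n_A * mu``,
dispersion ``phi / n_A``), and the two-sided p-value sums the probabilities of
all outcomes of the A-sum, conditional on the observed total, that are no more
likely than the observed one.  At ``phi = 0`` the model degenerates to Poisson
and the conditional law is exactly Binomial(total, n_A / (n_A + n_B)).

Genes are called up/down at strict thresholds on the raw p-value and the
log2 fold change (defaults p < 0.01, |logFC| > 2).  Keyword enrichment of a
gene set against its universe uses the upper-tail hypergeometric probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "DispersionEstimate",
    "EnrichmentResult",
    "estimate_common_dispersion",
    "equalize_library_sizes",
    "exact_test",
    "log_fold_change",
    "dge_table",
    "call_degs",
    "deg_set_overlaps",
    "keyword_enrichment",
]

#: Common NB dispersion reported for the 4-tissue x 2-replicate study design
#: this pipeline emulates (BCV = sqrt(phi) = 0.41).
DEFAULT_DISPERSION = 0.168531


@dataclass(frozen=True)
class DispersionEstimate:
    """Common negative-binomial dispersion phi; BCV = sqrt(phi)."""

    dispersion: float
    method: str = "pooled-mom"

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @property
    def bcv(self) -> float:
        return float(np.sqrt(self.dispersion))


def equalize_library_sizes(counts: pd.DataFrame) -> pd.DataFrame:
    """Rescale every sample column to the geometric-mean library size.

    Returns integer counts (rounded); exact-test machinery assumes equal
    libraries, which the synthetic generator provides only in expectation.
    """
    libs = counts.sum(axis=0).astype(float)
    if (libs <= 0).any():
        raise ValueError("cannot equalize a sample with zero total count")
    target = float(np.exp(np.log(libs).mean()))
    scaled = counts.mul(target / libs, axis=1)
    return scaled.round().astype(int)


def estimate_common_dispersion(
    counts: pd.DataFrame, groups: dict[str, list[str]] | pd.Series
) -> DispersionEstimate:
    """Pooled method-of-moments common dispersion.

    For every (gene, group) cell with >= 2 replicates and positive mean, the
    moment estimate ``(s^2 - m) / m^2`` is formed from the within-group sample
    mean and variance; phi-hat is the median of these, floored at zero.
    Libraries are equalized to the geometric mean first.
    """
    if isinstance(groups, pd.Series):
        groups = {g: list(idx) for g, idx in groups.groupby(groups).groups.items()}
    replicated = {g: s for g, s in groups.items() if len(s) >= 2}
    if not replicated:
        raise ValueError("no group has >= 2 replicates; dispersion is not estimable")
    eq = equalize_library_sizes(counts)
    cells = []
    for g, samples in replicated.items():
        sub = eq[samples].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        cells.append((v[ok] - m[ok]) / m[ok] ** 2)
    est = np.concatenate(cells)
    if est.size == 0:
        raise ValueError("no gene with positive mean in a replicated group")
    return DispersionEstimate(dispersion=float(max(0.0, np.median(est))))


def _group_sum_logpmf(x: np.ndarray, n: int, mu: float, phi: float) -> np.ndarray:
    """log pmf of the sum of ``n`` iid NB(mean mu, dispersion phi) counts."""
    if phi == 0.0:
        return stats.poisson.logpmf(x, n * mu)
    r = n / phi  # sum of n NB(r=1/phi) is NB with r = n/phi, same p
    p = r / (r + n * mu)
    return stats.nbinom.logpmf(x, r, p)


def exact_test(
    count_sum_a: int,
    count_sum_b: int,
    n_a: int,
    n_b: int,
    dispersion: float = DEFAULT_DISPERSION,
) -> float:
    """Two-sided conditional NB exact test on two group count sums.

    Assumes equal per-sample library sizes (equalize upstream).  The p-value
    enumerates every split of the observed total between the groups and sums
    the conditional probabilities of splits no more likely than the observed
    one.  ``total = 0`` returns 1 by convention (no information).
    """
    for name, v in (("count_sum_a", count_sum_a), ("count_sum_b", count_sum_b)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if n_a < 1 or n_b < 1:
        raise ValueError("need >= 1 sample per group")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    total = int(count_sum_a + count_sum_b)
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)  # common per-sample mean under H0
    a = np.arange(total + 1)
    if dispersion == 0.0:
        # Poisson counts: conditional law is exactly binomial
        logp = stats.binom.logpmf(a, total, n_a / (n_a + n_b))
    else:
        logp = _group_sum_logpmf(a, n_a, mu, dispersion) + _group_sum_logpmf(
            total - a, n_b, mu, dispersion
        )
        logp = logp - logsumexp(logp)
    log_obs = logp[int(count_sum_a)]
    # tolerance absorbs floating noise among tied outcome probabilities
    keep = logp <= log_obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def log_fold_change(
    counts: pd.DataFrame,
    groups: dict[str, list[str]],
    prior: float = 0.5,
) -> pd.Series:
    """Per-gene log2 fold change between two groups of library-equal samples.

    ``logFC = log2((mean_B + prior) / (mean_A + prior))`` with the group order
    taken from ``groups``; the prior keeps it finite at zero counts.
    """
    if len(groups) != 2:
        raise ValueError("log_fold_change compares exactly two groups")
    if prior < 0:
        raise ValueError("prior must be >= 0")
    (name_a, samples_a), (name_b, samples_b) = groups.items()
    mean_a = counts[samples_a].mean(axis=1)
    mean_b = counts[samples_b].mean(axis=1)
    lfc = np.log2((mean_b + prior) / (mean_a + prior))
    lfc.name = f"logFC_{name_b}_vs_{name_a}"
    return lfc


def dge_table(
    counts: pd.DataFrame,
    groups: dict[str, list[str]],
    dispersion: float = DEFAULT_DISPERSION,
    prior: float = 0.5,
    p_thresh: float = 0.01,
    lfc_thresh: float = 2.0,
    equalize: bool = True,
) -> pd.DataFrame:
    """Exact test + logFC for every gene between two groups.

    Returns a frame with gene id index and columns comparison, logFC, p,
    direction.  Direction follows the strict decision rule (see
    :func:`call_degs`).
    """
    if len(groups) != 2:
        raise ValueError("dge_table compares exactly two groups")
    eq = equalize_library_sizes(counts) if equalize else counts
    (name_a, samples_a), (name_b, samples_b) = groups.items()
    sum_a = eq[samples_a].sum(axis=1)
    sum_b = eq[samples_b].sum(axis=1)
    pvals = [
        exact_test(int(sa), int(sb), len(samples_a), len(samples_b), dispersion)
        for sa, sb in zip(sum_a, sum_b)
    ]
    lfc = log_fold_change(eq, groups, prior=prior)
    out = pd.DataFrame(
        {
            "comparison": f"{name_a} vs {name_b}",
            "logFC": lfc.to_numpy(),
            "p": pvals,
        },
        index=eq.index,
    )
    out["direction"] = _directions(out["p"], out["logFC"], p_thresh, lfc_thresh)
    return out


def _directions(p: pd.Series, lfc: pd.Series, p_thresh: float, lfc_thresh: float) -> pd.Series:
    up = (p < p_thresh) & (lfc > lfc_thresh)
    down = (p < p_thresh) & (lfc < -lfc_thresh)
    return pd.Series(np.where(up, "up", np.where(down, "down", "ns")), index=p.index)


def call_degs(
    results: pd.DataFrame,
    p_thresh: float = 0.01,
    lfc_thresh: float = 2.0,
) -> dict[str, set[str]]:
    """Strict up/down calls: up iff p < p_thresh and logFC > lfc_thresh,
    down iff p < p_thresh and logFC < -lfc_thresh; everything else is ns."""
    direction = _directions(results["p"], results["logFC"], p_thresh, lfc_thresh)
    return {
        "up": set(results.index[direction == "up"]),
        "down": set(results.index[direction == "down"]),
    }


def deg_set_overlaps(named_sets: dict[str, set[str]]) -> dict[frozenset, int]:
    """Exclusive-intersection counts over named gene sets (UpSet-style).

    For every non-empty combination of set names, counts the genes belonging
    to exactly those sets; the counts sum to the size of the union.
    """
    if len(named_sets) < 2:
        raise ValueError("need >= 2 sets to intersect")
    names = sorted(named_sets)
    counts: dict[frozenset, int] = {}
    universe = set().union(*named_sets.values())
    for gene in universe:
        member = frozenset(n for n in names if gene in named_sets[n])
        counts[member] = counts.get(member, 0) + 1
    return counts


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail hypergeometric enrichment of one keyword in a gene set."""

    keyword: str
    k: int  # keyword genes in the set
    n: int  # set size
    K: int  # keyword genes in the universe
    N: int  # universe size
    p: float

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValueError("k cannot exceed min(n, K)")


def keyword_enrichment(
    gene_set: set[str],
    universe: set[str],
    keyword_map: pd.DataFrame,
) -> pd.DataFrame:
    """Hypergeometric over-representation of every keyword in ``gene_set``.

    ``keyword_map`` holds one row per (transcript_id, keyword) assignment.
    ``p = P(X >= k)`` for X ~ Hypergeom(N, K, n), evaluated through the
    log-space survival function.  Keywords absent from the universe are
    skipped with a warning.  Rows are sorted by ascending p then keyword.
    """
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    kw = keyword_map[keyword_map["transcript_id"].isin(universe)]
    rows = []
    n, N = len(gene_set), len(universe)
    for keyword, sub in kw.groupby("keyword", sort=True):
        carriers = set(sub["transcript_id"])
        K = len(carriers)
        if K == 0:
            continue
        k = len(carriers & gene_set)
        if k == 0:
            p = 1.0
        else:
            # P(X >= k): sum the upper-tail pmf terms in log space
            j = np.arange(k, min(n, K) + 1)
            p = float(np.exp(logsumexp(stats.hypergeom.logpmf(j, N, K, n))))
        rows.append(EnrichmentResult(keyword, k, n, K, N, min(1.0, p)))
    skipped = set(keyword_map["keyword"]) - {r.keyword for r in rows}
    if skipped:
        warnings.warn(f"keywords absent from the universe skipped: {sorted(skipped)}", stacklevel=2)
    out = pd.DataFrame([r.__dict__ for r in rows])
    if len(out):
        out = out.sort_values(["p", "keyword"]).reset_index(drop=True)
    return out
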