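"""Expression matrices: TPM normalization, filtering, log transform, replicate QC.

The quantitative input is a transcript x sample matrix of read counts together
with transcript lengths.  Counts are taken as given (quantification is upstream
of this package).  Abundances are expressed as transcripts per million (TPM):

    TPM_gs = (c_gs / l_g) / sum_j (c_js / l_j) * 1e6

so every sample column sums to one million.  Downstream correlation work uses
``log2(TPM + pseudocount)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "QCReport",
    "compute_tpm",
    "filter_low_expression",
    "log_transform",
    "replicate_qc",
]


@dataclass
class CountMatrix:
    """Integer read counts per transcript per sample, plus transcript lengths.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, transcripts as rows, samples as columns.
    lengths : pandas.Series
        Transcript length in nucleotides, indexed like ``counts``; all > 0.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate transcript ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("negative counts")
        if values.size and not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integral")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][0]
            raise ValueError(f"transcript {missing!r} has no length")
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise ValueError(f"transcript {bad!r} has non-positive length")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def compute_tpm(counts: CountMatrix) -> pd.DataFrame:
    """Length- and depth-normalize counts to transcripts per million.

    Every returned column sums to 1e6 (relative tolerance 1e-6).  Zero-length
    transcripts and all-zero sample columns are rejected with the offender
    named.
    """
    rate = counts.counts.div(counts.lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum[colsum <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has an all-zero count column")
    return rate.div(colsum, axis=1) * 1e6


def filter_low_expression(
    tpm: pd.DataFrame,
    threshold: float = 5.0,
    rule: str = "max",
    renormalize: bool = False,
) -> pd.DataFrame:
    """Drop weakly expressed transcripts (TPM filter, strictly greater than).

    ``rule`` decides which per-transcript statistic must exceed ``threshold``:
    ``max`` (default; keep anything well expressed somewhere), ``mean``, or
    ``all`` (every sample must exceed it).  By default retained TPM values keep
    their pre-filter meaning; ``renormalize=True`` rescales columns to 1e6.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if rule == "max":
        stat = tpm.max(axis=1)
    elif rule == "mean":
        stat = tpm.mean(axis=1)
    elif rule == "all":
        stat = tpm.min(axis=1)
    else:
        raise ValueError(f"unknown filter rule {rule!r}")
    kept = tpm.loc[stat > threshold]
    if kept.shape[0] == 0:
        warnings.warn("low-expression filter removed every transcript", stacklevel=2)
    if renormalize and kept.shape[0]:
        kept = kept.div(kept.sum(axis=0), axis=1) * 1e6
    return kept


def log_transform(tpm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Return ``log2(TPM + pseudocount)``; the pseudocount keeps it finite."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2(tpm + pseudocount)


@dataclass
class QCReport:
    """Within-tissue replicate agreement.

    ``pairs`` has one row per within-tissue replicate pair with both Spearman
    and Pearson correlations, the pass flag (rho strictly above threshold on
    the chosen method), and a reason when the coefficient is undefined.
    """

    pairs: pd.DataFrame
    method: str
    min_rho: float

    @property
    def all_pass(self) -> bool:
        return bool(self.pairs["pass"].all()) if len(self.pairs) else False


def replicate_qc(
    tpm: pd.DataFrame,
    meta: pd.DataFrame,
    method: str = "spearman",
    min_rho: float = 0.9,
) -> QCReport:
    """Correlate replicate pairs within each tissue and flag failures.

    ``meta`` needs ``sample_id`` and ``tissue`` columns covering the TPM
    samples.  A constant column leaves the coefficient undefined; the pair is
    reported as failed with a reason rather than raising.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    rows = []
    any_pair = False
    for tissue, sub in meta.groupby("tissue", sort=True):
        samples = [s for s in sub.index if s in tpm.columns]
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                any_pair = True
                a, b = tpm[samples[i]], tpm[samples[j]]
                reason = ""
                if a.nunique() <= 1 or b.nunique() <= 1:
                    rho_s = rho_p = np.nan
                    reason = "constant column"
                else:
                    rho_s = stats.spearmanr(a, b).statistic
                    rho_p = stats.pearsonr(a, b).statistic
                rho = rho_s if method == "spearman" else rho_p
                rows.append(
                    {
                        "tissue": tissue,
                        "sample_a": samples[i],
                        "sample_b": samples[j],
                        "spearman": rho_s,
                        "pearson": rho_p,
                        "pass": bool(rho > min_rho) if np.isfinite(rho) else False,
                        "reason": reason,
                    }
                )
    if not any_pair:
        raise ValueError("no tissue has >= 2 replicates; nothing to QC")
    return QCReport(pairs=pd.DataFrame(rows), method=method, min_rho=min_rho)
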