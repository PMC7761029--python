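"""Transcript redundancy compaction by greedy incremental clustering.

A merged multi-sample de novo assembly carries many redundant transcript
variants (fragments, near-copies).  After dropping weakly expressed
transcripts (TPM filter), sequences are clustered greedily, longest first:
each sequence joins the first existing representative it matches at
``min_identity`` over an alignment covering at least ``min_coverage`` of the
shorter sequence, else it founds its own cluster.  One consensus sequence per
cluster is then selected.  This is a CD-HIT-style re-statement of assembly
compaction with fully specified, deterministic rules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .exprmat import CountMatrix, compute_tpm, filter_low_expression
from .homology import ScoringScheme, align_pair, _check_sequence

__all__ = [
    "ClusterParams",
    "ClusterAssignment",
    "CompactionReport",
    "cluster_transcripts",
    "select_representatives",
    "compact_pipeline",
]


@dataclass(frozen=True)
class ClusterParams:
    """Greedy clustering thresholds.

    ``min_coverage`` is measured on the shorter sequence of a pair, as in
    coverage-of-the-shorter clustering modes.  ``kmer_size`` controls the
    exact-k-mer candidate pre-screen that bounds alignment cost; true
    redundancy partners share long exact stretches, so the screen does not
    change results on realistic inputs.
    """

    min_identity: float = 0.9
    min_coverage: float = 0.8
    kmer_size: int = 11

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.kmer_size < 4:
            raise ValueError("kmer_size must be >= 4")


@dataclass
class ClusterAssignment:
    """A partition of the input sequences into redundancy clusters."""

    representative_of: dict[str, str]
    clusters: dict[str, list[str]]
    params: ClusterParams

    def __post_init__(self) -> None:
        for rep, members in self.clusters.items():
            if self.representative_of.get(rep) != rep:
                raise ValueError(f"representative {rep!r} does not map to itself")
            for m in members:
                if self.representative_of.get(m) != rep:
                    raise ValueError(f"member {m!r} not mapped to {rep!r}")
        n = sum(len(m) for m in self.clusters.values())
        if n != len(self.representative_of):
            raise ValueError("clusters do not partition the input")


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def cluster_transcripts(
    seqs: dict[str, str],
    params: ClusterParams | None = None,
    scheme: ScoringScheme | None = None,
) -> ClusterAssignment:
    """Greedy incremental clustering, longest sequence first.

    Candidates are pre-screened for at least one shared exact k-mer; survivors
    are aligned locally and join the first (longest, earliest-founded)
    representative meeting both thresholds.  Ties in length are broken by
    lexicographic id, making the whole procedure deterministic.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    params = params or ClusterParams()
    scheme = scheme or ScoringScheme(mode="local")
    clean = {name: _check_sequence(repr(name), s) for name, s in seqs.items()}
    order = sorted(clean, key=lambda name: (-len(clean[name]), name))
    reps: list[str] = []
    rep_kmers: dict[str, set[str]] = {}
    representative_of: dict[str, str] = {}
    clusters: dict[str, list[str]] = {}
    for name in order:
        seq = clean[name]
        km = _kmers(seq, params.kmer_size)
        joined = None
        for rep in reps:
            if not (km & rep_kmers[rep]):
                continue
            res = align_pair(seq, clean[rep], scheme)
            if res.length == 0:
                continue
            identity = res.identities / res.length
            # coverage measured on the shorter sequence of the pair
            if len(seq) <= len(clean[rep]):
                shorter_cov = res.query_coverage
            else:
                shorter_cov = res.subject_coverage
            if identity >= params.min_identity and shorter_cov >= params.min_coverage:
                joined = rep
                break
        if joined is None:
            reps.append(name)
            rep_kmers[name] = km
            representative_of[name] = name
            clusters[name] = [name]
        else:
            representative_of[name] = joined
            clusters[joined].append(name)
    return ClusterAssignment(representative_of, clusters, params)


def select_representatives(
    assignment: ClusterAssignment,
    seqs: dict[str, str],
    tpm: pd.DataFrame | None = None,
) -> dict[str, str]:
    """One consensus sequence per cluster.

    The longest member wins; length ties go to the highest max-TPM member when
    a TPM table is supplied, then to the lexicographically smaller id.
    Members missing from the TPM table fall back to the length/id rule with a
    warning.
    """
    chosen: dict[str, str] = {}
    for rep in sorted(assignment.clusters):
        members = assignment.clusters[rep]
        max_tpm = {}
        for m in members:
            if tpm is not None:
                if m in tpm.index:
                    max_tpm[m] = float(tpm.loc[m].max())
                else:
                    warnings.warn(
                        f"member {m!r} missing from TPM table; using length rule",
                        stacklevel=2,
                    )
                    max_tpm[m] = -math.inf
            else:
                max_tpm[m] = 0.0
        winner = min(members, key=lambda m: (-len(seqs[m]), -max_tpm[m], m))
        chosen[winner] = seqs[winner]
    return dict(sorted(chosen.items()))


@dataclass
class CompactionReport:
    """Input/retained/cluster tallies for each compaction stage."""

    n_input: int
    n_after_tpm_filter: int
    n_clusters: int
    n_consensus: int
    table: pd.DataFrame  # member, representative per retained transcript


def compact_pipeline(
    seqs: dict[str, str],
    counts: CountMatrix,
    tpm_threshold: float = 5.0,
    params: ClusterParams | None = None,
    filter_rule: str = "max",
) -> tuple[dict[str, str], CompactionReport]:
    """Filter weakly expressed transcripts, cluster, and pick consensus.

    ``seqs`` and ``counts`` must describe the same transcript universe.
    """
    ids = set(seqs)
    missing = ids.symmetric_difference(counts.transcript_ids)
    if missing:
        raise ValueError(f"FASTA and count ids inconsistent, e.g. {sorted(missing)[:3]}")
    tpm = compute_tpm(counts)
    kept = filter_low_expression(tpm, threshold=tpm_threshold, rule=filter_rule)
    if kept.shape[0] == 0:
        raise ValueError("no transcripts retained by the TPM filter")
    retained = {name: seqs[name] for name in kept.index}
    assignment = cluster_transcripts(retained, params)
    consensus = select_representatives(assignment, retained, kept)
    table = pd.DataFrame(
        sorted(assignment.representative_of.items()),
        columns=["member", "representative"],
    )
    report = CompactionReport(
        n_input=len(seqs),
        n_after_tpm_filter=len(retained),
        n_clusters=len(assignment.clusters),
        n_consensus=len(consensus),
        table=table,
    )
    return consensus, report
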