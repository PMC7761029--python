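"""Pairwise alignment, percent identity, best hits, conservation tiers.

Bait (known pathway) genes are compared with assembled transcripts by optimal
affine-gap dynamic-programming alignment, nucleotide space only.  Ranking is
by raw DP score under a fixed scoring scheme, which is order-equivalent to a
bit score for a fixed scheme.  Best hits per bait feed a four-band
conservation tiering of percent identity (>=85, [78,85), [70,78), <70) that
mirrors the qualitative conservation groups seen across the target pathway.

The DP engine is Bio.Align.PairwiseAligner; ``N`` matches nothing (it is
scored and counted as a mismatch against every base, including itself).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "HomologyHit",
    "align_pair",
    "best_hits",
    "assign_conservation_tier",
    "conservation_summary",
    "reverse_complement",
]

_ALPHABET = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_sequence(name: str, seq: str) -> str:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    seq = seq.upper()
    if set(seq) - set(_ALPHABET):
        bad = sorted(set(seq) - set(_ALPHABET))
        raise ValueError(f"{name} sequence contains non-ACGTN symbols {bad}")
    return seq


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters (blastn-flavoured defaults).

    ``gap_open`` is the score of the first position of a gap and
    ``gap_extend`` of each subsequent position, so a length-L gap scores
    ``gap_open + (L - 1) * gap_extend``.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    mode: str = "local"

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.mode not in ("local", "global"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = scheme.mode
    matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            hit = a == b and a != "N"  # N matches nothing
            matrix[a, b] = scheme.match if hit else scheme.mismatch
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


@dataclass
class AlignmentResult:
    """Optimal pairwise alignment summary.

    ``length`` counts alignment columns (matches, mismatches and internal gap
    columns); ``identities`` counts identical non-N column pairs.  Coverages
    are the aligned span of each sequence divided by its full length.
    """

    score: float
    length: int
    identities: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    query_length: int
    subject_length: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identities / self.length if self.length else 0.0

    @property
    def query_coverage(self) -> float:
        return (self.query_end - self.query_start) / self.query_length

    @property
    def subject_coverage(self) -> float:
        return (self.subject_end - self.subject_start) / self.subject_length


def align_pair(a: str, b: str, scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal DP alignment of ``a`` (query) vs ``b`` (subject), one strand.

    Local mode clips to the best-scoring segment; global mode penalizes end
    gaps.  Among co-optimal alignments the aligner's first traceback is
    summarized (the score is unique).
    """
    scheme = scheme or ScoringScheme()
    a = _check_sequence("query", a)
    b = _check_sequence("subject", b)
    aligner = _make_aligner(scheme)
    if scheme.mode == "local" and aligner.score(a, b) <= 0:
        # nothing aligns better than the empty local segment
        return AlignmentResult(0.0, 0, 0, 0, 0, 0, 0, len(a), len(b))
    alignment = next(iter(aligner.align(a, b)))
    qblocks, sblocks = alignment.aligned
    identities = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        aligned_cols += qe - qs
        for x, y in zip(a[qs:qe], b[ss:se]):
            if x == y and x != "N":
                identities += 1
    if len(qblocks):
        q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
        s0, s1 = int(sblocks[0][0]), int(sblocks[-1][1])
    else:  # empty local alignment (all-mismatch pair)
        q0 = q1 = s0 = s1 = 0
    if scheme.mode == "global":
        # end gaps are part of a global alignment's columns
        q0, q1, s0, s1 = 0, len(a), 0, len(b)
    length = (q1 - q0) + (s1 - s0) - aligned_cols
    return AlignmentResult(
        score=float(alignment.score),
        length=int(length),
        identities=int(identities),
        query_start=q0,
        query_end=q1,
        subject_start=s0,
        subject_end=s1,
        query_length=len(a),
        subject_length=len(b),
    )


@dataclass
class HomologyHit:
    """Best scoring transcript for one bait, or a ``no hit`` placeholder."""

    query: str
    subject: str | None
    score: float
    length: int
    identities: int
    percent_identity: float
    coverage: float
    strand: str
    tier: int | None

    @property
    def is_hit(self) -> bool:
        return self.subject is not None


def assign_conservation_tier(percent_identity: float) -> int:
    """Map percent identity to the four conservation bands.

    Tier 1: >= 85; tier 2: [78, 85); tier 3: [70, 78); tier 4: < 70.
    Boundaries are half-open, upper band inclusive.
    """
    if not 0.0 <= percent_identity <= 100.0:
        raise ValueError(f"percent identity {percent_identity} outside [0, 100]")
    if percent_identity >= 85.0:
        return 1
    if percent_identity >= 78.0:
        return 2
    if percent_identity >= 70.0:
        return 3
    return 4


def best_hits(
    baits: dict[str, str],
    transcripts: dict[str, str],
    scheme: ScoringScheme | None = None,
    min_score: float = 50.0,
    min_aln_len: int | None = None,
    both_strands: bool = True,
) -> list[HomologyHit]:
    """Best-scoring transcript per bait.

    Each bait is aligned to every transcript (both strands by default since
    assembled transcripts have arbitrary orientation).  Ties on raw score are
    broken by higher percent identity, then lexicographic subject id.  Hits
    below ``min_score`` (or shorter than ``min_aln_len``) are reported as
    "no hit" placeholders rather than dropped.
    """
    if not baits or not transcripts:
        raise ValueError("need at least one bait and one transcript")
    scheme = scheme or ScoringScheme()
    hits = []
    for bait_id in baits:
        best: tuple | None = None
        for subject_id in sorted(transcripts):
            for strand in ("+", "-") if both_strands else ("+",):
                seq = transcripts[subject_id]
                if strand == "-":
                    seq = reverse_complement(seq)
                res = align_pair(baits[bait_id], seq, scheme)
                cand = (res.score, res.percent_identity, subject_id, strand, res)
                if best is None:
                    best = cand
                    continue
                # higher score, then higher identity, then smaller subject id,
                # then forward strand
                if (cand[0], cand[1]) != (best[0], best[1]):
                    if (cand[0], cand[1]) > (best[0], best[1]):
                        best = cand
                elif cand[2] < best[2]:
                    best = cand
        score, pid, subject_id, strand, res = best
        too_short = min_aln_len is not None and res.length < min_aln_len
        if score < min_score or too_short:
            hits.append(
                HomologyHit(bait_id, None, score, res.length, res.identities, pid, 0.0, strand, None)
            )
        else:
            hits.append(
                HomologyHit(
                    query=bait_id,
                    subject=subject_id,
                    score=score,
                    length=res.length,
                    identities=res.identities,
                    percent_identity=pid,
                    coverage=res.subject_coverage,
                    strand=strand,
                    tier=assign_conservation_tier(pid),
                )
            )
    return hits


def conservation_summary(hits: list[HomologyHit], group_map: dict[str, str]) -> pd.DataFrame:
    """Mean best-hit percent identity per pathway branch.

    Baits without a hit are excluded from the mean and counted separately;
    a branch with only no-hit baits gets NA.
    """
    missing = [h.query for h in hits if h.query not in group_map]
    if missing:
        raise ValueError(f"baits without a branch assignment: {missing}")
    rows = []
    branches = sorted(set(group_map.values()))
    for branch in branches:
        members = [h for h in hits if group_map[h.query] == branch]
        with_hit = [h for h in members if h.is_hit]
        rows.append(
            {
                "branch": branch,
                "n_baits": len(members),
                "n_hits": len(with_hit),
                "n_no_hit": len(members) - len(with_hit),
                "mean_percent_identity": (
                    float(np.mean([h.percent_identity for h in with_hit])) if with_hit else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("branch")


def hits_table(hits: list[HomologyHit]) -> pd.DataFrame:
    """Hits as a TSV-ready table (bait, subject, score, aln_len, pct_id, ...)."""
    return pd.DataFrame(
        [
            {
                "bait": h.query,
                "subject": h.subject if h.is_hit else "no_hit",
                "score": h.score,
                "aln_len": h.length,
                "pct_id": round(h.percent_identity, 3),
                "coverage": round(h.coverage, 4),
                "strand": h.strand,
                "tier": h.tier if h.is_hit else "NA",
            }
            for h in hits
        ]
    )
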