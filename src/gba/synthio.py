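"""Seeded synthetic datasets with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a 4-tissue x 2-replicate bulk RNA-seq design with negative-binomial
counts at a common dispersion (default 0.168531, i.e. BCV 0.41), planted
co-expression modules with tissue-specific activity, planted differential
expression, redundant transcript variants for compaction, bait homologs at
controlled percent identity, and a keyword table with one enriched keyword.

Expression model
----------------
Every gene g gets a baseline proportion drawn log-normally.  Genes belong
either to one of the planted modules -- each active in a distinct pair of
tissues, where the gene's proportion is multiplied by ``module_fold`` -- or
to one of the background expression programs: binary tissue-activity
archetypes over the tissue subsets *not* used by any module, with per-gene
fold drawn log-normally around ``module_fold``.  Real bulk transcriptomes
over a handful of organs are pervasively modular (organ-specific gene
batteries); an unstructured background would be the one pathological case
for mutual-rank statistics.  Proportions are renormalized per sample and
counts drawn NB(mean = library_size * proportion, dispersion phi).

Module 0 is the "pathway" module, active in the young aerial parts (YL, YS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .exprmat import CountMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_expression_dataset",
    "generate_sequence_fixtures",
    "generate_annotations",
    "simulate_dataset",
    "write_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    Expression defaults follow the emulated design: 2000 genes, 5 planted
    modules of 50 genes, 4 tissues x 2 replicates, NB dispersion 0.168531,
    module fold 8, 5e6 reads per sample.
    """

    n_genes: int = 2000
    n_modules: int = 5
    module_size: int = 50
    tissues: tuple[str, ...] = ("YL", "YS", "OL", "AR")
    replicates_per_tissue: int = 2
    library_size: int = 5_000_000
    dispersion: float = 0.168531
    module_fold: float = 8.0
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    background_fold_sd: float = 0.2  # ln-scale spread of background program folds
    seed: int = 42
    # sequence fixtures
    n_baits: int = 3
    bait_length: int = 1200
    identity_targets: tuple[float, ...] = (0.95, 0.85, 0.75)
    n_redundancy_groups: int = 5
    redundancy_group_size: int = 4
    redundancy_coverage: float = 0.85
    background_seq_length: int = 1000
    # annotations
    keyword: str = "alkaloid biosynthesis"
    keyword_module: int = 0
    keyword_module_fraction: float = 0.8
    keyword_background_rate: float = 0.05
    n_background_keywords: int = 10

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "replicates_per_tissue": self.replicates_per_tissue,
            "library_size": self.library_size,
            "bait_length": self.bait_length,
            "background_seq_length": self.background_seq_length,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not self.tissues:
            raise ValueError("need at least one tissue")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("duplicate tissue labels")
        if self.n_modules < 0 or self.module_size < 0:
            raise ValueError("module counts must be >= 0")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError(
                f"module overcommit: {self.n_modules} x {self.module_size} genes "
                f"exceed n_genes = {self.n_genes}"
            )
        if self.n_modules > 0 and len(self.tissues) >= 2:
            if self.n_modules > len(list(combinations(self.tissues, 2))):
                raise ValueError("more modules than distinct tissue-pair activity patterns")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.module_fold < 1:
            raise ValueError("module_fold must be >= 1")
        for t in self.identity_targets:
            if not 0.0 < t <= 1.0:
                raise ValueError(f"identity target {t} outside (0, 1]")
        if self.n_baits > len(self.identity_targets):
            raise ValueError("need one identity target per bait")
        for name in ("keyword_module_fraction", "keyword_background_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.redundancy_coverage <= 1.0:
            raise ValueError("redundancy_coverage must be in (0, 1]")
        seq_genes = (
            self.n_redundancy_groups * self.redundancy_group_size + self.n_baits
        )
        if self.n_modules * self.module_size + seq_genes > self.n_genes:
            raise ValueError("sequence fixture roles overcommit the background genes")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{t}{r + 1}" for t in self.tissues for r in range(self.replicates_per_tissue)
        ]


def _module_patterns(tissues: tuple[str, ...], n_modules: int) -> list[tuple[str, ...]]:
    """Distinct tissue-pair activity patterns; module 0 pairs the first two
    tissues (the young aerial parts under the default labels)."""
    T = len(tissues)
    if n_modules == 0:
        return []
    if T == 1:
        return [(tissues[0],)] * n_modules
    pairs = list(combinations(range(T), 2))
    if T == 4:
        # prioritize balanced coverage of tissues across modules
        priority = [(0, 1), (2, 3), (0, 2), (1, 2), (0, 3), (1, 3)]
        pairs = priority
    return [tuple(tissues[i] for i in pairs[m]) for m in range(n_modules)]


def _background_programs(
    tissues: tuple[str, ...], used: list[tuple[str, ...]]
) -> list[tuple[str, ...]]:
    """Binary tissue-activity archetypes not claimed by a planted module."""
    subsets = [
        s
        for k in range(1, len(tissues))
        for s in combinations(tissues, k)
        if s not in used
    ]
    return subsets or [tuple(tissues)]


@dataclass
class SyntheticTruth:
    """Ground truth against which recovery is measured.

    ``planted_degs`` maps an ordered tissue pair (a, b) to the set of
    (gene, direction) pairs, direction "up" meaning higher in b.
    ``redundancy_groups`` maps each representative to all member ids
    (representative included).  Extra diagnostic fields record the background
    program of every unplanted gene and the expected per-tissue NB mean.
    """

    module_of: dict[str, int | None]
    activity: dict[int, dict[str, bool]]
    planted_degs: dict[tuple[str, str], set[tuple[str, str]]] = field(default_factory=dict)
    redundancy_groups: dict[str, list[str]] = field(default_factory=dict)
    identity_targets: dict[tuple[str, str], float] = field(default_factory=dict)
    enriched_keyword: str | None = None
    background_program_of: dict[str, tuple[str, ...]] = field(default_factory=dict)
    expected_mean: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for (ta, tb), pairs in self.planted_degs.items():
            for gene, _direction in pairs:
                m = self.module_of.get(gene)
                if m is None:
                    raise ValueError(f"planted DEG {gene!r} is not a module gene")
                if self.activity[m][ta] == self.activity[m][tb]:
                    raise ValueError(
                        f"planted DEG {gene!r}: module {m} activity equal in {ta}/{tb}"
                    )
        for t in self.identity_targets.values():
            if not 0.0 < t <= 1.0:
                raise ValueError(f"identity target {t} outside (0, 1]")

    def to_dict(self) -> dict:
        return {
            "module_of": self.module_of,
            "activity": {str(m): act for m, act in self.activity.items()},
            "planted_degs": {
                f"{ta}|{tb}": sorted(list(p) for p in pairs)
                for (ta, tb), pairs in self.planted_degs.items()
            },
            "redundancy_groups": self.redundancy_groups,
            "identity_targets": {f"{b}|{g}": t for (b, g), t in self.identity_targets.items()},
            "enriched_keyword": self.enriched_keyword,
            "background_program_of": {
                g: list(p) for g, p in self.background_program_of.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            module_of={g: (None if m is None else int(m)) for g, m in d["module_of"].items()},
            activity={int(m): act for m, act in d["activity"].items()},
            planted_degs={
                tuple(key.split("|")): {(g, direction) for g, direction in pairs}
                for key, pairs in d["planted_degs"].items()
            },
            redundancy_groups=d["redundancy_groups"],
            identity_targets={
                tuple(key.split("|")): float(t) for key, t in d["identity_targets"].items()
            },
            enriched_keyword=d.get("enriched_keyword"),
            background_program_of={
                g: tuple(p) for g, p in d.get("background_program_of", {}).items()
            },
        )


def generate_expression_dataset(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw the count matrix, sample metadata and ground truth.

    Deterministic given ``config`` (all randomness flows from ``config.seed``
    through a generator-specific stream).
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = config.gene_ids
    n = config.n_genes
    tissues = config.tissues
    patterns = _module_patterns(tissues, config.n_modules)
    module_of = np.full(n, -1)
    for m in range(config.n_modules):
        module_of[m * config.module_size : (m + 1) * config.module_size] = m
    bg_idx = np.where(module_of < 0)[0]
    programs = _background_programs(tissues, patterns)
    prog_of = rng.integers(0, len(programs), bg_idx.size)
    bg_fold = np.exp(
        rng.normal(np.log(config.module_fold), config.background_fold_sd, bg_idx.size)
    )
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)
    lengths = rng.integers(600, 3001, n)

    activity = {
        m: {t: t in patterns[m] for t in tissues} for m in range(config.n_modules)
    }
    expected = np.zeros((n, len(tissues)))
    counts = np.zeros((n, len(config.sample_ids)), dtype=np.int64)
    for ti, t in enumerate(tissues):
        prop = baseline.copy()
        for m in range(config.n_modules):
            if activity[m][t]:
                prop[module_of == m] *= config.module_fold
        active_bg = np.array([t in programs[p] for p in prog_of])
        prop[bg_idx[active_bg]] *= bg_fold[active_bg]
        prop /= prop.sum()
        mu = prop * config.library_size
        expected[:, ti] = mu
        for r in range(config.replicates_per_tissue):
            col = ti * config.replicates_per_tissue + r
            if config.dispersion > 0:
                shape = 1.0 / config.dispersion
                counts[:, col] = rng.negative_binomial(shape, shape / (shape + mu))
            else:
                counts[:, col] = rng.poisson(mu)

    planted: dict[tuple[str, str], set[tuple[str, str]]] = {}
    if config.module_fold > 1:
        for ta, tb in combinations(tissues, 2):
            pairs: set[tuple[str, str]] = set()
            for m in range(config.n_modules):
                if activity[m][ta] == activity[m][tb]:
                    continue
                direction = "up" if activity[m][tb] else "down"
                for gi in np.where(module_of == m)[0]:
                    pairs.add((genes[gi], direction))
            if pairs:
                planted[(ta, tb)] = pairs

    truth = SyntheticTruth(
        module_of={g: (int(module_of[i]) if module_of[i] >= 0 else None) for i, g in enumerate(genes)},
        activity=activity,
        planted_degs=planted,
        background_program_of={genes[gi]: programs[p] for gi, p in zip(bg_idx, prog_of)},
        expected_mean=pd.DataFrame(expected, index=genes, columns=list(tissues)),
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=config.sample_ids),
        lengths=pd.Series(lengths, index=genes, name="length"),
    )
    meta = pd.DataFrame(
        {
            "sample_id": config.sample_ids,
            "tissue": [t for t in tissues for _ in range(config.replicates_per_tissue)],
            "replicate": [
                r + 1 for _ in tissues for r in range(config.replicates_per_tissue)
            ],
        }
    )
    return cm, meta, truth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Point-substitute at ``rate`` (uniform positions, always to a new base)."""
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    for i in np.where(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def generate_sequence_fixtures(
    config: SimConfig, truth: SyntheticTruth
) -> tuple[dict[str, str], dict[str, str], SyntheticTruth]:
    """Emit transcript and bait FASTA contents; update the ground truth.

    Non-module gene ids are assigned, in id order: redundancy groups (the
    first id of each group is the representative, kept longest), bait-homolog
    carriers (one per bait, point-mutated at 1 - target identity,
    substitutions only), then unrelated random background.  Module genes get
    unrelated random sequences.
    """
    rng = np.random.default_rng([config.seed, 2])
    genes = sorted(truth.module_of)
    background = [g for g in genes if truth.module_of[g] is None]
    transcripts: dict[str, str] = {}
    cursor = 0
    for _ in range(config.n_redundancy_groups):
        group = background[cursor : cursor + config.redundancy_group_size]
        cursor += config.redundancy_group_size
        rep = group[0]
        rep_seq = _random_seq(rng, config.background_seq_length)
        transcripts[rep] = rep_seq
        for member in group[1:]:
            frac = rng.uniform(config.redundancy_coverage, 0.98)
            length = max(1, int(round(frac * len(rep_seq))))
            start = rng.integers(0, len(rep_seq) - length + 1)
            frag = rep_seq[start : start + length]
            frag = _mutate(rng, frag, 0.01)
            if rng.random() < 0.5 and len(frag) > 10:  # small internal deletion
                cut = rng.integers(1, len(frag) - 4)
                frag = frag[:cut] + frag[cut + 3 :]
            transcripts[member] = frag
        truth.redundancy_groups[rep] = list(group)
    baits: dict[str, str] = {}
    for b in range(config.n_baits):
        target = config.identity_targets[b]
        if not 0.0 < target <= 1.0:
            raise ValueError(f"identity target {target} outside (0, 1]")
        bait_id = f"bait{b:02d}"
        carrier = background[cursor]
        cursor += 1
        bait_seq = _random_seq(rng, config.bait_length)
        baits[bait_id] = bait_seq
        transcripts[carrier] = _mutate(rng, bait_seq, 1.0 - target)
        truth.identity_targets[(bait_id, carrier)] = target
    for g in genes:
        if g not in transcripts:
            transcripts[g] = _random_seq(rng, config.background_seq_length)
    transcripts = {g: transcripts[g] for g in genes}
    return transcripts, baits, truth


def generate_annotations(truth: SyntheticTruth, config: SimConfig) -> pd.DataFrame:
    """Keyword table with one keyword enriched in the designated module.

    The planted keyword hits ``keyword_module_fraction`` of the designated
    module's genes in expectation and ``keyword_background_rate`` elsewhere;
    ``n_background_keywords`` generic keywords are assigned at the background
    rate everywhere.  One row per (transcript_id, keyword).
    """
    if config.keyword_module not in truth.activity:
        raise ValueError(
            f"designated module {config.keyword_module} absent from the truth"
        )
    rng = np.random.default_rng([config.seed, 3])
    genes = sorted(truth.module_of)
    in_module = np.array(
        [truth.module_of[g] == config.keyword_module for g in genes]
    )
    p = np.where(
        in_module, config.keyword_module_fraction, config.keyword_background_rate
    )
    rows = []
    hit = rng.random(len(genes)) < p
    for g, h in zip(genes, hit):
        if h:
            rows.append({"transcript_id": g, "keyword": config.keyword})
    for k in range(config.n_background_keywords):
        hit = rng.random(len(genes)) < config.keyword_background_rate
        for g, h in zip(genes, hit):
            if h:
                rows.append({"transcript_id": g, "keyword": f"kw{k:02d}"})
    truth.enriched_keyword = config.keyword
    out = pd.DataFrame(rows, columns=["transcript_id", "keyword"])
    return out.sort_values(["transcript_id", "keyword"]).reset_index(drop=True)


@dataclass
class SyntheticDataset:
    """Everything one synthetic study produces, ready to analyse or write."""

    config: SimConfig
    counts: CountMatrix
    meta: pd.DataFrame
    truth: SyntheticTruth
    transcripts: dict[str, str]
    baits: dict[str, str]
    keywords: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Run all generators and reconcile transcript lengths with sequences."""
    cm, meta, truth = generate_expression_dataset(config)
    transcripts, baits, truth = generate_sequence_fixtures(config, truth)
    lengths = pd.Series({g: len(s) for g, s in transcripts.items()}, name="length")
    cm = CountMatrix(counts=cm.counts, lengths=lengths.reindex(cm.counts.index))
    if config.n_modules > 0:
        keywords = generate_annotations(truth, config)
    else:
        keywords = pd.DataFrame(columns=["transcript_id", "keyword"])
    return SyntheticDataset(config, cm, meta, truth, transcripts, baits, keywords)


def write_fixture(dataset: SyntheticDataset, out_dir: str | Path, overwrite: bool = False) -> None:
    """Write counts.tsv, lengths.tsv, samples.tsv, transcripts.fasta,
    baits.fasta, keywords.tsv and truth.json; round-trips through gba.io."""
    if dataset.counts.counts.size == 0:
        raise ValueError("refusing to write an empty dataset")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = [
        "counts.tsv",
        "lengths.tsv",
        "samples.tsv",
        "transcripts.fasta",
        "baits.fasta",
        "keywords.tsv",
        "truth.json",
    ]
    existing = [n for n in names if (out / n).exists()]
    if existing and not overwrite:
        raise FileExistsError(f"refusing to overwrite {existing} (pass overwrite=True)")
    gio.write_counts(dataset.counts, out / "counts.tsv", out / "lengths.tsv")
    gio.write_samples(dataset.meta, out / "samples.tsv")
    gio.write_fasta(dataset.transcripts, out / "transcripts.fasta")
    gio.write_fasta(dataset.baits, out / "baits.fasta")
    gio.write_keywords(dataset.keywords, out / "keywords.tsv")
    gio.write_json(dataset.truth.to_dict(), out / "truth.json")
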