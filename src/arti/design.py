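"""Guide design: bias matrices, candidate enumeration, scoring, selection.

The design space is the set of concrete 22-mers conforming to the degenerate
base-composition matrix.  Candidates are scored for predicted efficacy (the
default scorer is a position-frequency-matrix log-odds score; published
linear-model predictors such as DSIR can be plugged in via ``scorer``),
screened for extended-seed off-targets, and the top N survivors selected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqcore import DegenerateMatrix, NucSeq, SeedSpec, matches_matrix, revcomp, subseq

__all__ = [
    "PositionFrequencyMatrix",
    "DesignConfig",
    "GuideRecord",
    "build_bias_matrix",
    "triplet_start_frequency",
    "enumerate_candidates",
    "score_candidate",
    "make_guide_record",
    "select_top",
]

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position relative base frequencies of an aligned guide set."""

    freq: pd.DataFrame  # index = 1-based position, columns = A,C,G,T

    def __post_init__(self) -> None:
        f = self.freq
        if list(f.columns) != list(BASES):
            raise ValueError(f"columns must be {BASES}")
        if (f.values < 0).any():
            raise ValueError("negative frequency")
        sums = f.sum(axis=1).values
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-position frequencies must sum to 1")

    @property
    def length(self) -> int:
        return len(self.freq)

    def to_tsv(self, path) -> None:
        self.freq.to_csv(path, sep="\t", index_label="position")

    @classmethod
    def from_tsv(cls, path) -> "PositionFrequencyMatrix":
        df = pd.read_csv(path, sep="\t", index_col="position")
        return cls(df[list(BASES)])


def build_bias_matrix(guides: Sequence[NucSeq | str]) -> PositionFrequencyMatrix:
    """Count per-position base frequencies over an equal-length guide set.

    This is how design criteria are derived from a pool of top-scoring
    guides: the position biases of the pool become the pattern.
    """
    if not guides:
        raise ValueError("need at least one guide")
    seqs = [g.bases if isinstance(g, NucSeq) else str(NucSeq(g)) for g in guides]
    length = len(seqs[0])
    for i, s in enumerate(seqs):
        if len(s) != length:
            raise ValueError(
                f"guide #{i + 1} has length {len(s)}, expected {length} ({s})"
            )
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), length)
    counts = np.stack([(arr == b.encode()).sum(axis=0) for b in BASES], axis=1)
    freq = counts / len(seqs)
    df = pd.DataFrame(freq, columns=list(BASES), index=pd.RangeIndex(1, length + 1))
    return PositionFrequencyMatrix(df)


def triplet_start_frequency(seeds: Sequence[NucSeq | str]) -> pd.Series:
    """Fraction of seeds starting with each 5' triplet, descending.

    Used to quantify seed-start biases of a low-off-target seed universe
    (e.g. how often TCG or CGC leads the seed).  Fractions sum to 1 over
    observed triplets.
    """
    if not seeds:
        raise ValueError("empty seed set")
    starts = []
    for s in seeds:
        bases = s.bases if isinstance(s, NucSeq) else str(NucSeq(s))
        if len(bases) < 3:
            raise ValueError(f"seed {bases!r} shorter than 3 nt")
        starts.append(bases[:3])
    frac = pd.Series(starts).value_counts(normalize=True)
    frac.index.name = "triplet"
    frac.name = "fraction"
    return frac


def enumerate_candidates(
    m: DegenerateMatrix, cap: int = 10**7
) -> list[NucSeq]:
    """All concrete sequences matching the degenerate pattern.

    Deterministic lexicographic order.  Rejects expansions above ``cap``
    (the ARTi matrix expands to 2^5 * 4^3 * 3^2 = 18,432).
    """
    n = m.n_candidates
    if n > cap:
        raise ValueError(f"pattern expands to {n} sequences, above cap {cap}")
    choices = [sorted(s) for s in m.allowed]
    return [NucSeq("".join(t)) for t in itertools.product(*choices)]


def score_candidate(
    guide: NucSeq | str,
    pfm: PositionFrequencyMatrix,
    pseudocount: float = 0.01,
) -> float:
    """PFM log-odds efficacy score: sum over positions of
    ``log((freq + pc) / (0.25 + pc))``.

    Additive per position, zero for a uniform PFM, maximal for the
    consensus.  Stands behind the pluggable scorer interface.
    """
    g = guide if isinstance(guide, NucSeq) else NucSeq(guide)
    if len(g) != pfm.length:
        raise ValueError(f"guide length {len(g)} != matrix length {pfm.length}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    f = pfm.freq.values
    cols = {b: j for j, b in enumerate(BASES)}
    return float(
        sum(
            np.log((f[i, cols[b]] + pseudocount) / (0.25 + pseudocount))
            for i, b in enumerate(g.bases)
        )
    )


@dataclass(frozen=True)
class GuideRecord:
    """A 22-nt guide with its derived target site, seeds, score and flags."""

    guide: NucSeq
    target_site: NucSeq
    seed: NucSeq
    extended_seed: NucSeq
    efficacy_score: float = float("nan")
    seed_offtarget_score: float = float("nan")
    passes_matrix: bool = False
    passes_extended_seed_filter: bool = True
    name: str | None = None

    def __post_init__(self) -> None:
        if self.target_site.bases != revcomp(self.guide).bases:
            raise ValueError("target_site must be revcomp(guide)")


def make_guide_record(
    guide: NucSeq | str,
    matrix: DegenerateMatrix | None = None,
    spec: SeedSpec = SeedSpec(),
    name: str | None = None,
) -> GuideRecord:
    """Derive target site, seed and extended seed from a guide strand."""
    g = guide if isinstance(guide, NucSeq) else NucSeq(guide)
    return GuideRecord(
        guide=g,
        target_site=revcomp(g),
        seed=subseq(g, *spec.seed_span),
        extended_seed=subseq(g, *spec.extended_span),
        passes_matrix=matches_matrix(g, matrix) if matrix is not None else True,
        name=name,
    )


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the enumerate → score → filter → select pipeline.

    ``score_threshold`` mirrors the "keep only top-scoring predictions"
    cut applied with an external predictor (the published workflow used a
    DSIR score > 105); with the default log-odds scorer no cut is applied
    unless set.  ``position20_rule`` requires G/C at guide position 20 —
    redundant for the built-in matrix (position 20 is fixed G) but
    meaningful for user-supplied matrices: an A/U 5' end on the passenger
    strand would make it RISC-loadable.
    """

    matrix: DegenerateMatrix = field(default_factory=DegenerateMatrix.arti)
    score_threshold: float | None = None
    n_select: int = 6
    position20_rule: bool = True
    seed_spec: SeedSpec = SeedSpec()
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


def select_top(
    candidates: Iterable[GuideRecord],
    cfg: DesignConfig,
) -> tuple[list[GuideRecord], bool]:
    """The n_select highest-scoring candidates passing every filter.

    Filters: matrix conformity, extended-seed elimination flag, optional
    score threshold, optional position-20 G/C rule.  Deterministic
    tie-break: score descending, then lexicographic guide.  Returns
    ``(selected, short)`` where ``short`` flags fewer survivors than
    requested.
    """
    survivors = []
    for rec in candidates:
        if not rec.passes_matrix:
            continue
        if not rec.passes_extended_seed_filter:
            continue
        if cfg.score_threshold is not None and not (
            rec.efficacy_score > cfg.score_threshold
        ):
            continue
        if cfg.position20_rule and len(rec.guide) >= 20:
            if rec.guide.bases[19] not in "GC":
                continue
        survivors.append(rec)
    survivors.sort(key=lambda r: (-r.efficacy_score, r.guide.bases))
    selected = survivors[: cfg.n_select]
    return selected, len(selected) < cfg.n_select


def records_to_frame(records: Sequence[GuideRecord]) -> pd.DataFrame:
    """Tabular view of guide records for TSV export."""
    return pd.DataFrame(
        {
            "id": [r.name or f"guide{i + 1}" for i, r in enumerate(records)],
            "guide": [r.guide.bases for r in records],
            "target_site": [r.target_site.bases for r in records],
            "seed": [r.seed.bases for r in records],
            "extended_seed": [r.extended_seed.bases for r in records],
            "efficacy_score": [r.efficacy_score for r in records],
            "seed_offtarget_score": [r.seed_offtarget_score for r in records],
            "passes_matrix": [r.passes_matrix for r in records],
            "passes_extended_seed_filter": [
                r.passes_extended_seed_filter for r in records
            ],
        }
    )
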