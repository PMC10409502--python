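"""Synthetic fixtures with known ground truth.

Desk-scale stand-ins for the external inputs of the design workflow: random
transcriptomes with planted seed-match motifs, seed universes with planted
5'-triplet mixtures, and flow-style event tables with a known residual
expression.  Background bases are i.i.d. at a stated GC content — adequate
for exact-match screens, not a model of real transcriptome composition.
All generators are bit-reproducible under a fixed ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqcore import NucSeq

__all__ = [
    "DEFAULT_SEED",
    "SyntheticSpec",
    "generate_transcriptome",
    "generate_seed_universe",
    "generate_events",
    "generate_de_table",
]

#: Suite-wide default seed; any integer is accepted.
DEFAULT_SEED = 20230808

BASES = np.array(list("ACGT"))


def _random_bases(rng: np.random.Generator, n: int, gc_content: float) -> str:
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    return "".join(rng.choice(BASES, size=n, p=[p_at, p_gc, p_gc, p_at]))


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic transcriptome.

    ``planted_motifs`` lists (motif, copies, record_indices); each copy is
    inserted intact (overwriting background) at a position drawn within a
    listed record, and all positions are reported as ground truth.
    """

    rng_seed: int = DEFAULT_SEED
    n_records: int = 20
    record_length: int = 500
    gc_content: float = 0.5
    planted_motifs: tuple[tuple[str, int, tuple[int, ...]], ...] = ()

    def __post_init__(self) -> None:
        if self.n_records < 1 or self.record_length < 1:
            raise ValueError("need n_records >= 1 and record_length >= 1")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        for motif, copies, which in self.planted_motifs:
            if len(motif) > self.record_length:
                raise ValueError(
                    f"motif {motif!r} longer than record_length {self.record_length}"
                )
            if copies < 1 or not which:
                raise ValueError("each planted motif needs copies >= 1 and target records")
            if any(not (0 <= i < self.n_records) for i in which):
                raise ValueError("planted motif record index out of range")


def generate_transcriptome(
    spec: SyntheticSpec,
) -> tuple[list[NucSeq], pd.DataFrame]:
    """Random transcripts plus a ground-truth manifest of planted sites.

    The manifest has one row per planted copy: motif, record index, record
    name, 0-based start.  Later plantings may overwrite earlier ones only
    if spans collide; spans are drawn without overlap within a record.
    """
    rng = np.random.default_rng(spec.rng_seed)
    seqs = [
        list(_random_bases(rng, spec.record_length, spec.gc_content))
        for _ in range(spec.n_records)
    ]
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(spec.n_records)}
    rows = []
    for motif, copies, which in spec.planted_motifs:
        m = len(motif)
        for c in range(copies):
            ridx = int(which[c % len(which)])
            for _ in range(1000):
                start = int(rng.integers(0, spec.record_length - m + 1))
                if all(
                    start + m <= lo or start >= hi for lo, hi in occupied[ridx]
                ):
                    break
            else:
                raise ValueError(f"could not place motif {motif!r} in record {ridx}")
            occupied[ridx].append((start, start + m))
            seqs[ridx][start : start + m] = list(motif)
            rows.append(
                {"motif": motif, "record_index": ridx,
                 "record": f"tx{ridx + 1}", "start": start}
            )
    records = [
        NucSeq("".join(s), name=f"tx{i + 1}") for i, s in enumerate(seqs)
    ]
    manifest = pd.DataFrame(rows, columns=["motif", "record_index", "record", "start"])
    return records, manifest


def generate_seed_universe(
    n: int,
    triplet_mix: dict[str, float] | None = None,
    rng_seed: int = DEFAULT_SEED,
    seed_length: int = 7,
) -> list[NucSeq]:
    """Random seeds whose 5' triplets follow a planted mixture.

    ``triplet_mix`` maps triplets to fractions summing to <= 1; the
    remaining mass is spread uniformly over the *other* 5' triplets, so the
    expected planted fraction equals the mixture exactly.  The tail of each
    seed is uniform.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(triplet_mix or {})
    for t, f in mix.items():
        if len(t) != 3 or f < 0:
            raise ValueError(f"invalid mixture entry {t!r}: {f}")
    total = sum(mix.values())
    if total > 1.0 + 1e-9:
        raise ValueError(f"mixture fractions sum to {total} > 1")
    rng = np.random.default_rng(rng_seed)
    triplets = list(mix)
    probs = list(mix.values()) + [max(0.0, 1.0 - total)]
    choices = rng.choice(len(triplets) + 1, size=n, p=np.array(probs) / sum(probs))
    listed = set(triplets)
    seeds = []
    for c in choices:
        if c < len(triplets):
            head = triplets[c]
        else:
            while True:
                head = "".join(rng.choice(BASES, size=3))
                if head not in listed:
                    break
        tail = "".join(rng.choice(BASES, size=seed_length - 3))
        seeds.append(NucSeq(head + tail))
    return seeds


def generate_events(
    n: int,
    true_residual: float,
    marker_fraction: float = 0.5,
    noise_cv: float = 0.3,
    baseline: float = 1000.0,
    rng_seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Flow-style event table with a known residual reporter expression.

    Marker-negative reporter signals are lognormal around ``baseline``;
    marker-positive around ``baseline * true_residual``.  The knockdown
    estimator recovers 1 - true_residual up to Monte-Carlo error.
    """
    if n < 2:
        raise ValueError("need n >= 2 events")
    if not (0.0 < marker_fraction < 1.0):
        raise ValueError("marker_fraction must be in (0, 1)")
    if true_residual < 0:
        raise ValueError("true_residual must be >= 0")
    if noise_cv <= 0 or baseline <= 0:
        raise ValueError("noise_cv and baseline must be > 0")
    rng = np.random.default_rng(rng_seed)
    pos = rng.random(n) < marker_fraction
    # lognormal with unit mean: exp(N(-sigma^2/2, sigma^2))
    sigma = np.sqrt(np.log1p(noise_cv**2))
    noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n)
    mean_level = np.where(pos, baseline * true_residual, baseline)
    reporter = mean_level * noise
    marker = np.where(pos, 1.0, 0.0) * baseline * rng.lognormal(
        -sigma**2 / 2.0, sigma, size=n
    )
    return pd.DataFrame(
        {"reporter": reporter, "marker": marker, "marker_positive": pos}
    )


def generate_de_table(
    n_genes: int,
    n_up: int,
    n_down: int,
    lfc_cut: float = 2.0,
    p_cut: float = 5.0,
    rng_seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """DE-result table with exactly ``n_up``/``n_down`` planted passing genes.

    Null genes get |log2FC| < lfc_cut or -log10 p < p_cut, so the filter's
    ground truth is exact by construction.
    """
    if n_up + n_down > n_genes:
        raise ValueError("more planted genes than rows")
    rng = np.random.default_rng(rng_seed)
    lfc = rng.uniform(-lfc_cut * 0.9, lfc_cut * 0.9, size=n_genes)
    p = rng.uniform(0.0, p_cut * 4.0, size=n_genes)
    idx = rng.permutation(n_genes)
    up, down = idx[:n_up], idx[n_up : n_up + n_down]
    lfc[up] = rng.uniform(lfc_cut, lfc_cut * 3, size=n_up)
    lfc[down] = -rng.uniform(lfc_cut, lfc_cut * 3, size=n_down)
    p[np.concatenate([up, down])] = rng.uniform(p_cut, p_cut * 3, size=n_up + n_down)
    return pd.DataFrame(
        {
            "gene": [f"g{i + 1}" for i in range(n_genes)],
            "log2fc": lfc,
            "neg_log10_p": p,
        }
    )
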