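"""Seed-level off-target screening against a transcriptome or 3'-UTR set.

A guide silences transcripts carrying the reverse complement of its seed
region, so the k-mer index built over transcript *sense* strands is queried
with ``revcomp(seed)``.  Two screens are provided:

* extended-seed elimination — any guide whose extended seed (guide
  positions 2-14) has a perfect 13-mer complement anywhere in the
  transcriptome is discarded;
* a seed off-target potential score — the count of 7-mer seed-complement
  sites across an indexed 3'-UTR set, normalised per sequence.  This is a
  hit-count analogue of published seed-centric potentials (POTS-like, not
  per-site-weighted POTS).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .seqcore import DNA_ALPHABET, NucSeq, SeedSpec, revcomp, subseq

__all__ = [
    "TranscriptomeIndex",
    "SeedOfftargetScore",
    "build_index",
    "extended_seed_has_match",
    "seed_offtarget_score",
    "seed_percentiles",
]


@dataclass(frozen=True)
class TranscriptomeIndex:
    """Exact k-mer occurrence counts over a set of sequences.

    Overlapping occurrences are counted; windows containing any non-ACGT
    character (e.g. N in a transcript) are skipped, so an ambiguous base can
    never create a "perfect match".
    """

    k: int
    counts: dict[str, int]
    n_sequences: int
    source_label: str = ""

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.counts

    def count(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)

    @property
    def total_windows(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            sorted(self.counts.items()), columns=["kmer", "count"]
        )
        df.to_csv(path, sep="\t", index=False)


def build_index(
    records: Iterable[NucSeq], k: int, source_label: str = ""
) -> TranscriptomeIndex:
    """Index every valid k-window of the records' sense strands."""
    if k < 1:
        raise ValueError("k must be >= 1")
    records = list(records)
    if not records:
        raise ValueError("no records to index")
    counts: Counter[str] = Counter()
    n = 0
    for rec in records:
        n += 1
        s = rec.bases
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= DNA_ALPHABET:
                counts[w] += 1
    if not counts:
        warnings.warn(f"k={k} longer than every record; index is empty")
    return TranscriptomeIndex(k=k, counts=dict(counts), n_sequences=n,
                              source_label=source_label)


def extended_seed_has_match(
    guide: NucSeq | str,
    idx: TranscriptomeIndex,
    spec: SeedSpec = SeedSpec(),
    both_orientations: bool = False,
) -> bool:
    """Does the guide's extended seed have a perfect transcriptome match?

    Queries the index with the reverse complement of the extended seed
    (the target-strand text a silenced transcript would carry).  With
    ``both_orientations`` the guide-strand text itself is also queried.
    Guides returning True are eliminated upstream.
    """
    if idx.k != spec.extended_length:
        raise ValueError(
            f"index k={idx.k} does not match extended-seed length "
            f"{spec.extended_length}"
        )
    ext = subseq(guide, *spec.extended_span)
    if revcomp(ext).bases in idx:
        return True
    if both_orientations and ext.bases in idx:
        return True
    return False


@dataclass(frozen=True)
class SeedOfftargetScore:
    """Seed-complement site burden of one guide seed in a 3'-UTR set."""

    seed: NucSeq
    complement_hits: int
    normalized_score: float
    percentile: float | None = None


def seed_offtarget_score(
    guide_or_seed: NucSeq | str,
    utr_idx: TranscriptomeIndex,
    spec: SeedSpec = SeedSpec(),
) -> SeedOfftargetScore:
    """Count seed-complement sites in the indexed 3'-UTR set.

    Accepts a full guide (seed extracted per ``spec``) or a bare seed of
    the seed length.  ``normalized_score`` is hits per indexed sequence.
    """
    s = guide_or_seed if isinstance(guide_or_seed, NucSeq) else NucSeq(guide_or_seed)
    if len(s) == spec.seed_length:
        seed = s
    else:
        seed = subseq(s, *spec.seed_span)
    if utr_idx.k != spec.seed_length:
        raise ValueError(
            f"index k={utr_idx.k} does not match seed length {spec.seed_length}"
        )
    hits = utr_idx.count(revcomp(seed).bases)
    return SeedOfftargetScore(
        seed=seed,
        complement_hits=hits,
        normalized_score=hits / utr_idx.n_sequences,
    )


def seed_percentiles(
    seed_universe: Sequence[NucSeq | str],
    utr_idx: TranscriptomeIndex,
    spec: SeedSpec = SeedSpec(),
) -> pd.DataFrame:
    """Percentile-rank a universe of seeds by seed-complement hit count.

    Ascending mean-rank convention: percentile = 100 * (rank - 0.5) / n,
    ties sharing the mean rank.  "Lowest predicted off-target activity
    (top 1%)" therefore means percentile <= 1.
    """
    if len(seed_universe) == 0:
        raise ValueError("empty seed universe")
    seeds = [
        s if isinstance(s, NucSeq) else NucSeq(s) for s in seed_universe
    ]
    hits = [seed_offtarget_score(s, utr_idx, spec).complement_hits for s in seeds]
    ser = pd.Series(hits, dtype=float)
    pct = 100.0 * (ser.rank(method="average") - 0.5) / len(ser)
    return pd.DataFrame(
        {
            "seed": [s.bases for s in seeds],
            "complement_hits": hits,
            "percentile": pct.values,
        }
    )
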