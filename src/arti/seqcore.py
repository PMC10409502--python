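"""Nucleotide-sequence primitives shared by the whole package.

Sequences are stored as DNA (``T``, never ``U``) even though shRNA guides are
RNA — every oligo a user orders or clones is DNA.  Coordinates throughout the
package are 1-based and inclusive on both ends, matching the field's
"guide positions 2-8" convention for seed regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucSeq",
    "DegenerateMatrix",
    "SeedSpec",
    "revcomp",
    "matches_matrix",
    "subseq",
    "read_fasta",
    "write_fasta",
]

DNA_ALPHABET = frozenset("ACGT")

#: IUPAC nucleotide ambiguity codes mapped to their concrete-base sets.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _normalize(bases: str) -> str:
    return bases.upper().replace("U", "T")


@dataclass(frozen=True)
class NucSeq:
    """A validated DNA sequence with an optional identifier.

    Input is uppercased and ``U`` is normalised to ``T``.  Any character
    outside {A, C, G, T} is rejected with its (1-based) position.
    """

    bases: str
    name: str | None = None

    def __post_init__(self) -> None:
        norm = _normalize(self.bases)
        if not norm:
            raise ValueError("empty sequence")
        for i, b in enumerate(norm, start=1):
            if b not in DNA_ALPHABET:
                raise ValueError(
                    f"non-DNA character {b!r} at position {i}"
                    + (f" in {self.name!r}" if self.name else "")
                )
        object.__setattr__(self, "bases", norm)

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def gc_count(self) -> int:
        return self.bases.count("G") + self.bases.count("C")

    @classmethod
    def transcript(cls, bases: str, name: str | None = None) -> "NucSeq":
        """A transcript-style sequence that may carry N (ambiguous) bases.

        N windows are skipped during k-mer indexing, so an N can never
        create a perfect seed match.
        """
        norm = _normalize(bases)
        if not norm:
            raise ValueError("empty sequence")
        for i, b in enumerate(norm, start=1):
            if b not in DNA_ALPHABET | {"N"}:
                raise ValueError(f"non-nucleotide character {b!r} at position {i}")
        obj = object.__new__(cls)
        object.__setattr__(obj, "bases", norm)
        object.__setattr__(obj, "name", name)
        return obj


#: The 22-position degenerate base-composition pattern for ARTi guide design.
#: Positions 1-4 are fixed TTCG (low-off-target seed start), positions 5-7 and
#: 13-14 are biased to A/T to preserve 5'-3' duplex asymmetry, and the 3' half
#: carries fixed efficacy-associated bases, with G fixed at position 20 so the
#: passenger strand cannot be RISC-loaded.
ARTI_PATTERN = "TTCGWWWNNAHHWWCATCCGGN"


@dataclass(frozen=True)
class DegenerateMatrix:
    """An IUPAC degenerate pattern with per-position allowed-base sets."""

    pattern: str
    allowed: tuple[frozenset[str], ...] = field(init=False)

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if not pat:
            raise ValueError("empty pattern")
        try:
            allowed = tuple(IUPAC_CODES[c] for c in pat)
        except KeyError as exc:
            raise ValueError(f"invalid IUPAC code {exc.args[0]!r} in pattern") from None
        object.__setattr__(self, "pattern", pat)
        object.__setattr__(self, "allowed", allowed)

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def n_candidates(self) -> int:
        """Size of the concrete sequence space (product of degeneracies)."""
        n = 1
        for s in self.allowed:
            n *= len(s)
        return n

    @classmethod
    def arti(cls) -> "DegenerateMatrix":
        """The built-in 22-nt ARTi design matrix."""
        return cls(ARTI_PATTERN)


@dataclass(frozen=True)
class SeedSpec:
    """Seed and extended-seed intervals on the guide, 1-based inclusive.

    The seed (default guide positions 2-8) is the principal determinant of
    miRNA-like off-target repression; a perfect transcriptome match to the
    extended seed (default positions 2-14) is grounds for elimination.
    """

    seed_span: tuple[int, int] = (2, 8)
    extended_span: tuple[int, int] = (2, 14)

    def __post_init__(self) -> None:
        for lo, hi in (self.seed_span, self.extended_span):
            if not (1 <= lo <= hi <= 22):
                raise ValueError(f"span {lo}-{hi} outside [1, 22]")
        if not (
            self.extended_span[0] <= self.seed_span[0]
            and self.seed_span[1] <= self.extended_span[1]
        ):
            raise ValueError("seed span must lie within the extended span")

    @property
    def seed_length(self) -> int:
        return self.seed_span[1] - self.seed_span[0] + 1

    @property
    def extended_length(self) -> int:
        return self.extended_span[1] - self.extended_span[0] + 1


def revcomp(seq: NucSeq | str) -> NucSeq:
    """Reverse complement.  An involution: ``revcomp(revcomp(s)) == s``."""
    s = seq if isinstance(seq, NucSeq) else NucSeq(seq)
    return NucSeq(s.bases.translate(_COMPLEMENT)[::-1], name=s.name)


def matches_matrix(seq: NucSeq | str, m: DegenerateMatrix) -> bool:
    """True iff ``seq`` has the pattern's length and every base is allowed
    at its position.  Length mismatch is simply ``False``, not an error."""
    bases = seq.bases if isinstance(seq, NucSeq) else _normalize(seq)
    if len(bases) != len(m.pattern):
        return False
    return all(b in allowed for b, allowed in zip(bases, m.allowed))


def subseq(seq: NucSeq | str, start: int, end: int) -> NucSeq:
    """1-based inclusive substring: ``subseq("TTCGA", 2, 4) == "TCG"``."""
    s = seq if isinstance(seq, NucSeq) else NucSeq(seq)
    if start < 1:
        raise ValueError(f"start {start} below lower bound 1")
    if end > len(s):
        raise ValueError(f"end {end} beyond sequence length {len(s)}")
    if start > end:
        raise ValueError(f"empty span {start}-{end}")
    return NucSeq(s.bases[start - 1 : end])


def read_fasta(path, allow_n: bool = True) -> list[NucSeq]:
    """Read a multi-record FASTA into validated :class:`NucSeq` records.

    Lowercase is uppercased and U normalised to T.  ``N`` characters are
    tolerated in transcriptome input when ``allow_n`` (they are stored but
    never match a concrete base during k-mer indexing); any other
    non-nucleotide character is rejected.  Duplicate IDs are kept (the
    caller is warned via a ``UserWarning``).
    """
    import warnings

    records: list[NucSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        bases = _normalize(str(rec.seq))
        ok = DNA_ALPHABET | {"N"} if allow_n else DNA_ALPHABET
        for i, b in enumerate(bases, start=1):
            if b not in ok:
                raise ValueError(
                    f"record {rec.id!r}: non-nucleotide character {b!r} at position {i}"
                )
        if rec.id in seen:
            warnings.warn(f"duplicate FASTA id {rec.id!r}; keeping both")
        seen.add(rec.id)
        if allow_n and "N" in bases:
            ns = NucSeq.transcript(bases, rec.id)
        else:
            ns = NucSeq(bases, name=rec.id)
        records.append(ns)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path, width: int = 80) -> None:
    """Write records as wrapped FASTA (read∘write is the identity)."""
    seqrecords = [
        SeqRecord(Seq(r.bases), id=r.name or f"seq{i + 1}", description="")
        for i, r in enumerate(records)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)
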