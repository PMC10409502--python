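"""miR-E construct grammar: 97-mer oligos and target-site cassettes.

A miR-E cloning oligo is 97 nt: 5' flank (18) + sense (22) + loop (19) +
guide (22) + 3' flank (16).  The sense strand is the reverse complement of
the guide with position 1 replaced by C — a convention validated against
all six published ARTi oligos (see ``ARTI_GUIDES``), under which the oligo
always reads ...GAGCGC after the flank.

Target-site cassettes make any transgene or endogenous transcript
ARTi-repressible: concatenated 22-nt target sites are inserted either
in-frame immediately before the stop codon (prefix-padded with 'A' to a
multiple of 3) or unpadded into the 3'-UTR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .seqcore import NucSeq, revcomp

__all__ = [
    "MIR_E_FLANK5",
    "MIR_E_LOOP",
    "MIR_E_FLANK3",
    "ARTI_GUIDES",
    "Construct97",
    "Cassette",
    "assemble_97mer",
    "parse_97mer",
    "target_site_of",
    "build_cds_cassette",
    "build_utr_cassette",
]

MIR_E_FLANK5 = "TGCTGTTGACAGTGAGCG"
MIR_E_LOOP = "TAGTGAAGCCACAGATGTA"
MIR_E_FLANK3 = "TGCCTACTGCCTCGGA"

#: The six validated ARTi guide strands, keyed by their published names.
#: Target sites are the reverse complements of these guides.
ARTI_GUIDES: dict[str, str] = {
    "ARTi.6588": "TTCGATATAAACTTCATCCGGA",
    "ARTi.6570": "TTCGATAACAATATCATCCGGA",
    "ARTi.6634": "TTCGATTAAAACATCATCCGGA",
    "ARTi.6786": "TTCGTATACAATATCATCCGGA",
    "ARTi.6834": "TTCGTATGCAATATCATCCGGA",
    "ARTi.6516": "TTCGAATTAAACTTCATCCGGA",
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class Construct97:
    """Five-part decomposition of a miR-E 97-mer oligo."""

    flank5: NucSeq
    sense: NucSeq
    loop: NucSeq
    guide: NucSeq
    flank3: NucSeq

    @property
    def oligo(self) -> NucSeq:
        return NucSeq(
            self.flank5.bases
            + self.sense.bases
            + self.loop.bases
            + self.guide.bases
            + self.flank3.bases,
            name=self.guide.name,
        )

    @property
    def target_site(self) -> NucSeq:
        return revcomp(self.guide)


def target_site_of(guide: NucSeq | str) -> NucSeq:
    """The 22-nt site a guide silences: its reverse complement."""
    g = guide if isinstance(guide, NucSeq) else NucSeq(guide)
    if len(g) != 22:
        raise ValueError(f"guide must be 22 nt, got {len(g)}")
    return revcomp(g)


def _sense_of(guide: NucSeq) -> NucSeq:
    rc = revcomp(guide).bases
    return NucSeq("C" + rc[1:])


def assemble_97mer(guide: NucSeq | str, name: str | None = None) -> Construct97:
    """Build the miR-E 97-mer cloning oligo for a 22-nt guide."""
    g = guide if isinstance(guide, NucSeq) else NucSeq(guide)
    if len(g) != 22:
        raise ValueError(f"guide must be 22 nt, got {len(g)}")
    if name is not None:
        g = NucSeq(g.bases, name=name)
    return Construct97(
        flank5=NucSeq(MIR_E_FLANK5),
        sense=_sense_of(g),
        loop=NucSeq(MIR_E_LOOP),
        guide=g,
        flank3=NucSeq(MIR_E_FLANK3),
    )


class FlankMismatch(ValueError):
    """A 97-mer whose fixed miR-E segments do not match the canonical strings."""

    def __init__(self, mismatches: list[str]):
        self.mismatches = mismatches
        super().__init__(
            "not a miR-E 97-mer; mismatched segment(s): " + ", ".join(mismatches)
        )


def parse_97mer(oligo: NucSeq | str, strict: bool = True) -> Construct97:
    """Decompose a 97-nt oligo into its five miR-E parts.

    Validates the three fixed segments against the canonical miR-E strings
    and the sense strand against the position-1→C rule; ``strict=False``
    returns the decomposition with mismatches unraised (for reporting).
    """
    o = oligo if isinstance(oligo, NucSeq) else NucSeq(oligo)
    if len(o) != 97:
        raise ValueError(f"miR-E oligo must be 97 nt, got {len(o)}")
    s = o.bases
    parts = Construct97(
        flank5=NucSeq(s[:18]),
        sense=NucSeq(s[18:40]),
        loop=NucSeq(s[40:59]),
        guide=NucSeq(s[59:81], name=o.name),
        flank3=NucSeq(s[81:]),
    )
    mismatches = []
    if parts.flank5.bases != MIR_E_FLANK5:
        mismatches.append("flank5")
    if parts.loop.bases != MIR_E_LOOP:
        mismatches.append("loop")
    if parts.flank3.bases != MIR_E_FLANK3:
        mismatches.append("flank3")
    if parts.sense.bases != _sense_of(parts.guide).bases:
        mismatches.append("sense")
    if strict and mismatches:
        raise FlankMismatch(mismatches)
    return parts


@dataclass(frozen=True)
class Cassette:
    """A concatenation of target sites ready for insertion."""

    kind: str  # "cds_in_frame" | "utr"
    sites: tuple[NucSeq, ...]
    pad: str
    stop_codons_in_frame: tuple[str, ...] = ()

    @property
    def sequence(self) -> NucSeq:
        return NucSeq(self.pad + "".join(s.bases for s in self.sites))


def _frame1_stops(seq: str) -> tuple[str, ...]:
    return tuple(
        seq[i : i + 3]
        for i in range(0, len(seq) - 2, 3)
        if seq[i : i + 3] in STOP_CODONS
    )


def build_cds_cassette(sites: Sequence[NucSeq | str]) -> Cassette:
    """In-frame cassette for insertion before a stop codon.

    Prefix-pads with the fewest 'A' bases needed to make the total length
    divisible by 3 (two 22-nt sites → pad "A", 45 nt).  Any stop codon in
    reading frame 1 of the padded cassette is recorded (a warning for the
    caller, not an error).
    """
    if not sites:
        raise ValueError("need at least one target site")
    tsites = tuple(s if isinstance(s, NucSeq) else NucSeq(s) for s in sites)
    total = sum(len(s) for s in tsites)
    pad = "A" * (-total % 3)
    seq = pad + "".join(s.bases for s in tsites)
    return Cassette(
        kind="cds_in_frame",
        sites=tsites,
        pad=pad,
        stop_codons_in_frame=_frame1_stops(seq),
    )


def build_utr_cassette(sites: Sequence[NucSeq | str]) -> Cassette:
    """Plain concatenation for insertion after a stop codon (3'-UTR)."""
    if not sites:
        raise ValueError("need at least one target site")
    tsites = tuple(s if isinstance(s, NucSeq) else NucSeq(s) for s in sites)
    return Cassette(kind="utr", sites=tsites, pad="")
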