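"""End-to-end guide design: enumerate → score → screen → select → assemble.

The single entry point behind the ``arti design`` command and the worked
examples: expand the degenerate matrix, score every candidate, eliminate
candidates whose extended seed has a perfect transcriptome match, rank the
survivors and assemble cloning oligos for the top N.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .assembly import ARTI_GUIDES, Construct97, assemble_97mer
from .design import (
    DesignConfig,
    GuideRecord,
    PositionFrequencyMatrix,
    build_bias_matrix,
    enumerate_candidates,
    make_guide_record,
    records_to_frame,
    score_candidate,
    select_top,
)
from .offtarget import TranscriptomeIndex, extended_seed_has_match
from .seqcore import NucSeq

__all__ = ["DesignResult", "design_guides", "reference_pfm"]


def reference_pfm() -> PositionFrequencyMatrix:
    """Position bias matrix of the six validated ARTi guides.

    The default efficacy scorer ranks candidates by similarity to this
    pool.  Any PFM derived from a user's own top-scoring guide set (or an
    external predictor altogether) can be used instead.
    """
    return build_bias_matrix([NucSeq(g) for g in ARTI_GUIDES.values()])


@dataclass(frozen=True)
class DesignResult:
    """Everything a design run produces."""

    candidates: list[GuideRecord]
    survivors: list[GuideRecord]
    selected: list[GuideRecord]
    constructs: list[Construct97]
    short: bool  # fewer survivors than requested

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def n_eliminated(self) -> int:
        return len(self.candidates) - len(self.survivors)

    def to_frame(self) -> pd.DataFrame:
        df = records_to_frame(self.selected)
        df["oligo_97mer"] = [c.oligo.bases for c in self.constructs]
        return df


def design_guides(
    cfg: DesignConfig = DesignConfig(),
    transcriptome_index: TranscriptomeIndex | None = None,
    pfm: PositionFrequencyMatrix | None = None,
    scorer=None,
    both_orientations: bool = False,
) -> DesignResult:
    """Run the full design pipeline.

    With no transcriptome index, no candidate is eliminated (an empty
    screen).  ``scorer`` maps a guide to a float; the default is the PFM
    log-odds score against ``pfm`` (falling back to the built-in
    reference pool).
    """
    if len(cfg.matrix) != 22:
        raise ValueError(
            f"design matrix is {len(cfg.matrix)} nt: candidates cannot form "
            "22-nt guides for miR-E 97-mer assembly"
        )
    if scorer is None:
        the_pfm = pfm if pfm is not None else reference_pfm()

        def scorer(g: NucSeq) -> float:
            return score_candidate(g, the_pfm, cfg.pseudocount)

    records = []
    for cand in enumerate_candidates(cfg.matrix):
        rec = make_guide_record(cand, matrix=cfg.matrix, spec=cfg.seed_spec)
        eliminated = transcriptome_index is not None and extended_seed_has_match(
            cand, transcriptome_index, cfg.seed_spec, both_orientations
        )
        records.append(
            replace(
                rec,
                efficacy_score=scorer(cand),
                passes_extended_seed_filter=not eliminated,
            )
        )
    survivors = [
        r for r in records if r.passes_matrix and r.passes_extended_seed_filter
    ]
    selected, short = select_top(records, cfg)
    constructs = [assemble_97mer(r.guide) for r in selected]
    return DesignResult(
        candidates=records,
        survivors=survivors,
        selected=selected,
        constructs=constructs,
        short=short,
    )
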