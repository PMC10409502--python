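"""Assay quantification: reporter knockdown, DE filter counts, tumor volume.

Knockdown is read out with a two-colour reporter assay: a GFP transgene
carries the shRNA target sites in its 3'-UTR, and the shRNA is co-expressed
with an mCherry marker.  Knockdown efficiency is 1 minus the ratio of mean
GFP in marker-positive (shRNA-expressing) cells over marker-negative cells,
normalised to a neutral control hairpin (Ren.713, against Renilla
luciferase).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFilterConfig",
    "KnockdownResult",
    "validate_event_table",
    "reporter_ratio",
    "knockdown_efficiency",
    "count_deregulated",
    "tumor_volume",
]

EVENT_COLUMNS = ("reporter", "marker", "marker_positive")


def validate_event_table(events: pd.DataFrame) -> pd.DataFrame:
    """Check a flow-style event table: reporter/marker signals plus a
    boolean marker-positive gate, with both gate classes present."""
    missing = [c for c in ("reporter", "marker_positive") if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing column(s): {missing}")
    if (events["reporter"] < 0).any():
        raise ValueError("negative reporter signal")
    pos = events["marker_positive"].astype(bool)
    if not pos.any() or pos.all():
        raise ValueError(
            "need at least one marker-positive and one marker-negative event"
        )
    return events


def reporter_ratio(events: pd.DataFrame) -> float:
    """Mean reporter signal in marker-positive over marker-negative events
    — the residual reporter expression r (1 = no knockdown)."""
    validate_event_table(events)
    pos = events["marker_positive"].astype(bool)
    mean_neg = events.loc[~pos, "reporter"].mean()
    if mean_neg <= 0:
        raise ValueError("mean marker-negative reporter signal must be > 0")
    return float(events.loc[pos, "reporter"].mean() / mean_neg)


@dataclass(frozen=True)
class KnockdownResult:
    raw_kd: float
    normalized_kd: float
    ratio: float
    control_ratio: float

    @property
    def negative_kd(self) -> bool:
        """Flag: marker-positive cells showed *more* reporter signal."""
        return self.raw_kd < 0


def knockdown_efficiency(
    events: pd.DataFrame, control: pd.DataFrame
) -> KnockdownResult:
    """Raw and control-normalised knockdown efficiency.

    raw_kd = 1 - r with r = mean(reporter | marker+) / mean(reporter | marker-);
    normalized_kd = 1 - r / r_control, the residual-expression ratio against
    the neutral-control table.  r > 1 (negative knockdown) is reported, not
    rejected.
    """
    r = reporter_ratio(events)
    r_ctrl = reporter_ratio(control)
    if r_ctrl <= 0:
        raise ValueError("control ratio must be > 0")
    return KnockdownResult(
        raw_kd=1.0 - r,
        normalized_kd=1.0 - r / r_ctrl,
        ratio=r,
        control_ratio=r_ctrl,
    )


@dataclass(frozen=True)
class DEFilterConfig:
    """Thresholds for calling genes de-regulated from a DE result table.

    Defaults: |log2 fold-change| >= 2 and -log10 p >= 5.  ``literal_down``
    applies the down filter as log2FC <= +2 (so "down" would include
    unchanged genes) instead of the symmetric <= -2 reading.
    """

    lfc_up: float = 2.0
    lfc_down: float = -2.0
    neg_log10_p: float = 5.0
    literal_down: bool = False

    def __post_init__(self) -> None:
        if self.neg_log10_p < 0:
            raise ValueError("neg_log10_p must be >= 0")


def count_deregulated(
    de_table: pd.DataFrame, cfg: DEFilterConfig = DEFilterConfig()
) -> tuple[int, int]:
    """(n_up, n_down) passing the fold-change and significance filters.

    Expects columns ``log2fc`` and ``neg_log10_p``; each gene counts at
    most once per direction.
    """
    for c in ("log2fc", "neg_log10_p"):
        if c not in de_table.columns:
            raise ValueError(f"DE table missing column {c!r}")
    vals = de_table[["log2fc", "neg_log10_p"]].astype(float)
    if not np.isfinite(vals.values).all():
        raise ValueError("non-finite value in DE table")
    sig = vals["neg_log10_p"] >= cfg.neg_log10_p
    n_up = int((sig & (vals["log2fc"] >= cfg.lfc_up)).sum())
    down_cut = 2.0 if cfg.literal_down else cfg.lfc_down
    n_down = int((sig & (vals["log2fc"] <= down_cut)).sum())
    return n_up, n_down


def tumor_volume(length: float, diameter: float) -> float:
    """Caliper tumor volume in mm^3: length * diameter^2 * pi / 6."""
    if length < 0 or diameter < 0:
        raise ValueError("length and diameter must be non-negative")
    return length * diameter**2 * math.pi / 6.0
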