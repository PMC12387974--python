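"""Categorical tissue maps and wound-bed composition summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: palette indices for categorical tissue grids
TISSUE_OTHER, TISSUE_SLOUGH, TISSUE_NECROSIS = 0, 1, 2
TISSUE_LABELS = {TISSUE_OTHER: "other", TISSUE_SLOUGH: "slough",
                 TISSUE_NECROSIS: "necrosis"}


@dataclass
class TissueMap:
    """Per-pixel tissue classes {other, slough, necrosis} inside a wound.

    Slough/necrosis labels are only valid inside the associated wound
    mask; anything outside the mask is forced to "other".
    """

    labels: np.ndarray       # (H, W) uint8 in {0, 1, 2}
    wound_mask: np.ndarray   # (H, W) bool

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.wound_mask = np.asarray(self.wound_mask, dtype=bool)
        if self.labels.shape != self.wound_mask.shape:
            raise ValueError("labels and wound mask shapes differ")
        if not np.isin(self.labels, [0, 1, 2]).all():
            raise ValueError("tissue labels must be in {0, 1, 2}")
        self.labels = np.where(self.wound_mask, self.labels, 0).astype(np.uint8)


@dataclass(frozen=True)
class TissueFractions:
    """Composition of the wound bed, in percent of wound pixels."""

    slough_pct: float
    necrosis_pct: float
    wound_pixels: int


def tissue_fractions(t: TissueMap) -> TissueFractions:
    """Percentage of wound-bed pixels labelled slough / necrosis.

    An empty wound mask yields (0, 0) with wound_pixels = 0.
    """
    n = int(t.wound_mask.sum())
    if n == 0:
        return TissueFractions(0.0, 0.0, 0)
    inside = t.labels[t.wound_mask]
    return TissueFractions(
        slough_pct=100.0 * float((inside == TISSUE_SLOUGH).sum()) / n,
        necrosis_pct=100.0 * float((inside == TISSUE_NECROSIS).sum()) / n,
        wound_pixels=n,
    )


def presence_call(f: TissueFractions, threshold_pct: float = 1.0):
    """Binary presence flags for slough and necrosis.

    A tissue counts as present when its wound-bed percentage strictly
    exceeds threshold_pct (default 1%: trace fractions of a percent are
    treated as segmentation noise, not clinical presence).
    """
    return {"slough_present": f.slough_pct > threshold_pct,
            "necrosis_present": f.necrosis_pct > threshold_pct}
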