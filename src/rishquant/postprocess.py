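"""Post-processing of probability maps and dot counting.

A sigmoid probability map is thresholded into a binary mask, cleaned by
binary morphology (default: opening with a 3x3 square, the standard
despeckle), and dots are counted as connected components above a minimum
area. Per-sample quantities are arithmetic means of per-field counts.
Merged/touching dots are not split (no watershed); overlapping signals
count as one, a known limitation of connected-component counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "MorphConfig",
    "binarize",
    "morph_clean",
    "count_dots",
    "quantify_sample",
    "quantify_counts",
]


@dataclass(frozen=True)
class MorphConfig:
    """Binarization, morphology and counting parameters."""

    operation_sequence: tuple[str, ...] = ("erode", "dilate")
    structuring_element: int = 3  # square side, px
    iterations: int = 1
    binarize_threshold: float = 0.5
    min_dot_area: int = 2  # px
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.min_dot_area < 1:
            raise ValueError("min_dot_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        bad = set(self.operation_sequence) - {"erode", "dilate"}
        if bad:
            raise ValueError(f"unknown morphological operation(s): {sorted(bad)}")


def binarize(prob: np.ndarray, cfg: MorphConfig | None = None) -> np.ndarray:
    """Threshold a [0, 1] probability map into a 0/1 mask."""
    cfg = cfg or MorphConfig()
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map must lie in [0, 1]")
    return (prob >= cfg.binarize_threshold).astype(np.uint8)


def morph_clean(mask: np.ndarray, cfg: MorphConfig | None = None) -> np.ndarray:
    """Apply the configured erode/dilate sequence (default = opening)."""
    cfg = cfg or MorphConfig()
    m = np.asarray(mask).astype(bool)
    selem = np.ones((cfg.structuring_element,) * 2, dtype=bool)
    for op in cfg.operation_sequence:
        if op == "erode":
            m = ndimage.binary_erosion(m, structure=selem, iterations=cfg.iterations)
        else:
            m = ndimage.binary_dilation(m, structure=selem, iterations=cfg.iterations)
    return m.astype(np.uint8)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def count_dots(mask: np.ndarray, cfg: MorphConfig | None = None) -> int:
    """Count connected components with area >= min_dot_area."""
    cfg = cfg or MorphConfig()
    labeled, n = ndimage.label(np.asarray(mask) > 0, structure=_structure(cfg.connectivity))
    if n == 0:
        return 0
    areas = np.bincount(labeled.ravel())[1:]
    return int(np.count_nonzero(areas >= cfg.min_dot_area))


def quantify_sample(records: pd.DataFrame) -> pd.Series:
    """Mean per-field blue/red counts for one sample's count records."""
    if records.empty:
        raise ValueError("no field records for sample")
    return pd.Series(
        {
            "mean_blue": float(records["blue_count"].mean()),
            "mean_red": float(records["red_count"].mean()),
        }
    )


def quantify_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-field count table into per-sample means.

    Expects columns sample_id, field_index, blue_count, red_count;
    returns one row per sample with mean_blue / mean_red (reported to
    two decimals in CSV output).
    """
    if counts.empty:
        raise ValueError("empty count table")
    out = (
        counts.groupby("sample_id", sort=True)
        .apply(quantify_sample, include_groups=False)
        .reset_index()
    )
    return out
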