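"""Intensity normalization: histogram equalization and gray-level quantization.

Equalization is computed over foreground (non-zero) voxels only — background
zeros of masked brain images would otherwise dominate the CDF.  The transform
is a single 256-entry monotone LUT per image, returned for audit.
Quantization then discretizes the (already flattened) foreground histogram
into ``G`` equal-width bins, giving levels ``1..G``; background stays 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import QuantizedVolume, Volume

__all__ = ["EqualizationTransform", "equalize", "quantize", "sweep_bins"]

_LUT_LEVELS = 256


@dataclass
class EqualizationTransform:
    """256-entry input-level → output-level mapping plus its provenance."""

    lut: np.ndarray
    source_range: tuple[float, float]
    mask_rule: str = "foreground"

    def __post_init__(self) -> None:
        self.lut = np.asarray(self.lut, dtype=np.float64)
        if self.lut.shape != (_LUT_LEVELS,):
            raise ValueError("lut must have exactly 256 entries")
        if np.any(np.diff(self.lut) < 0):
            raise ValueError("lut must be monotonically non-decreasing")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"input_level": np.arange(_LUT_LEVELS), "output_level": self.lut}
        ).to_csv(path, index=False)
        return path


def _input_levels(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    scaled = (values - lo) / (hi - lo) * (_LUT_LEVELS - 1)
    return np.clip(np.floor(scaled), 0, _LUT_LEVELS - 1).astype(np.intp)


def equalize(vol: Volume) -> tuple[Volume, EqualizationTransform]:
    """CDF-based histogram equalization over foreground voxels.

    Output foreground intensities lie in ``[1, 256]`` (so they can never
    collide with the background value 0); the mapping is monotone, hence
    rank-preserving.
    """
    fg = vol.foreground
    values = vol.data[fg]
    if values.size == 0 or np.unique(values).size < 2:
        raise ValueError("degenerate histogram: need >= 2 distinct foreground intensities")

    lo, hi = float(values.min()), float(values.max())

    # exact empirical CDF over foreground: ties map together, ranks preserved
    uniq, counts = np.unique(values, return_counts=True)
    cdf_exact = np.cumsum(counts) / values.size
    mapped = cdf_exact[np.searchsorted(uniq, values)] * _LUT_LEVELS

    # 256-entry audit LUT: the same transform discretized to input levels
    levels = _input_levels(values, lo, hi)
    hist = np.bincount(levels, minlength=_LUT_LEVELS)
    cdf = np.cumsum(hist) / values.size
    lut = cdf * _LUT_LEVELS

    out = np.zeros_like(vol.data, dtype=np.float64)
    out[fg] = mapped
    transform = EqualizationTransform(lut=lut, source_range=(lo, hi))
    return vol.with_data(out), transform


def quantize(vol: Volume, n_bins: int) -> QuantizedVolume:
    """Equal-width binning of foreground intensities into levels ``1..n_bins``."""
    if n_bins < 2 or n_bins > 256 or n_bins % 2:
        raise ValueError("n_bins must be even and within [2, 256]")
    fg = vol.foreground
    values = vol.data[fg]
    if values.size == 0 or np.unique(values).size < 2:
        raise ValueError("degenerate histogram: need >= 2 distinct foreground intensities")

    lo, hi = float(values.min()), float(values.max())
    levels = 1 + np.floor((values - lo) / (hi - lo) * n_bins).astype(np.int32)
    levels = np.clip(levels, 1, n_bins)

    out = np.zeros(vol.data.shape, dtype=np.int32)
    out[fg] = levels
    return QuantizedVolume(
        data=out,
        n_bins=n_bins,
        voxel_size=vol.voxel_size,
        subject_id=vol.subject_id,
        group=vol.group,
    )


DEFAULT_BIN_GRID = tuple(range(2, 257, 2))  # 128 candidates


def sweep_bins(bins, evaluate) -> pd.DataFrame:
    """Run ``evaluate(n_bins) -> balanced accuracy`` over a bin-count grid.

    Returns a table with one row per candidate and a ``selected`` column
    marking the argmax; ties break toward fewer bins.
    """
    bins = list(bins)
    if not bins:
        raise ValueError("bins list must not be empty")
    for b in bins:
        if b < 2 or b > 256 or b % 2:
            raise ValueError(f"invalid bin count {b}: must be even and in [2, 256]")

    rows = [{"n_bins": b, "balanced_accuracy": float(evaluate(b))} for b in bins]
    table = pd.DataFrame(rows)
    ordered = table.sort_values(
        ["balanced_accuracy", "n_bins"], ascending=[False, True], kind="stable"
    )
    best = int(ordered.iloc[0]["n_bins"])
    table["selected"] = table["n_bins"] == best
    return table
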