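"""Layer-wise relevance propagation through the trained dense network.

Relevance starts at the output score and is redistributed layer by layer
with the ε-rule: unit j passes its relevance to input i proportionally to
the signed contribution z_ij = w_ij·a_i, with the stabilized denominator
Σ_i z_ij + b_j + ε·s·sign(·), where s is the magnitude of the raw
denominator (a sign-matched stabilizer scaled to the denominators, so the
per-layer conservation factor is exactly 1/(1+ε) regardless of unit scale).
The bias term's share is dropped (absorbed), which is the documented
conservation leak; with zero biases conservation holds up to ε leakage.

Input relevances live on the model's selected feature columns; they are
scattered back to voxel coordinates, clipped to their positive part and
Gaussian-smoothed for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import TrainedMLP, _forward
from .core import RelevanceMap
from .glcm import smooth_array

__all__ = [
    "LRPRule",
    "lrp",
    "relevance_to_map",
    "positive_relevance",
    "smooth_relevance",
]


@dataclass(frozen=True)
class LRPRule:
    variant: str = "epsilon"
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.variant != "epsilon":
            raise ValueError("only the epsilon variant is implemented")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def _sign(x: np.ndarray) -> np.ndarray:
    s = np.sign(x)
    return np.where(s == 0, 1.0, s)


def lrp(model: TrainedMLP, x: np.ndarray, rule: LRPRule = LRPRule()) -> np.ndarray:
    """Per-input relevance for one standardization-ready feature vector.

    ``x`` is raw (unstandardized) selected-feature values; the model's
    training-fold z-scoring is applied before propagation, and relevance is
    reported on the standardized input coordinates.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size != model.weights[0].shape[0]:
        raise ValueError(
            f"expected input of size {model.weights[0].shape[0]}, got {x.shape}"
        )
    xz = (x - model.feature_mean) / model.feature_std
    acts = _forward(model.weights, model.biases, xz[None, :])
    acts = [a[0] for a in acts]

    relevance = np.array([acts[-1][0]])  # output score seeds the decomposition
    for layer in range(len(model.weights) - 1, -1, -1):
        W = model.weights[layer]
        b = model.biases[layer]
        a_in = acts[layer]
        z = a_in[:, None] * W  # signed contributions z_ij
        raw = z.sum(axis=0) + b
        scale = np.where(np.abs(raw) > 0, np.abs(raw), 1.0)
        denom = raw + rule.epsilon * scale * _sign(raw)
        if not np.isfinite(denom).all():
            raise FloatingPointError(f"non-finite denominator at layer {layer}")
        relevance = (z / denom) @ relevance
        if not np.isfinite(relevance).all():
            raise FloatingPointError(f"non-finite relevance at layer {layer}")
    return relevance


def relevance_to_map(
    relevance: np.ndarray,
    columns: np.ndarray,
    column_coords: np.ndarray,
    grid_shape: tuple[int, int, int],
    subject_id: str = "",
    model_id: str = "",
    voxel_size: float = 1.0,
) -> RelevanceMap:
    """Scatter per-column relevances onto the volume grid.

    ``column_coords`` maps every design-matrix column to its (z, y, x) voxel;
    ``columns`` are the model's selected columns, aligned with ``relevance``.
    """
    relevance = np.asarray(relevance, dtype=np.float64)
    columns = np.asarray(columns)
    if relevance.shape != columns.shape:
        raise ValueError("relevance and column index arrays must align")
    coords = np.asarray(column_coords)[columns]
    if (coords < 0).any() or (coords >= np.array(grid_shape)).any():
        raise ValueError("column coordinate outside grid")
    data = np.zeros(grid_shape, dtype=np.float64)
    np.add.at(data, tuple(coords.T), relevance)
    return RelevanceMap(
        data=data, subject_id=subject_id, model_id=model_id, voxel_size=voxel_size
    )


def positive_relevance(rmap: RelevanceMap) -> RelevanceMap:
    """Clip negative relevance to zero."""
    return RelevanceMap(
        data=np.maximum(rmap.data, 0.0),
        subject_id=rmap.subject_id,
        model_id=rmap.model_id,
        voxel_size=rmap.voxel_size,
        smoothing=rmap.smoothing,
    )


def smooth_relevance(
    rmap: RelevanceMap,
    support: int | None = None,
    fwhm_mm: float | None = 10.0,
) -> RelevanceMap:
    """Gaussian-smooth a relevance map (10 mm FWHM default; or a voxel-support
    kernel for figure-stage maps)."""
    if support is not None:
        data = smooth_array(rmap.data, support=support)
        desc = f"support={support}"
    else:
        data = smooth_array(
            rmap.data, support=None, fwhm_mm=fwhm_mm, voxel_size=rmap.voxel_size
        )
        desc = f"fwhm={fwhm_mm}mm"
    return RelevanceMap(
        data=data,
        subject_id=rmap.subject_id,
        model_id=rmap.model_id,
        voxel_size=rmap.voxel_size,
        smoothing=desc,
    )
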