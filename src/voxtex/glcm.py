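"""Voxel-wise 3D gray-level co-occurrence matrices and texture-feature maps.

For every voxel a cube (default 7×7×7, cropped at volume boundaries) is
slid over the quantized volume; co-occurrence counts are accumulated over
all in-cube voxel pairs at the configured displacements, symmetrized and
normalized per cube, and a scalar feature of the resulting distribution is
written to the cube center.  Pairs with a background (level-0) member are
excluded; cubes with no valid pair emit 0.

The default displacement set is the 13 unique distance-1 3D directions,
pooled into a single symmetrized matrix per cube.  Feature formulas (log
base 2, ``0·log 0 := 0``):

    energy             Σ p²
    entropy            −Σ p log₂ p
    contrast           Σ (g1−g2)² p
    homogeneity        Σ p / (1 + |g1−g2|)
    sum_entropy        −Σₖ q⁺(k) log₂ q⁺(k),  q⁺(k) = Σ_{g1+g2=k} p
    difference_entropy −Σₖ q⁻(k) log₂ q⁻(k),  q⁻(k) = Σ_{|g1−g2|=k} p

The sliding-window path is blocked/vectorized for speed; its correctness is
defined solely by the naive per-voxel enumeration it is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FeatureMap, QuantizedVolume

__all__ = [
    "FEATURE_NAMES",
    "OFFSETS_13",
    "GLCM",
    "glcm_from_window",
    "feature_from_glcm",
    "texture_map",
    "texture_maps",
    "smooth_map",
    "gaussian_kernel_1d",
]

FEATURE_NAMES = (
    "entropy",
    "sum_entropy",
    "difference_entropy",
    "energy",
    "contrast",
    "homogeneity",
)


def _unique_directions() -> tuple[tuple[int, int, int], ...]:
    dirs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                d = (dz, dy, dx)
                if d > (0, 0, 0):  # lexicographic half-space: 13 of 26
                    dirs.append(d)
    return tuple(dirs)


OFFSETS_13 = _unique_directions()


def validate_offsets(offsets) -> tuple[tuple[int, int, int], ...]:
    offs = [tuple(int(c) for c in o) for o in offsets]
    seen = set()
    for o in offs:
        if o == (0, 0, 0):
            raise ValueError("zero offset not allowed")
        if tuple(-c for c in o) in seen:
            raise ValueError(f"offset {o} is the negation of another; symmetrization covers reverses")
        seen.add(o)
    return tuple(offs)


@dataclass
class GLCM:
    """Symmetrized, normalized co-occurrence matrix over levels 1..G."""

    matrix: np.ndarray  # (G, G); matrix[a-1, b-1] = p(a, b)
    pair_count: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GLCM matrix must be square")


def glcm_from_window(window: np.ndarray, n_levels: int, offsets=OFFSETS_13) -> GLCM:
    """Accumulate co-occurrences over all in-window pairs at the given offsets.

    Each directed pair event (v, v+d) with both members foreground adds one
    count at (a, b) and one at (b, a).  ``pair_count`` is the number of
    directed events (before the symmetric doubling).
    """
    window = np.asarray(window)
    if window.ndim != 3:
        raise ValueError("window must be a 3D array")
    if min(window.shape) < 1 or max(window.shape) < 2:
        raise ValueError("window edge must be >= 2 on at least one axis")
    offsets = validate_offsets(offsets)

    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    n_events = 0
    for d in offsets:
        src = tuple(
            slice(max(0, -c), window.shape[a] - max(0, c)) for a, c in enumerate(d)
        )
        dst = tuple(
            slice(max(0, c), window.shape[a] + min(0, c)) for a, c in enumerate(d)
        )
        a = window[src].ravel()
        b = window[dst].ravel()
        valid = (a > 0) & (b > 0)
        a, b = a[valid] - 1, b[valid] - 1
        np.add.at(counts, (a, b), 1)
        np.add.at(counts, (b, a), 1)
        n_events += int(valid.sum())

    matrix = counts.astype(np.float64)
    if n_events > 0:
        matrix /= matrix.sum()
    return GLCM(matrix=matrix, pair_count=n_events)


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def feature_from_glcm(glcm: GLCM, feature_name: str) -> float:
    if feature_name not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature_name!r}; choose from {FEATURE_NAMES}")
    if glcm.pair_count == 0:
        return float("nan")
    p = glcm.matrix
    G = p.shape[0]
    g1, g2 = np.meshgrid(np.arange(1, G + 1), np.arange(1, G + 1), indexing="ij")

    if feature_name == "energy":
        return float(np.sum(p * p))
    if feature_name == "entropy":
        return float(-np.sum(_xlog2x(p)))
    if feature_name == "contrast":
        return float(np.sum((g1 - g2) ** 2 * p))
    if feature_name == "homogeneity":
        return float(np.sum(p / (1.0 + np.abs(g1 - g2))))
    if feature_name == "sum_entropy":
        q = np.bincount((g1 + g2).ravel(), weights=p.ravel())
        return float(-np.sum(_xlog2x(q)))
    # difference_entropy
    q = np.bincount(np.abs(g1 - g2).ravel(), weights=p.ravel())
    return float(-np.sum(_xlog2x(q)))


# ---------------------------------------------------------------------------
# fast sliding-window maps
# ---------------------------------------------------------------------------

def _box_sum_axis(arr: np.ndarray, axis: int, lo: int, hi: int) -> np.ndarray:
    """Per-position sum of arr over window [pos+lo, pos+hi], cropped at edges."""
    n = arr.shape[axis]
    cs = np.cumsum(arr, axis=axis)
    pad = np.zeros_like(np.take(cs, [0], axis=axis))
    cs = np.concatenate([pad, cs], axis=axis)
    upper = np.clip(np.arange(n) + hi + 1, 0, n)
    lower = np.clip(np.arange(n) + lo, 0, n)
    return np.take(cs, upper, axis=axis) - np.take(cs, lower, axis=axis)


def _window_sum(arr: np.ndarray, d: tuple[int, int, int], half: int) -> np.ndarray:
    """Sum of anchor-attributed pair events whose both endpoints fall in the
    cube centered at each voxel: anchors v ∈ [c−h−min(0,dₐ)… c+h−max(0,dₐ)]."""
    out = arr
    for axis, comp in enumerate(d):
        lo = -half - min(0, comp)
        hi = half - max(0, comp)
        out = _box_sum_axis(out, axis, lo, hi)
    return out


def _pair_class_volume(q: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """Unordered pair-class index per anchor voxel, −1 where no valid pair."""
    shape = q.shape
    kvol = np.full(shape, -1, dtype=np.int32)
    src = tuple(slice(max(0, -c), shape[a] - max(0, c)) for a, c in enumerate(d))
    dst = tuple(slice(max(0, c), shape[a] + min(0, c)) for a, c in enumerate(d))
    a = q[src]
    b = q[dst]
    valid = (a > 0) & (b > 0)
    lo = np.minimum(a, b) - 1
    hi = np.maximum(a, b) - 1
    k = hi * (hi + 1) // 2 + lo
    region = kvol[src]
    region[valid] = k[valid]
    kvol[src] = region
    return kvol


def texture_maps(
    qvol: QuantizedVolume,
    features=FEATURE_NAMES,
    cube_size: int = 7,
    offsets=OFFSETS_13,
    class_chunk: int = 64,
) -> dict[str, FeatureMap]:
    """Compute all requested feature maps in one blocked sliding-window pass.

    Co-occurrence events are held as unordered level-pair classes; windowed
    class counts are obtained from cumulative-sum box filters (one shifted
    box per displacement, so boundary cropping is exact) and folded into the
    feature accumulators chunk by chunk to bound memory at large G.
    """
    if cube_size < 3 or cube_size % 2 == 0:
        raise ValueError("cube_size must be odd and >= 3")
    if cube_size > min(qvol.shape):
        raise ValueError("cube larger than volume")
    features = [features] if isinstance(features, str) else list(features)
    for f in features:
        if f not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {f!r}")
    offsets = validate_offsets(offsets)

    G = qvol.n_bins
    q = qvol.data
    shape = q.shape
    half = cube_size // 2
    n_classes = G * (G + 1) // 2

    # per-class level geometry (class k ↔ unordered levels (lo+1, hi+1))
    k_hi = np.zeros(n_classes, dtype=np.int64)
    k_lo = np.zeros(n_classes, dtype=np.int64)
    for hi in range(G):
        for lo in range(hi + 1):
            k = hi * (hi + 1) // 2 + lo
            k_hi[k], k_lo[k] = hi, lo
    k_diff = k_hi - k_lo
    k_sum = k_hi + k_lo + 2  # gray-level sum in 2..2G
    k_diag = k_diff == 0

    kvols = [_pair_class_volume(q, d) for d in offsets]

    # pass 1: total directed pair events per window
    N = np.zeros(shape, dtype=np.float64)
    for kvol, d in zip(kvols, offsets):
        N += _window_sum((kvol >= 0).astype(np.float64), d, half)
    has_pairs = N > 0
    Nsafe = np.where(has_pairs, N, 1.0)

    ene = np.zeros(shape)
    plogp = np.zeros(shape)
    con = np.zeros(shape)
    hom = np.zeros(shape)
    qsum = np.zeros(shape + (2 * G - 1,)) if "sum_entropy" in features else None
    qdiff = np.zeros(shape + (G,)) if "difference_entropy" in features else None

    for c0 in range(0, n_classes, class_chunk):
        c1 = min(c0 + class_chunk, n_classes)
        width = c1 - c0
        counts = np.zeros(shape + (width,), dtype=np.float64)
        for kvol, d in zip(kvols, offsets):
            in_chunk = (kvol >= c0) & (kvol < c1)
            if not in_chunk.any():
                continue
            onehot = np.zeros(shape + (width,), dtype=np.float64)
            pos = np.nonzero(in_chunk)
            onehot[pos + (kvol[in_chunk] - c0,)] = 1.0
            counts += _window_sum(onehot, d, half)

        p1 = counts / Nsafe[..., None]  # per-class mass c_k / N
        diag = k_diag[c0:c1]
        diff = k_diff[c0:c1].astype(np.float64)

        # ordered matrix: off-diagonal classes occupy two cells of p1/2 each;
        # diagonal classes one cell of mass p1
        half_p = np.where(diag, p1, p1 / 2.0)
        cells = np.where(diag, 1.0, 2.0)
        ene += np.sum(cells * half_p * half_p, axis=-1)
        plogp += np.sum(cells * _xlog2x(half_p), axis=-1)
        con += np.sum(diff**2 * p1, axis=-1)
        hom += np.sum(p1 / (1.0 + diff), axis=-1)
        if qsum is not None:
            for j, k in enumerate(range(c0, c1)):
                qsum[..., k_sum[k] - 2] += p1[..., j]
        if qdiff is not None:
            for j, k in enumerate(range(c0, c1)):
                qdiff[..., k_diff[k]] += p1[..., j]

    values = {
        "energy": ene,
        "entropy": -plogp,
        "contrast": con,
        "homogeneity": hom,
    }
    if qsum is not None:
        values["sum_entropy"] = -np.sum(_xlog2x(qsum), axis=-1)
    if qdiff is not None:
        values["difference_entropy"] = -np.sum(_xlog2x(qdiff), axis=-1)

    out = {}
    for f in features:
        data = np.where(has_pairs, values[f], 0.0)
        out[f] = FeatureMap(
            data=data,
            feature_name=f,
            cube_size=cube_size,
            voxel_size=qvol.voxel_size,
            subject_id=qvol.subject_id,
            group=qvol.group,
        )
    return out


def texture_map(
    qvol: QuantizedVolume,
    feature_name: str,
    cube_size: int = 7,
    offsets=OFFSETS_13,
) -> FeatureMap:
    """Single-feature convenience wrapper around :func:`texture_maps`."""
    return texture_maps(qvol, [feature_name], cube_size, offsets)[feature_name]


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


def gaussian_kernel_1d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_array(
    data: np.ndarray,
    support: int | None = 7,
    fwhm_mm: float | None = None,
    voxel_size: float = 1.0,
    sigma_voxels: float | None = None,
) -> np.ndarray:
    """Separable truncated-Gaussian smoothing with zero boundary condition.

    Either a voxel ``support`` (odd edge length, sigma 1 voxel by default) or
    a physical ``fwhm_mm`` may be given; the kernel always has unit sum.
    """
    if fwhm_mm is not None:
        sigma = fwhm_mm / _FWHM_TO_SIGMA / voxel_size
        radius = max(1, int(round(3.0 * sigma)))
    else:
        if support is None or support < 3 or support % 2 == 0:
            raise ValueError("support must be odd and >= 3")
        sigma = 1.0 if sigma_voxels is None else sigma_voxels
        radius = support // 2
    if sigma_voxels is not None:
        sigma = sigma_voxels

    kernel = gaussian_kernel_1d(sigma, radius)
    out = np.asarray(data, dtype=np.float64)
    for axis in range(out.ndim):
        padded = np.zeros(
            tuple(s + 2 * radius if a == axis else s for a, s in enumerate(out.shape))
        )
        sl = tuple(
            slice(radius, radius + s) if a == axis else slice(None)
            for a, s in enumerate(out.shape)
        )
        padded[sl] = out
        acc = np.zeros_like(out)
        for i, w in enumerate(kernel):
            shifted = tuple(
                slice(i, i + s) if a == axis else slice(None)
                for a, s in enumerate(out.shape)
            )
            acc += w * padded[shifted]
        out = acc
    return out


def smooth_map(
    fmap: FeatureMap,
    support: int | None = 7,
    fwhm_mm: float | None = None,
    foreground: np.ndarray | None = None,
    sigma_voxels: float | None = None,
) -> FeatureMap:
    """Gaussian-smooth a feature map; optionally re-zero known background."""
    data = smooth_array(
        fmap.data,
        support=support,
        fwhm_mm=fwhm_mm,
        voxel_size=fmap.voxel_size,
        sigma_voxels=sigma_voxels,
    )
    if foreground is not None:
        data = np.where(foreground, data, 0.0)
    desc = f"fwhm={fwhm_mm}mm" if fwhm_mm is not None else f"support={support}"
    return FeatureMap(
        data=data,
        feature_name=fmap.feature_name,
        cube_size=fmap.cube_size,
        voxel_size=fmap.voxel_size,
        subject_id=fmap.subject_id,
        group=fmap.group,
        smoothing=desc,
    )
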