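"""Synthetic phantom cohorts with texture-only planted group differences.

Phantoms are brain-shaped three-compartment volumes (CSF-like < GM-like <
WM-like bands) built from concentric smoothed ellipsoids plus spatially
correlated subject noise.  A group effect is planted inside known ROI masks
by re-arranging voxel values so that local co-occurrence structure changes
while first-order statistics (ROI histogram, hence mean and volume) are
preserved — exactly, for permutation-based effect kinds.

Generation is a pure function of ``(spec, seed)``: every subject draws from
an independent stream derived from ``SeedSequence([seed, subject_index])``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Volume, save_volume

__all__ = [
    "DEFAULT_GROUP_SIZES",
    "TextureEffect",
    "CohortSpec",
    "SubjectRecord",
    "default_roi_mask",
    "make_phantom",
    "plant_texture_effect",
    "iter_cohort",
    "write_cohort",
    "load_cohort",
]

DEFAULT_GROUP_SIZES = {"FEP": 77, "CHR_NT": 58, "CHR_T": 15, "HC": 44}

EFFECT_KINDS = ("pair-shuffle", "checker-mix", "corr-shift")


@dataclass(frozen=True)
class TextureEffect:
    """A texture-only perturbation planted inside ROI masks.

    kind
        ``pair-shuffle``  — random permutation of voxel values within small
        blocks; destroys local autocorrelation, preserves the ROI histogram
        exactly.
        ``checker-mix``   — within-block reordering that sends high values to
        one checkerboard parity and low values to the other; maximizes local
        alternation (raises GLCM contrast), histogram preserved exactly.
        ``corr-shift``    — replaces ROI values by a shorter-correlation-length
        Gaussian field rank-matched to the original ROI multiset; histogram
        preserved exactly by construction.
    magnitude
        Fraction in [0, 1] of ROI blocks (or rank-matched mass) affected;
        0 is the identity.
    affected_groups
        Group labels receiving the effect.
    """

    kind: str = "pair-shuffle"
    magnitude: float = 0.0
    affected_groups: tuple[str, ...] = ("FEP", "CHR_T")
    block_size: int = 3

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}; choose from {EFFECT_KINDS}")
        if not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("magnitude must lie in [0, 1]")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")


def _default_sizes() -> dict[str, int]:
    return dict(DEFAULT_GROUP_SIZES)


@dataclass
class CohortSpec:
    """Everything needed to deterministically generate a phantom cohort."""

    group_sizes: dict[str, int] = field(default_factory=_default_sizes)
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 1.0
    roi_masks: dict[str, np.ndarray] | None = None
    effect: TextureEffect = field(default_factory=TextureEffect)
    noise_sd: float = 0.08
    noise_smoothing: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group counts must be >= 0")
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive on all three axes")
        if self.roi_masks is None:
            self.roi_masks = {"roi": default_roi_mask(self.grid_shape)}
        brain = brain_mask(self.grid_shape)
        if not brain.any():
            raise ValueError("empty brain mask for this grid")
        for name, mask in self.roi_masks.items():
            if mask.shape != tuple(self.grid_shape):
                raise ValueError(f"roi mask {name!r} does not match grid_shape")
            if (mask & ~brain).any():
                raise ValueError(f"roi mask {name!r} must lie inside the brain mask")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.group_sizes.values()))

    def subject_table(self) -> pd.DataFrame:
        """Subject ids and group labels in canonical generation order."""
        rows = []
        for group, count in self.group_sizes.items():
            for i in range(count):
                rows.append({"subject_id": f"{group}_{i:03d}", "group": group})
        return pd.DataFrame(rows, columns=["subject_id", "group"])

    def to_jsonable(self) -> dict:
        return {
            "group_sizes": dict(self.group_sizes),
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": self.voxel_size_mm,
            "roi_masks": sorted(self.roi_masks),
            "effect": {
                "kind": self.effect.kind,
                "magnitude": self.effect.magnitude,
                "affected_groups": list(self.effect.affected_groups),
                "block_size": self.effect.block_size,
            },
            "noise_sd": self.noise_sd,
            "noise_smoothing": self.noise_smoothing,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    volume_path: Path | None = None


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

def _radial(shape: tuple[int, int, int]) -> np.ndarray:
    # normalized elliptical radius: 0 at center, 1 at the bounding ellipsoid
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(zz**2 + (yy / 0.92) ** 2 + (xx / 0.85) ** 2)


def brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    return _radial(shape) < 0.9


def default_roi_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """A ball centered in the WM-like band, strictly inside the brain."""
    center = np.array([0.55 * s for s in shape])
    radius = min(shape) / 5.0
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    mask = dist2 < radius**2
    return mask & brain_mask(shape)


def _base_anatomy(shape: tuple[int, int, int]) -> np.ndarray:
    r = _radial(shape)
    vol = np.zeros(shape)
    vol[r < 0.9] = 0.30   # CSF-like rim
    vol[r < 0.75] = 0.55  # GM-like band
    vol[r < 0.45] = 0.85  # WM-like core
    smoothed = ndimage.gaussian_filter(vol, sigma=1.0)
    smoothed[r >= 0.9] = 0.0
    return smoothed


def _subject_rng(seed: int, subject_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, subject_index, stream]))


def make_phantom(spec: CohortSpec, subject_index: int) -> Volume:
    """Deterministic brain-shaped phantom for one subject.

    The volume is the shared three-compartment anatomy plus a subject-specific
    spatially correlated noise field; the planted effect (if any, and if the
    subject's group is affected) is applied inside every ROI mask.
    """
    table = spec.subject_table()
    if subject_index >= len(table):
        raise IndexError(
            f"subject_index {subject_index} out of range for cohort of {len(table)}"
        )
    row = table.iloc[subject_index]
    base = _base_anatomy(tuple(spec.grid_shape))
    mask = brain_mask(tuple(spec.grid_shape))

    rng = _subject_rng(spec.seed, subject_index, stream=0)
    noise = rng.standard_normal(spec.grid_shape)
    if spec.noise_smoothing > 0:
        noise = ndimage.gaussian_filter(noise, sigma=spec.noise_smoothing)
        noise /= noise.std() or 1.0
    data = base + spec.noise_sd * noise
    data = np.clip(data, 0.05, None)  # keep foreground strictly positive
    data[~mask] = 0.0

    vol = Volume(
        data=data,
        voxel_size=spec.voxel_size_mm,
        subject_id=str(row.subject_id),
        group=str(row.group),
    )

    effect = spec.effect
    if effect.magnitude > 0 and row.group in effect.affected_groups:
        erng = _subject_rng(spec.seed, subject_index, stream=1)
        for roi in spec.roi_masks.values():
            vol = plant_texture_effect(vol, roi, effect, erng)
    return vol


# ---------------------------------------------------------------------------
# planted effects
# ---------------------------------------------------------------------------

def _roi_blocks(mask: np.ndarray, block: int) -> list[np.ndarray]:
    """Flat voxel indices of ROI voxels grouped into cubic blocks."""
    idx = np.flatnonzero(mask)
    coords = np.array(np.unravel_index(idx, mask.shape)).T
    keys = tuple((coords[:, a] // block) for a in range(3))
    order = np.lexsort(keys[::-1])
    idx = idx[order]
    key_arr = np.stack([k[order] for k in keys], axis=1)
    changes = np.any(np.diff(key_arr, axis=0) != 0, axis=1)
    bounds = np.flatnonzero(changes) + 1
    return np.split(idx, bounds)


def plant_texture_effect(
    vol: Volume,
    mask: np.ndarray,
    effect: TextureEffect,
    rng: np.random.Generator,
) -> Volume:
    """Re-arrange ROI voxel values so co-occurrence structure changes.

    For ``pair-shuffle`` and ``checker-mix`` the output is a permutation of
    the input inside the ROI (histogram exactly preserved); ``corr-shift``
    rank-matches a re-synthesized field to the original ROI multiset, which
    also preserves the histogram exactly.
    """
    if mask.shape != vol.data.shape:
        raise ValueError("mask shape does not match volume")
    if not mask.any():
        warnings.warn("plant_texture_effect: empty mask, returning input unchanged")
        return vol
    if effect.magnitude == 0:
        return vol

    data = vol.data.copy()
    flat = data.ravel()

    if effect.kind in ("pair-shuffle", "checker-mix"):
        blocks = _roi_blocks(mask, effect.block_size)
        n_hit = int(round(effect.magnitude * len(blocks)))
        hit = rng.choice(len(blocks), size=n_hit, replace=False) if n_hit else []
        if effect.kind == "pair-shuffle":
            for b in hit:
                idx = blocks[b]
                flat[idx] = flat[idx][rng.permutation(len(idx))]
        else:  # checker-mix: alternate sorted values across checkerboard parity
            shape = data.shape
            for b in hit:
                idx = blocks[b]
                coords = np.array(np.unravel_index(idx, shape))
                parity = coords.sum(axis=0) % 2
                vals = np.sort(flat[idx])
                out = np.empty_like(vals)
                n_hi = int(parity.sum())
                # high values on odd parity, low on even → max alternation
                out[parity == 1] = vals[len(vals) - n_hi:]
                out[parity == 0] = vals[: len(vals) - n_hi]
                flat[idx] = out
    else:  # corr-shift: shorter correlation length, rank-matched histogram
        idx = np.flatnonzero(mask)
        sigma = max(0.1, 1.2 * (1.0 - 0.8 * effect.magnitude))
        fresh = ndimage.gaussian_filter(rng.standard_normal(vol.data.shape), sigma)
        ranks = np.argsort(np.argsort(fresh.ravel()[idx]))
        flat[idx] = np.sort(flat[idx])[ranks]

    return vol.with_data(flat.reshape(vol.data.shape))


# ---------------------------------------------------------------------------
# cohort emission
# ---------------------------------------------------------------------------

def iter_cohort(spec: CohortSpec):
    """Yield ``(SubjectRecord, Volume)`` for every subject, in table order."""
    table = spec.subject_table()
    for i in range(len(table)):
        vol = make_phantom(spec, i)
        yield SubjectRecord(vol.subject_id, vol.group), vol


def write_cohort(spec: CohortSpec, out_dir: str | Path) -> list[SubjectRecord]:
    """Write one NIfTI per subject plus a TSV subject table and a manifest."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {out_dir}: {exc}") from exc

    records: list[SubjectRecord] = []
    checksums: dict[str, str] = {}
    for rec, vol in iter_cohort(spec):
        path = out_dir / f"{rec.subject_id}.nii.gz"
        save_volume(vol, path)
        checksums[rec.subject_id] = hashlib.sha256(
            np.ascontiguousarray(vol.data).tobytes()
        ).hexdigest()
        records.append(SubjectRecord(rec.subject_id, rec.group, path))

    table = spec.subject_table()
    table.to_csv(out_dir / "subjects.tsv", sep="\t", index=False)
    manifest = {"spec": spec.to_jsonable(), "checksums": checksums}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return records


def load_cohort(directory: str | Path) -> list[SubjectRecord]:
    """Read a cohort directory written by :func:`write_cohort` (or user data)."""
    directory = Path(directory)
    table_path = directory / "subjects.tsv"
    if not table_path.exists():
        raise FileNotFoundError(f"missing subject table: {table_path}")
    table = pd.read_csv(table_path, sep="\t")
    if "subject_id" not in table.columns or "group" not in table.columns:
        raise ValueError("subject table must have columns: subject_id, group")
    records = []
    for row in table.itertuples(index=False):
        path = directory / f"{row.subject_id}.nii.gz"
        if not path.exists():
            path = directory / f"{row.subject_id}.nii"
        records.append(SubjectRecord(str(row.subject_id), str(row.group), path))
    return records
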