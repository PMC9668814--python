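"""Core image containers and NIfTI round-tripping.

All stages of the pipeline exchange :class:`Volume` (float intensities,
background exactly 0), :class:`QuantizedVolume` (integer gray levels
``1..G`` on foreground, 0 on background) and per-voxel scalar maps
(:class:`FeatureMap`, :class:`RelevanceMap`).  Volumes are assumed to be
co-registered: every subject shares one grid and one isotropic voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "QuantizedVolume",
    "FeatureMap",
    "RelevanceMap",
    "load_volume",
    "save_volume",
]


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and subject identity."""

    data: np.ndarray
    voxel_size: float = 1.0
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def foreground(self) -> np.ndarray:
        """Boolean mask of non-zero voxels."""
        return self.data != 0

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


@dataclass
class QuantizedVolume:
    """Integer gray levels in {0} ∪ {1..G}; 0 marks background."""

    data: np.ndarray
    n_bins: int
    voxel_size: float = 1.0
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("quantized data must be integer typed")
        if self.n_bins < 2 or self.n_bins > 256 or self.n_bins % 2:
            raise ValueError("n_bins must be even and within [2, 256]")
        if self.data.min() < 0 or self.data.max() > self.n_bins:
            raise ValueError("levels must lie in {0} ∪ {1..n_bins}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def foreground(self) -> np.ndarray:
        return self.data > 0


@dataclass
class FeatureMap:
    """Per-voxel scalar map of one named texture feature."""

    data: np.ndarray
    feature_name: str
    cube_size: int = 7
    voxel_size: float = 1.0
    subject_id: str = ""
    group: str = ""
    smoothing: str = "none"


@dataclass
class RelevanceMap:
    """Per-voxel signed relevance for one subject under one model set."""

    data: np.ndarray
    subject_id: str = ""
    model_id: str = ""
    voxel_size: float = 1.0
    smoothing: str = "none"


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


def save_volume(vol, path: str | Path) -> Path:
    """Write any of the volume containers to a NIfTI-1 file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(vol.data)
    img = nib.Nifti1Image(data.astype(np.float32), _affine(vol.voxel_size))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path, subject_id: str = "", group: str = "") -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    voxel_size = float(img.header.get_zooms()[0])
    return Volume(
        data=np.asarray(img.get_fdata(), dtype=np.float64),
        voxel_size=voxel_size,
        subject_id=subject_id,
        group=group,
    )
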