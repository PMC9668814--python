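import numpy as np
import pytest

from voxtex.core import QuantizedVolume, Volume
from voxtex.synthetic import CohortSpec, TextureEffect


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    """A small masked random-intensity volume with zero background."""
    data = rng.uniform(0.1, 1.0, size=(12, 12, 12))
    mask = np.zeros((12, 12, 12), dtype=bool)
    mask[2:10, 2:10, 2:10] = True
    data[~mask] = 0.0
    return Volume(data=data)


@pytest.fixture
def random_qvol(rng):
    data = rng.integers(0, 7, size=(12, 12, 12)).astype(np.int32)
    return QuantizedVolume(data=data, n_bins=6)


@pytest.fixture
def tiny_spec():
    """Two-group phantom cohort at desk scale, no planted effect."""
    return CohortSpec(
        group_sizes={"FEP": 4, "HC": 4},
        grid_shape=(16, 16, 16),
        seed=11,
        effect=TextureEffect(magnitude=0.0),
    )


@pytest.fixture
def effect_spec():
    """Planted pair-shuffle effect in the FEP-like groups."""
    return CohortSpec(
        group_sizes={"FEP": 6, "HC": 6},
        grid_shape=(20, 20, 20),
        seed=5,
        effect=TextureEffect(
            kind="pair-shuffle", magnitude=0.8, affected_groups=("FEP", "CHR_T")
        ),
    )


def naive_glcm_counts(window: np.ndarray, n_levels: int, offsets) -> tuple[np.ndarray, int]:
    """Brute-force double-loop co-occurrence counting: the correctness oracle.

    Visits every voxel and every offset explicitly; returns the symmetrized
    integer count matrix and the number of directed pair events.
    """
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    events = 0
    shape = window.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                a = window[z, y, x]
                if a == 0:
                    continue
                for dz, dy, dx in offsets:
                    z2, y2, x2 = z + dz, y + dy, x + dx
                    if not (0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2]):
                        continue
                    b = window[z2, y2, x2]
                    if b == 0:
                        continue
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
                    events += 1
    return counts, events


def glcm_feature_oracle(p: np.ndarray, name: str) -> float:
    """Straight-from-formula evaluation on a normalized matrix (log base 2)."""
    G = p.shape[0]
    total = 0.0
    if name == "energy":
        return float(np.sum(p**2))
    if name == "entropy":
        for i in range(G):
            for j in range(G):
                if p[i, j] > 0:
                    total -= p[i, j] * np.log2(p[i, j])
        return total
    if name == "contrast":
        for i in range(G):
            for j in range(G):
                total += (i - j) ** 2 * p[i, j]
        return total
    if name == "homogeneity":
        for i in range(G):
            for j in range(G):
                total += p[i, j] / (1 + abs(i - j))
        return total
    if name == "sum_entropy":
        q = {}
        for i in range(G):
            for j in range(G):
                q[i + j] = q.get(i + j, 0.0) + p[i, j]
        return -sum(v * np.log2(v) for v in q.values() if v > 0)
    if name == "difference_entropy":
        q = {}
        for i in range(G):
            for j in range(G):
                q[abs(i - j)] = q.get(abs(i - j), 0.0) + p[i, j]
        return -sum(v * np.log2(v) for v in q.values() if v > 0)
    raise ValueError(name)
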