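"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library routines they check:
distances are exhaustive nearest-neighbour scans, morphology is pairwise
distance thresholding, hole filling is a hand-rolled BFS flood fill, and the
local-thickness oracle enumerates every candidate sphere.
"""

from __future__ import annotations

import numpy as np
import pytest

from fibrequant import phantoms as ph
from fibrequant.core import Mask3D, Volume3D


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_distance_map(mask: np.ndarray, voxel_size: float = 1.0) -> np.ndarray:
    """Distance to nearest background voxel centre; grid border = background."""
    padded = np.pad(mask, 1, constant_values=False)
    bg = np.argwhere(~padded) - 1
    out = np.zeros(mask.shape, dtype=float)
    for x in np.argwhere(mask):
        d2 = ((bg - x) ** 2).sum(axis=1).min()
        out[tuple(x)] = np.sqrt(d2) * voxel_size
    return out


def brute_force_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Voxel is set iff some foreground voxel lies within ``radius``."""
    fg = np.argwhere(mask)
    out = np.zeros_like(mask)
    if len(fg) == 0:
        return out
    for x in np.ndindex(mask.shape):
        d2 = ((fg - np.array(x)) ** 2).sum(axis=1).min()
        if d2 <= radius**2:
            out[x] = True
    return out


def brute_force_erode(mask: np.ndarray, radius: int) -> np.ndarray:
    """Voxel stays iff every voxel within ``radius`` is foreground.

    Matches binary erosion with a ball structuring element and the default
    zero padding outside the grid (border voxels see background)."""
    out = np.zeros_like(mask)
    shape = np.array(mask.shape)
    offs = np.array(
        [o for o in np.ndindex(2 * radius + 1, 2 * radius + 1, 2 * radius + 1)]
    ) - radius
    offs = offs[(offs**2).sum(axis=1) <= radius**2]
    for x in np.argwhere(mask):
        nb = x + offs
        inside = np.all((nb >= 0) & (nb < shape), axis=1)
        if not inside.all():
            continue  # ball sticks out of the grid -> background outside
        if mask[tuple(nb.T)].all():
            out[tuple(x)] = True
    return out


def brute_force_fill_holes(mask: np.ndarray) -> np.ndarray:
    """Background connected (6-neighbourhood) to the border stays; the rest
    is filled. Hand-rolled BFS."""
    from collections import deque

    shape = mask.shape
    reach = np.zeros(shape, dtype=bool)
    queue: deque = deque()
    for x in np.ndindex(shape):
        if any(x[a] in (0, shape[a] - 1) for a in range(3)) and not mask[x]:
            reach[x] = True
            queue.append(x)
    nbs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while queue:
        x = queue.popleft()
        for d in nbs:
            y = tuple(np.array(x) + d)
            if all(0 <= y[a] < shape[a] for a in range(3)):
                if not mask[y] and not reach[y]:
                    reach[y] = True
                    queue.append(y)
    return mask | ~reach


def brute_force_median(mask: np.ndarray, radius: int) -> np.ndarray:
    """Majority vote over the ball neighbourhood (outside counts background)."""
    offs = np.array(
        [o for o in np.ndindex(2 * radius + 1, 2 * radius + 1, 2 * radius + 1)]
    ) - radius
    offs = offs[(offs**2).sum(axis=1) <= radius**2]
    shape = np.array(mask.shape)
    out = np.zeros_like(mask)
    for x in np.ndindex(mask.shape):
        nb = np.array(x) + offs
        inside = np.all((nb >= 0) & (nb < shape), axis=1)
        votes = mask[tuple(nb[inside].T)].sum()
        out[x] = votes * 2 > len(offs)
    return out


def brute_force_local_thickness(mask: np.ndarray, voxel_size: float = 1.0) -> np.ndarray:
    """Exhaustive inscribed-sphere thickness.

    For every foreground centre c the admissible squared radius is the
    squared distance to the nearest background centre (border counts as
    background); every voxel x with |x - c|^2 < r^2(c) is covered by that
    sphere. Thickness = 2 x sqrt of the best covering squared radius.
    Vectorised but definition-level: no distance transform, no painting
    order tricks.
    """
    padded = np.pad(mask, 1, constant_values=False)
    bg = np.argwhere(~padded) - 1
    fg = np.argwhere(mask)
    th2 = np.zeros(mask.shape, dtype=np.int64)
    flat = th2.reshape(-1)
    fg_flat = np.ravel_multi_index(fg.T, mask.shape)
    for c in fg:
        r2 = int(((bg - c) ** 2).sum(axis=1).min())
        cover = ((fg - c) ** 2).sum(axis=1) < r2
        if cover.any():
            np.maximum.at(flat, fg_flat[cover], r2)
    out = 2.0 * np.sqrt(th2.astype(float)) * voxel_size
    out[~mask] = 0.0
    return out


def char_poly_eigenvalues(a: np.ndarray) -> np.ndarray:
    """Eigenvalues of a symmetric 3x3 matrix from its characteristic
    polynomial roots (independent of numpy.linalg.eigh)."""
    i1 = np.trace(a)
    i2 = 0.5 * (i1**2 - np.trace(a @ a))
    i3 = np.linalg.det(a)
    roots = np.roots([1.0, -i1, i2, -i3])
    return np.sort(roots.real)


def random_mask(rng: np.random.Generator, max_side: int = 20) -> np.ndarray:
    shape = tuple(rng.integers(5, max_side + 1, 3))
    p = rng.uniform(0.25, 0.7)
    m = rng.random(shape) < p
    if not m.any():
        m[tuple(s // 2 for s in shape)] = True
    return m


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def cylinder_phantom():
    """Single straight cylinder (d = 16 µm) along e_y, blurred."""
    vol, gt = ph.make_cylinder_phantom([16.0], axis=(0, 1, 0), spacing=100,
                                       shape=(48, 48, 48))
    noisy = ph.add_imaging_noise(vol, blur_sigma=1.0, seed=3)
    return noisy, gt


@pytest.fixture(scope="session")
def fibre_phantom_small():
    """Dispersed straight-fibre phantom, 64^3, for recovery tests."""
    spec = ph.FibrePhantomSpec(
        shape=(64, 64, 64), voxel_size=1.0, mean_direction=(0, 1, 0),
        kappa=4.0, radius_mean=3.0, radius_sd=0.3, n_fibres=150,
        period=60.0, seed=21,
    )
    vol, gt = ph.make_fibre_phantom(spec)
    return ph.add_imaging_noise(vol, blur_sigma=1.0, seed=21), gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
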