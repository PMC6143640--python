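"""Synthetic phantom generators with exact ground truth.

Every generator is deterministic under a fixed seed and returns both a
:class:`~fibrequant.core.Volume3D` (or mask) and a
:class:`PhantomGroundTruth` holding the generative parameters, so the whole
downstream analysis can be validated by parameter recovery.

Fibre centrelines follow

    x(t) = x0 + t*d + R0v*sin(2*pi*t/lam + psi_v)*nv
                    + R0w*sin(2*pi*t/lam + psi_w)*nw

with the fibre axis ``d`` drawn from a Watson-type axial distribution
(density proportional to ``exp(kappa * (p.d)^2)``) about the mean direction,
and ``(nv, nw)`` an orthonormal transverse pair.  Voxelisation marks a voxel
foreground when its centre lies within the fibre radius of the centreline,
with the centreline sampled at a 0.25-voxel step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .core import Mask3D, Volume3D

__all__ = [
    "FibrePhantomSpec",
    "PhantomGroundTruth",
    "sample_watson_axes",
    "make_fibre_phantom",
    "make_cylinder_phantom",
    "make_slab_phantom",
    "make_bead_phantom",
    "apply_affine",
    "add_imaging_noise",
]


@dataclass
class FibrePhantomSpec:
    """Generative parameters for a wavy-fibre network phantom.

    All lengths are in µm; the grid must be at least 32 voxels per axis.
    ``kappa`` is the Watson axial concentration (``numpy.inf`` pins every
    fibre to the mean direction; 0 is isotropic).
    """

    shape: tuple[int, int, int]
    voxel_size: float
    mean_direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    kappa: float = np.inf
    radius_mean: float = 3.0
    radius_sd: float = 0.0
    n_fibres: int = 50
    amplitude_v: float = 0.0   # R0 along the first transverse axis
    amplitude_w: float = 0.0   # R0 along the second transverse axis
    period: float = 50.0       # lambda_gen, shared by both transverse planes
    randomise_phase: bool = True
    foreground: float = 200.0
    background: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)  # type: ignore[assignment]
        if min(self.shape) < 32:
            raise ValueError(f"grid must be >= 32 voxels per axis, got {self.shape}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.radius_mean <= 0:
            raise ValueError("fibre radius must be > 0")
        if self.period <= 0:
            raise ValueError("waviness period must be > 0")
        if self.amplitude_v < 0 or self.amplitude_w < 0:
            raise ValueError("waviness amplitude must be >= 0")
        d = np.asarray(self.mean_direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("mean direction must be non-zero")
        self.mean_direction = tuple(d / n)  # type: ignore[assignment]


@dataclass
class PhantomGroundTruth:
    """Exact generative record used by parameter-recovery tests."""

    voxel_size: float
    centrelines: list[np.ndarray] = field(default_factory=list)  # (n_pts, 3) µm
    radii: list[float] = field(default_factory=list)
    axes: list[np.ndarray] = field(default_factory=list)         # unit mean axes
    orientation_tensor: np.ndarray | None = None                 # A_gen, 3x3
    period: float | None = None
    amplitude_v: float | None = None
    amplitude_w: float | None = None
    phases: list[tuple[float, float]] = field(default_factory=list)
    bead_centroids: np.ndarray | None = None                     # (n, 3) µm
    bead_radius: float | None = None
    thickness_field: np.ndarray | None = None                    # µm
    diameters: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)

        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x

        payload = {
            "voxel_size": self.voxel_size,
            "centrelines": [c.tolist() for c in self.centrelines],
            "radii": list(self.radii),
            "axes": [a.tolist() for a in self.axes],
            "orientation_tensor": conv(self.orientation_tensor),
            "period": self.period,
            "amplitude_v": self.amplitude_v,
            "amplitude_w": self.amplitude_w,
            "phases": [list(p) for p in self.phases],
            "bead_centroids": conv(self.bead_centroids),
            "bead_radius": self.bead_radius,
            "thickness_field": conv(self.thickness_field),
            "diameters": list(self.diameters),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


# ---------------------------------------------------------------------------
# direction sampling
# ---------------------------------------------------------------------------

def _uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_watson_axes(
    mean: np.ndarray, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` axes from a Watson axial distribution about ``mean``.

    Rejection sampling with envelope ``exp(kappa * ((p.mu)^2 - 1)) <= 1``.
    ``kappa = inf`` returns the mean axis; ``kappa = 0`` is isotropic.
    """
    mean = np.asarray(mean, dtype=float)
    mean = mean / np.linalg.norm(mean)
    if np.isinf(kappa):
        return np.tile(mean, (n, 1))
    if kappa == 0:
        return _uniform_sphere(rng, n)
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        batch = max(4 * (n - filled), 64)
        cand = _uniform_sphere(rng, batch)
        dot2 = (cand @ mean) ** 2
        accept = rng.random(batch) < np.exp(kappa * (dot2 - 1.0))
        good = cand[accept]
        take = min(len(good), n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def _transverse_pair(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """An orthonormal pair spanning the plane perpendicular to ``d``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 0.0, 1.0])
    nv = np.cross(d, helper)
    nv /= np.linalg.norm(nv)
    nw = np.cross(d, nv)
    return nv, nw


# ---------------------------------------------------------------------------
# voxelisation helper
# ---------------------------------------------------------------------------

def _stamp_tube(
    fg: np.ndarray, points_vox: np.ndarray, radius_vox: float
) -> None:
    """Mark voxels whose centre lies within ``radius_vox`` of any sample point.

    ``points_vox`` is an (n, 3) array in voxel units. Modifies ``fg`` in
    place.
    """
    if len(points_vox) == 0:
        return
    shape = fg.shape
    r_ceil = int(np.ceil(radius_vox)) + 1
    # candidate voxels: integer offsets around each sample point
    offs = np.stack(
        np.meshgrid(*([np.arange(-r_ceil, r_ceil + 1)] * 3), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    offs = offs[np.linalg.norm(offs, axis=1) <= radius_vox + 1.0]
    base = np.rint(points_vox).astype(np.int64)
    cand = (base[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    # dedupe before the exact distance test
    inside = np.all((cand >= 0) & (cand < np.array(shape)), axis=1)
    cand = cand[inside]
    if len(cand) == 0:
        return
    flat = np.ravel_multi_index(cand.T, shape)
    flat = np.unique(flat)
    cand = np.stack(np.unravel_index(flat, shape), axis=1)
    tree = cKDTree(points_vox)
    dist, _ = tree.query(cand.astype(float), k=1)
    hit = dist <= radius_vox
    if hit.any():
        fg[tuple(cand[hit].T)] = True


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_fibre_phantom(spec: FibrePhantomSpec) -> tuple[Volume3D, PhantomGroundTruth]:
    """Voxelise a network of quasi-sinusoidal wavy fibres.

    The generative orientation tensor ``A_gen`` is computed by dense sampling
    of the analytic centreline tangents (step <= 0.1 * period) restricted to
    the in-grid portion of each fibre.
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.shape)
    extent = shape * spec.voxel_size  # µm
    mean = np.asarray(spec.mean_direction)
    axes = sample_watson_axes(mean, spec.kappa, spec.n_fibres, rng)
    # canonical axial representative: keep hemisphere of the mean direction
    flip = axes @ mean < 0
    axes[flip] *= -1

    radii = rng.normal(spec.radius_mean, spec.radius_sd, spec.n_fibres)
    radii = np.clip(radii, 0.2 * spec.radius_mean, None)

    half_diag = float(np.linalg.norm(extent)) / 2.0
    step_vox = 0.25 * spec.voxel_size
    t_vals = np.arange(-half_diag, half_diag + step_vox, step_vox)
    # tangent-sampling grid for A_gen (step <= 0.1 * period, and fine enough
    # for straight fibres too)
    t_tan = np.arange(-half_diag, half_diag, min(0.1 * spec.period, 2 * spec.voxel_size))

    fg = np.zeros(spec.shape, dtype=bool)
    gt = PhantomGroundTruth(
        voxel_size=spec.voxel_size,
        period=spec.period,
        amplitude_v=spec.amplitude_v,
        amplitude_w=spec.amplitude_w,
    )
    tangents_all = []
    for k in range(spec.n_fibres):
        d = axes[k]
        nv, nw = _transverse_pair(d)
        x0 = rng.random(3) * extent
        if spec.randomise_phase:
            psi_v, psi_w = rng.random(2) * 2 * np.pi
        else:
            psi_v = psi_w = 0.0
        omega = 2 * np.pi / spec.period

        def centreline(t: np.ndarray) -> np.ndarray:
            return (
                x0[None, :]
                + t[:, None] * d[None, :]
                + spec.amplitude_v * np.sin(omega * t + psi_v)[:, None] * nv[None, :]
                + spec.amplitude_w * np.sin(omega * t + psi_w)[:, None] * nw[None, :]
            )

        pts = centreline(t_vals)
        in_grid = np.all((pts >= 0) & (pts < extent[None, :]), axis=1)
        pts_in = pts[in_grid]
        if len(pts_in):
            _stamp_tube(fg, pts_in / spec.voxel_size, radii[k] / spec.voxel_size)
            gt.centrelines.append(pts_in)
            gt.radii.append(float(radii[k]))
            gt.axes.append(d.copy())
            gt.phases.append((float(psi_v), float(psi_w)))
        # analytic tangents on the in-grid portion
        pts_t = centreline(t_tan)
        in_t = np.all((pts_t >= 0) & (pts_t < extent[None, :]), axis=1)
        if in_t.any():
            tt = t_tan[in_t]
            tan = (
                d[None, :]
                + spec.amplitude_v * omega * np.cos(omega * tt + psi_v)[:, None] * nv[None, :]
                + spec.amplitude_w * omega * np.cos(omega * tt + psi_w)[:, None] * nw[None, :]
            )
            tan /= np.linalg.norm(tan, axis=1, keepdims=True)
            tangents_all.append(tan)

    if not fg.any():
        raise ValueError("phantom spec produced zero foreground voxels")
    tangents = np.concatenate(tangents_all)
    a_gen = tangents[:, :, None] * tangents[:, None, :]
    gt.orientation_tensor = a_gen.mean(axis=0)

    data = np.where(fg, spec.foreground, spec.background).astype(np.float32)
    vol = Volume3D(data=data, voxel_size=spec.voxel_size,
                   provenance=[{"op": "make_fibre_phantom", "seed": spec.seed}])
    return vol, gt


def make_cylinder_phantom(
    diameters: Sequence[float],
    axis: Sequence[float],
    spacing: float,
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size: float = 1.0,
    foreground: float = 200.0,
    background: float = 50.0,
) -> tuple[Volume3D, PhantomGroundTruth]:
    """Parallel straight circular cylinders (diameters and spacing in µm).

    Cylinders are laid out along a direction perpendicular to ``axis`` with
    centre-to-centre distance ``spacing``; overlap is an error.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    diameters = [float(d) for d in diameters]
    for d in diameters:
        if d < 6 * voxel_size:
            raise ValueError(f"cylinder diameter {d} µm below 6-voxel floor")
    for i in range(len(diameters) - 1):
        if spacing < (diameters[i] + diameters[i + 1]) / 2:
            raise ValueError("cylinders overlap: spacing below the sum of radii")

    shape_arr = np.array(shape)
    extent = shape_arr * voxel_size
    nv, nw = _transverse_pair(axis)
    centre = extent / 2.0
    n = len(diameters)
    offsets = (np.arange(n) - (n - 1) / 2.0) * spacing

    half_diag = float(np.linalg.norm(extent))
    t_vals = np.arange(-half_diag, half_diag, 0.25 * voxel_size)
    fg = np.zeros(shape, dtype=bool)
    gt = PhantomGroundTruth(voxel_size=voxel_size, diameters=diameters)
    for d_um, off in zip(diameters, offsets):
        x0 = centre + off * nv
        pts = x0[None, :] + t_vals[:, None] * axis[None, :]
        in_grid = np.all((pts >= 0) & (pts < extent[None, :]), axis=1)
        pts_in = pts[in_grid]
        if len(pts_in) == 0:
            raise ValueError("cylinder lies outside the grid")
        _stamp_tube(fg, pts_in / voxel_size, (d_um / 2) / voxel_size)
        gt.centrelines.append(pts_in)
        gt.radii.append(d_um / 2)
        gt.axes.append(axis.copy())
    gt.orientation_tensor = np.outer(axis, axis)
    data = np.where(fg, foreground, background).astype(np.float32)
    vol = Volume3D(data=data, voxel_size=voxel_size,
                   provenance=[{"op": "make_cylinder_phantom"}])
    return vol, gt


def make_slab_phantom(
    thickness_field: np.ndarray,
    voxel_size: float = 1.0,
    margin: int = 4,
) -> tuple[Mask3D, PhantomGroundTruth]:
    """Binary slab whose local thickness along ``e_z`` follows a 2D map (µm).

    The slab is centred in ``z``; ``thickness_field`` has shape (nx, ny).
    Zero-thickness cells are excluded from the mask; positive thickness must
    be at least 3 voxels.
    """
    tf = np.asarray(thickness_field, dtype=float)
    if tf.ndim != 2:
        raise ValueError("thickness field must be 2D")
    t_vox = np.rint(tf / voxel_size).astype(int)
    pos = t_vox > 0
    if pos.any() and t_vox[pos].min() < 3:
        raise ValueError("positive thickness must be >= 3 voxels")
    nz = int(t_vox.max()) + 2 * margin
    nx, ny = tf.shape
    mask = np.zeros((nx, ny, nz), dtype=bool)
    z = np.arange(nz)
    centre = nz / 2.0
    half = t_vox / 2.0
    # symmetric band of exactly t_vox voxels about the z centre
    lo = np.ceil(centre - half).astype(int)
    for ix in range(nx):
        for iy in range(ny):
            t = t_vox[ix, iy]
            if t > 0:
                mask[ix, iy, lo[ix, iy] : lo[ix, iy] + t] = True
    gt = PhantomGroundTruth(voxel_size=voxel_size,
                            thickness_field=t_vox * voxel_size)
    return (
        Mask3D(data=mask, voxel_size=voxel_size,
               provenance=[{"op": "make_slab_phantom"}]),
        gt,
    )


def make_bead_phantom(
    centroids: Sequence[Sequence[float]],
    radius: float,
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size: float = 1.0,
    foreground: float = 230.0,
    background: float = 30.0,
) -> tuple[Volume3D, PhantomGroundTruth]:
    """Bright spheres on a dark background (centroids and radius in µm)."""
    cents = np.asarray(centroids, dtype=float)
    if cents.ndim != 2 or cents.shape[1] != 3:
        raise ValueError("centroids must be an (n, 3) array of physical points")
    extent = np.array(shape) * voxel_size
    if np.any(cents - radius < 0) or np.any(cents + radius >= extent):
        raise ValueError("bead clipped by the grid boundary")
    if len(cents) > 1:
        d = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 2 * radius:
            raise ValueError("beads overlap")
    fg = np.zeros(shape, dtype=bool)
    grids = np.meshgrid(*[np.arange(n) * voxel_size for n in shape], indexing="ij")
    pos = np.stack(grids, axis=-1)
    for c in cents:
        fg |= np.linalg.norm(pos - c[None, None, None, :], axis=-1) <= radius
    data = np.where(fg, foreground, background).astype(np.float32)
    gt = PhantomGroundTruth(voxel_size=voxel_size,
                            bead_centroids=cents.copy(), bead_radius=radius)
    vol = Volume3D(data=data, voxel_size=voxel_size,
                   provenance=[{"op": "make_bead_phantom"}])
    return vol, gt


def apply_affine(
    phantom: tuple[Volume3D, PhantomGroundTruth], matrix: np.ndarray
) -> tuple[Volume3D, PhantomGroundTruth]:
    """Transform a bead phantom by a 3x3 affine matrix about the origin.

    Bead centroids are mapped exactly and spheres re-rendered at the new
    positions (glass beads are rigid). Beads leaving the grid are an error.
    """
    vol, gt = phantom
    if gt.bead_centroids is None:
        raise ValueError("apply_affine expects a bead phantom")
    matrix = np.asarray(matrix, dtype=float).reshape(3, 3)
    new_cents = gt.bead_centroids @ matrix.T
    fg_level = float(vol.data.max())
    bg_level = float(vol.data.min())
    return make_bead_phantom(
        new_cents,
        gt.bead_radius,
        shape=vol.shape,
        voxel_size=vol.voxel_size,
        foreground=fg_level,
        background=bg_level,
    )


def add_imaging_noise(
    volume: Volume3D,
    blur_sigma: float = 0.0,
    noise_sd: float = 0.0,
    halo_strength: float = 0.0,
    seed: int = 0,
) -> Volume3D:
    """Blur + Gaussian noise + an edge halo mimicking phase-contrast fringes.

    The halo is a signed ring obtained by subtracting ``halo_strength`` times
    the Laplacian of the blurred image (bright overshoot inside the edge,
    dark undershoot outside). All parameters must be non-negative; all-zero
    parameters return the input unchanged.
    """
    if blur_sigma < 0 or noise_sd < 0 or halo_strength < 0:
        raise ValueError("noise parameters must be non-negative")
    data = volume.data.astype(np.float64)
    if blur_sigma > 0:
        data = ndi.gaussian_filter(data, blur_sigma)
    if halo_strength > 0:
        data = data - halo_strength * ndi.laplace(data)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, data.shape)
    return volume.with_data(
        data.astype(np.float32),
        note={"op": "add_imaging_noise", "blur_sigma": blur_sigma,
              "noise_sd": noise_sd, "halo_strength": halo_strength, "seed": seed},
    )
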