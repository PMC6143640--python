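"""Per-voxel 3D structure-tensor orientation analysis.

The route: grey-level gradients by centred finite differences -> local
Gaussian-window averages of the gradient outer product (structure tensors)
-> per-voxel minor eigenvectors ``p_i`` (locally parallel to fibres) ->
orientation distribution function over the angles ``(theta_i, phi_i)`` and
the second-order orientation tensor ``A = (1/N) sum p_i (x) p_i``.

Angle convention: ``theta`` in [0, 180] degrees is the angle between ``p``
and ``e_z``; ``phi`` in [0, 180) degrees is the angle between the
projection of ``p`` onto the (e_x, e_y) plane and ``e_x``, so that

    p = sin(theta) cos(phi) e_x + sin(theta) sin(phi) e_y + cos(theta) e_z.

Antipodal canonicalisation: flip ``p`` so ``p_y >= 0``; if ``p_y == 0``
require ``p_x >= 0``; if both vanish require ``p_z >= 0`` and set
``phi = 0``. This makes (theta, phi) unique over those ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .core import Mask3D, Volume3D

__all__ = [
    "OrientationField",
    "OrientationTensor",
    "ODFHistogram",
    "grey_gradient",
    "structure_tensor_field",
    "orientation_field",
    "canonicalise",
    "angles_from_vector",
    "vector_from_angles",
    "orientation_tensor",
    "orientation_tensor_2d",
    "odf_histogram",
    "find_odf_peaks",
    "angle_summary",
]

_PLANE_AXES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


@dataclass
class OrientationField:
    """Per-voxel canonical fibre vectors and angles on a grid.

    ``vectors`` has shape (nx, ny, nz, 3); ``theta``/``phi`` are in degrees;
    ``coherence`` is ``1 - mu_min/mu_max`` of the structure tensor; ``valid``
    marks voxels that passed the mask, depth and coherence gates.
    """

    vectors: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    coherence: np.ndarray
    valid: np.ndarray
    window: int
    voxel_size: float = 1.0

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_vectors(self) -> np.ndarray:
        return self.vectors[self.valid]

    def valid_angles(self) -> tuple[np.ndarray, np.ndarray]:
        return self.theta[self.valid], self.phi[self.valid]


@dataclass
class OrientationTensor:
    """Second-order orientation tensor (3x3, or 2x2 planar variant)."""

    matrix: np.ndarray
    n: int
    frame: tuple[str, ...] = ("x", "y", "z")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = self.matrix.shape[0]
        if self.matrix.shape != (k, k) or k not in (2, 3):
            raise ValueError("orientation tensor must be 2x2 or 3x3")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("orientation tensor must be symmetric")
        if abs(np.trace(self.matrix) - 1.0) > 1e-9:
            raise ValueError("orientation tensor must have unit trace")
        if np.linalg.eigvalsh(self.matrix).min() < -1e-12:
            raise ValueError("orientation tensor must be positive semi-definite")

    def components(self) -> dict[str, float]:
        labels = self.frame
        out = {}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if j >= i:
                    out[f"a_{a}{b}"] = float(self.matrix[i, j])
        return out


@dataclass
class ODFHistogram:
    """Discrete orientation distribution over (theta, phi) bins."""

    counts: np.ndarray          # (n_theta, n_phi)
    bin_width: float            # degrees
    theta_centres: np.ndarray
    phi_centres: np.ndarray
    peaks: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


# ---------------------------------------------------------------------------
# gradients and structure tensors
# ---------------------------------------------------------------------------

def grey_gradient(volume: Volume3D) -> np.ndarray:
    """Grey-level gradient by centred finite differences (intensity / µm).

    Boundaries use mirror padding, so edge voxels see a symmetric
    neighbourhood (zero normal derivative at the border).
    """
    if min(volume.shape) < 3:
        raise ValueError("gradient needs at least 3 voxels per axis")
    padded = np.pad(volume.data.astype(np.float64), 1, mode="reflect")
    gx, gy, gz = np.gradient(padded, volume.voxel_size)
    core = (slice(1, -1),) * 3
    return np.stack([gx[core], gy[core], gz[core]], axis=-1)


def structure_tensor_field(gradient: np.ndarray, window: int) -> np.ndarray:
    """Gaussian-window structure tensors ``S = <grad g (x) grad g>``.

    ``window`` is the lateral window size in voxels (odd, >= 3); the Gaussian
    has sigma = window / 6 and is truncated at the window edge, so the
    support spans +-3 sigma. Returns an (nx, ny, nz, 3, 3) array; every
    tensor is symmetric positive semi-definite by construction.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd voxel count >= 3")
    shape = gradient.shape[:3]
    if window > min(shape):
        raise ValueError("window larger than the grid")
    sigma = window / 6.0
    radius = (window - 1) // 2
    truncate = radius / sigma
    out = np.empty(shape + (3, 3), dtype=np.float64)
    for i in range(3):
        for j in range(i, 3):
            comp = ndi.gaussian_filter(
                gradient[..., i] * gradient[..., j], sigma, truncate=truncate
            )
            out[..., i, j] = comp
            out[..., j, i] = comp
    return out


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------

def canonicalise(p: np.ndarray) -> np.ndarray:
    """Map axial vectors to their canonical hemisphere representative.

    Rule: ``p_y >= 0``; ties broken by ``p_x >= 0`` then ``p_z >= 0``.
    Accepts a single vector or an (..., 3) stack.
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    q = np.atleast_2d(p).copy()
    py, px, pz = q[..., 1], q[..., 0], q[..., 2]
    flip = (py < 0) | ((py == 0) & (px < 0)) | ((py == 0) & (px == 0) & (pz < 0))
    q[flip] *= -1
    return q[0] if single else q.reshape(p.shape)


def angles_from_vector(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(theta, phi) in degrees for unit vectors, after canonicalisation.

    theta = angle to e_z in [0, 180]; phi = in-plane angle to e_x in
    [0, 180); phi := 0 at the poles (p parallel to e_z).
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    q = np.atleast_2d(p)
    norms = np.linalg.norm(q, axis=-1)
    if np.any(norms < 1e-12):
        raise ValueError("zero vector has no orientation")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        q = q / norms[..., None]
    q = canonicalise(q)
    theta = np.degrees(np.arccos(np.clip(q[..., 2], -1.0, 1.0)))
    phi = np.degrees(np.arctan2(q[..., 1], q[..., 0]))
    # pole tie-break and range closure
    in_plane = np.hypot(q[..., 0], q[..., 1])
    phi = np.where(in_plane < 1e-12, 0.0, phi)
    phi = np.where(phi >= 180.0, 0.0, phi)  # p_y==0, p_x>0 maps to 0 not 180
    phi = np.where(phi < 0.0, 0.0, phi)
    if single:
        return float(theta[0]), float(phi[0])
    return theta, phi


def vector_from_angles(theta, phi) -> np.ndarray:
    """Unit vector from (theta, phi) in degrees (the inverse convention)."""
    th = np.radians(np.asarray(theta, dtype=float))
    ph = np.radians(np.asarray(phi, dtype=float))
    return np.stack(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)], axis=-1
    )


# ---------------------------------------------------------------------------
# orientation field
# ---------------------------------------------------------------------------

def orientation_field(
    tensors: np.ndarray,
    fibre_mask: Mask3D | np.ndarray,
    distance_map: Volume3D | np.ndarray | None = None,
    min_depth: float = 0.0,
    min_coherence: float = 0.2,
    window: int = 0,
    voxel_size: float = 1.0,
) -> OrientationField:
    """Minor-eigenvector field of the structure tensors with validity gates.

    A voxel is valid iff it lies inside ``fibre_mask``, its distance-map
    value is >= ``min_depth`` (µm), its coherence ``1 - mu3/mu1`` is
    >= ``min_coherence``, and its two smallest eigenvalues are not
    degenerate (relative gap >= 1e-9), which would leave the minor
    eigenvector undefined.
    """
    mask = fibre_mask.data if isinstance(fibre_mask, Mask3D) else np.asarray(fibre_mask)
    if isinstance(fibre_mask, Mask3D):
        voxel_size = fibre_mask.voxel_size
    shape = tensors.shape[:3]
    if mask.shape != shape:
        raise ValueError("mask grid does not match the tensor field")
    candidate = mask.astype(bool).copy()
    if distance_map is not None:
        dist = distance_map.data if isinstance(distance_map, Volume3D) else np.asarray(distance_map)
        if dist.shape != shape:
            raise ValueError("distance map grid does not match the tensor field")
        candidate &= dist >= min_depth

    vectors = np.zeros(shape + (3,), dtype=np.float64)
    theta = np.zeros(shape)
    phi = np.zeros(shape)
    coherence = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)

    idx = np.nonzero(candidate)
    if idx[0].size:
        sel = tensors[idx]  # (m, 3, 3)
        w, v = np.linalg.eigh(sel)  # ascending eigenvalues
        mu3, mu2, mu1 = w[:, 0], w[:, 1], w[:, 2]
        ok = mu1 > 0
        coh = np.zeros(len(mu1))
        coh[ok] = 1.0 - mu3[ok] / mu1[ok]
        degenerate = (mu2 - mu3) <= 1e-9 * np.maximum(np.abs(mu1), 1e-300)
        good = ok & ~degenerate & (coh >= min_coherence)
        minor = canonicalise(v[:, :, 0])
        th, ph = angles_from_vector(minor[good]) if good.any() else (np.array([]), np.array([]))
        vectors[idx] = minor
        coherence[idx] = coh
        gidx = tuple(a[good] for a in idx)
        valid[gidx] = True
        theta[gidx] = th
        phi[gidx] = ph
    return OrientationField(
        vectors=vectors, theta=theta, phi=phi, coherence=coherence,
        valid=valid, window=window, voxel_size=voxel_size,
    )


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def orientation_tensor(field: OrientationField | np.ndarray) -> OrientationTensor:
    """A = (1/N) sum p_i (x) p_i over valid voxels (or a vector stack)."""
    if isinstance(field, OrientationField):
        p = field.valid_vectors()
    else:
        p = np.atleast_2d(np.asarray(field, dtype=float))
    if len(p) == 0:
        raise ValueError("orientation tensor of an empty field")
    a = (p[:, :, None] * p[:, None, :]).mean(axis=0)
    a = 0.5 * (a + a.T)
    a /= np.trace(a)
    return OrientationTensor(matrix=a, n=len(p))


def orientation_tensor_2d(
    field: OrientationField | np.ndarray, plane: str = "xy"
) -> OrientationTensor:
    """Planar orientation tensor from the in-plane projections of ``p_i``.

    Each vector is projected onto the plane and renormalised; vectors with
    in-plane norm < 1e-6 are discarded.
    """
    if plane not in _PLANE_AXES:
        raise ValueError(f"plane must be one of {sorted(_PLANE_AXES)}")
    i, j = _PLANE_AXES[plane]
    if isinstance(field, OrientationField):
        p = field.valid_vectors()
    else:
        p = np.atleast_2d(np.asarray(field, dtype=float))
    q = p[:, [i, j]]
    norms = np.linalg.norm(q, axis=1)
    q = q[norms >= 1e-6]
    if len(q) == 0:
        raise ValueError("all projections degenerate in the requested plane")
    q = q / np.linalg.norm(q, axis=1, keepdims=True)
    a = (q[:, :, None] * q[:, None, :]).mean(axis=0)
    a = 0.5 * (a + a.T)
    a /= np.trace(a)
    return OrientationTensor(matrix=a, n=len(q), frame=(plane[0], plane[1]))


def odf_histogram(
    field: OrientationField,
    bin_width: float = 3.0,
    weight_by_coherence: bool = False,
    solid_angle_correction: bool = False,
) -> ODFHistogram:
    """Raw-count histogram of (theta, phi) over valid voxels.

    ``bin_width`` (degrees) must divide 180. Optional flags weight entries by
    coherence or divide by sin(theta) (solid-angle correction); both default
    off.
    """
    if abs(180.0 / bin_width - round(180.0 / bin_width)) > 1e-9:
        raise ValueError("bin width must divide 180 degrees")
    nb = int(round(180.0 / bin_width))
    th, ph = field.valid_angles()
    weights = None
    if weight_by_coherence:
        weights = field.coherence[field.valid]
    counts, te, pe = np.histogram2d(
        th, ph, bins=nb, range=[[0, 180], [0, 180]], weights=weights
    )
    if solid_angle_correction:
        tc = (te[:-1] + te[1:]) / 2
        s = np.sin(np.radians(tc))
        counts = counts / np.where(s > 1e-9, s, 1e-9)[:, None]
    return ODFHistogram(
        counts=counts,
        bin_width=bin_width,
        theta_centres=(te[:-1] + te[1:]) / 2,
        phi_centres=(pe[:-1] + pe[1:]) / 2,
    )


def find_odf_peaks(
    hist: ODFHistogram,
    min_separation: float = 15.0,
    rel_height: float = 0.5,
    smooth_sigma: float = 1.0,
) -> list[tuple[float, float, float]]:
    """Local maxima of the lightly smoothed ODF, on bin centres.

    Peaks must exceed ``rel_height`` times the global (smoothed) maximum and
    be at least ``min_separation`` degrees apart (Euclidean in angle space);
    greedy suppression keeps the higher peak.
    """
    smoothed = ndi.gaussian_filter(hist.counts.astype(float), smooth_sigma, mode="nearest")
    if smoothed.max() <= 0:
        hist.peaks = []
        return []
    local_max = smoothed == ndi.maximum_filter(smoothed, size=3, mode="nearest")
    threshold = rel_height * smoothed.max()
    cand = np.argwhere(local_max & (smoothed >= threshold))
    heights = smoothed[tuple(cand.T)]
    order = np.argsort(-heights)
    kept: list[tuple[float, float, float]] = []
    for k in order:
        t = hist.theta_centres[cand[k, 0]]
        p = hist.phi_centres[cand[k, 1]]
        h = float(heights[k])
        if all(np.hypot(t - t0, p - p0) >= min_separation for t0, p0, _ in kept):
            kept.append((float(t), float(p), h))
    hist.peaks = kept
    return kept


def angle_summary(
    field: OrientationField, circular: bool = False
) -> dict[str, float]:
    """Mean and standard deviation of theta and phi over valid voxels.

    Arithmetic statistics on the [0, 180] degree range by default; a
    circular (axial, period-180) mode is available but off by default.
    """
    th, ph = field.valid_angles()
    if len(th) < 2:
        raise ValueError("angle summary needs at least 2 valid voxels")
    if not circular:
        return {
            "theta_mean": float(th.mean()),
            "theta_sd": float(th.std(ddof=0)),
            "phi_mean": float(ph.mean()),
            "phi_sd": float(ph.std(ddof=0)),
            "n": int(len(th)),
        }
    out: dict[str, float] = {"n": int(len(th))}
    for name, ang in (("theta", th), ("phi", ph)):
        z = np.exp(2j * np.radians(ang))  # axial: double the angle
        m = z.mean()
        mean = np.degrees(np.angle(m)) / 2.0 % 180.0
        r = np.abs(m)
        sd = np.degrees(np.sqrt(-2 * np.log(max(r, 1e-300)))) / 2.0
        out[f"{name}_mean"] = float(mean)
        out[f"{name}_sd"] = float(sd)
    return out
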