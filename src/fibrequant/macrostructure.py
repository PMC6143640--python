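"""Layer-scale descriptors: local thickness maps and bead-marker elongation.

Local thickness follows the inscribed-sphere definition: the thickness at a
point is the diameter of the largest sphere that is fully inside the
structure and contains the point. Distances are voxel-centre distances; the
grid border counts as background. A sphere of radius r centred on a voxel c
is "inside" iff every voxel centre strictly closer than r to c is
foreground, so the largest admissible radius at c equals the Euclidean
distance from c to the nearest background centre.

Elongation: bead centroids are detected in a reference and a deformed state;
for every bead pair the distance ratio lambda = l / l0 is computed and
averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage as ndi

from .core import Mask3D, Volume3D

__all__ = [
    "ThicknessMap",
    "BeadSet",
    "ElongationResult",
    "local_thickness",
    "thickness_summary",
    "detect_beads",
    "elongation",
]


@dataclass
class ThicknessMap:
    """Per-voxel local thickness (µm) on the mask support."""

    data: np.ndarray
    voxel_size: float

    def summary(self) -> dict[str, float]:
        vals = self.data[self.data > 0]
        return {
            "min": float(vals.min()),
            "max": float(vals.max()),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=0)),
            "count": int(len(vals)),
        }


@dataclass
class BeadSet:
    """Labelled bead centroids (physical µm) with component volumes."""

    centroids: np.ndarray     # (n, 3)
    labels: list[int]
    volumes: np.ndarray       # µm^3

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ElongationResult:
    pair_labels: list[tuple[int, int]]
    l0: np.ndarray
    l: np.ndarray
    ratios: np.ndarray
    mean: float


# ---------------------------------------------------------------------------
# local thickness
# ---------------------------------------------------------------------------

def _squared_edt(mask: np.ndarray) -> np.ndarray:
    """Exact integer squared voxel-centre distance to the nearest background
    voxel, with the grid border counted as background."""
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    _, idx = ndi.distance_transform_edt(padded, return_indices=True)
    pos = np.indices(padded.shape)
    d2 = ((idx.astype(np.int64) - pos) ** 2).sum(axis=0)
    return d2[1:-1, 1:-1, 1:-1]


def local_thickness(mask: Mask3D) -> ThicknessMap:
    """Inscribed-sphere local thickness map (µm).

    thickness(x) = 2 * max{ edt(c) : foreground c with |x - c| < edt(c) },
    computed by painting each candidate sphere over the current maximum,
    processed in descending radius order. Exact in integer squared-distance
    arithmetic, so it matches a brute-force sphere-enumeration oracle
    bit-for-bit.
    """
    m = mask.data
    if not m.any():
        raise ValueError("local thickness of an empty mask")
    d2 = _squared_edt(m)
    shape = m.shape
    thick2 = np.zeros(shape, dtype=np.int64)  # squared radius of best sphere
    fg = np.argwhere(m)
    vals = d2[tuple(fg.T)]
    order = np.argsort(-vals)
    fg = fg[order]
    vals = vals[order]

    # group centres by squared radius, paint each group's ball in one shot
    start = 0
    n = len(vals)
    while start < n:
        r2 = int(vals[start])
        stop = start
        while stop < n and vals[stop] == r2:
            stop += 1
        centres = fg[start:stop]
        start = stop
        if r2 == 0:
            continue
        r = int(np.ceil(np.sqrt(r2)))
        rng = np.arange(-r, r + 1)
        ox, oy, oz = np.meshgrid(rng, rng, rng, indexing="ij")
        inside = (ox**2 + oy**2 + oz**2) < r2  # strict: |x - c| < radius
        offs = np.stack([ox[inside], oy[inside], oz[inside]], axis=1)
        tgt = centres[:, None, :] + offs[None, :, :]
        tgt = tgt.reshape(-1, 3)
        ok = np.all((tgt >= 0) & (tgt < np.array(shape)), axis=1)
        tgt = tgt[ok]
        flat = np.ravel_multi_index(tgt.T, shape)
        np.maximum.at(thick2.reshape(-1), flat, r2)

    thickness = 2.0 * np.sqrt(thick2.astype(np.float64)) * mask.voxel_size
    thickness[~m] = 0.0
    return ThicknessMap(data=thickness, voxel_size=mask.voxel_size)


def thickness_summary(
    tmap: ThicknessMap,
    region: np.ndarray | None = None,
    n_measurements: int | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Min/max/mean/sd/count of the thickness map over a region.

    With ``n_measurements``, a seeded random subsample of that many support
    voxels is used (emulating a fixed number of manual measurements).
    """
    support = tmap.data > 0
    if region is not None:
        support &= np.asarray(region, dtype=bool)
    vals = tmap.data[support]
    if len(vals) == 0:
        raise ValueError("region does not intersect the thickness support")
    if n_measurements is not None and n_measurements < len(vals):
        rng = np.random.default_rng(seed)
        vals = rng.choice(vals, size=n_measurements, replace=False)
    return {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=0)),
        "count": int(len(vals)),
    }


# ---------------------------------------------------------------------------
# beads and elongation
# ---------------------------------------------------------------------------

def detect_beads(
    volume: Volume3D,
    intensity_gate: float,
    volume_gate: tuple[float, float] = (0.0, np.inf),
) -> BeadSet:
    """Detect bright spherical markers.

    Thresholds at ``intensity_gate``, labels connected components, keeps
    components whose physical volume (µm^3) lies within ``volume_gate`` and
    returns intensity-weighted centres of mass. Labels are assigned by
    descending component volume, ties broken by lexicographic centroid
    order.
    """
    fg = volume.data > intensity_gate
    labels, n = ndi.label(fg)
    cents: list[np.ndarray] = []
    vols: list[float] = []
    vvol = volume.voxel_size**3
    for lab in range(1, n + 1):
        comp = labels == lab
        v = float(comp.sum()) * vvol
        if not (volume_gate[0] <= v <= volume_gate[1]):
            continue
        weights = np.where(comp, volume.data, 0.0)
        com = ndi.center_of_mass(weights)
        cents.append(np.array(com) * volume.voxel_size)
        vols.append(v)
    if not cents:
        warnings.warn("no bead components within the volume gate", stacklevel=2)
        return BeadSet(centroids=np.empty((0, 3)), labels=[], volumes=np.empty(0))
    cent_arr = np.array(cents)
    vol_arr = np.array(vols)
    order = sorted(
        range(len(vols)),
        key=lambda k: (-vol_arr[k], tuple(cent_arr[k])),
    )
    cent_arr = cent_arr[order]
    vol_arr = vol_arr[order]
    return BeadSet(centroids=cent_arr, labels=list(range(len(vols))), volumes=vol_arr)


def _pair_mutual_nearest(ref: BeadSet, deformed: BeadSet) -> list[tuple[int, int]]:
    """Mutual-nearest pairing after rigid prealignment by centroid shift."""
    a = ref.centroids - ref.centroids.mean(axis=0)
    b = deformed.centroids - deformed.centroids.mean(axis=0)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    fwd = np.argmin(d, axis=1)
    bwd = np.argmin(d, axis=0)
    pairs = [(i, int(fwd[i])) for i in range(len(a)) if bwd[fwd[i]] == i]
    matched_ref = {i for i, _ in pairs}
    matched_def = {j for _, j in pairs}
    orphans_ref = [ref.labels[i] for i in range(len(a)) if i not in matched_ref]
    orphans_def = [deformed.labels[j] for j in range(len(b)) if j not in matched_def]
    if orphans_ref or orphans_def:
        raise ValueError(
            "mutual-nearest pairing is not a bijection; orphans: "
            f"reference {orphans_ref}, deformed {orphans_def}"
        )
    return pairs


def elongation(
    reference: BeadSet,
    deformed: BeadSet,
    pairing: str = "by_label",
) -> ElongationResult:
    """Marker-based elongation lambda = l / l0 over all bead pairs.

    Beads are matched between states by label (default) or by mutual nearest
    neighbour after centroid prealignment. For every pair of matched beads
    the reference distance l0 and deformed distance l give one ratio; the
    mean over pairs is reported.
    """
    if len(reference) < 2 or len(deformed) < 2:
        raise ValueError("elongation needs at least 2 beads per state")
    if pairing == "by_label":
        if sorted(reference.labels) != sorted(deformed.labels):
            raise ValueError("by_label pairing requires identical label sets")
        ref_ix = {lab: k for k, lab in enumerate(reference.labels)}
        def_ix = {lab: k for k, lab in enumerate(deformed.labels)}
        matches = [(ref_ix[lab], def_ix[lab]) for lab in sorted(reference.labels)]
    elif pairing == "mutual_nearest":
        matches = _pair_mutual_nearest(reference, deformed)
    else:
        raise ValueError("pairing must be 'by_label' or 'mutual_nearest'")

    pair_labels: list[tuple[int, int]] = []
    l0s: list[float] = []
    ls: list[float] = []
    for (ri, di), (rj, dj) in combinations(matches, 2):
        l0 = float(np.linalg.norm(reference.centroids[ri] - reference.centroids[rj]))
        l1 = float(np.linalg.norm(deformed.centroids[di] - deformed.centroids[dj]))
        if l0 <= 0:
            raise ValueError("coincident reference beads")
        pair_labels.append((reference.labels[ri], reference.labels[rj]))
        l0s.append(l0)
        ls.append(l1)
    l0_arr = np.array(l0s)
    l_arr = np.array(ls)
    ratios = l_arr / l0_arr
    return ElongationResult(
        pair_labels=pair_labels, l0=l0_arr, l=l_arr,
        ratios=ratios, mean=float(ratios.mean()),
    )
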