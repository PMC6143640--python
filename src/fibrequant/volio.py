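"""Volume I/O and image pre-treatment.

Supported on-disk layouts:

* multipage TIFF (one page per ``z`` slice) with a JSON metadata block in the
  image description carrying voxel size and axis labels;
* a directory of single-slice TIFFs (lexicographic slice order) plus a
  ``meta.json`` sidecar;
* a raw binary block plus a JSON sidecar (shape, dtype, voxel size, labels).

Voxel-size metadata is mandatory on read — a missing value is an error,
never a silent default.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .core import ANATOMICAL_AXES, Mask3D, Volume3D

__all__ = [
    "read",
    "write",
    "threshold_volume",
    "morph_clean",
    "euclidean_distance_map",
    "crop_roi",
]

_META_KEYS = ("voxel_size", "axis_labels")


def _meta_dict(volume: Volume3D | Mask3D) -> dict[str, Any]:
    return {
        "voxel_size": volume.voxel_size,
        "axis_labels": list(volume.axis_labels),
        "origin": list(volume.origin),
    }


def _volume_from(data: np.ndarray, meta: dict[str, Any]) -> Volume3D:
    for key in _META_KEYS:
        if key not in meta:
            raise ValueError(f"metadata missing required key {key!r}")
    return Volume3D(
        data=data,
        voxel_size=float(meta["voxel_size"]),
        axis_labels=tuple(meta["axis_labels"]),
        origin=tuple(meta.get("origin", (0.0, 0.0, 0.0))),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write(volume: Volume3D | Mask3D, path: str | Path, format: str | None = None) -> Path:
    """Write a volume to disk.

    ``format`` is one of ``"tiff"`` (multipage), ``"tiff_dir"`` (slice
    directory) or ``"raw"`` (raw block + sidecar); inferred from the path
    suffix when omitted (.tif/.tiff -> tiff, .raw -> raw, else tiff_dir).
    Masks are stored as 8-bit 0/255.
    """
    path = Path(path)
    if format is None:
        if path.suffix.lower() in (".tif", ".tiff"):
            format = "tiff"
        elif path.suffix.lower() == ".raw":
            format = "raw"
        else:
            format = "tiff_dir"

    data = volume.data
    if data.dtype == bool:
        data = (data.astype(np.uint8)) * 255
    # grid order is (x, y, z); TIFF pages are z slices -> (z, y, x)
    pages = np.transpose(data, (2, 1, 0))
    meta = _meta_dict(volume)
    meta["dtype"] = str(data.dtype)
    meta["shape"] = list(data.shape)

    if format == "tiff":
        tifffile.imwrite(path, pages, description=json.dumps(meta))
    elif format == "tiff_dir":
        path.mkdir(parents=True, exist_ok=True)
        ndigits = max(4, len(str(pages.shape[0])))
        for k in range(pages.shape[0]):
            tifffile.imwrite(path / f"slice_{k:0{ndigits}d}.tif", pages[k])
        (path / "meta.json").write_text(json.dumps(meta, indent=2))
    elif format == "raw":
        path.write_bytes(np.ascontiguousarray(pages).tobytes())
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    else:
        raise ValueError(f"unsupported format {format!r}")
    return path


def read(path: str | Path, format: str | None = None) -> Volume3D:
    """Read a volume written by :func:`write`.

    Raises if voxel-size metadata is absent or if a raw block's size does not
    match its sidecar shape.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "tiff_dir"
        elif path.suffix.lower() in (".tif", ".tiff"):
            format = "tiff"
        elif path.suffix.lower() == ".raw":
            format = "raw"
        else:
            raise ValueError(f"cannot infer format for {path}")

    if format == "tiff":
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            desc = tif.pages[0].description
        if not desc:
            raise ValueError(f"{path}: no voxel-size metadata in TIFF description")
        meta = json.loads(desc)
        if pages.ndim == 2:
            pages = pages[None]
        data = np.transpose(pages, (2, 1, 0))
        return _volume_from(data, meta)
    if format == "tiff_dir":
        sidecar = path / "meta.json"
        if not sidecar.exists():
            raise ValueError(f"{path}: missing meta.json sidecar")
        meta = json.loads(sidecar.read_text())
        slices = sorted(p for p in path.glob("*.tif"))
        if not slices:
            raise ValueError(f"{path}: no .tif slices found")
        pages = np.stack([tifffile.imread(p) for p in slices])
        data = np.transpose(pages, (2, 1, 0))
        return _volume_from(data, meta)
    if format == "raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(f"{path}: missing JSON sidecar")
        meta = json.loads(sidecar.read_text())
        for key in ("shape", "dtype"):
            if key not in meta:
                raise ValueError(f"sidecar missing required key {key!r}")
        shape = tuple(meta["shape"])
        dtype = np.dtype(meta["dtype"])
        raw = path.read_bytes()
        expected = int(np.prod(shape)) * dtype.itemsize
        if len(raw) != expected:
            raise ValueError(
                f"{path}: raw block is {len(raw)} bytes but sidecar shape "
                f"{shape} ({dtype}) implies {expected}"
            )
        pages = np.frombuffer(raw, dtype=dtype).reshape(
            (shape[2], shape[1], shape[0])
        )
        data = np.transpose(pages, (2, 1, 0))
        return _volume_from(data, meta)
    raise ValueError(f"unsupported format {format!r}")


# ---------------------------------------------------------------------------
# Pre-treatment chain
# ---------------------------------------------------------------------------

def threshold_volume(volume: Volume3D, method: str = "otsu", value: float | None = None) -> Mask3D:
    """Coarse foreground thresholding.

    ``method`` is ``"otsu"`` or ``"fixed"`` (requires ``value``).  Foreground
    is strictly above the threshold; the threshold used is logged in the mask
    provenance.
    """
    if method == "otsu":
        data = volume.data
        if np.all(data == data.flat[0]):
            raise ValueError("otsu thresholding requires a non-constant volume")
        thr = float(threshold_otsu(data))
    elif method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        thr = float(value)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = volume.data > thr
    prov = list(volume.provenance) + [{"op": "threshold", "method": method, "value": thr}]
    return Mask3D(
        data=mask,
        voxel_size=volume.voxel_size,
        axis_labels=volume.axis_labels,
        origin=volume.origin,
        provenance=prov,
    )


def morph_clean(mask: Mask3D, plan: Sequence[tuple[str, int] | str]) -> Mask3D:
    """Apply an ordered morphological cleaning plan with ball structuring
    elements.

    Each step is ``("median", r)``, ``"fill_holes"``, ``("open", r)`` or
    ``("close", r)`` with radius ``r >= 1`` voxel.
    """
    data = mask.data.copy()
    applied: list[dict[str, Any]] = []
    for step in plan:
        if isinstance(step, str):
            name, radius = step, None
        else:
            name, radius = step
        if name == "fill_holes":
            data = ndi.binary_fill_holes(data)
            applied.append({"op": "fill_holes"})
            continue
        if radius is None or radius < 1:
            raise ValueError(f"step {name!r} requires radius >= 1, got {radius}")
        footprint = ball(radius)
        if name == "median":
            # majority vote over the ball
            count = ndi.convolve(data.astype(np.int32), footprint.astype(np.int32),
                                 mode="constant", cval=0)
            data = count * 2 > footprint.sum()
        elif name == "open":
            data = ndi.binary_opening(data, structure=footprint)
        elif name == "close":
            data = ndi.binary_closing(data, structure=footprint)
        else:
            raise ValueError(f"unknown morphology step {name!r}")
        applied.append({"op": name, "radius": radius})
    if not data.any():
        warnings.warn("morphological cleaning produced an empty mask", stacklevel=2)
    return mask.with_data(data, note={"op": "morph_clean", "plan": applied})


def euclidean_distance_map(mask: Mask3D) -> Volume3D:
    """3D Euclidean distance map in physical units (µm).

    Each foreground voxel carries the voxel-centre distance to the nearest
    background voxel; the grid border counts as background, so an
    all-foreground grid still has finite distances. Background voxels are 0.
    """
    if not mask.data.any():
        raise ValueError("distance map of an empty mask")
    padded = np.pad(mask.data, 1, mode="constant", constant_values=False)
    dist = ndi.distance_transform_edt(padded, sampling=mask.voxel_size)
    dist = dist[1:-1, 1:-1, 1:-1]
    return Volume3D(
        data=dist,
        voxel_size=mask.voxel_size,
        axis_labels=mask.axis_labels,
        origin=mask.origin,
        provenance=list(mask.provenance) + [{"op": "euclidean_distance_map"}],
    )


def crop_roi(volume: Volume3D | Mask3D, bounds: Iterable[tuple[int, int]]):
    """Crop to half-open index ranges ``((x0, x1), (y0, y1), (z0, z1))``.

    Metadata is preserved; the physical origin is offset accordingly.
    """
    bounds = tuple(tuple(b) for b in bounds)
    if len(bounds) != 3:
        raise ValueError("bounds must give a (start, stop) pair per axis")
    for axis, (lo, hi) in enumerate(bounds):
        if not (0 <= lo < hi <= volume.shape[axis]):
            raise ValueError(
                f"axis {axis}: range [{lo}, {hi}) invalid for size {volume.shape[axis]}"
            )
    sl = tuple(slice(lo, hi) for lo, hi in bounds)
    data = volume.data[sl].copy()
    origin = tuple(
        volume.origin[a] + bounds[a][0] * volume.voxel_size for a in range(3)
    )
    cls = type(volume)
    return cls(
        data=data,
        voxel_size=volume.voxel_size,
        axis_labels=volume.axis_labels,
        origin=origin,
        provenance=list(volume.provenance) + [{"op": "crop_roi", "bounds": bounds}],
    )
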