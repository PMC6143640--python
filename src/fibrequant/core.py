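"""Core volume containers shared by all analysis stages.

Conventions
-----------
* Grids are stored with axis order ``(x, y, z)``; axis 0 is ``e_x``
  (mediolateral), axis 1 is ``e_y`` (anteroposterior), axis 2 is ``e_z``
  (inferosuperior).
* Indices are 0-based; physical coordinates are ``index * voxel_size`` (µm),
  i.e. the voxel centre at index ``i`` sits at ``i * voxel_size``.
* Voxels are isotropic; ``voxel_size`` is in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

ANATOMICAL_AXES = ("mediolateral", "anteroposterior", "inferosuperior")

__all__ = ["Volume3D", "Mask3D", "ANATOMICAL_AXES"]


def _check_axis_labels(labels: tuple[str, str, str]) -> None:
    if tuple(sorted(labels)) != tuple(sorted(ANATOMICAL_AXES)):
        raise ValueError(
            f"axis labels must be a permutation of {ANATOMICAL_AXES}, got {labels!r}"
        )


@dataclass
class Volume3D:
    """A greyscale scalar grid with isotropic voxel size.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities.
    voxel_size : float
        Isotropic voxel edge length in µm. Must be positive.
    axis_labels : tuple of str
        Mapping of grid axes to anatomical directions.
    origin : tuple of float
        Physical coordinate (µm) of the voxel at index (0, 0, 0); updated by
        ROI cropping.
    provenance : list
        Ordered record of the operations that produced this volume.
    """

    data: np.ndarray
    voxel_size: float
    axis_labels: tuple[str, str, str] = ANATOMICAL_AXES
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if not (self.voxel_size > 0):
            raise ValueError(f"voxel size must be > 0, got {self.voxel_size}")
        self.axis_labels = tuple(self.axis_labels)  # type: ignore[assignment]
        _check_axis_labels(self.axis_labels)
        self.origin = tuple(float(v) for v in self.origin)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, note: dict[str, Any] | None = None) -> "Volume3D":
        """Return a copy carrying ``data`` and an extended provenance list."""
        prov = list(self.provenance)
        if note is not None:
            prov.append(note)
        return Volume3D(
            data=data,
            voxel_size=self.voxel_size,
            axis_labels=self.axis_labels,
            origin=self.origin,
            provenance=prov,
        )

    def voxel_centres(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (µm) of voxel centres per axis."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.voxel_size
            for a in range(3)
        )  # type: ignore[return-value]


@dataclass
class Mask3D:
    """A boolean grid congruent with a source :class:`Volume3D`."""

    data: np.ndarray
    voxel_size: float
    axis_labels: tuple[str, str, str] = ANATOMICAL_AXES
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        if not (self.voxel_size > 0):
            raise ValueError(f"voxel size must be > 0, got {self.voxel_size}")
        self.axis_labels = tuple(self.axis_labels)  # type: ignore[assignment]
        _check_axis_labels(self.axis_labels)
        self.origin = tuple(float(v) for v in self.origin)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, note: dict[str, Any] | None = None) -> "Mask3D":
        prov = list(self.provenance)
        if note is not None:
            prov.append(note)
        return Mask3D(
            data=data,
            voxel_size=self.voxel_size,
            axis_labels=self.axis_labels,
            origin=self.origin,
            provenance=prov,
        )
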