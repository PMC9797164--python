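"""Volumes, label masks and world/voxel coordinate conversions.

Conventions used throughout the package:

* arrays are indexed ``(x, y, z)`` with an identity direction matrix;
* world coordinates are millimetres, ``world = origin + index * spacing``;
* voxel indices are 0-based and continuous (no half-voxel shift).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume", "LabelMask", "world_to_voxel", "voxel_to_world"]


@dataclass(frozen=True)
class Volume:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    data:
        3D array of intensities (CT-like, arbitrary units). Stored as
        ``float64``.
    spacing:
        Voxel size ``(sx, sy, sz)`` in mm; strictly positive.
    origin:
        World coordinate of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={data.ndim}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume data contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or len(origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> np.ndarray:
        """World-space bounds ``(2, 3)``: min corner and max voxel-center."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return np.stack([lo, hi])

    def same_geometry(self, other: "Volume | LabelMask") -> bool:
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and self.origin == other.origin
        )

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(n, 3)``."""
        idx = np.indices(self.shape, dtype=np.float64).reshape(3, -1).T
        return voxel_to_world(self, idx)

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.spacing, self.origin)


@dataclass(frozen=True)
class LabelMask:
    """Binary region defined on the same grid as a parent :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"mask data must be 3D, got ndim={data.ndim}")
        if data.dtype != bool:
            vals = np.unique(data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask values must be in {0, 1}")
            data = data.astype(bool)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @classmethod
    def from_volume(cls, volume: Volume, data: np.ndarray) -> "LabelMask":
        data = np.asarray(data)
        if data.shape != volume.shape:
            raise ValueError(
                f"mask shape {data.shape} does not match volume shape {volume.shape}"
            )
        return cls(data, volume.spacing, volume.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def same_geometry(self, other: "Volume | LabelMask") -> bool:
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and self.origin == other.origin
        )

    def check_matches(self, volume: "Volume | LabelMask") -> None:
        """Reject geometry mismatch; masks are never silently resampled."""
        if not self.same_geometry(volume):
            raise ValueError(
                "mask geometry does not match volume geometry: "
                f"{self.shape}/{self.spacing}/{self.origin} vs "
                f"{volume.shape}/{volume.spacing}/{volume.origin}"
            )

    def foreground_world(self) -> np.ndarray:
        """World coordinates of foreground voxel centers, shape ``(n, 3)``."""
        idx = np.argwhere(self.data).astype(np.float64)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


def world_to_voxel(volume: Volume | LabelMask, p_world: np.ndarray) -> np.ndarray:
    """Continuous voxel index of world point(s) ``p_world`` (mm).

    Exact inverse of :func:`voxel_to_world`; points outside the grid come
    back with out-of-range indices and are left to the caller.
    """
    p = np.atleast_2d(np.asarray(p_world, dtype=np.float64))
    idx = (p - np.asarray(volume.origin)) / np.asarray(volume.spacing)
    return idx if np.asarray(p_world).ndim > 1 else idx[0]


def voxel_to_world(volume: Volume | LabelMask, idx: np.ndarray) -> np.ndarray:
    """World coordinate (mm) of continuous voxel index/indices ``idx``."""
    v = np.atleast_2d(np.asarray(idx, dtype=np.float64))
    p = v * np.asarray(volume.spacing) + np.asarray(volume.origin)
    return p if np.asarray(idx).ndim > 1 else p[0]
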