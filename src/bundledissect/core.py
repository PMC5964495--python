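"""Core containers: reference spaces, tractograms and volumes.

All geometry downstream of I/O lives in world coordinates (mm, RAS+:
+x right, +y anterior, +z superior). Voxel indices appear only at
interpolation / lookup boundaries, are 0-based, and a voxel's world
position is the center of its cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ReferenceSpace",
    "Tractogram",
    "ScalarVolume",
    "LabelVolume",
    "default_space",
]


@dataclass(frozen=True)
class ReferenceSpace:
    """A 3-D grid embedded in world space by a voxel-to-world affine."""

    affine: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "shape", shape)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel coordinates to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm to continuous voxel coordinates (no rounding)."""
        xyz = np.asarray(xyz, dtype=float)
        inv = self.inverse_affine
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def contains_voxel(self, ijk: np.ndarray) -> np.ndarray:
        """True where integer voxel indices fall inside the grid."""
        ijk = np.asarray(ijk)
        return np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=-1)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of every voxel center, as three grids."""
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        xyz = self.voxel_to_world(pts).reshape(self.shape + (3,))
        return xyz[..., 0], xyz[..., 1], xyz[..., 2]


def default_space(voxel_size: float = 3.0) -> ReferenceSpace:
    """MNI-like bounding grid: x in [-75,75], y in [-110,75], z in [-50,80] mm."""
    lo = np.array([-75.0, -110.0, -50.0])
    hi = np.array([75.0, 75.0, 80.0])
    shape = tuple(int(np.floor((h - l) / voxel_size)) + 1 for l, h in zip(lo, hi))
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size
    affine[:3, 3] = lo
    return ReferenceSpace(affine=affine, shape=shape)


def _as_streamline(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("a streamline needs >=2 points of dimension 3")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline has non-finite coordinates")
    return pts


@dataclass
class Tractogram:
    """Ordered polylines in world mm, sharing one reference space."""

    streamlines: list[np.ndarray]
    space: ReferenceSpace
    tags: list[str] | None = None

    def __post_init__(self) -> None:
        self.streamlines = [_as_streamline(s) for s in self.streamlines]
        if self.tags is not None and len(self.tags) != len(self.streamlines):
            raise ValueError("tags length must match streamline count")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterable[np.ndarray]:
        return iter(self.streamlines)

    def subset(self, indices: Sequence[int]) -> "Tractogram":
        tags = [self.tags[i] for i in indices] if self.tags is not None else None
        return Tractogram([self.streamlines[i] for i in indices], self.space, tags)

    def total_length(self) -> float:
        """Total polyline arc length in mm."""
        return float(
            sum(np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in self.streamlines)
        )


@dataclass
class ScalarVolume:
    """One scalar per voxel (FA, an ADC in μm²/s, a compartment fraction...)."""

    grid: np.ndarray
    space: ReferenceSpace
    units: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.shape != tuple(self.space.shape):
            raise ValueError(
                f"grid shape {self.grid.shape} != space shape {self.space.shape}"
            )


@dataclass
class LabelVolume:
    """Integer parcel grid with a label -> parcel-name map; 0 is background."""

    grid: np.ndarray
    space: ReferenceSpace
    names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise TypeError("label grid must be integer typed")
        if self.grid.shape != tuple(self.space.shape):
            raise ValueError(
                f"grid shape {self.grid.shape} != space shape {self.space.shape}"
            )
        if self.grid.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.grid).tolist()) - {0}
        missing = present - set(int(k) for k in self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    def mask_of(self, name: str) -> np.ndarray:
        ids = [lab for lab, n in self.names.items() if n == name]
        return np.isin(self.grid, ids)
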