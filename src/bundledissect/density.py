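"""Fiber-density rendering, indicator thresholding, group averages and
relative sub-bundle maps.

Density is streamline-*length* splatting: each streamline is resampled
to short steps and every step's length (mm) is distributed over the 8
voxel centers surrounding its midpoint with trilinear weights. The grid
therefore holds "mm of streamline per voxel" and its sum equals the
total in-grid streamline length (the conservation invariant). Relative
maps, in contrast, count *streamlines* passing each voxel, because they
answer "what percentage of bundle streamlines run through here".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ReferenceSpace, Tractogram

logger = logging.getLogger(__name__)

__all__ = [
    "DensityMap",
    "subdivide_polyline",
    "GroupProbabilityMap",
    "resample_polyline",
    "render_density",
    "threshold_indicator",
    "group_average",
    "relative_map",
    "passage_counts",
]


@dataclass
class DensityMap:
    """mm of streamline length per voxel."""

    grid: np.ndarray
    space: ReferenceSpace
    provenance: str = ""
    #: total streamline length that fell outside the grid and was dropped
    dropped_length: float = 0.0


@dataclass
class GroupProbabilityMap:
    """Per-voxel percentage of subjects whose indicator covers the voxel."""

    grid: np.ndarray
    space: ReferenceSpace
    n_subjects: int = 0


def subdivide_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Subdivide every segment into equal parts <= ``step`` mm.

    Unlike :func:`resample_polyline`, the original vertices are kept, so
    the subdivided polyline has *identical* geometry and arc length —
    required for exact mass conservation in density splatting.
    """
    p = np.asarray(points, dtype=float)
    if len(p) < 2:
        return p.copy()
    pieces = []
    for a, b in zip(p[:-1], p[1:]):
        k = max(int(np.ceil(np.linalg.norm(b - a) / step)), 1)
        frac = np.arange(k)[:, None] / k
        pieces.append(a + frac * (b - a))
    pieces.append(p[-1:])
    return np.vstack(pieces)


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing <= ``step`` mm,
    keeping both endpoints exactly (vertices may move along the line)."""
    p = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    total = seg.sum()
    if total == 0 or len(p) < 2:
        return p.copy()
    n = max(int(np.ceil(total / step)), 1)
    s_new = np.linspace(0.0, total, n + 1)
    s_old = np.concatenate([[0.0], np.cumsum(seg)])
    out = np.empty((n + 1, 3))
    for d in range(3):
        out[:, d] = np.interp(s_new, s_old, p[:, d])
    return out


def render_density(t: Tractogram, space: ReferenceSpace | None = None,
                   step: float = 0.5, provenance: str = "") -> DensityMap:
    """Render a streamline-length density map on ``space``'s grid.

    Each resampled step contributes its length at its midpoint via
    trilinear splatting. Out-of-grid mass is dropped and totalled in
    ``dropped_length`` (and logged when nonzero).
    """
    space = space or t.space
    grid = np.zeros(space.shape, dtype=float)
    dropped = 0.0
    shape = np.array(space.shape)
    for s in t.streamlines:
        rp = subdivide_polyline(s, step)
        seg_len = np.linalg.norm(np.diff(rp, axis=0), axis=1)
        mids = 0.5 * (rp[:-1] + rp[1:])
        c = space.world_to_voxel(mids)  # continuous voxel coords of midpoints
        base = np.floor(c).astype(int)
        frac = c - base
        for corner in range(8):
            off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
            idx = base + off
            w = np.prod(np.where(off == 1, frac, 1.0 - frac), axis=1)
            mass = w * seg_len
            inside = np.all((idx >= 0) & (idx < shape), axis=1)
            if np.any(inside):
                np.add.at(grid, tuple(idx[inside].T), mass[inside])
            dropped += float(mass[~inside].sum())
    if dropped > 0:
        logger.info("render_density: dropped %.3f mm outside the grid", dropped)
    return DensityMap(grid=grid, space=space, provenance=provenance,
                      dropped_length=dropped)


def threshold_indicator(d: DensityMap, tau: float = 1.0) -> np.ndarray:
    """Binary indicator: density >= tau (mm of streamline per voxel)."""
    if tau < 0:
        raise ValueError("threshold must be >= 0")
    return d.grid >= tau


def group_average(indicators: list[np.ndarray]) -> GroupProbabilityMap:
    """Average subject indicators into a percent occurrence map."""
    if not indicators:
        raise ValueError("need at least one indicator")
    shape = indicators[0].shape
    for ind in indicators:
        if ind.shape != shape:
            raise ValueError("indicator grids differ in shape")
    stack = np.stack([ind.astype(float) for ind in indicators])
    return GroupProbabilityMap(grid=100.0 * stack.mean(axis=0),
                               space=None,  # set by caller when known
                               n_subjects=len(indicators))


def passage_counts(t: Tractogram, space: ReferenceSpace, step: float = 0.5) -> np.ndarray:
    """Number of distinct streamlines whose resampled points visit each voxel."""
    counts = np.zeros(space.shape, dtype=np.int64)
    shape = np.array(space.shape)
    for s in t.streamlines:
        rp = subdivide_polyline(s, step)
        idx = np.rint(space.world_to_voxel(rp)).astype(int)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        if not np.any(inside):
            continue
        vox = np.unique(idx[inside], axis=0)
        counts[tuple(vox.T)] += 1
    return counts


def relative_map(sub: Tractogram, full: Tractogram, space: ReferenceSpace,
                 step: float = 0.5) -> np.ndarray:
    """Per-voxel percentage of full-bundle streamlines that belong to the
    sub-bundle, among streamlines passing that voxel. 0/0 -> 0."""
    ns = passage_counts(sub, space, step)
    nf = passage_counts(full, space, step)
    out = np.zeros(space.shape, dtype=float)
    np.divide(100.0 * ns, nf, out=out, where=nf > 0)
    return out
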