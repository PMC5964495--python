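"""Deterministic tensor-based FACT streamline propagation.

Classic FACT: from each seed, walk bidirectionally along the principal
eigenvector of the *nearest voxel's* tensor (no interpolation by
default), flipping eigenvector sign to stay aligned with the previous
step. Propagation stops when FA drops below threshold, the turn angle
exceeds the maximum, the walker leaves the white-matter mask or the
grid, or the streamline reaches its length cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Tractogram
from .tensor import TensorVolume, tensor_metrics

logger = logging.getLogger(__name__)

__all__ = ["TrackingParams", "seed_sphere", "track_fact", "dice"]


@dataclass(frozen=True)
class TrackingParams:
    step: float = 1.0            # mm
    fa_threshold: float = 0.15   # stop below this FA
    max_angle: float = 45.0      # degrees per step
    max_length: float = 300.0    # mm per streamline
    interpolate: bool = False    # trilinear direction field instead of nearest voxel

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not 0 <= self.fa_threshold < 1:
            raise ValueError("FA threshold must be in [0, 1)")
        if not 0 < self.max_angle <= 90:
            raise ValueError("max angle must be in (0, 90] degrees")


def seed_sphere(center, radius: float, n: int, seed: int) -> np.ndarray:
    """n points uniform in the ball of ``radius`` around ``center``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return np.asarray(center, float) + v * r[:, None]


def _principal_field(t: TensorVolume) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel principal eigenvector and FA."""
    m = t.as_matrices()
    w, v = np.linalg.eigh(m)
    e1 = v[..., :, 2]  # eigenvector of the largest eigenvalue
    fa = tensor_metrics(t)["fa"].grid
    return e1, fa


def track_fact(t: TensorVolume, wm_mask: np.ndarray,
               params: TrackingParams | None = None,
               seeds: np.ndarray | None = None) -> Tractogram:
    """Propagate FACT streamlines from world-space seed points.

    Seeds outside the grid or the white-matter mask are skipped (count
    logged). Streamlines with fewer than 2 points are discarded. Every
    retained point lies inside ``wm_mask``. Output is deterministic and
    independent of seed ordering.
    """
    p = params or TrackingParams()
    if seeds is None:
        raise ValueError("seeds are required")
    if wm_mask.shape != tuple(t.space.shape):
        raise ValueError("wm_mask must live on the tensor grid")
    e1, fa = _principal_field(t)
    space = t.space
    shape = np.array(space.shape)
    cos_max = np.cos(np.deg2rad(p.max_angle))
    max_steps = int(np.ceil(p.max_length / p.step))

    def voxel_of(pt: np.ndarray) -> tuple[int, int, int] | None:
        ijk = np.rint(space.world_to_voxel(pt)).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= shape):
            return None
        return tuple(ijk)

    def direction_at(pt: np.ndarray) -> tuple[np.ndarray, float] | None:
        if not p.interpolate:
            vox = voxel_of(pt)
            if vox is None or not wm_mask[vox]:
                return None
            return e1[vox], float(fa[vox])
        # trilinear blend of sign-aligned eigenvectors
        c = space.world_to_voxel(pt)
        base = np.floor(c).astype(int)
        frac = c - base
        acc = np.zeros(3)
        fa_acc = 0.0
        ref = None
        for corner in range(8):
            off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
            idx = base + off
            if np.any(idx < 0) or np.any(idx >= shape):
                return None
            idx = tuple(idx)
            if not wm_mask[idx]:
                return None
            w = float(np.prod(np.where(off == 1, frac, 1.0 - frac)))
            v = e1[idx]
            if ref is None:
                ref = v
            if np.dot(v, ref) < 0:
                v = -v
            acc += w * v
            fa_acc += w * float(fa[idx])
        nrm = np.linalg.norm(acc)
        if nrm == 0:
            return None
        return acc / nrm, fa_acc

    def walk(start: np.ndarray, d0: np.ndarray) -> list[np.ndarray]:
        pts = [start]
        prev = d0
        pos = start
        for _ in range(max_steps):
            res = direction_at(pos)
            if res is None:
                break
            v, fa_here = res
            if fa_here < p.fa_threshold:
                break
            if np.dot(v, prev) < 0:
                v = -v
            if np.dot(v, prev) < cos_max:
                break
            nxt = pos + p.step * v
            vox = voxel_of(nxt)
            if vox is None or not wm_mask[vox]:
                break
            pts.append(nxt)
            pos, prev = nxt, v
        return pts

    streamlines: list[np.ndarray] = []
    skipped = 0
    for seed in np.asarray(seeds, dtype=float):
        vox = voxel_of(seed)
        if vox is None or not wm_mask[vox]:
            skipped += 1
            continue
        if fa[vox] < p.fa_threshold:
            continue
        d0 = e1[vox]
        fwd = walk(seed, d0)
        bwd = walk(seed, -d0)
        line = bwd[::-1] + fwd[1:]
        if len(line) >= 2:
            streamlines.append(np.asarray(line))
    if skipped:
        logger.info("track_fact: skipped %d seeds outside volume/mask", skipped)
    return Tractogram(streamlines, space)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of two binary masks; 0/0 -> 0."""
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
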