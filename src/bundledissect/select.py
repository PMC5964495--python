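"""Geometric streamline selection of the superolateral medial forebrain bundle.

Three rules, applied to every streamline of a whole-brain tractogram in
MNI-like world mm:

1. the streamline must visit a 3 mm sphere centered on the lateral
   ventral tegmental area, at (±6, −12, −8);
2. it must connect a frontal region (endpoint with y > 18) to a basal
   region (endpoint with z < −8);
3. it must stay exclusively within one hemisphere (all x strictly > 0
   or strictly < 0; touching the midline voids exclusivity).

The sphere test is segment-aware (distance from the center to every
polyline segment, boundary inclusive), so it is robust to resampling.
All thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Tractogram

__all__ = [
    "SelectionCriteria",
    "visits_sphere",
    "connects_frontal_basal",
    "hemisphere_side",
    "select_slmfb",
    "SelectionResult",
]

VTA_RIGHT = (6.0, -12.0, -8.0)
VTA_LEFT = (-6.0, -12.0, -8.0)


@dataclass(frozen=True)
class SelectionCriteria:
    sphere_center_right: tuple[float, float, float] = VTA_RIGHT
    sphere_center_left: tuple[float, float, float] = VTA_LEFT
    sphere_radius: float = 3.0
    y_front: float = 18.0
    z_base: float = -8.0
    #: test frontal/basal membership on endpoints (terminals) or on any point
    endpoint_rule: bool = True

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere radius must be positive")

    def center(self, side: str) -> np.ndarray:
        return np.asarray(
            self.sphere_center_right if side == "right" else self.sphere_center_left
        )


def _segment_distances(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Min distance from ``center`` to each segment of a polyline."""
    p = np.asarray(points, dtype=float)
    c = np.asarray(center, dtype=float)
    a, b = p[:-1], p[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.einsum("ij,ij->i", c - a, ab) / np.where(denom > 0, denom, 1.0)
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(proj - c, axis=1)


def visits_sphere(points: np.ndarray, center, radius: float) -> bool:
    """True iff the polyline (including between-vertex segments) comes
    within ``radius`` mm of ``center`` (boundary inclusive)."""
    return bool(_segment_distances(points, np.asarray(center, float)).min() <= radius)


def connects_frontal_basal(points: np.ndarray, y_front: float = 18.0,
                           z_base: float = -8.0, endpoint_rule: bool = True) -> bool:
    """True iff the streamline connects frontal (y > y_front) and basal
    (z < z_base) territory. With ``endpoint_rule`` (default) one endpoint
    must be frontal and the other basal; otherwise any visitation counts."""
    p = np.asarray(points, dtype=float)
    if endpoint_rule:
        e0, e1 = p[0], p[-1]
        return bool((e0[1] > y_front and e1[2] < z_base)
                    or (e1[1] > y_front and e0[2] < z_base))
    return bool(np.any(p[:, 1] > y_front) and np.any(p[:, 2] < z_base))


def hemisphere_side(points: np.ndarray) -> str | None:
    """'right' if all x > 0, 'left' if all x < 0, else None (midline
    contact, x == 0, also voids exclusivity)."""
    x = np.asarray(points, dtype=float)[:, 0]
    if np.all(x > 0):
        return "right"
    if np.all(x < 0):
        return "left"
    return None


@dataclass
class SelectionResult:
    """Selected hemispheric bundles plus a per-streamline audit record."""

    right: Tractogram
    left: Tractogram
    #: per input streamline: dict(index, side, passed, failed) where
    #: ``failed`` names the first predicate that failed ('sphere',
    #: 'frontal_basal', 'hemisphere') or None.
    records: list[dict] = field(default_factory=list)

    def selected(self, side: str) -> Tractogram:
        return self.right if side == "right" else self.left


def select_slmfb(t: Tractogram, criteria: SelectionCriteria | None = None) -> SelectionResult:
    """Apply the three selection rules to every streamline.

    A streamline is kept for hemisphere H iff it visits H's sphere, has a
    frontal and a basal terminal, and lies exclusively in H. The audit
    record stores which predicate failed first (sphere → frontal/basal →
    hemisphere), for rejected streamlines.
    """
    c = criteria or SelectionCriteria()
    keep: dict[str, list[int]] = {"right": [], "left": []}
    records: list[dict] = []
    for i, s in enumerate(t.streamlines):
        vis = {side: visits_sphere(s, c.center(side), c.sphere_radius)
               for side in ("right", "left")}
        fb = connects_frontal_basal(s, c.y_front, c.z_base, c.endpoint_rule)
        hemi = hemisphere_side(s)
        failed = None
        side_kept = None
        if not (vis["right"] or vis["left"]):
            failed = "sphere"
        elif not fb:
            failed = "frontal_basal"
        elif hemi is None or not vis[hemi]:
            failed = "hemisphere"
        else:
            side_kept = hemi
            keep[hemi].append(i)
        records.append({"index": i, "side": side_kept,
                        "passed": failed is None, "failed": failed})
    return SelectionResult(right=t.subset(keep["right"]),
                           left=t.subset(keep["left"]),
                           records=records)
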