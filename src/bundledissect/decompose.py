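"""Decomposition of a selected bundle into prefrontal sub-bundles.

Cortical parcellations are thin, so a streamline's membership in a
parcel is decided by its *distal* portion only: the final 20 mm of arc
length before the frontal terminal is resampled finely and tested
against the label volume with nearest-voxel lookup. A streamline may
graze two adjacent parcels and belong to both — sub-bundles are not
forced to be disjoint, so per-parcel percentages can sum to more
than 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LabelVolume, ScalarVolume, Tractogram
from .density import DensityMap, render_density, subdivide_polyline, threshold_indicator

logger = logging.getLogger(__name__)

__all__ = [
    "PARCEL_NAMES",
    "distal_segment",
    "assign_parcels",
    "decompose",
    "SubBundleReport",
    "tract_scalar_stats",
]

#: The eight prefrontal parcels used for sub-bundle decomposition
#: (Desikan/Killiany-style naming; superiorfrontal includes the frontal pole,
#: caudalmiddlefrontal is the pars caudalis of the middle frontal gyrus).
PARCEL_NAMES = (
    "superiorfrontal",
    "rostralmiddlefrontal",
    "caudalmiddlefrontal",
    "lateralorbitofrontal",
    "medialorbitofrontal",
    "parstriangularis",
    "parsopercularis",
    "parsorbitalis",
)


def distal_segment(points: np.ndarray, length: float = 20.0,
                   y_front: float = 18.0) -> np.ndarray:
    """The sub-polyline of arc length min(length, total) ending at the
    frontal terminal (endpoint with y > y_front), with an interpolated cut
    so the arc length is exact.

    If neither or both endpoints are frontal the endpoint with larger y is
    used (logged once per call site at debug level).
    """
    p = np.asarray(points, dtype=float)
    front_first = p[0, 1] > y_front
    front_last = p[-1, 1] > y_front
    if front_first == front_last:  # ambiguous: both or neither frontal
        logger.debug("ambiguous frontal endpoint; using the larger-y endpoint")
        front_last = p[-1, 1] >= p[0, 1]
    if not front_last:
        p = p[::-1]
    if length <= 0:
        return p[-1:].copy()
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s_cum = np.concatenate([[0.0], np.cumsum(seg)])  # arc length at each vertex
    total = s_cum[-1]
    if total <= length:
        return p.copy()
    cut_s = total - length  # arc position of the cut, measured from the far end
    j = int(np.searchsorted(s_cum, cut_s, side="right"))  # first vertex past the cut
    if np.isclose(s_cum[j - 1], cut_s):
        return p[j - 1:].copy()
    frac = (cut_s - s_cum[j - 1]) / (s_cum[j] - s_cum[j - 1])
    cut = p[j - 1] + frac * (p[j] - p[j - 1])
    return np.vstack([cut, p[j:]])


def assign_parcels(points: np.ndarray, labels: LabelVolume, length: float = 20.0,
                   step: float = 0.5, parcel_names: set[str] | None = None,
                   y_front: float = 18.0) -> set[str]:
    """Prefrontal parcel names hit by the distal segment.

    The distal segment is resampled at <= ``step`` mm and each sample is
    looked up in the label grid with nearest-voxel (no label interpolation).
    Only names in ``parcel_names`` count (default: the eight prefrontal
    parcels, matched as a suffix so hemisphere-prefixed label names work).
    """
    seg = distal_segment(points, length=length, y_front=y_front)
    rp = subdivide_polyline(seg, step) if len(seg) > 1 else seg
    idx = np.rint(labels.space.world_to_voxel(rp)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(labels.space.shape)), axis=1)
    hit_ids = np.unique(labels.grid[tuple(idx[inside].T)]) if np.any(inside) else []
    wanted = set(parcel_names) if parcel_names is not None else set(PARCEL_NAMES)
    out: set[str] = set()
    for lab in hit_ids:
        if lab == 0:
            continue
        name = labels.names.get(int(lab))
        if name is None:
            continue
        base = name.split("-", 1)[-1] if name[:3] in ("rh-", "lh-") else name
        if base in wanted or name in wanted:
            out.add(name)
    return out


@dataclass
class SubBundleReport:
    """Table-style summary of a decomposed hemispheric bundle."""

    hemisphere: str
    n_total: int
    n_frontal: int
    counts: dict[str, int]
    percent_of_frontal: dict[str, float]
    percent_of_full: float
    scalar_means: dict[str, dict[str, float]] = field(default_factory=dict)
    n_non_frontal: int = 0

    def to_frame(self, per_mille: bool = False) -> pd.DataFrame:
        """One row per parcel with counts, percentages and scalar means.

        ``per_mille`` multiplies FA and compartment fractions by 1000 for
        direct comparison with per-mille normative tables.
        """
        rows = []
        for parcel, count in self.counts.items():
            row = {"hemisphere": self.hemisphere, "parcel": parcel,
                   "count": count,
                   "percent_of_frontal": self.percent_of_frontal[parcel]}
            for scalar, means in self.scalar_means.items():
                v = means.get(parcel, float("nan"))
                if per_mille and scalar in ("fa", "intra_axonal", "extra_axonal"):
                    v = v * 1000.0
                row[scalar] = v
            rows.append(row)
        return pd.DataFrame(rows)


def decompose(slmfb: Tractogram, labels: LabelVolume, hemisphere: str = "",
              length: float = 20.0, step: float = 0.5,
              parcel_names: tuple[str, ...] = PARCEL_NAMES,
              y_front: float = 18.0) -> tuple[SubBundleReport, list[set[str]]]:
    """Split a selected single-hemisphere bundle into prefrontal sub-bundles.

    Returns the report skeleton (counts, % of frontal projection, % of
    full) and the per-streamline parcel sets. Streamlines whose distal
    segment hits no prefrontal parcel form the non-frontal residual; they
    enter the "% of full" denominator but are not percentaged.
    """
    parcel_sets = [assign_parcels(s, labels, length=length, step=step,
                                  parcel_names=set(parcel_names), y_front=y_front)
                   for s in slmfb.streamlines]
    frontal = [ps for ps in parcel_sets if ps]
    n_total = len(slmfb)
    n_frontal = len(frontal)

    def base(name: str) -> str:
        return name.split("-", 1)[-1] if name[:3] in ("rh-", "lh-") else name

    counts = {p: 0 for p in parcel_names}
    for ps in parcel_sets:
        for name in ps:
            counts[base(name)] = counts.get(base(name), 0) + 1
    pct = {p: (100.0 * c / n_frontal if n_frontal else 0.0)
           for p, c in counts.items()}
    report = SubBundleReport(
        hemisphere=hemisphere,
        n_total=n_total,
        n_frontal=n_frontal,
        counts=counts,
        percent_of_frontal=pct,
        percent_of_full=(100.0 * n_frontal / n_total if n_total else 0.0),
        n_non_frontal=n_total - n_frontal,
    )
    return report, parcel_sets


def tract_scalar_stats(region: np.ndarray, scalars: dict[str, ScalarVolume],
                       weights: np.ndarray | None = None) -> dict[str, float]:
    """Mean of each scalar over a tract-defined region.

    ``region`` is a binary voxel mask (typically a density map thresholded
    at 1 mm of streamline length per voxel); ``weights`` switches to a
    density-weighted mean. An empty region yields NaN for every scalar.
    """
    out: dict[str, float] = {}
    if not np.any(region):
        logger.warning("tract_scalar_stats: empty region")
        return {name: float("nan") for name in scalars}
    for name, vol in scalars.items():
        if vol.grid.shape != region.shape:
            raise ValueError(f"scalar {name!r} grid does not match region shape")
        vals = vol.grid[region]
        if weights is not None:
            w = weights[region]
            out[name] = float(np.average(vals, weights=w)) if w.sum() > 0 else float("nan")
        else:
            out[name] = float(vals.mean())
    return out


def subbundle_scalar_means(slmfb: Tractogram, parcel_sets: list[set[str]],
                           scalars: dict[str, ScalarVolume],
                           parcel_names: tuple[str, ...] = PARCEL_NAMES,
                           density_threshold: float = 1.0,
                           step: float = 0.5) -> dict[str, dict[str, float]]:
    """Tract-averaged scalars per sub-bundle.

    For each parcel, the sub-bundle's density map is thresholded (default
    1 mm of streamline length per voxel) and every scalar is averaged over
    that region (unweighted).
    """
    def base(name: str) -> str:
        return name.split("-", 1)[-1] if name[:3] in ("rh-", "lh-") else name

    space = next(iter(scalars.values())).space if scalars else slmfb.space
    means: dict[str, dict[str, float]] = {name: {} for name in scalars}
    for parcel in parcel_names:
        idx = [i for i, ps in enumerate(parcel_sets)
               if any(base(n) == parcel for n in ps)]
        if not idx:
            for name in scalars:
                means[name][parcel] = float("nan")
            continue
        dens = render_density(slmfb.subset(idx), space, step=step)
        region = threshold_indicator(dens, density_threshold)
        stats = tract_scalar_stats(region, scalars)
        for name, v in stats.items():
            means[name][parcel] = v
    return means
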