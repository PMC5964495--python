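"""Table-style reporting of sub-bundle anatomy and microstructure.

The canonical report has one row per hemisphere × prefrontal parcel
with the streamline percentage of all frontal projections and
tract-averaged scalars (FA and compartment fractions optionally in
parts per thousand, ADCs in μm²/s). The module also ships the published
normative group table for the superolateral medial forebrain bundle in
adults (n = 55), used as a consistency reference: its three dominant
parcels (superior frontal, rostral middle frontal, lateral
orbitofrontal) carry nearly the entire frontal projection.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .decompose import SubBundleReport

__all__ = [
    "reference_table",
    "dominant_projection_sum",
    "group_table",
    "recovery_table",
]

# Published normative group means (per-mille FA and compartment fractions,
# μm²/s ADCs, percent of frontal projection), eight prefrontal parcels per
# hemisphere. Used only as a reference for consistency checks.
_REFERENCE_CSV = """\
hemisphere,parcel,fa,axial_adc,mean_adc,radial_adc,extra_axonal,intra_axonal,percent_of_frontal
right,superiorfrontal,354,923,799,549,376,451,38
right,rostralmiddlefrontal,341,921,802,564,386,437,35
right,lateralorbitofrontal,342,941,821,581,382,433,24
right,parstriangularis,365,938,810,557,367,451,15
right,parsorbitalis,362,942,816,565,371,445,11
right,parsopercularis,414,917,776,496,354,479,2
right,medialorbitofrontal,377,942,811,548,374,447,5
right,caudalmiddlefrontal,422,908,766,479,347,489,1
left,superiorfrontal,351,939,815,566,379,439,31
left,rostralmiddlefrontal,342,933,812,571,382,438,35
left,lateralorbitofrontal,333,953,834,597,381,427,32
left,parstriangularis,363,950,823,569,364,449,16
left,parsorbitalis,364,954,827,572,369,443,8
left,parsopercularis,405,949,810,531,348,475,3
left,medialorbitofrontal,356,960,833,580,377,433,7
left,caudalmiddlefrontal,421,928,784,496,336,500,2
"""


def reference_table() -> pd.DataFrame:
    """The normative group table as a DataFrame (one row per
    hemisphere × parcel)."""
    return pd.read_csv(io.StringIO(_REFERENCE_CSV))


def dominant_projection_sum(table: pd.DataFrame, hemisphere: str, k: int = 3) -> float:
    """Sum of the ``k`` largest per-parcel percentages of the frontal
    projection for one hemisphere — the share of the bundle carried by its
    dominant sub-bundles."""
    sub = table[table["hemisphere"] == hemisphere]
    if sub.empty:
        raise ValueError(f"no rows for hemisphere {hemisphere!r}")
    return float(sub["percent_of_frontal"].nlargest(k).sum())


def group_table(reports: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean over subjects of per-(hemisphere, parcel) report rows."""
    if not reports:
        raise ValueError("no subject reports")
    allrows = pd.concat(reports, ignore_index=True)
    num = allrows.select_dtypes(include=[np.number]).columns
    return (allrows.groupby(["hemisphere", "parcel"], sort=False)[list(num)]
            .mean().reset_index())


def recovery_table(estimated: pd.DataFrame, true_proportions: dict[str, float]
                   ) -> pd.DataFrame:
    """True vs estimated parcel percentages with absolute errors.

    ``estimated`` needs columns parcel / percent_of_frontal (already
    averaged over subjects and hemispheres as desired)."""
    rows = []
    for parcel, frac in true_proportions.items():
        est = estimated.loc[estimated["parcel"] == parcel, "percent_of_frontal"]
        est_pct = float(est.mean()) if len(est) else float("nan")
        rows.append({"parcel": parcel, "true_percent": 100.0 * frac,
                     "estimated_percent": est_pct,
                     "abs_error": abs(est_pct - 100.0 * frac)})
    return pd.DataFrame(rows)
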