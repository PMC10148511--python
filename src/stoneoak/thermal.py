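"""Thermal-zone classification of species distribution centers.

Species are placed in warmth-index zones by the mean annual temperature
(MAT, degrees C) of their distribution center: tropical above 22, subtropical
on (19, 22], warm temperate on [11, 19], and flagged out-of-range below 11.
The boundary closure (19.0 -> warm temperate, 22.0 -> subtropical, strictly
above 22 -> tropical) is the unique closure consistent with published zone
tables.  The center is the median MAT over a species' localities; comparing
it with the mean flags skewed distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

ZONES = ("tropical", "subtropical", "warm_temperate", "out_of_range")
# rank for "cooler than" comparisons; out_of_range is coolest
_ZONE_RANK = {"tropical": 0, "subtropical": 1, "warm_temperate": 2, "out_of_range": 3}


class ThermalError(ValueError):
    pass


@dataclass
class ThermalProfile:
    species: str
    median_mat: float
    mean_mat: float
    median_zone: str
    mean_zone: str
    skew: str  # "none" | "toward_colder" | "toward_warmer"
    mat_values: np.ndarray | None = None
    fruit_type: str | None = None


def classify_mat(t: float) -> str:
    """Zone of a single MAT value (degrees C)."""
    if not math.isfinite(t):
        raise ThermalError(f"MAT must be finite, got {t!r}")
    if t > 22.0:
        return "tropical"
    if t > 19.0:
        return "subtropical"
    if t >= 11.0:
        return "warm_temperate"
    return "out_of_range"


def thermal_profile(
    species: str,
    mat_values=None,
    median: float | None = None,
    mean: float | None = None,
    fruit_type: str | None = None,
) -> ThermalProfile:
    """Build a per-species thermal profile from locality MATs or summaries.

    The median uses the midpoint rule for even counts.  The skew flag is set
    when the median- and mean-based zones disagree: ``toward_colder`` when
    the mean falls in the cooler zone (distribution tail toward cold sites),
    ``toward_warmer`` otherwise.
    """
    if mat_values is not None:
        vals = np.asarray(mat_values, dtype=float)
        if vals.size == 0:
            raise ThermalError(f"{species}: empty MAT sample")
        if not np.all(np.isfinite(vals)):
            raise ThermalError(f"{species}: non-finite MAT value")
        med, mn = float(np.median(vals)), float(vals.mean())
    else:
        if median is None or mean is None:
            raise ThermalError(f"{species}: need MAT values or both median and mean")
        vals, med, mn = None, float(median), float(mean)
    mz, ez = classify_mat(med), classify_mat(mn)
    if mz == ez:
        skew = "none"
    elif _ZONE_RANK[ez] > _ZONE_RANK[mz]:
        skew = "toward_colder"
    else:
        skew = "toward_warmer"
    return ThermalProfile(species=species, median_mat=med, mean_mat=mn,
                          median_zone=mz, mean_zone=ez, skew=skew,
                          mat_values=vals, fruit_type=fruit_type)


def profiles_from_table(table: pd.DataFrame) -> list[ThermalProfile]:
    """Profiles from a summary table with ``median_mat`` / ``mean_mat`` columns."""
    return [
        thermal_profile(
            row["species"], median=row["median_mat"], mean=row["mean_mat"],
            fruit_type=row.get("fruit_type"),
        )
        for _, row in table.iterrows()
    ]


def zone_summary(profiles: list[ThermalProfile]) -> dict:
    """Zone contingency counts and median/mean mismatch bookkeeping."""
    overall = {z: 0 for z in ZONES}
    by_type: dict[str, dict[str, int]] = {}
    mismatches = []
    skew_counts = {"toward_colder": 0, "toward_warmer": 0}
    pair_counts: dict[tuple[str, str], int] = {}
    for p in profiles:
        overall[p.median_zone] += 1
        ft = p.fruit_type or "unlabeled"
        by_type.setdefault(ft, {z: 0 for z in ZONES})[p.median_zone] += 1
        if p.skew != "none":
            mismatches.append(p.species)
            skew_counts[p.skew] += 1
            key = (p.median_zone, p.mean_zone)
            pair_counts[key] = pair_counts.get(key, 0) + 1
    return dict(
        overall={z: c for z, c in overall.items() if c},
        by_fruit_type={ft: {z: c for z, c in zc.items() if c} for ft, zc in by_type.items()},
        n_mismatch=len(mismatches),
        mismatch_species=mismatches,
        skew_counts=skew_counts,
        mismatch_pairs={f"{a}->{b}": c for (a, b), c in sorted(pair_counts.items())},
    )
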