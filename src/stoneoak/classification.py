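"""Species-level aggregation, AC/ER fruit-type assignment, group contrasts.

A species is called ER (enclosed receptacle) when its mean seed-surface
coverage by receptacle exceeds the coverage by pericarp (``S_r > S_p``), and
AC (acorn) otherwise; an exact tie is classified AC with an ambiguity flag,
since ER is defined by strict receptacle dominance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DIMENSIONS = ["S_p", "S_r", "S_s", "V_p", "V_r", "V_s"]


class ClassificationError(ValueError):
    pass


@dataclass
class SpeciesRecord:
    """One species: fruit-type label, sample size and mean dimensions."""

    species: str
    fruit_type: str  # "AC" | "ER" | "unassigned"
    n: int
    means: dict[str, float]
    fruit_dimensions: pd.DataFrame | None = None
    ambiguous: bool = False

    @property
    def V_h(self) -> float:
        return self.means["V_p"] + self.means["V_r"]

    @property
    def defense_index(self) -> float:
        return self.V_h / self.means["S_s"]


@dataclass
class GroupContrast:
    dimension: str
    counts: dict[str, int]
    means: dict[str, float]
    sds: dict[str, float]
    statistic: float
    p_value: float
    er_exceeds_ac: bool


def species_means(fruit_table: pd.DataFrame) -> list[SpeciesRecord]:
    """Aggregate a per-fruit dimension table into per-species records.

    Each row must carry a ``species`` key and the six dimension columns.
    Empty groups cannot arise from a well-formed table; species whose rows
    are all-NaN in any dimension are excluded with a warning attribute.
    """
    if "species" not in fruit_table.columns:
        raise ClassificationError("fruit table must have a 'species' column")
    missing = [c for c in DIMENSIONS if c not in fruit_table.columns]
    if missing:
        raise ClassificationError(f"fruit table missing dimension columns {missing}")
    records = []
    for sp, grp in fruit_table.groupby("species", sort=True):
        sub = grp[DIMENSIONS].dropna()
        if len(sub) == 0:
            continue
        means = sub.mean().to_dict()
        rec = SpeciesRecord(
            species=str(sp), fruit_type="unassigned", n=len(sub),
            means=means, fruit_dimensions=sub.reset_index(drop=True),
        )
        rec.fruit_type = classify_species(rec)
        records.append(rec)
    return records


def classify_species(rec: SpeciesRecord) -> str:
    """AC/ER call from mean seed coverages; ties go to AC with a flag."""
    S_p, S_r = rec.means.get("S_p"), rec.means.get("S_r")
    if S_p is None or S_r is None or not (np.isfinite(S_p) and np.isfinite(S_r)):
        return "unassigned"
    if S_r > S_p:
        return "ER"
    if S_r == S_p:
        rec.ambiguous = True
    return "AC"


def records_from_species_table(table: pd.DataFrame) -> list[SpeciesRecord]:
    """Build records from a species-mean table (``table1``-shaped fixture)."""
    records = []
    for _, row in table.iterrows():
        rec = SpeciesRecord(
            species=row["species"],
            fruit_type="unassigned",
            n=int(row.get("n", 1)),
            means={c: float(row[c]) for c in DIMENSIONS},
        )
        rec.fruit_type = classify_species(rec)
        records.append(rec)
    return records


def records_to_frame(records: list[SpeciesRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dict(species=r.species, fruit_type=r.fruit_type, n=r.n, **r.means)
        d["V_h"] = r.V_h
        d["defense_index"] = r.defense_index
        rows.append(d)
    return pd.DataFrame(rows)


def intraspecific_subset(records: list[SpeciesRecord], min_n: int = 8) -> list[SpeciesRecord]:
    """Species with enough fruits for within-species analysis (default >= 8)."""
    return [r for r in records if r.n >= min_n]


def group_contrast(records: list[SpeciesRecord], dimension: str) -> GroupContrast:
    """Welch two-sample contrast of a dimension between the fruit types.

    Species are the units (one value per species).  ``dimension`` may be any
    of the six dimensions, ``V_h`` or ``defense_index``.
    """
    def value(r: SpeciesRecord) -> float:
        if dimension == "V_h":
            return r.V_h
        if dimension == "defense_index":
            return r.defense_index
        if dimension not in r.means:
            raise ClassificationError(f"unknown dimension {dimension!r}")
        return r.means[dimension]

    groups = {
        ft: np.array([value(r) for r in records if r.fruit_type == ft])
        for ft in ("AC", "ER")
    }
    for ft, vals in groups.items():
        if len(vals) < 2:
            raise ClassificationError(f"fruit type {ft} has fewer than 2 species")
    if np.allclose(groups["AC"].mean(), groups["ER"].mean()) and np.array_equal(
        np.sort(groups["AC"]), np.sort(groups["ER"])
    ):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ttest_ind(groups["ER"], groups["AC"], equal_var=False)
    return GroupContrast(
        dimension=dimension,
        counts={ft: len(v) for ft, v in groups.items()},
        means={ft: float(v.mean()) for ft, v in groups.items()},
        sds={ft: float(v.std(ddof=1)) for ft, v in groups.items()},
        statistic=float(stat),
        p_value=float(p),
        er_exceeds_ac=bool(groups["ER"].mean() > groups["AC"].mean()),
    )
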