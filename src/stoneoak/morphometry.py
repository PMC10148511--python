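"""Fruit tissue surface areas and volumes from longitudinal-section measurements.

A stone-oak fruit is treated as a solid of revolution about its longitudinal
axis.  On one half-plane of the longitudinal section, twelve quantities are
measured per fruit: for each of the three tissues -- pericarp (``p``),
receptacle (``r``) and seed space (``s``) -- the boundary-curve length ``L``
(cm), the distance ``r`` from the axis to the centroid of that curve (cm),
the section region area ``A`` (cm^2) and the distance ``R`` from the axis to
the centroid of that region (cm).

The theorems of Pappus and Guldinus then give the full-revolution surface
area ``S = 2 pi r L`` and volume ``V = 2 pi R A`` of each tissue.  Husk
volume is ``V_h = V_p + V_r`` and the mechanical-defense index is
``V_h / S_s`` (cm^3 of husk per cm^2 of seed surface).

All quantities are in cm / cm^2 / cm^3; no unit auto-detection is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import pandas as pd

TISSUES = ("p", "r", "s")

PARAMETER_COLUMNS = [f"{q}_{t}" for q in ("L", "r", "A", "R") for t in TISSUES]
DIMENSION_COLUMNS = ["S_p", "S_r", "S_s", "V_p", "V_r", "V_s", "V_h", "defense_index"]


class MorphometryError(ValueError):
    """Invalid section parameters or an undefined derived quantity."""


@dataclass(frozen=True)
class SectionParameters:
    """The twelve per-fruit section measurements (cm-based units)."""

    L_p: float
    L_r: float
    L_s: float
    r_p: float
    r_r: float
    r_s: float
    A_p: float
    A_r: float
    A_s: float
    R_p: float
    R_r: float
    R_s: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise MorphometryError(
                    f"section parameter {f.name} must be finite and >= 0, got {v!r}"
                )
        for t in TISSUES:
            L, A = getattr(self, f"L_{t}"), getattr(self, f"A_{t}")
            if (L == 0.0) != (A == 0.0):
                raise MorphometryError(
                    f"tissue {t!r}: zero curve length must pair with zero area "
                    f"(L_{t}={L}, A_{t}={A})"
                )

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class MorphometricDimensions:
    """Derived per-fruit dimensions: surfaces (cm^2), volumes (cm^3)."""

    S_p: float
    S_r: float
    S_s: float
    V_p: float
    V_r: float
    V_s: float
    V_h: float
    defense_index: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def surface_of_revolution(L: float, r: float) -> float:
    """Area swept by a plane curve of length ``L`` revolved about the axis.

    ``r`` is the distance from the axis to the curve's centroid; the result is
    ``2 pi r L`` (one full revolution).
    """
    if L < 0 or r < 0:
        raise MorphometryError(f"curve length and centroid distance must be >= 0 (L={L}, r={r})")
    return 2.0 * math.pi * r * L


def volume_of_revolution(A: float, R: float) -> float:
    """Volume swept by a plane region of area ``A`` revolved about the axis.

    ``R`` is the distance from the axis to the region's centroid; the result
    is ``2 pi R A`` (one full revolution).
    """
    if A < 0 or R < 0:
        raise MorphometryError(f"region area and centroid distance must be >= 0 (A={A}, R={R})")
    return 2.0 * math.pi * R * A


def compute_dimensions(p: SectionParameters) -> MorphometricDimensions:
    """Derive the six tissue dimensions plus husk volume and defense index.

    The defense index is ``V_h / S_s``; it is 0 for a fully degenerate fruit
    (no husk, no seed surface) and an error when a husk exists but the seed
    surface is zero.
    """
    S = {t: surface_of_revolution(getattr(p, f"L_{t}"), getattr(p, f"r_{t}")) for t in TISSUES}
    V = {t: volume_of_revolution(getattr(p, f"A_{t}"), getattr(p, f"R_{t}")) for t in TISSUES}
    V_h = V["p"] + V["r"]
    if S["s"] == 0.0:
        if V_h > 0.0:
            raise MorphometryError("defense index undefined: S_s = 0 with nonzero husk volume")
        defense = 0.0
    else:
        defense = V_h / S["s"]
    return MorphometricDimensions(
        S_p=S["p"], S_r=S["r"], S_s=S["s"],
        V_p=V["p"], V_r=V["r"], V_s=V["s"],
        V_h=V_h, defense_index=defense,
    )


# ---------------------------------------------------------------------------
# tabular interface

def compute_dimensions_table(params: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`compute_dimensions` over a per-fruit parameter table.

    ``params`` must carry the twelve parameter columns; identifier columns
    (``fruit_id``, ``species``) are passed through unchanged.
    """
    missing = [c for c in PARAMETER_COLUMNS if c not in params.columns]
    if missing:
        raise MorphometryError(f"parameter table is missing columns: {missing}")
    out = params.loc[:, [c for c in ("fruit_id", "species") if c in params.columns]].copy()
    rows = [
        compute_dimensions(SectionParameters(**{c: float(row[c]) for c in PARAMETER_COLUMNS})).as_dict()
        for _, row in params.iterrows()
    ]
    dims = pd.DataFrame(rows, index=params.index)
    return pd.concat([out, dims], axis=1)


def read_parameters_csv(path) -> pd.DataFrame:
    """Read a per-fruit section-parameter CSV (comma, header, UTF-8)."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in PARAMETER_COLUMNS if c not in df.columns]
    if missing:
        raise MorphometryError(f"{path}: missing parameter columns {missing}")
    return df


def write_parameters_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")
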