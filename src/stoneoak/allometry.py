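"""Standard major axis (SMA) allometry on log10-transformed dimensions.

For a power law ``y = c x^b``, log-transform gives the line
``log10 y = log10 c + b log10 x``.  The SMA slope is
``sign(cov) * sd(log10 y) / sd(log10 x)`` -- symmetric in the sense that
swapping the axes inverts the slope -- and is the standard line-fitting
choice in allometry, where both variables carry biological variation.

The common-slope (slope heterogeneity) test follows the likelihood-ratio
construction of Warton & Weber: at slope ``b`` the SMA residual
``y - b x`` and fitted axis ``y + b x`` scores are uncorrelated within a
group iff ``b`` is that group's SMA slope, so
``LR(b) = -sum_i w_i ln(1 - r_i(b)^2)`` (with ``r_i`` the residual/fitted
correlation and ``w_i = n_i - 2.5``, a small-sample Bartlett factor)
minimized over ``b`` is compared to a chi-square with ``groups - 1``
degrees of freedom.  A seeded residual-permutation p-value is optional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class AllometryError(ValueError):
    pass


@dataclass
class SMAFit:
    slope: float
    intercept: float  # on the log10 scale
    r: float
    n: int
    ci_lower: float
    ci_upper: float
    group: str = ""

    @property
    def allometric_constant(self) -> float:
        return 10.0 ** self.intercept


@dataclass
class SlopeHeterogeneityResult:
    group_slopes: dict[str, float]
    common_slope: float
    statistic: float
    df: int
    p_value: float
    perm_p_value: float | None = None
    n_perm: int = 0
    seed: int | None = None


def _log_moments(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AllometryError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise AllometryError(f"need n >= 3 points, got {len(x)}")
    for name, v in (("x", x), ("y", y)):
        bad = np.nonzero(~(v > 0))[0]
        if len(bad):
            raise AllometryError(f"non-positive {name} value at row {bad[0]} (log-transform)")
    lx, ly = np.log10(x), np.log10(y)
    sxx = np.var(lx, ddof=1)
    syy = np.var(ly, ddof=1)
    sxy = np.cov(lx, ly, ddof=1)[0, 1]
    if sxx == 0 or syy == 0:
        raise AllometryError("zero variance on the log scale")
    return lx, ly, sxx, syy, sxy


def sma_fit(x, y, alpha: float = 0.05, group: str = "") -> SMAFit:
    """Fit the SMA line to positive data after log10 transformation.

    The slope CI uses the standard F-pivot: with
    ``B = F(1-alpha; 1, n-2) (1 - r^2)/(n - 2)``, the interval is
    ``b (sqrt(B + 1) +/- sqrt(B))``.
    """
    lx, ly, sxx, syy, sxy = _log_moments(x, y)
    n = len(lx)
    r = sxy / math.sqrt(sxx * syy)
    slope = math.copysign(math.sqrt(syy / sxx), sxy if sxy != 0 else 1.0)
    intercept = float(ly.mean() - slope * lx.mean())
    B = stats.f.ppf(1 - alpha, 1, n - 2) * (1 - r * r) / (n - 2)
    lo = slope * (math.sqrt(B + 1) - math.sqrt(B))
    hi = slope * (math.sqrt(B + 1) + math.sqrt(B))
    if lo > hi:
        lo, hi = hi, lo
    return SMAFit(slope=slope, intercept=intercept, r=float(r), n=n,
                  ci_lower=float(lo), ci_upper=float(hi), group=group)


def _res_fit_corr2(b, sxx, syy, sxy):
    """Squared correlation between SMA residual and fitted-axis scores."""
    vu = syy - 2 * b * sxy + b * b * sxx
    vv = syy + 2 * b * sxy + b * b * sxx
    cuv = syy - b * b * sxx
    if vu <= 0 or vv <= 0:
        return 1.0
    return min(cuv * cuv / (vu * vv), 1.0 - 1e-15)


def slope_heterogeneity_test(
    groups: dict[str, tuple[np.ndarray, np.ndarray]],
    n_perm: int = 0,
    seed: int | None = None,
    bartlett: bool = True,
) -> SlopeHeterogeneityResult:
    """Likelihood-ratio test of a common SMA slope across labeled groups."""
    if len(groups) < 2:
        raise AllometryError("need at least two groups")
    moms, slopes = {}, {}
    for g, (x, y) in groups.items():
        lx, ly, sxx, syy, sxy = _log_moments(x, y)
        w = (len(lx) - 2.5) if bartlett else len(lx)
        moms[g] = (lx, ly, sxx, syy, sxy, w)
        slopes[g] = sma_fit(x, y, group=g).slope

    def lr(b):
        return -sum(w * math.log1p(-_res_fit_corr2(b, sxx, syy, sxy))
                    for (_, _, sxx, syy, sxy, w) in moms.values())

    sgn = math.copysign(1.0, np.mean(list(slopes.values())))
    mags = [abs(s) for s in slopes.values()]
    res = optimize.minimize_scalar(
        lambda u: lr(sgn * math.exp(u)),
        bounds=(math.log(min(mags)) - 2, math.log(max(mags)) + 2),
        method="bounded", options=dict(xatol=1e-12),
    )
    b_common = sgn * math.exp(res.x)
    statistic = max(lr(b_common), 0.0)
    df = len(groups) - 1
    p = float(stats.chi2.sf(statistic, df))

    perm_p = None
    if n_perm > 0:
        # permute group labels of the (x, y) pairs, seeded
        rng = np.random.default_rng(seed)
        allx = np.concatenate([np.asarray(x, float) for x, _ in groups.values()])
        ally = np.concatenate([np.asarray(y, float) for _, y in groups.values()])
        sizes = [len(x) for x, _ in groups.values()]
        hits = 0
        for _ in range(n_perm):
            idx = rng.permutation(len(allx))
            start, gperm = 0, {}
            for g, m in zip(groups, sizes):
                sel = idx[start:start + m]
                gperm[g] = (allx[sel], ally[sel])
                start += m
            try:
                stat_p = slope_heterogeneity_test(gperm, bartlett=bartlett).statistic
            except AllometryError:
                continue
            hits += stat_p >= statistic
        perm_p = (hits + 1) / (n_perm + 1)
    return SlopeHeterogeneityResult(
        group_slopes=slopes, common_slope=float(b_common), statistic=float(statistic),
        df=df, p_value=p, perm_p_value=perm_p, n_perm=n_perm, seed=seed,
    )


def fit_fruit_type_allometries(
    species_table, min_n: int = 8, n_perm: int = 0, seed: int | None = None
) -> dict:
    """Per-fruit-type SMA fits for the coverage and volume dimension pairs.

    For each pair the pericarp dimension is the dependent variable
    (``S_p ~ S_r`` and ``V_p ~ V_r``) and species means are the units.  By
    default only species with at least ``min_n`` fruits enter the fits (the
    measurement error of small-sample species means otherwise dilutes the
    slopes); pass ``min_n=1`` to use every species.
    """
    import pandas as pd

    from .classification import SpeciesRecord, records_to_frame

    if isinstance(species_table, list) and (
        not species_table or isinstance(species_table[0], SpeciesRecord)
    ):
        species_table = records_to_frame(species_table)
    df = pd.DataFrame(species_table)
    df = df[df["n"] >= min_n]
    pairs = {"coverage": ("S_r", "S_p"), "volume": ("V_r", "V_p")}
    report: dict = {"min_n": int(min_n), "pairs": {}}
    for pair, (xc, yc) in pairs.items():
        fits, grp_data = {}, {}
        for ft, grp in df.groupby("fruit_type"):
            if len(grp) < 3:
                report.setdefault("warnings", []).append(
                    f"{pair}: group {ft} too small ({len(grp)}), skipped")
                continue
            x, y = grp[xc].to_numpy(), grp[yc].to_numpy()
            fits[ft] = sma_fit(x, y, group=ft)
            grp_data[ft] = (x, y)
        entry = {"fits": fits}
        if len(grp_data) >= 2:
            entry["heterogeneity"] = slope_heterogeneity_test(
                grp_data, n_perm=n_perm, seed=seed)
        report["pairs"][pair] = entry
    return report
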