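"""Parametric fruit longitudinal profiles and their section parameters.

The fruit is modeled as a solid of revolution.  The seed space is an
ellipsoid: on the half-plane right of the rotation axis its boundary is the
parametric curve ``z(t) = -b cos(pi t)``, ``r(t) = a sin(pi t)`` for
``t in [0, 1]`` (``t = 0`` at the base pole, ``t = 1`` at the apex), with
``a`` the radial and ``b`` the axial semi-axis in cm.

The two husk tissues are shells offset outward from the seed boundary along
its normal: the pericarp adjoins the apical fraction ``f_p`` of the seed
boundary arc, the receptacle the basal fraction ``f_r``.  This encodes the
two archetypes: acorn (AC) fruits have a thin pericarp covering most of the
seed with a basal receptacle; enclosed-receptacle (ER) fruits have a thick
receptacle covering most of the seed with a reduced apical pericarp.

Exact section parameters (curve lengths, region areas, centroid distances)
are computed by adaptive quadrature; :func:`rasterize` and
:func:`extract_parameters` provide the discrete, image-based path that
mirrors manual measurement on section photographs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import quad
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from skimage import measure

from .morphometry import SectionParameters

QUAD_KW = dict(epsabs=1e-12, epsrel=1e-10, limit=200)

LABEL_BACKGROUND, LABEL_PERICARP, LABEL_RECEPTACLE, LABEL_SEED = 0, 1, 2, 3
TISSUE_LABELS = {"p": LABEL_PERICARP, "r": LABEL_RECEPTACLE, "s": LABEL_SEED}


class ProfileError(ValueError):
    """Invalid profile construction (e.g. overlapping shells)."""


@dataclass(frozen=True)
class RadialProfile:
    """A two-tissue fruit profile built around an ellipsoidal seed space.

    ``seed_semi_axes`` is (radial, axial) in cm; ``shell_thicknesses`` is
    (pericarp, receptacle) in cm; ``coverage_fractions`` is (f_p, f_r), the
    fractions of the seed boundary arc adjoined by pericarp (from the apex)
    and receptacle (from the base).
    """

    seed_semi_axes: tuple[float, float]
    shell_thicknesses: tuple[float, float]
    coverage_fractions: tuple[float, float]
    fruit_type: str = "AC"
    overlap_tol: float = 1e-9

    def __post_init__(self) -> None:
        a, b = self.seed_semi_axes
        tp, tr = self.shell_thicknesses
        fp, fr = self.coverage_fractions
        if a <= 0 or b <= 0:
            raise ProfileError(f"seed semi-axes must be > 0, got {self.seed_semi_axes}")
        if tp < 0 or tr < 0:
            raise ProfileError(f"shell thicknesses must be >= 0, got {self.shell_thicknesses}")
        if not (0 <= fp <= 1 and 0 <= fr <= 1):
            raise ProfileError(f"coverage fractions must lie in [0, 1], got {self.coverage_fractions}")
        if fp + fr > 1 + self.overlap_tol:
            raise ProfileError(
                f"pericarp and receptacle shells overlap: f_p + f_r = {fp + fr:.6g} > 1"
            )

    # -- parametric seed boundary (t in [0, 1], base pole -> apex pole) ----
    def seed_point(self, t):
        a, b = self.seed_semi_axes
        return -b * np.cos(np.pi * t), a * np.sin(np.pi * t)

    def _derivs(self, t):
        a, b = self.seed_semi_axes
        zp = np.pi * b * np.sin(np.pi * t)
        rp = np.pi * a * np.cos(np.pi * t)
        zpp = np.pi**2 * b * np.cos(np.pi * t)
        rpp = -np.pi**2 * a * np.sin(np.pi * t)
        return zp, rp, zpp, rpp

    def speed(self, t):
        zp, rp, _, _ = self._derivs(t)
        return np.hypot(zp, rp)

    def normal(self, t):
        """Outward unit normal of the seed boundary (away from the axis)."""
        zp, rp, _, _ = self._derivs(t)
        s = np.hypot(zp, rp)
        return -rp / s, zp / s

    def curvature(self, t):
        """Signed curvature; outward normal offset expands by (1 - u*kappa)."""
        zp, rp, zpp, rpp = self._derivs(t)
        return (zp * rpp - rp * zpp) / np.hypot(zp, rp) ** 3

    def seed_arc_length(self, t0: float = 0.0, t1: float = 1.0) -> float:
        return quad(self.speed, t0, t1, **QUAD_KW)[0]

    def band_range(self, tissue: str) -> tuple[float, float]:
        """Parameter range [t0, t1] of the seed arc adjoined by a husk tissue."""
        L = self.seed_arc_length()
        fp, fr = self.coverage_fractions
        if tissue == "p":
            if fp <= 0:
                return (1.0, 1.0)
            if fp >= 1:
                return (0.0, 1.0)
            t0 = brentq(lambda t: self.seed_arc_length(t, 1.0) - fp * L, 0.0, 1.0, xtol=1e-14)
            return (t0, 1.0)
        if tissue == "r":
            if fr <= 0:
                return (0.0, 0.0)
            if fr >= 1:
                return (0.0, 1.0)
            t1 = brentq(lambda t: self.seed_arc_length(0.0, t) - fr * L, 0.0, 1.0, xtol=1e-14)
            return (0.0, t1)
        raise ValueError(f"unknown husk tissue {tissue!r}")

    def shell_outer_point(self, t, tissue: str):
        tau = self.shell_thicknesses[0 if tissue == "p" else 1]
        z, r = self.seed_point(t)
        nz, nr = self.normal(t)
        return z + tau * nz, r + tau * nr

    @property
    def axial_extent(self) -> tuple[float, float]:
        a, b = self.seed_semi_axes
        tau = max(self.shell_thicknesses)
        return (-b - tau, b + tau)

    @property
    def radial_extent(self) -> float:
        a, b = self.seed_semi_axes
        return a + max(self.shell_thicknesses)


_ARCHETYPE_DEFAULTS = {
    # (radial, axial) cm, (pericarp, receptacle) cm, (f_p, f_r)
    "AC": dict(seed_semi_axes=(1.0, 1.2), shell_thicknesses=(0.08, 0.18),
               coverage_fractions=(0.85, 0.15)),
    "ER": dict(seed_semi_axes=(1.4, 1.6), shell_thicknesses=(0.06, 0.45),
               coverage_fractions=(0.15, 0.85)),
}


def make_archetype(
    fruit_type: str,
    seed_semi_axes: tuple[float, float] | None = None,
    shell_thicknesses: tuple[float, float] | None = None,
    coverage_fractions: tuple[float, float] | None = None,
    seed: int | None = None,
    jitter_cv: float = 0.0,
) -> RadialProfile:
    """Build an AC or ER archetype profile.

    Defaults encode the anatomy of the two fruit types (thin, near-complete
    pericarp for AC; thick, near-complete receptacle for ER).  When
    ``jitter_cv > 0`` the linear parameters are multiplied by lognormal
    factors drawn from the seeded generator, so repeated calls with the same
    ``seed`` are identical.
    """
    if fruit_type not in _ARCHETYPE_DEFAULTS:
        raise ProfileError(f"fruit_type must be 'AC' or 'ER', got {fruit_type!r}")
    d = _ARCHETYPE_DEFAULTS[fruit_type]
    axes = tuple(seed_semi_axes) if seed_semi_axes is not None else d["seed_semi_axes"]
    thick = tuple(shell_thicknesses) if shell_thicknesses is not None else d["shell_thicknesses"]
    cover = tuple(coverage_fractions) if coverage_fractions is not None else d["coverage_fractions"]
    if jitter_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(jitter_cv**2))
        jit = lambda v: tuple(x * rng.lognormal(-sigma**2 / 2, sigma) for x in v)
        axes, thick = jit(axes), jit(thick)
    return RadialProfile(axes, thick, cover, fruit_type=fruit_type)


# ---------------------------------------------------------------------------
# exact section parameters by quadrature

def exact_parameters(profile: RadialProfile) -> SectionParameters:
    """Exact section parameters of a profile (quadrature, ~1e-10 relative).

    Seed-space curve quantities come from line integrals over the parametric
    boundary; shell region quantities integrate the normal-offset strip with
    area element ``(1 - u*kappa) ds du`` for offset distance ``u``.
    ``L_p`` / ``L_r`` are the internal (seed-facing) boundary lengths.
    """
    ds = profile.speed

    L_s = quad(ds, 0, 1, **QUAD_KW)[0]
    m1 = quad(lambda t: profile.seed_point(t)[1] * ds(t), 0, 1, **QUAD_KW)[0]
    r_s = m1 / L_s

    # half-section region of the seed: area = int r dz, moment = int r^2/2 dz
    a, b = profile.seed_semi_axes
    A_s = math.pi * a * b / 2.0
    R_s = 4.0 * a / (3.0 * math.pi)

    vals: dict[str, float] = dict(L_s=L_s, r_s=r_s, A_s=A_s, R_s=R_s)
    for tissue in ("p", "r"):
        tau = profile.shell_thicknesses[0 if tissue == "p" else 1]
        t0, t1 = profile.band_range(tissue)
        if t1 <= t0 or tau == 0.0:
            vals.update({f"L_{tissue}": 0.0, f"r_{tissue}": 0.0,
                         f"A_{tissue}": 0.0, f"R_{tissue}": 0.0})
            continue
        L_in = quad(ds, t0, t1, **QUAD_KW)[0]
        r_in = quad(lambda t: profile.seed_point(t)[1] * ds(t), t0, t1, **QUAD_KW)[0] / L_in

        def strip_area(t):
            k = profile.curvature(t)
            return (tau - k * tau**2 / 2.0) * ds(t)

        def strip_moment(t):
            k = profile.curvature(t)
            r = profile.seed_point(t)[1]
            nr = profile.normal(t)[1]
            return (r * tau + (nr - r * k) * tau**2 / 2.0 - nr * k * tau**3 / 3.0) * ds(t)

        A = quad(strip_area, t0, t1, **QUAD_KW)[0]
        M = quad(strip_moment, t0, t1, **QUAD_KW)[0]
        if A <= 0:
            raise ProfileError(f"shell {tissue!r} self-intersects: thickness exceeds curvature radius")
        vals.update({f"L_{tissue}": L_in, f"r_{tissue}": r_in,
                     f"A_{tissue}": A, f"R_{tissue}": M / A})
    return SectionParameters(**vals)


# ---------------------------------------------------------------------------
# rasterization

@dataclass
class LabeledSectionImage:
    """Integer-labeled half-plane section mask.

    Labels: 0 background, 1 pericarp, 2 receptacle, 3 seed.  ``axis_col`` is
    the image column whose *left edge* carries the rotation axis; pixel
    centers sit at ``(col - axis_col + 0.5) / px_per_cm`` cm from the axis.
    """

    labels: np.ndarray
    px_per_cm: float
    axis_col: int = 0
    origin_z: float = 0.0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        bad = set(np.unique(lab)) - {0, 1, 2, 3}
        if bad:
            raise ProfileError(f"mask contains invalid labels {sorted(bad)}")
        if not (0 <= self.axis_col < lab.shape[1] + 1):
            raise ProfileError(f"axis column {self.axis_col} outside mask of width {lab.shape[1]}")
        self.labels = lab.astype(np.uint8)


def rasterize(profile: RadialProfile, px_per_cm: float) -> LabeledSectionImage:
    """Rasterize a profile by pixel-center sampling.

    The rotation axis is the left image edge (``axis_col = 0``); rows index
    the axial coordinate.  A tissue whose exact section area is positive but
    receives no pixels is flagged in ``warnings``.
    """
    if px_per_cm <= 0:
        raise ProfileError("px_per_cm must be > 0")
    import shapely

    z_lo, z_hi = profile.axial_extent
    r_hi = profile.radial_extent
    pad = 2.0 / px_per_cm
    z_lo, z_hi, r_hi = z_lo - pad, z_hi + pad, r_hi + pad
    s = 1.0 / px_per_cm
    n_rows = int(math.ceil((z_hi - z_lo) / s))
    n_cols = int(math.ceil(r_hi / s))
    zc = z_lo + (np.arange(n_rows) + 0.5) * s
    rc = (np.arange(n_cols) + 0.5) * s
    Z, R = np.meshgrid(zc, rc, indexing="ij")

    a, b = profile.seed_semi_axes
    labels = np.zeros((n_rows, n_cols), dtype=np.uint8)
    seed_mask = (Z / b) ** 2 + (R / a) ** 2 <= 1.0
    labels[seed_mask] = LABEL_SEED

    t_dense = np.linspace(0.0, 1.0, 4001)
    for tissue, code in (("p", LABEL_PERICARP), ("r", LABEL_RECEPTACLE)):
        tau = profile.shell_thicknesses[0 if tissue == "p" else 1]
        t0, t1 = profile.band_range(tissue)
        if t1 <= t0 or tau == 0.0:
            continue
        tt = t0 + (t1 - t0) * t_dense
        zi, ri = profile.seed_point(tt)
        zo, ro = profile.shell_outer_point(tt, tissue)
        ring = np.concatenate(
            [np.column_stack([zi, ri]), np.column_stack([zo, ro])[::-1]]
        )
        poly = shapely.Polygon(ring)
        inside = shapely.contains_xy(poly, Z.ravel(), R.ravel()).reshape(Z.shape)
        labels[inside & (labels == 0)] = code

    img = LabeledSectionImage(labels, px_per_cm, axis_col=0, origin_z=z_lo)
    exact = exact_parameters(profile)
    for tissue, code in TISSUE_LABELS.items():
        if getattr(exact, f"A_{tissue}") > 0 and not np.any(labels == code):
            img.warnings.append(f"tissue {tissue!r} vanished at {px_per_cm} px/cm")
    return img


# ---------------------------------------------------------------------------
# parameter extraction from labeled masks

def _contours(mask: np.ndarray, smooth_px: float) -> list[np.ndarray]:
    """Sub-pixel contours of a binary mask (marching squares).

    The mask is smoothed with a small Gaussian before contouring so the
    polyline tracks the underlying smooth boundary instead of the pixel
    lattice; this removes the constant overestimation bias of staircase
    perimeters.  Falls back to raw marching squares when smoothing erases a
    tiny region.
    """
    f = gaussian_filter(mask.astype(float), smooth_px, mode="constant")
    cs = measure.find_contours(f, 0.5)
    if not cs and mask.any():
        cs = measure.find_contours(mask.astype(float), 0.5)
    return cs


def _segments(contour: np.ndarray):
    """(midpoints, lengths, unit normals) of a contour polyline (array coords)."""
    p0, p1 = contour[:-1], contour[1:]
    d = p1 - p0
    lengths = np.hypot(d[:, 0], d[:, 1])
    keep = lengths > 0
    d, p0, p1, lengths = d[keep], p0[keep], p1[keep], lengths[keep]
    mid = (p0 + p1) / 2.0
    normals = np.column_stack([d[:, 1], -d[:, 0]]) / lengths[:, None]
    return mid, lengths, normals


def _label_at(labels: np.ndarray, pts: np.ndarray) -> np.ndarray:
    rr = np.clip(np.rint(pts[:, 0]).astype(int), 0, labels.shape[0] - 1)
    cc = np.clip(np.rint(pts[:, 1]).astype(int), 0, labels.shape[1] - 1)
    return labels[rr, cc]


def extract_parameters(img: LabeledSectionImage, smooth_px: float = 1.5) -> SectionParameters:
    """Recover the twelve section parameters from a labeled mask.

    Region areas and centroid distances come from pixel counts and first
    moments about the declared axis.  The seed curve length is the
    marching-squares contour of the seed label (excluding any run along the
    axis); the internal pericarp / receptacle lengths are the portions of
    that contour adjacent to the corresponding label, probed just outside the
    seed.  An isolated husk region that never touches the seed falls back to
    its own contour length, with a warning recorded on ``img``.
    """
    labels = img.labels
    if not (0 <= img.axis_col <= labels.shape[1]):
        raise ProfileError("axis column outside mask")
    s = 1.0 / img.px_per_cm

    vals: dict[str, float] = {}
    for tissue, code in TISSUE_LABELS.items():
        mask = labels == code
        n = int(mask.sum())
        if n == 0:
            img.warnings.append(f"label for tissue {tissue!r} missing; reporting zeros")
            vals.update({f"A_{tissue}": 0.0, f"R_{tissue}": 0.0})
            continue
        cols = np.nonzero(mask)[1]
        r_pix = (cols - img.axis_col + 0.5) * s
        vals[f"A_{tissue}"] = n * s * s
        vals[f"R_{tissue}"] = float(r_pix.mean())

    # seed boundary
    seed_mask = labels == LABEL_SEED
    L_s = r_s = 0.0
    seg_store = []  # (mid_xy_cm, length_cm, outside_label)
    if seed_mask.any():
        for contour in _contours(seed_mask, smooth_px):
            mid, lengths, normals = _segments(contour)
            if len(mid) == 0:
                continue
            # orient normals to point away from the seed
            inside = _label_at(labels, mid - 0.75 * normals) == LABEL_SEED
            normals = np.where(inside[:, None], normals, -normals)
            # radial position of segment midpoints (cm from axis)
            r_mid = (mid[:, 1] - img.axis_col + 0.5) * s
            on_axis = r_mid < 0.75 * s
            lengths_cm = lengths * s
            keep = ~on_axis
            L_s += float(lengths_cm[keep].sum())
            r_s += float((lengths_cm[keep] * r_mid[keep]).sum())
            # adjacency: probe outward at increasing distances
            outside = np.full(len(mid), LABEL_BACKGROUND, dtype=int)
            undecided = np.ones(len(mid), dtype=bool)
            for dist in (0.8, 1.4, 2.0):
                probe = _label_at(labels, mid + dist * normals)
                hit = undecided & (probe != LABEL_SEED) & (probe != LABEL_BACKGROUND)
                outside[hit] = probe[hit]
                undecided &= ~hit
            for m, l, o, k in zip(mid, lengths_cm, outside, keep):
                if k:
                    seg_store.append(((m[1] - img.axis_col + 0.5) * s, l, o))
    if L_s > 0:
        r_s /= L_s
    vals["L_s"], vals["r_s"] = L_s, r_s

    for tissue, code in (("p", LABEL_PERICARP), ("r", LABEL_RECEPTACLE)):
        segs = [(r, l) for r, l, o in seg_store if o == code]
        L = sum(l for _, l in segs)
        if L == 0.0 and np.any(labels == code):
            # isolated region: fall back to its own boundary length
            img.warnings.append(
                f"tissue {tissue!r} has no seed-facing boundary; using its own contour"
            )
            total = 0.0
            mom = 0.0
            for contour in _contours(labels == code, smooth_px):
                mid, lengths, _ = _segments(contour)
                if len(mid) == 0:
                    continue
                r_mid = (mid[:, 1] - img.axis_col + 0.5) * s
                total += float(lengths.sum() * s)
                mom += float((lengths * s * r_mid).sum())
            L = max(total, s)  # a present tissue has at least one pixel of boundary
            vals[f"L_{tissue}"], vals[f"r_{tissue}"] = L, (mom / total if total > 0 else 0.0)
            continue
        vals[f"L_{tissue}"] = L
        vals[f"r_{tissue}"] = (sum(r * l for r, l in segs) / L) if L > 0 else 0.0

    if vals["A_s"] == 0.0 and (vals["A_p"] > 0 or vals["A_r"] > 0):
        # keep the invariant "zero length pairs with zero area" for the seed
        vals["L_s"] = 0.0
    return SectionParameters(**vals)


# ---------------------------------------------------------------------------
# mask I/O: PGM (P2/P5) or CSV grid, with a JSON sidecar

def save_mask(img: LabeledSectionImage, path, fmt: str = "pgm", binary: bool = False) -> None:
    path = Path(path)
    lab = img.labels
    if fmt == "pgm":
        with open(path, "wb") as fh:
            magic = b"P5" if binary else b"P2"
            fh.write(magic + b"\n%d %d\n255\n" % (lab.shape[1], lab.shape[0]))
            if binary:
                fh.write(lab.astype(np.uint8).tobytes())
            else:
                for row in lab:
                    fh.write((" ".join(map(str, row)) + "\n").encode())
    elif fmt == "csv":
        np.savetxt(path, lab, fmt="%d", delimiter=",")
    else:
        raise ValueError(f"unknown mask format {fmt!r}")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        dict(px_per_cm=img.px_per_cm, axis_col=img.axis_col, origin_z=img.origin_z)
    ))


def load_mask(path) -> LabeledSectionImage:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raw = path.read_bytes()
    if raw.startswith(b"P2") or raw.startswith(b"P5"):
        header, rest = raw.split(b"\n", 1)
        fields_ = []
        while len(fields_) < 3:
            line, rest = rest.split(b"\n", 1)
            if not line.startswith(b"#"):
                fields_.extend(line.split())
        w, h = int(fields_[0]), int(fields_[1])
        if raw.startswith(b"P5"):
            lab = np.frombuffer(rest[: w * h], dtype=np.uint8).reshape(h, w)
        else:
            lab = np.array(rest.split(), dtype=np.uint8)[: w * h].reshape(h, w)
    else:
        lab = np.loadtxt(path, delimiter=",", dtype=int)
    return LabeledSectionImage(lab, meta["px_per_cm"], meta["axis_col"], meta.get("origin_z", 0.0))
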