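# Methods

This note documents the models, numerical choices and known limitations of
the `stoneoak` pipeline, in the order the stages run.

## Solids of revolution

Each fruit is assumed to be a perfect body of revolution about its
longitudinal axis; all quantities are measured on one half-plane of the
longitudinal section, and the Pappus–Guldinus theorems give the
full-revolution (2π) surface areas and volumes. Units are fixed to
cm / cm² / cm³ with no auto-detection; unit consistency is the caller's
responsibility. Density differences between tissues are ignored, so husk
volume is a proxy for mechanical investment, not mass.

No constraint ties `S_p + S_r` to `S_s`: empirical coverages can overlap
or exceed the seed surface (both tissues can adjoin the same arc, and
measurement conventions differ), so the engine never "reconciles" them.
The defense index `V_h / S_s` raises an error when the seed surface is
zero but husk volume is not; the fully degenerate all-zero fruit yields 0.

## Parametric fruit profiles

The seed space is an ellipsoid with radial semi-axis *a* and axial
semi-axis *b*; its half-plane boundary is parametrized from base pole to
apex pole. Husk tissues are shells offset *outward along the boundary
normal* by their thickness: the pericarp adjoins the apical fraction `f_p`
of the seed-boundary arc, the receptacle the basal fraction `f_r`, and
`f_p + f_r <= 1` (overlapping shells are a construction error). Archetype
defaults — AC: *a* = 1.0 cm, *b* = 1.2 cm, shells (0.08, 0.18) cm,
coverages (0.85, 0.15); ER: *a* = 1.4 cm, *b* = 1.6 cm, shells
(0.06, 0.45) cm, coverages (0.15, 0.85) — encode the thin-pericarp /
thick-receptacle contrast at typical fruit scale.

Exact section parameters use adaptive quadrature (`scipy.integrate.quad`,
relative tolerance 1e-10). Shell regions are integrated as normal-offset
strips with area element `(1 - u kappa) ds du`, which is exact for offsets
smaller than the local curvature radius; a non-positive strip area raises
an error. The "internal lengths" `L_p`, `L_r` are the seed-facing
boundary lengths, i.e. arc fractions of the seed boundary, so
`L_p = f_p L_s` exactly. One consequence worth noting: for a thin shell
the *surface ratio* `S_p / S_s` equals `f_p · (r̄_covered / r̄_total)`,
not `f_p` — an apex-anchored band has an above-average centroid radius,
so the ratio exceeds the arc fraction (≈ 0.94 at `f_p = 0.85` for the AC
archetype). It equals 1 exactly at full coverage, which is what the tests
assert.

### Raster path

`rasterize` samples pixel centers (axis on the left image edge, pixel
centers at `(j + 0.5)/px_per_cm` from the axis); shell membership uses
dense shapely polygons of the offset curves. `extract_parameters`
recovers areas and region centroids from pixel counts and first moments,
and boundary lengths from marching-squares contours
(`skimage.measure.find_contours` at level 0.5) of each label's mask after
smoothing with a small Gaussian (1.5 px). Smoothing matters: contours of
raw binary masks carry a resolution-independent overestimation bias
(staircase/octagonal perimeters), while contours of the smoothed field
track the underlying boundary and make the bias shrink with pixel size.
The pericarp/receptacle internal boundaries are the portions of the seed
contour whose outward probe (0.8–2 px) hits that label; an isolated husk
region that never touches the seed falls back to its own contour length
with a warning. Convergence is verified empirically: at 400 px/cm the
raster path agrees with the exact chain to better than 2% on both
archetypes, and errors decrease with resolution.

## Classification and contrasts

Species means are arithmetic means of per-fruit dimensions. ER requires
strict receptacle dominance (`S_r > S_p`); an exact tie classifies AC with
an ambiguity flag, because ER is *defined* by receptacle dominance.
Species with a single fruit are classified but excluded from
within-species allometry.

Fruit-type contrasts in seed volume and defense index are Welch
two-sample tests on species values. The original analysis fitted
linear mixed models to fruit-level data with species as a random effect;
fruit-level raw data are not published, so the species-level Welch
contrast replaces it here. Only the *direction* of the published contrast
(ER exceeding AC in both quantities) is reproduced and asserted, not the
mixed-model estimates.

## SMA allometry

Log base 10 throughout; the "allometric constant" is `10^intercept`.
Orientation: the pericarp dimension is the dependent variable
(`S_p ~ S_r`, `V_p ~ V_r`); with this orientation the species-mean
dispersion yields AC exponents below 1 and ER exponents above 1,
matching the published pattern. Slope CIs use the standard F-pivot
`b (sqrt(B+1) ± sqrt(B))` with `B = F(1-α; 1, n-2)(1-r²)/(n-2)`.

The common-slope test profiles the bivariate-normal likelihood: at slope
*b* the residual `y - b x` and fitted-axis `y + b x` scores are
uncorrelated within a group exactly when *b* is the group's SMA slope, so
`LR(b) = -Σ_i (n_i - 2.5) ln(1 - r_i(b)²)` minimized over *b* is referred
to a chi-square with `groups - 1` degrees of freedom (the `n - 2.5`
weight is a small-sample Bartlett factor). A seeded label-permutation
p-value is available as a robustness check.

Default analysis set: species with at least 8 measured fruits
(`min_n = 8`, 51 AC + 11 ER species on the packaged table). Species means
from small samples carry enough measurement error to attenuate
log-scale dispersion asymmetrically; the published exponents
(0.71 / 1.39 coverage, 0.88 / 0.94 volume) are reproduced on this subset,
and `min_n=1` uses every species. Within-species allometry runs the same
fits inside each species with ≥ 8 fruits.

## Comparative methods

*Mk model.* Two states (AC = 0, ER = 1), forward rate `q01`, backward
`q10`; the 2×2 transition probability uses the closed-form exponential.
Likelihood by Felsenstein pruning; the root prior is uniform by default
(stationary available). ML fitting optimizes log-rates with L-BFGS-B in
[1e-8, 1e3]; monomorphic data are flagged degenerate. Missing tip states
are an error — there is no missing-data support.

*Marginal ancestral states* use the outside/inside (re-rooting-equivalent)
decomposition and require a fully bifurcating tree. Transition counts
compare MAP states of parent and child (tips use observed states);
a seeded backward-filtering/forward-sampling mode gives mean counts over
joint node-state draws as a sensitivity check (it samples node states,
not within-branch paths, so it does not count multiple hits on one edge).

*Blomberg's K* uses the GLS phylogenetic mean: the observed MSE₀/MSE is
divided by its Brownian expectation `(tr(C) - n/(1'C⁻¹1))/(n-1)`.
A binary fruit type is coerced to 0/1 and treated as continuous — an
approximation, flagged as such, used because the published analysis
reports a single K for fruit type without specifying its procedure.
The permutation p-value shuffles tip values (seeded). Zero or missing
branch lengths are replaced by 1e-6 of tree height with a warning;
a star tree makes K undefined and raises.

*Brownian ancestral states* are GLS conditional expectations
`mu + c_a' C⁻¹ (x - mu)` with `c_a[i]` the depth of the MRCA of node *a*
and tip *i*; the root estimate is the GLS mean — internally consistent
with the mean used inside K. Per-tip change categories compare the tip
value with its parent's estimate on the analysis (log) scale; "same"
means the difference is within ε times the trait range, with ε = 0.05 by
default (the published narrative never defines its threshold, so this is
a package choice, configurable). Note that on ultrametric trees a pure
time trend is invisible to BM reconstruction — all tips are equidistant
from the root — so change categories reflect the relative configuration
of tip values, not absolute time trends.

*Simulators.* Birth–death trees conditioned on the number of extant tips
(dendropy); the conditioning leaves the newest cherry with zero-length
terminal branches, which are nudged to the epsilon above so tip
covariances stay nonsingular. Mk histories use exact exponential waiting
times (true jump counts recorded); BM accrues variance `sigma² t` per
branch. Everything is reproducible from one seed.

## Thermal zones

Zone rule on MAT: tropical strictly above 22 °C, subtropical on
(19, 22], warm temperate on [11, 19], flagged `out_of_range` below 11 °C
(the warmth-index definition implies a cooler category the study area
never uses, so values below 11 are flagged rather than named). This
boundary closure is the unique one consistent with the packaged table's
printed labels (19.0 → warm temperate, 20.8 → subtropical,
22.2 → tropical), and it reproduces all 144 printed zone labels.
Classification operates on values as given (one decimal in the fixture);
nothing is re-rounded. The skew flag compares median- and mean-based
zones: `toward_colder` when the mean falls in the cooler zone.

## Synthetic studies

Defaults define the study conditions: 80 species from a birth–death tree
(birth 1.0, death 0.3) rescaled to unit height; Mk rates 0.15 (AC→ER) and
0.05 (ER→AC) per unit height with an AC root, so ER is derived,
polyphyletic in most replicates, and occasionally reverses; log seed
radial semi-axis = type mean (log 0.85 cm for AC, log 1.25 cm for ER) +
Brownian deviation (σ = 0.25), giving phylogenetically structured,
stochastically larger ER seeds; per-type shell-thickness fractions and
coverage ranges mirror the archetype defaults. Species truth is computed
through the exact quadrature chain, so the generator exercises the same
geometry as the analysis.

Fruit-level noise is multiplicative lognormal with two components: a
latent fruit-size factor (CV 0.10 on linear size, entering surfaces as
the square and volumes as the cube — this is what makes all six
dimensions strongly positively correlated within species) and independent
per-dimension noise (CV 0.20). Fruits per species follow a rounded
lognormal (median 4, log-sd 1.1, capped at 250), mimicking the heavily
skewed sampling of herbarium material. MAT samples are normal around zone
centers (25.5 / 20.5 / 16.0 °C, sd 1.2 °C, 3–30 localities); with
probability 0.15 a quarter of the localities are shifted −6 °C, creating
the cold-tail median/mean mismatches seen in real ranges. All randomness
flows from a single master seed through named substreams.

What passing on synthetic data does *not* show: robustness to real
section-image segmentation error, non-ellipsoidal seed shapes,
correlated sampling effort, or climate sampling biases — none of which
the generator emulates.

## Problem sizes in tests

Simulation-based tests use 60–200 replicates at 60–200 tips (K
calibration: 200 replicates of 100-tip trees; Mk rate recovery: 100
replicates of 200-tip trees; SMA calibration: 200–500 replicates), sizes
at which the Monte-Carlo error of each checked statistic is comfortably
inside its asserted band while the whole suite stays quick.

## Known limitations

- Tree inference, alignment and model selection are out of scope; trees
  are inputs. The published 72-species phylogeny is not distributed, so
  its K = 0.24 and its reconstruction figures are not reproduced.
- Mixed-model fruit-level contrasts are replaced by species-level Welch
  tests (direction-only agreement, above).
- The published allometric constants could not be reconciled with
  back-transformed intercepts under any axis orientation on the
  species-mean tables; constants are reported but never asserted.
- Binary-trait K and MAP-based transition counts are approximations;
  both are flagged and the latter has a stochastic-draw alternative.
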