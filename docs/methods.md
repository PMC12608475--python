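# Methods

## The problem

A candidate food-packaging polymer should be as inert toward the packaged
food as possible: constituents of the material must not migrate into the
food, and food compounds (flavors, volatiles) should not sorb into and
permeate the material. Both phenomena require favorable polymer–compound
interactions, so a fast first-pass screen is to ask whether the polymer and
the food's component classes are *compatible* in the thermodynamic sense.
Hansen solubility parameters (HSP) provide exactly that screen.

Every substance is placed at a point (δd, δp, δhb) in MPa^1/2 — the
dispersion, polar and hydrogen-bonding contributions to its cohesive energy
density. Compatibility is distance in this space:

    Ra² = 4 (δd1 − δd2)² + (δp1 − δp2)² + (δhb1 − δhb2)²

The factor 4 on the dispersion term is the standard Hansen convention (the
dispersion axis is compressed relative to the other two); `hspscreen` uses
this form throughout. Note that renderings of the Ra formula in print
sometimes drop the radical and the squares through typesetting loss; the
implemented quantity is the square root of the weighted sum of squared
differences, which is a true metric on the rescaled space (2δd, δp, δhb).

Dividing by an interaction radius Ro gives the Relative Energy Difference

    RED = Ra / Ro,

with RED < 1 read as "likely compatible" and RED > 1 as "poor
compatibility". Verdicts carry a configurable borderline band (default
±0.05 around RED = 1) so that values indistinguishable from the threshold
at tabulated-HSP precision are not over-claimed either way.

## Swelling as the affinity measurement

A cross-linked polymer cannot be dissolved, so its HSP cannot be fitted
from solubility data. Instead it swells in good solvents. The package
quantifies affinity as volumetric swelling after immersion,

    % swelling = 100 · (V_after − V_before) / V_before,

with volumes either supplied directly or computed as rectangular-slab
products of caliper dimensions (irregular samples must come as volumes).
The ×100 places outputs on the percent scale on which such tables are
reported. Replicate summaries use the sample (n−1) standard deviation; for
two replicates this is |x1 − x2|/√2. Display rounding is half-up at one
decimal; full precision is kept internally.

### Reactive solvents

Swelling is only a valid affinity probe if the polymer is chemically
unchanged by the solvent. Polyesters are vulnerable on two fronts: water
hydrolyzes ester bonds, and alcohols can transesterify them. A solvent that
reacts changes the structure being measured, so its swelling value refers
to a different material and must not enter the fit. `hspscreen` encodes
this as per-solvent exclusion flags with reason codes
(`chemical_alteration`, `user`) rather than hard-coded solvent names:
excluded solvents stay in the dataset and its summaries but are dropped
before estimation.

## Inverse HSP estimation

Across a solvent panel, % swelling should *decrease* with the Hansen
distance Ra between polymer and solvent, roughly linearly over the ranges
probed. The polymer's unknown (δd, δp, δhb) is therefore estimated as the
point maximizing the R² of the ordinary least-squares line of Ra on
% swelling, restricted to candidates with *negative* correlation
(candidates producing a positive correlation score −R², so any maximizer
rejects them), over the box [2.5, 40]³ MPa^1/2 — the range spanned by the
vast majority of substances.

The search is a deterministic two-stage grid scan:

1. **coarse** — vectorized scoring of the full box at 0.5 MPa^1/2 steps
   (~4.4 × 10⁵ candidates);
2. **refine** — rescoring the ±0.5 neighborhood of the coarse optimum at
   0.05 MPa^1/2 steps.

Exact score ties resolve to the lexicographically smallest
(δd, δp, δhb), making results reproducible bit-for-bit. An optional
seeded multi-start L-BFGS-B polish (`multistart_count > 0`) is available
but off by default; it never replaces the grid optimum unless strictly
better.

Three diagnostics are always reported because this objective is often
nearly flat:

* **boundary flags** — any fitted component resting exactly on a box bound
  signals that the data do not identify that component (a bound is a
  constraint, not an estimate);
* **plateau** — every scanned grid point within `plateau_tolerance`
  (default 10⁻⁶) of the optimum's R², exposing flat directions instead of
  silently resolving them;
* **slope sign and residuals** — of the Ra-on-swelling line (the regression
  direction does not change R² for a simple linear fit; Ra-on-swelling is
  fixed for residual reporting).

Independent repetition experiments are fitted separately and the fitted
HSP triples averaged component-wise (repeats of the whole experiment are
not pooled into one regression; with n = 2 repetitions the average is the
honest summary and the per-repetition spread the honest dispersion).

### What the shipped cutin fixture shows

The shipped reference experiment (cutin, a cross-linked plant polyester,
swollen in seven solvents, two repetitions) reproduces the known behavior
of this estimator: the five-solvent fit (water and isopropanol excluded as
reactive) lands near (19.7, 5.4, 2.5) with δhb on the 2.5 lower bound,
while re-admitting isopropanol — a high-δhb solvent whose anomalously high
swelling is attributed to transesterification — drags δd and δhb up and
pins δp to the bound instead. Because the solvent HSP table behind the
original analysis is not published, the shipped handbook table cannot be
guaranteed identical; agreement is therefore asserted to ±1 MPa^1/2 per
component, not bit-exact. With the shipped table, repetition 1's δhb
optimum sits marginally interior (2.55 at grid resolution, continuous
optimum ≈ 2.54) while repetition 2 rests exactly on 2.5; the δhb
lower-bound flag is asserted on the repetition-aggregated flags.

## Screening and uncertainty

Food components are screened in groups (carbohydrates; fats and lipids;
amino acids; vitamins; polar and non-polar essential-oil components). Two
database granularities are supported and every report labels which one it
used:

* **component level** — Ra per individual substance, then group
  mean ± (n−1) sd of Ra. This is the procedure behind published group
  averages.
* **summary level** — Ra evaluated at the group-mean HSP, with sd
  propagated from the group's HSP sds. Only group-level means ± sds are
  usually published, so this is the reproducible granularity.

The two differ by a Jensen gap: the mean of distances is ≥ the distance to
the mean, so summary-level Ra is a slight *underestimate* of the
component-averaged Ra. Against the shipped group summaries the gap is at
most ~0.2 MPa^1/2 (one-decimal rounding of the published values allows one
group to violate the exact inequality by 0.05).

Ro defaults to the polymer's distance to its poorest swelling solvent
(hexane for the shipped cutin record): any substance farther away than the
worst solvent interacts even more weakly, so RED > 1 marks "worse than the
worst solvent we measured". A numeric Ro can be supplied instead.

Uncertainty propagation treats the three group HSP sds as independent (no
covariances are published):

* **delta method** (default) — first-order propagation through the Ra
  gradient at the group mean; at a coincident point (Ra = 0, gradient
  undefined) it falls back to the norm of the weighted sds.
* **Monte Carlo** — independent normals truncated at zero (HSPs are
  non-negative), ≥ 100 draws, seeded; reports the sample sd of the Ra
  draws.

For published sd magnitudes the two agree within ~30 % relative (the
truncation and the curvature of Ra account for the difference; the delta
method is exact only in the small-sd limit). `sd_red = sd_ra / Ro` in both.

Multi-polymer comparison screens each polymer against the same database and
ranks the lowest RED per group — the qualitative contrast (which material
is most prone to interact with fats, with essential oils, …) is the
decision-relevant output, not the RED digits themselves. A polymer without
an interaction radius (e.g. the shipped PHB placeholder) fails loudly with
its name; PLA ships with a literature HSP of (17.9, 9.2, 5.9) but no Ro,
which the user must supply.

## Synthetic experiments

The generator emits the exact structure the estimator assumes: per-solvent
mean swelling `a − b·Ra(truth, solvent)` plus independent Gaussian
replicate noise, truncated at zero. Defaults — 8 solvents drawn uniformly
from δd ∈ [12, 20], δp ∈ [0, 14], δhb ∈ [0, 20]; a = 120 %,
b = 5 %/MPa^1/2; noise sd = 5 points; 2 replicates — give swelling spans
and scatter comparable to real volumetric measurements on cross-linked
polyesters. Truncation at zero means only the poorest (largest-Ra)
solvents clip, mirroring the near-zero swelling of the worst real solvents.
An `exponential` decay law is available as a robustness hook, and an
outlier spec adds a fixed offset to one solvent to mimic a reactive solvent
whose swelling does not reflect affinity.

What passing synthetic tests does **not** show: real swelling is not
exactly linear in Ra, replicate noise is not homoscedastic Gaussian, real
solvent panels are not uniform draws, and solvent HSPs themselves carry
uncertainty the generator ignores. Synthetic recovery results (median
per-component absolute error ≈ 0.3–0.9 MPa^1/2 at the default conditions)
are therefore a lower bound on real-data error, not an accuracy claim.

At 1e-6 plateau tolerance, three-solvent panels produce broad near-perfect
plateaus (three points always admit near-collinear Ra configurations),
which is why the estimator warns below five solvents and why the plateau
output exists.

## Numerical choices and limitations

* Units are MPa^1/2 everywhere; no conversion layer.
* Grid bounds [2.5, 40], coarse 0.5, refine 0.05; all configurable.
* Ties: lexicographic; candidates with numerically constant Ra across the
  panel score zero rather than amplifying rounding noise.
* The estimator assumes a *monotone linear* swelling–distance law; strongly
  nonlinear (e.g. saturating) swelling will bias the fit.
* Hansen sphere fitting from binary good/bad solvent labels, Flory–Huggins
  χ estimation, temperature dependence, molar-volume weighting, and
  diffusion-based migration kinetics are out of scope.
* Scale note: the problem sizes used in the test-suite and in
  `scripts/acceptance.py` (50–100 synthetic seeds, 0.1-step brute-force
  boxes up to [2.5, 20]³) were chosen as the smallest designs whose
  Monte-Carlo error is comfortably below the asserted margins.
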