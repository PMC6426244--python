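# Methods

This note documents the models, conventions and numerical choices behind the
package, and what the synthetic generator does and does not emulate.

## Isotope scale and calibration

All internal isotope arithmetic is on the **atom-fraction** scale (0–1).
δ¹⁵N (‰, vs. atmospheric N₂) converts through R = R_air·(δ/1000 + 1),
AF = R/(1+R), with R_air = 0.0036765 for the ¹⁵N/¹⁴N ratio of air N₂. The
conversion is exactly invertible; values below −1000‰ or atom fractions ≥ 1
are rejected as unphysical. Working in atom fractions avoids percent/fraction
unit bugs: the rate equation is invariant to that choice as long as the
nitrite concentration sets the output units.

Instrument δ¹⁵N values are calibrated by ordinary least squares against four
internal nitrite isotope standards (−76.9, −35.6, 1.7, 36.7‰), fitting
*known = slope·measured + intercept* and applying the line to samples. At
least two standards with non-zero spread are required; the residual SD is
reported as a calibration diagnostic. Calibration is affine, hence
idempotent on already-calibrated values.

## The end-point rate equation

The rate of ammonia oxidation over a single end-point incubation is

r = 2 · Δn¹⁵ · NO₂⁻(i) / (t · α)

with Δn¹⁵ the mean calibrated atom-fraction difference (final − initial)
measured on the azide-derived N₂O, NO₂⁻(i) the initial nitrite pool in
nmol L⁻¹ (after tracer and carrier additions; initial rather than final
because nitrite consumption during the incubation is assumed isotope-neutral),
t in days (hours/24), and α = spike/(spike + ambient NH₄⁺). The leading 2 is
the azide correction: each N₂O carries one nitrite-derived and one
azide-derived (unenriched) N atom, so the measured enrichment is half that of
the nitrite pool. The factor is applied exactly once.

Conventions:

* Duplicate bottles are averaged on the atom-fraction scale after
  calibration; per-bottle values remain available for dispersion estimates.
* A negative raw rate (¹⁵NO₂⁻ depleted relative to background) is a
  **non-detect**: reported rate 0, `detected=False`, signed value retained in
  `raw_rate`. Zero is a valid detected rate. The criterion is sign-based; an
  instrument detection limit is not enforced.
* Tracer additions above 15% of ambient NH₄⁺ set `overspike_flag` (possible
  rate stimulation by substrate addition). The spike-design rule is 5% of
  expected ambient with a 0.05 µmol L⁻¹ floor (engaging below 1 µmol L⁻¹).
* Not modelled, by design: nitrite oxidation to nitrate (¹⁵N leaving the
  nitrite pool), nitrite production, and NH₄⁺ regeneration corrections. These
  omissions bias the estimator in known directions, which the generator's
  bias switches reproduce.

**Uncertainty.** A seeded Monte-Carlo perturbs each bottle's δ¹⁵N
(σ = 6.8‰), ambient NH₄⁺ (σ = 0.2 µmol L⁻¹) and initial NO₂⁻
(σ = 0.06 µmol L⁻¹) as independent Gaussians truncated at physical bounds,
and reports the SD of the signed rate (signed, so that truncation at the
non-detect boundary does not bias the spread). The rate is nearly linear in
the dominant δ¹⁵N noise, so the SD scales almost proportionally with that
precision.

## Dissolved N₂O

Headspace equilibration: a sealed bottle of volume V_b (default 1.12 L) has
V_h (default 0.12 L) of water replaced by ambient air, then is shaken to
equilibrium. The mole balance

C_water·V_w + x_air·P·V_h/(R·T) = K₀(T_eq)·x_hs·P·V_w + x_hs·P·V_h/(R·T)

is solved for the original dissolved concentration C_water
(V_w = V_b − V_h). Both headspace states are treated as ideal gas at the
equilibration temperature and ambient pressure, with dry-air mixing ratios
(no water-vapour correction — immaterial at the stated precision).
Solubility K₀ (mol L⁻¹ atm⁻¹) follows Weiss & Price (1980) for N₂O at S = 0;
the implementation reproduces K₀(20 °C) ≈ 0.0288 mol L⁻¹ atm⁻¹ and is
strictly decreasing in temperature. Replicate vials are averaged before
solving. A record whose readings imply a negative initial concentration is
rejected with diagnostics rather than silently clipped.

C_eq = K₀(T_insitu)·x_air·P is each sample's own equilibrium concentration,
except under ice: the ice-covered water column cannot exchange with the
atmosphere, so every under-ice sample of a winter uses the C_eq of the first
under-ice sample of that winter (the first sample is its own reference and is
flagged; an open-water sample resets the reference so a later freeze starts a
new winter run). ΔN₂O = C_water − C_eq is reported both in nmol L⁻¹ and as a
ppm-equivalent partial-pressure deviation ΔN₂O/(K₀(T_insitu)·P), since field
reports quote either form; the dual report avoids guessing which is meant.

## Chlorophyll a

Monochromatic acidification method:
chl a = 26.7·[(A665 − A750)_before − (A665 − A750)_after]·v/(V·l) with extract
volume v (mL), filtered volume V (L) and path length l (cm). The 750 nm
reading cancels turbidity exactly when common to both readings. Negative
values (noise at low biomass) are clipped to zero with a QC flag; replicate
mean and SD are reported. Phaeopigments are computable from the same
readings but deliberately not reported.

## Drivers statistics

* **Group comparison**: Kruskal–Wallis omnibus, then pairwise Dunn z-tests on
  joint ranks with tie correction and Holm adjustment; a compact letter
  display (maximal non-significant cliques) summarizes group membership at
  α = 0.05. Dunn's test is implemented in-package (no installed library
  provides it); Holm comes from statsmodels.
* **Paired t** for depth and diel contrasts; identical pairs return
  (t = 0, p = 1), constant non-zero differences are reported as degenerate.
* **Forward MLR**: covariates standardized internally; candidates enter by
  smallest partial-F p-value while p < 0.05; singular (collinear) candidates
  are skipped. Right-skewed non-negative covariates can be pre-transformed
  with log₁₀(x + half the minimum positive value); the transform and offset
  are recorded in the output metadata (identity otherwise).
* **Univariate regression tree**: binary recursive partitioning minimizing
  child SSE; numeric splits at midpoints between sorted distinct values;
  factor splits by exhaustive subset search (≤ 8 levels); minimum leaf size 3
  (minimum split 6). Weakest-link cost-complexity pruning yields the nested
  subtree sequence; tree size is chosen at the **global minimum** of the
  seeded k-fold (default 10) cross-validated error, evaluating each
  pruning-interval's geometric-mean complexity, with ties resolved toward
  the smaller tree. The 1-SE rule is deliberately not used. A constant
  response yields a single leaf; leaf predictions are member means.
* **Pearson correlation** for the nitrification product NO₃⁻ + NO₂⁻, which
  is excluded from the regressions as response-coupled.

## The synthetic generator

`simulate_incubation` inverts the rate equation under a planted true rate,
with two methodological-bias switches and analytical noise:

* **Regeneration**: a constant unlabelled NH₄⁺ influx ρ (µmol L⁻¹ h⁻¹) with
  instantaneous mixing dilutes the labelled fraction,
  α(t) = spike/(P₀ + ρt); the labelled-substrate exposure has the closed form
  ∫₀ᵗ α = (spike/ρ)·ln(1 + ρt/P₀). The estimator assumes constant α₀, so any
  ρ > 0 biases it low, monotonically in ρ.
* **Over-spike stimulation**: the realized rate is
  r_true·(1 + stimulation·spike/ambient), so stimulation > 0 biases the
  estimate of r_true high, monotonically.
* Nitrite consumption is isotope-neutral (pool shrinks, δ¹⁵N unchanged) —
  precisely the assumption under which the estimator uses initial NO₂⁻ — so
  it introduces no estimator bias here; the switch exists to document that
  assumption.
* Noise: per-bottle δ¹⁵N σ = 6.8‰, NH₄⁺ σ = 0.2, NO₂⁻ σ = 0.06 µmol L⁻¹
  (the measured nitrite is floored at the exactly-known carrier amount),
  chl a σ = 0.3 µg L⁻¹. With all noise off the round trip
  simulate → estimate recovers any planted rate to better than 1e−9
  relative. At the stated δ¹⁵N precision and winter-like conditions the
  median absolute relative error of single-bottle estimates is ≈ 14%
  (bounded at 25% in the tests).

`simulate_year` draws a 13-month series (October–October, one sample per
date, alternating depths) with ice cover December 10 – April 13 defining
winter; spring runs to the onset of stratification (May 31), summer through
September, autumn to ice-on. Seasonal structure: NH₄⁺ ~ N(2.8, 0.5) winter,
N(0.4, 0.5) summer, intermediate shoulders with a November overturn pulse;
NO₃⁻+NO₂⁻ ramping under ice from 0.2 to a 3.3 µmol L⁻¹ peak at ice-off, then
declining; chl a 0.4 winter vs 4.0 µg L⁻¹ summer; light fraction 0 under ice
and 0.10/0.01 at the two depths in open water; under-ice ΔN₂O accumulating
to ≈ 6.6 nmol L⁻¹ (≈ 0.12 ppm-equivalent at 2 °C). The AO rate is a monotone
function of NH₄⁺, either saturating (default, r_max = 400 nmol L⁻¹ d⁻¹,
K_m = 2 µmol L⁻¹ — giving winter means near 230 and summer means near
60 nmol L⁻¹ d⁻¹) or a step (50 → 231 nmol L⁻¹ d⁻¹ at 2.6 µmol L⁻¹ NH₄⁺),
plus N(0, 40) scatter. Within-season SDs, the temperature/O₂ profiles and
the rate-scatter SD are the package's own choices of field-realistic values;
no published within-season variances constrain them.

What the generator does **not** emulate: hydrodynamics and mixing, process
coupling between nitrogen pools, spatial structure, autocorrelation in time,
non-Gaussian analytical error, or drifting instrument calibration. Passing
tests therefore demonstrate correctness of the computational chain and
statistical power under the stated seasonal contrasts — not field validity
of any particular dataset.

Problem sizes used by the tests and the acceptance script — 1000 random
bottles for the brute-force identity, 100 seeded replicates for noise/bias
summaries, 48-sample years for the drivers recovery, 200 solved bottles for
the mole-balance check — were chosen to make the Monte-Carlo summaries
stable at two significant figures.

## Degenerate inputs and tie-breaks

* Calibration: < 2 standards or zero spread → error.
* α requires a positive spike; ambient 0 gives α = 1 and an infinite
  over-spike ratio (flagged).
* All-tied data in the group comparison and zero-variance series in the
  Pearson correlation are errors, not NaNs.
* Tree: equal-SSE splits resolve to the first column in table order and the
  smallest threshold; CV ties resolve to the smaller tree.
* CSV round trips are bit-exact (floats parsed in round-trip mode);
  validation errors name file, row and column.

## Known limitations

* The Dunn letter display enumerates subsets, practical only for the ≤ ~10
  groups that seasonal designs produce.
* The regression tree is exact but O(n²) per node in the worst case;
  intended for the tens-to-hundreds of samples typical of seasonal studies.
* The Monte-Carlo SD treats calibration parameters as fixed; calibration-fit
  uncertainty (4 standards) is not propagated.
* Winter C_eq referencing assumes the series contains the first winter
  sample; a truncated series silently uses its earliest under-ice sample as
  the reference (flagged in the output).
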