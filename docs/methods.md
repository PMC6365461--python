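# Methods

This note records the models implemented in `canopylux`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
generators do and do not emulate.

## Problem setting

A grape cluster's flavonol content and, more robustly, its flavonol
*profile* (the percentage split of total flavonols across the six aglycone
classes, % kaempferol in particular) track the solar radiation the cluster
accumulated during ripening. The package quantifies that chain for
individual clusters: an upward-looking hemispherical photograph taken at
the cluster position describes which sky directions are open; simulating
the sun's path across the ripening window and reading the photograph along
it yields an accumulated radiation dose; HPLC-DAD chromatograms yield the
flavonol profile; breakpoint regression and correlation link the two.

## Fisheye geometry and sky segmentation

* **Projection.** Equidistant (equi-angular) fisheye: radial pixel distance
  is proportional to zenith angle, `zenith = max_zenith * r / radius_px`.
  This is the standard assumption in hemispherical canopy photography when
  the lens projection is uncalibrated. The geometry object is the single
  place a different projection would plug in.
* **Orientation.** The optical axis is assumed vertical (zenith at image
  centre). A 150° lens therefore sees zenith 0–75°; the 75–90° ring is
  unseen and treated as *blocked* throughout, which in a vineyard with
  closed neighbouring rows is close to the truth. Camera tilt is
  deliberately unsupported.
* **Azimuth convention.** Compass bearing (0 = north, clockwise)
  everywhere. The image "up" direction maps to `azimuth_offset`.
* **Segmentation.** Sky is bright in the blue channel and vegetation dark,
  so a pixel is sky iff `blue >= threshold`. The default is one fixed
  global threshold (128 of 255) applied identically to every image of a
  campaign — classification must be a property of the scene, not of the
  image — with Otsu's criterion available either per image or, preferably,
  on the pooled histogram of the whole set. The threshold actually used is
  recorded in the mask and its audit JSON. No gamma handling is attempted;
  the threshold is configuration, and no particular value is claimed to
  match any specific field study.
* Pixels outside the field-of-view circle are invalid and excluded from
  every numerator and denominator in the package.

## Canopy metrics

* **Porosity** is the sky fraction of valid pixels.
* **Gap fractions** T̄ᵢ are sky fractions within five 13°-wide zenith bands
  centred at 7, 23, 38, 53, 68° (half-open intervals `[lo, hi)`), the ring
  layout of commercial canopy analyzers.
* **LAI** uses the classic five-ring inversion
  `LAI = 2 Σᵢ Wᵢ (−ln T̄ᵢ)` with weights
  W = (0.034, 0.104, 0.160, 0.218, 0.494). The weights are used exactly as
  printed in the analyzer convention (they sum to 1.010); a
  `normalize_weights` switch renormalises them to 1 when a strictly
  convex combination is wanted. The estimate includes non-leaf vegetation
  (shoots, wires, fruit) — it is a plant-area index in the strict sense.
* **Zero gaps.** T̄ᵢ = 0 would give infinite LAI; values are clamped at a
  floor defaulting to 1/(band pixel count), the smallest transmittance the
  image could have resolved. The floor is recorded in the result.

## Sun path and radiation dose

* **Solar position.** NOAA solar-calculator equations: Meeus-style
  truncated series for the sun's geometric mean longitude and anomaly,
  equation of centre, apparent ecliptic longitude and corrected obliquity,
  then declination, equation of time and hour angle. Agreement with an
  independent Astronomical Almanac implementation is a few hundredths of a
  degree over 1950–2100; the package's accuracy contract, tested at twelve
  benchmark instants, is ±0.5°. No atmospheric refraction (sub-0.6° effects
  only at the horizon, where the beam is blocked anyway). Timestamps are
  local *standard* time via an explicit `utc_offset`; there is no
  daylight-saving logic by design.
* **Clear-sky beam.** `I = S0 τ^AM sin(h)` on the horizontal with
  S0 = 1367 W m⁻², bulk transmittance τ = 0.70 and Kasten–Young air mass.
  This is a deliberately simple envelope: absolute calibration is supplied
  by the met correction below, so only the within-day *shape* matters. τ is
  configuration.
* **Beam sampling.** At each timestep the sun's (zenith, azimuth) is mapped
  into the mask and the sky fraction of an angular disc (default radius 2°,
  roughly four apparent sun diameters) around it is the beam transmission.
  The disc damps single-pixel noise; when the disc falls between pixels the
  nearest valid pixel decides. Transmission is exactly 0 below the horizon
  and in the blocked 75–90° ring.
* **Diffuse sky.** Diffuse irradiance is a fixed fraction (default 15%) of
  the instantaneous clear-sky direct beam, admitted in proportion to canopy
  porosity, and *not* modulated by cloud cover — a deliberate, literal
  model choice: the cloudiness correction applies to the beam only.
* **Met correction.** For each day, `c_d = measured_global / modelled
  open-sky clear total (direct × (1 + diffuse fraction))`; the direct beam
  is multiplied by `c_d`. Thus for an open site the modelled direct total
  reproduces the measured global exactly up to the direct share. `c_d` is
  capped at 1.2 as a guard against unit errors in the met file; hitting the
  cap is logged and flagged in the per-day table.
* **Integration.** Midpoint rule at a 10-minute default timestep over days
  in `[start, end)` — 47 days for the 24 July → 9 September ripening
  window; the mean daily dose divides by the same calendar difference.
  Doubling the timestep moves a clear-day total by well under 1%.

## Flavonol quantification and profile

* Peaks detected at 365 nm are quantified against a single
  quercetin-3-O-glucoside response factor, so all concentrations are QGE
  (quercetin-3-O-glucoside equivalents). Per-compound molar response
  factors are deliberately not applied — single-standard quantification is
  the field convention and keeps profiles comparable between studies.
* Classes: kaempferol, quercetin (galactoside + glucuronide + glucoside),
  myricetin, isorhamnetin, laricitrin ("laricitin" accepted as a variant
  spelling), syringetin. Percentages are over the six-class total and are
  scale-free: they never require sample metadata.
* Per-berry contents require the extract volume and the skin dry mass per
  berry (plus the extracted aliquot mass, default 50 mg). These have **no
  defaults**: when absent the per-berry fields are simply empty, so
  absolute contents are never fabricated from guessed volumes.

## Statistics

* **Segmented regression.** One breakpoint ψ by iterative linearisation
  (Muggeo's update with the hinge `U = (x−ψ)+` and indicator
  `V = −1(x>ψ)`, `ψ ← ψ + γ̂/β̂`, convergence |Δψ| < 1e-6·range(x), 50
  iterations max). Because the RSS profile in ψ can hold several local
  minima, the converged solution is cross-checked against an exhaustive RSS
  scan over interior x-quantiles (grid ties broken toward smaller ψ) and
  re-polished from the grid argmin when that is better; if the iteration
  never converges the grid solution itself is returned with
  `method="grid"`. SE(ψ) by the delta method, SE(γ̂)/|β̂|. Fits with no
  detectable slope change, or iteration failure, are flagged
  `converged=False`; there is no formal test for breakpoint existence
  (a Davies-type test is out of scope and said so to users).
* **Spatially corrected correlation.** Pearson r with a
  Clifford–Richardson effective sample size: pairwise distances are binned
  (Sturges' rule on the pair count, minimum 5 classes, equal width;
  exactly coincident locations form their own lag-0 stratum), per-class
  autocorrelations of both variables estimate
  `trace(R_x R_y) = n + Σ_k N_k r_xk r_yk`, and
  `effective_n = 1 + n² / trace`, capped at n. The t-test then uses
  `effective_n − 2` degrees of freedom. Without coordinates the classical
  test is returned bit-identically. With effective_n ≤ 2 the test is
  undefined (p = NaN) while r is still reported.
* **ANOVA + LSD.** One-way ANOVA; Fisher's LSD
  `t(1−α/2, df_e) √(MSE(1/nᵢ+1/nⱼ))` pairwise; compact letters by
  insert-and-absorb (letters ordered from the largest mean, groups sharing
  no letter differ at α). All groups identical yields MSE = 0, flagged
  rather than tested. No multiple-testing correction is applied across
  analysis pairs, matching per-panel reporting practice.

## Synthetic generators

The generators define the package's test conditions; all are
bit-reproducible from an explicit seed.

* **Masks.** `bernoulli` mode draws each valid pixel independently with its
  zenith band's sky probability (pixels between bands take the nearest
  band's value) — an analytic oracle: expected gap fractions are the
  probabilities themselves. `discs` mode scatters opaque angular discs
  (Poisson count = density × visible solid angle, centres uniform on the
  spherical cap) — a Boolean clumping model closer to a real canopy. Real
  foliage is neither independent per pixel nor disc-shaped: passing tests
  demonstrate estimator correctness under known truth, not photographic
  realism, and no mixed-pixel, exposure or chromatic effects are emulated.
* **Met series.** Daily totals are the clear-sky open-site total times a
  Beta(8, 2) cloudiness factor (mean 0.8), hence always within the
  clear-sky envelope; `cloud_beta=None` gives a cloudless series equal to
  the envelope.
* **Dose–response.** Piecewise-linear mean with a planted breakpoint plus
  Gaussian noise; doses uniform over a range that must straddle the break.
  Defaults follow the ripening-window study conditions: ψ = 544.2 MJ m⁻²
  (the % kaempferol anchor; 560.2 for total flavonols), n = 48 clusters,
  doses 300–700 MJ m⁻², slopes 0.01 and 0.05 % per MJ m⁻², noise SD 0.5
  percentage points.
* **Peak tables.** Class areas realise a target percentage profile exactly
  (default: the Healdsburg Cabernet Sauvignon site averages — kaempferol
  5.40, quercetin 51.5, myricetin 31.7, remainder split equally across the
  methylated classes). The quercetin class is split 0.2/0.3/0.5 across
  galactoside/glucuronide/glucoside — an arbitrary documented choice that
  class-level outputs cannot see. Optional lognormal jitter adds
  integration noise.

## Problem sizes and determinism

Tests and the acceptance script run entirely on generated data: masks of
201–401 px (≥10⁵ valid pixels where binomial tolerances demand it), 47-day
radiation windows at 121 px, 200 breakpoint replicates at n = 48, 500
null replicates for test calibration, and a 48-cluster coupled end-to-end
run. Pipeline outputs are byte-stable: fixed float formatting, provenance
columns (config hash, package version, seed) on every table.

## Known limitations

* No lens calibration, tilt support or automatic optical-centre detection;
  geometry must be supplied per image.
* The clear-sky model is a one-parameter envelope; spectral (UV-B)
  transfer, ground-reflected radiation and anisotropic diffuse sky models
  are out of scope.
* LAI here is a plant-area index without clumping-index correction; the
  five printed ring weights are trusted as-is.
* The breakpoint fit assumes exactly one break and homoscedastic noise.
* The effective-sample-size correction is an approximation; with very few
  distance classes or tiny n its calibration degrades.
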