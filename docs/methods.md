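# Methods

This note documents the models, conventions, defaults and known limitations
of `fibrilmech`. Symbols follow the README.

## Contact-mechanics model

The analysis chain assumes an isotropic, linear-elastic sample indented by a
rigid-tipped conical/pyramidal indenter:

* Reduced modulus: `E_r = √π/(2β) · S_c/√A_c`. The shape factor β is 1.0226–
  1.085 in theory; the package fixes **β = 1** by default, a common AFM
  convention, configurable within the theoretical band.
* Two-body relation: `1/E_r = (1−ν_s²)/E_s + (1−ν_i²)/E_i` with silicon-tip
  defaults `E_i = 169 GPa`, `ν_i = 0.27`. The default *simplified* mode drops
  the indenter term; for hydrated fibrils (≤ 100 MPa) the two routes agree to
  < 0.1 %, at the stiff end (~13 GPa) the shortcut under-reports by ~9–10 %
  (covered by a test). The two-body mode raises on the non-physical case
  `E_r ≥ E_i/(1−ν_i²)`.
* Poisson ratio of the fibril: **ν = 0.5** (incompressible) by default. This
  is an assumption, echoed into every result row; any value in [0, 0.5] can
  be configured.
* Contact depth: `h_c = h_max − ε·P_max/S_c` with **ε = 2(π−2)/π ≈ 0.727**
  (Sneddon cone). This choice makes the analysis exactly consistent with the
  conical forward model: for `F = C δ²`, `h_c = (2/π)·δ_max` and the ideal
  cone area function returns the true modulus identically. The textbook
  ε = 0.75 (paraboloid) is selectable.
* Area function: ideal geometry `A_c = π·tan²θ·h_c²` with θ = 35° by default,
  or the standard calibration series `C₀h² + C₁h + C₂h^½ + …` loaded from
  JSON. The ideal-geometry prefactor is the same constant the synthetic
  generator uses; tip calibration itself is out of scope.

Since indentation of a transversely isotropic fibril mixes transverse
compression with longitudinal tension, results are reported as *indentation
moduli*, not transverse Young's moduli.

### Numerical choices

* **Contact point.** A line is fitted to the leading 30 % of the approach;
  contact is the first run of ≥ 5 samples above 5 baseline SDs, refined by
  minimizing a two-regime residual (zero force before `z₀`, `F = a·δ^m`
  after, m = 2 by default) over a bracket around the crossing. On noiseless
  curves the refinement lands on the true contact point to optimizer
  tolerance; at 2 % peak-force noise the median error is ≤ 1 sample spacing.
* **Errors-in-variables guard.** Deflection noise enters `F = k·d` and
  `δ = (z−z₀) − d` with opposite signs; a slope fitted to raw `F(δ)` is
  therefore attenuated (≈ −10 % at 2 % force noise under the default
  geometry). The deflection used for the *separation* (and inside the
  contact-point objective) is Savitzky–Golay smoothed (window 31, order 2);
  the force channel stays raw, so the regression noise is in the ordinate
  only. Noiseless analyses are unaffected.
* **Stiffness fit.** Power law over the top 30 % of the contact range
  (`fit_fraction = 0.3`). The `contact_stiffness` function fits a free
  exponent by default (so linear and quadratic laws are both recovered
  exactly); the full-curve analyzer fixes the exponent at 2, consistent with
  its ideal-cone area function — the free fit is available via
  `AnalysisConfig(stiffness_exponent=None)`. `P_max` is taken from the fitted
  law at `δ_max` (a smoothed maximum load).
* **Degenerate inputs.** Curves without a detectable contact return an
  explicit invalid result (excluded from batch statistics, never silently
  dropped); negative contact depths are clipped to zero with a warning;
  non-monotone contact segments (after coarse smoothing) raise.

## Thermal calibration

`k = correction · k_B·T / var(d)` with the deflection series in nm. The
mode-shape correction defaults to **0.971** (first flexural mode of a
rectangular lever). Zero-variance series raise.

## Topography

* Heights are nm, positive up; row-major grids, origin top-left, physical
  coordinate = pixel index × pixel size (pixel centers).
* **Axis tracing** removes a global substrate plane (two-pass least-squares
  excluding ridge pixels), estimates the substrate level from the modal
  histogram bin (robust even when the fibril covers most of the frame; noise
  from the lower-tail 10th percentile), thresholds halfway to the peak, takes
  the principal axis of the thresholded pixels and the per-station height
  maximum as the crest, lightly smoothed. Images without a ridge ≥ 10 noise
  SDs above the substrate return an empty polyline.
* **Cross-sections** are sampled perpendicular to the local axis direction
  (bilinear interpolation), averaged over 5 adjacent stations by default.
  The substrate baseline is a least-absolute-deviations line on flanking
  samples selected by height (below 20 % of the edge-detrended ridge
  height), which keeps wide fibrils out of the baseline. Fibril height is
  the baseline-corrected crest maximum; apparent width is the FWHM and is
  treated as tip-convolved (not used quantitatively).
* **D-period**: the crest profile is resampled at one-pixel arc-length steps,
  linearly detrended, and its dominant period taken from the Hann-windowed,
  8×-zero-padded FFT power spectrum with parabolic peak interpolation
  (confidence = peak/median in-band power, low-confidence below 50), or from
  the first prominent autocorrelation peak (confidence = correlation value,
  floor 0.25). Search band: 2 px < period < half the profile length.
* **Swelling convention.** `S = h_wet/h_dry`. Volume is taken proportional
  to height (`V_fold = S`): fibril length is constant and the apparent width
  unreliable, so `φ_w = 1 − 1/S`, `ρ_norm = 1/S`. At the wild-type mean fold
  S = 2.6 this gives φ_w = 0.615 — about two-thirds of the hydrated fibril
  volume being water — whereas an isotropic-cross-section convention
  (`V_fold = S²`, available as a switch) would give 0.85. For shrinkage
  (S < 1) φ_w is reported as 0.

## Microfibril arithmetic

Unit-cell volume uses the standard crystallographic formula and is oracle-
checked against the triple product of explicitly constructed lattice vectors
(a along x, b in the xy-plane); near-degenerate metrics (discriminant
≤ 1e-12) are rejected. The density comparison of the OIM homotrimer cell
uses the loaded-cell volume excess (1.14) as an *input constant* — the
deformed c-axis and angles under load are not available — under an
equal-mass assumption (12.3 % deficit); with the actual trimer masses
(405.621 vs 414.096 kDa) the deficit is 10.4 %. Tangent moduli come from a
least-squares polynomial σ(ε) (through the origin by default) solved by
bisection at the requested stress and differentiated there; requesting a
stress outside the fitted range raises with the range in the message. The
compression stress–strain polynomials of the source simulations are not
published, so pipeline and tests construct quadratic series whose 150 MPa
tangents equal the published endpoint values (1.05 / 0.79 GPa) and verify
their recovery.

## Cohort statistics

"GLM" here means a Gaussian linear model on `ln(modulus)` — the log corrects
the strong mean–variance coupling of per-fibril moduli — fitted as a
cell-means design (one indicator per observed factor-level combination) via
OLS. Least-square means are equal-weight marginal means over the factor
grid; a missing cell makes the requested marginal mean undefined and raises
with the offending cells named. Pairwise contrasts use the studentized-range
distribution (`P(q_{k,df} ≥ √2·|t|)`, scipy's numerically integrated CDF); a
Monte-Carlo simulation of the null range distribution cross-checks it in the
test suite, and at k = 2 the adjusted p equals the pooled two-sample t-test
p to 1e-6. Significance is α = 0.05. Fold ratios are ratios of
back-transformed lsmeans (geometric-mean scale), also rounded to the nearest
integer fold. Sex can be included as an additional factor.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure the analysis assumes*:
Sneddon-cone elasticity with white force noise and optional linear drift and
channel-consistent deflection (`z − z₀ = δ + F/k` solved in closed form);
semi-elliptic D-banded fibril cross-sections on a rough flat substrate with
optional spherical-cap grayscale tip dilation (wet state scales height and
width by the swelling fold, D-period unchanged); lognormal (default) or
zero-truncated-normal cohorts parameterized by arithmetic mean/SD. Lognormal
is the default because the downstream statistics log-transform.

They deliberately omit: adhesion and JKR/DMT contact, viscoelastic
creep/relaxation, substrate (finite-thickness) effects, instrument transfer
functions and 1/f noise, scanner drift/creep in images, multi-fibril fields,
and real tip-shape imperfections. Passing recovery tests therefore
demonstrates the correctness and noise behaviour of the estimators under the
stated model, not robustness to every artefact of real AFM data.

### Default study conditions

Cohort parameters mirror the published group summaries: air-dried WT
7.9 ± 2.8 GPa and OIM 5.3 ± 2.2 GPa (n = 10 per group; the air-dried n is not
published, so it was fixed once to match the hydrated WT group), PBS WT
3.3 ± 0.5 MPa (n = 10) vs OIM 16.2 ± 3.0 MPa (n = 8), ethanol-trial pair
1.2 ± 0.4 vs 10.8 ± 3.7 MPa (n = 8 each, unpublished); swelling folds
2.6 ± 0.4 (WT, n = 8) and 1.5 ± 0.3 (OIM, n = 7), dry heights 26 ± 4 nm.
Indentation depths and loads are likewise unpublished; the generator defaults
(50 nm indentation in PBS with the 0.24 N/m lever, 15 nm air-dried with the
44.5 N/m lever, 40 nm in EtOH with 8.3 N/m, 2 % peak-force noise, pre-contact
range twice the maximum indentation) are assumptions chosen to give realistic
deflections for each lever. Simulation sizes throughout (image frames of
~100×400 px at 2 nm/px, a few hundred samples per curve segment, 2000-rep
null simulations) are the package's own choices balancing resolution against
run time.

## Reproducibility

All randomness flows through `numpy.random.SeedSequence`; the pipeline
spawns per-stage and per-curve child seeds, so re-running with the same
configuration and seed reproduces every output byte-identically (run logs
with timings excluded). Every physical assumption (ν, ε, β, area-function
source, volume convention, statistics factors) is echoed into result rows
and the run summary.

## Known limitations

* The elastic, isotropic, rigid-cone contact model is an idealization for a
  hydrated, transversely isotropic biopolymer fibril; absolute moduli carry
  the usual AFM-nanoindentation caveats.
* Height-based swelling ignores any length change and treats width as
  unreliable; the density normalization inherits that convention.
* The D-period estimator assumes a single dominant axial period and ≥ 4
  periods of crest; it reports low confidence rather than failing outright.
* The statistics module covers fixed-effects factorial designs only (no
  mixed effects, no adjustments beyond Tukey).
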