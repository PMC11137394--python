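# Methods

`leafspec` monitors pollutant stress in food plants from handheld
vibrational spectra (Raman, FTIR-ATR on living or dried leaves) and from
digital leaf photographs. The core is multivariate statistical process
control (MSPC) on a healthy-plant PCA model; around it sit spectral
pretreatment, variographic sample-size design, chart-based colorimetry,
and a synthetic-data generator that provides the study conditions for all
tests.

## The monitoring model

Calibration spectra from healthy plants form a matrix **X** (samples x
wavenumbers). Each wavenumber is standardized with the calibration mean
and standard deviation,

    Z = (X - mu) / sigma,

so every wavenumber contributes equal variance (no prior knowledge about
band importance is assumed). Standard deviations below `eps = 1e-8` are
clamped with a warning rather than dropped, keeping the axis aligned
across experiments. `sigma` uses the m-1 denominator throughout.

Z is decomposed by singular values, `Z = T P' + E`, with `n` retained
components. Loadings signs are fixed (largest-magnitude element positive)
to remove the SVD ambiguity. The per-component calibration score variance
`lambda_j` (m-1 denominator) scales Hotelling's statistic:

* **T²** = sum_j t_j^2 / lambda_j — distance within the modelled
  variation; signals when the proportions between correlated bands change
  (a band falling three units per unit rise of its partner where the
  healthy model learned two).
* **SPEx** = sum_i (z_i - zhat_i)^2 — squared prediction error; signals
  variation the healthy model cannot represent (new covariation at bands
  that were inert during calibration).

Per-wavenumber contribution decompositions attribute a signal:
SPEx contributions are `(z_i - zhat_i)^2` (non-negative, summing exactly
to SPEx). T² contributions default to the residual-weighted form

    c_i = sum_j (t_j / lambda_j) p_ij (z_i - zhat_i),

with the literature-standard residual-free variant
`sum_j (t_j/lambda_j) p_ij z_i` selectable. Sign semantics of the default
form: in a broken-correlation scenario the variable that moved further
than the model expects receives a *positive* contribution and its
modelled partner a *negative* one (both follow from the formula; see
`test_t2_contribution_sign_semantics`). A practical consequence of the
residual factor: when a changed correlation stays entirely inside the
model span, residuals are near zero and the default T² contributions
de-localize; the residual-free variant is the better diagnostic there.

### Control limits

Limits are computed at configurable confidence levels (defaults: flags at
98%, reporting at 99.7%, contribution limits at 99.8%). Three methods:

* `empirical` — type-7 interpolated quantile of calibration statistic
  values (`h = (n-1)p + 1`).
* `t2_f_dist` — `n(m-1)(m+1) / (m(m-n)) * F_p(n, m-n)`.
* `spex_chi2_moment` — moment-matched `g * chi2_h(p)` with `g = v/2a`,
  `h = 2a^2/v` from the calibration SPEx mean `a` and variance `v`.

Empirical limits default to **leave-one-out cross-validated** calibration
statistics: each calibration sample is scored through the model refitted
without it. In-sample statistics are biased low — the estimated mean,
sigma and subspace absorb part of each sample's own noise — and a quantile
of them over-flags independent healthy data noticeably (the SPEx
distribution is tight, so a few percent of mean bias moves the tail a
lot). With cross-validated values the nominal false-alarm rate holds on
independent data to binomial accuracy. The in-sample basis remains
selectable (`limit_basis="in_sample"`). Note the intrinsic granularity of
a 99.7% empirical quantile from 200 calibration values: its exceedance
rate on new data fluctuates by several tenths of a percent across
calibration draws regardless of implementation.

If the model retains full rank, SPEx is identically zero on calibration
data; the chart carries an explicit warning that it is uninformative.

### Scenario A and Scenario B

Scenario A (monitoring) projects test spectra through the calibration
model and builds both charts; contribution profiles are computed for
every flagged sample, and wavenumbers exceeding the calibration
contribution limits in *both* charts for at least half of the respective
flagged samples (configurable) are reported as common peaks with an
up/down direction.

Scenario B fits separate models to a healthy and a polluted group, pairs
components by maximal absolute cosine between loadings (optimal
assignment), sign-aligns each pair, and reports per-pair loading
differences plus the difference of raw group mean spectra. A minimum
group size (default 10) is enforced because loadings estimated from
undersized subsets vary enough to make differences meaningless — the
variographic study below should precede any Scenario B comparison.

## Pretreatment

Configurable per-spectrum steps, with modality defaults:
Raman `baseline_polyfit -> normalize -> savgol -> crop_roi`; dried-leaf
FTIR `crop_roi -> flip_absorbance -> savgol -> normalize`; living-leaf
FTIR `savgol -> normalize`.

* `baseline_polyfit` — iterative clipped polynomial refit (fit, clip
  working values to the fit, refit) until the baseline moves less than
  `tol` x value range (defaults: order 5 for Raman, 2 inside an FTIR ROI;
  tol 1e-4; 100 iterations). Chosen as the standard parameter-light
  automated polynomial method; the abscissa is rescaled to [-1, 1] for
  conditioning.
* `baseline_iter_avg` — iterated minimum of (value, centered moving
  average), half-window >= 1; background is a fixed point, peaks erode.
  Guarantees corrected >= 0 up to float tolerance.
* `savgol` — Savitzky-Golay with window 11 / order 3 defaults; edge
  points are refit on the truncated one-sided window instead of padded,
  avoiding reflection artifacts at ROI boundaries. Requires a uniform
  axis (harmonize first).
* `normalize` — unit Euclidean norm by default (removes global
  instrument scale without anchoring to one peak); max-one and
  trapezoidal area-one variants provided. All idempotent.
* `flip_absorbance` — default affine flip `max(v) - v` (shape-preserving,
  no positivity requirement); physical `log10(1/R)` selectable.

Both baseline methods report the estimate additively: corrected +
baseline reconstructs the input exactly.

## Sample-size design

`variation_vs_n` draws seeded random subsets of each size, standardizes
within the subset, and records the total variance (sum of per-wavenumber
mean squared deviations, denominator n) of the standardized subset and of
its k-component PCA reconstruction, averaged over repeats. Under this
convention the raw curve rises as `q(n-1)/n` toward saturation — matching
the qualitative behavior that dataset variation grows continuously as
samples are added — while the reconstructed curve additionally reflects
how much systematic structure the subset exposes. `recommend_n` applies a
plateau rule: the smallest n whose look-ahead window (default w = 5)
grows by less than tau = 2% relative; if the curve never plateaus the
largest n is returned with a warning. Subset sizes start at
`max(3, n_components + 1)`.

`variogram_scores` computes the semivariance of PCA score vectors over
integer acquisition-order lags, `gamma(h) = sum ||t_{i+h} - t_i||^2 /
(2(m-h))`. Leaves carry no spatial coordinates, so acquisition order
stands in for the lag axis; for serially uncorrelated sampling the
variogram is flat at the total score variance.

## Colorimetry

Photographs include a 24-patch reference chart; patch positions are
configuration-supplied (chart corners -> 4 x 6 grid) rather than
auto-detected, keeping the pipeline deterministic. Patch colors are
averaged after a 10% per-side erosion. Correction is an affine 3 x 4
transform fitted by least squares in *linearized* sRGB (IEC 61966-2-1
transfer function) — the minimal model that removes per-channel gain and
offset casts and is exactly recoverable when the cast keeps all patches
in gamut; clipping at the gamut boundary destroys the affine relation, so
recovery guarantees apply to in-gamut casts only. Output pixels are
clipped, never wrapped.

Leaves are segmented on the excess-green index `2G - R - B` (linear RGB)
with a global Otsu threshold over non-excluded pixels, 8-connected
components, and a minimum area of 0.1% of the image; the chart region is
excluded via a mask (its green patches would otherwise segment as plant
material). Each leaf is summarized by its mean sRGB color; group
dispersion is the mean pairwise distance between leaf means, and
pollution heterogeneity is read from the treated/control dispersion
ratio. Shadows are not corrected algorithmically — acquisition should use
diffuse light — and this is a documented limitation.

## Synthetic data: what it emulates and what it does not

Healthy spectra are a low-rank factor model: Gaussian bands whose
amplitudes co-vary through latent factors (`amplitude = base (1 + L s)`),
a per-spectrum random polynomial baseline, and white noise. The default
generator places bands at 700-1740 cm^-1 on a 650-1800 cm^-1 axis with a
2 cm^-1 step and encodes the monitoring narrative: factor 0 couples
1580 cm^-1 (+1 unit) to 1000 cm^-1 (-2 units); factor 1 drives
1170/1740/850; four small *individual* modes (weight 0.08) give the major
bands independent variability, which places each band's coordinate
direction inside the healthy model span — the property that makes a
changed correlation ratio register as modelled variation (T²) rather
than residual variation (SPEx). 1300 cm^-1 stays inert as the
new-variation target. Noise sd 0.02, baseline order 2 with coefficient
sd 0.05.

Pollution effects: `mean_shift` offsets base amplitudes; `modelled_change`
rescales a band's loadings (ratio -2 -> -3 corresponds to magnitude 1.5);
`new_variation` appends a fresh factor coupling the inert target to the
most strongly loaded active band with the given weight on both. Negative
amplitudes are clipped at zero with a count warning (intensity cannot be
negative; strong effects make bands vanish).

The demo study conditions are 150 calibration spectra, 30 test spectra
per effect, 9 retained components (the generator's systematic dimension:
~3 baseline + 2 shared factors + 4 individual modes). The
`new_variation` demo magnitude is 0.8 (an amplitude swing of 0.64
intensity units, 32x the noise sd — the "band appears/disappears" regime
the contribution diagnostics are designed for).

What the generator does *not* emulate: fluorescence backgrounds with
physical shape, wavelength-dependent noise, instrument line-shape
functions, temperature drift, or biochemical band assignments. Passing
tests therefore demonstrate the statistical machinery under the stated
assumptions (low-rank structure + smooth baseline + white noise), not
instrument-level realism.

The sample-size study uses a separate archetype generator: 15 fixed
latent states in a 3-factor space cycled through the population, densely
overlapping bands so every wavenumber is factor-driven, near-zero noise
and no random baseline. Systematic variation saturates once all 15
archetypes are represented, and the plateau rule recovers n ~ 15.

Leaf images: gray background, rendered reference chart, non-overlapping
elliptical leaves with a small seeded per-leaf color jitter (sd 3 sRGB
units — a perfectly uniform control group would make dispersion ratios
degenerate), optional bright spots on a configured fraction of leaves,
and an optional affine illumination cast applied in linear RGB.

## Numerical choices

* Quantiles: numpy's default linear interpolation (type 7) everywhere.
* SVD-based fitting; brute-force eigendecomposition serves as the test
  oracle, never the implementation.
* Degenerate inputs: all-zero spectra cannot be normalized; identical
  calibration samples cannot be decomposed (no variance); identical
  samples in the variogram return a flat zero curve.
* Determinism: every stochastic routine takes an explicit seed; the
  pipeline derives per-stage seeds from one global seed via a fixed
  stage-name hash (CRC32), each below 2^31.

## Known limitations

* T² contribution profiles (default formula) do not localize purely
  in-model changes; use the residual-free variant for that diagnostic.
* Empirical limits at 99.7% from small calibration sets are granular
  (order-statistic noise); parametric limits are provided but assume
  approximate normality of scores.
* Colorimetric recovery guarantees hold for in-gamut casts only.
* The affine-in-linear-RGB correction cannot remove channel cross-talk
  (a full 3x3 mixing cast is fit, but nonlinear camera processing is out
  of scope).
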