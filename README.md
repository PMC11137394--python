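# leafspec

PCA-based statistical process control for plant-leaf vibrational spectra,
with spectral pretreatment, variographic sample-size design and leaf
colorimetry.

## Who this is for

Detecting pollutant stress (heavy-metal exposure, disease) in food plants
from portable Raman or FTIR-ATR spectra is attractive because it needs no
prior knowledge of the contaminant: instead of training a classifier on
known diseases, one calibrates a model of the *healthy* plant and flags
anything that deviates. `leafspec` implements that workflow for analysts
working with handheld spectrometers and digital leaf photography.

## The model

Healthy-plant calibration spectra **X** (samples × wavenumbers) are
standardized per wavenumber, `Z = (X − μ)/σ`, and decomposed by singular
values into scores and orthonormal loadings,

```
Z = T Pᵀ + E
```

with *n* retained principal components. New spectra are projected through
the calibration model and monitored on two complementary control charts:

* **Hotelling's T²** `= Σⱼ tⱼ²/λⱼ` (λⱼ = calibration score variance) —
  flags changes *within* the modelled variation, e.g. a band that now
  drops three units per unit rise of its partner where the healthy model
  learned two;
* **SPEx (Q)** `= Σᵢ (zᵢ − ẑᵢ)²` — flags *new* variation the model cannot
  represent, e.g. covariation appearing at a band that was inert in the
  healthy plant.

Per-wavenumber contributions (`(zᵢ − ẑᵢ)²` for SPEx;
`Σⱼ (tⱼ/λⱼ) pᵢⱼ (zᵢ − ẑᵢ)`, signed, for T²) attribute each alarm to
specific bands with an up/down direction. Control limits are empirical
quantiles of leave-one-out cross-validated calibration statistics
(parametric F and moment-matched χ² limits are also provided). Around
this core sit: configurable pretreatment (iterative polynomial or
moving-average baseline correction, Savitzky–Golay smoothing,
normalization, ROI cropping, reflectance→absorbance), a variogram-based
sample-size recommender, ColorChecker-based color correction with
excess-green leaf segmentation, and a seeded synthetic-data generator.
See `docs/methods.md` for the full account.

## Worked example

The bundled demo generates healthy calibration spectra (150 samples,
650–1800 cm⁻¹), two polluted test sets and a pair of leaf photographs,
then monitors and summarizes:

```
$ leafspec run --seed 1 --out demo_out
```

or equivalently in Python:

```python
from leafspec import pipeline
manifest = pipeline.run(pipeline.demo_config(seed=1, out_dir="demo_out"))
print(pipeline.render_report(manifest))
```

which prints (abbreviated):

```
| test set        | method     | T2 up [%] | SPEx up [%] | common peaks        |
|-----------------|------------|-----------|-------------|---------------------|
| modelled_change | ftir_alive | 6.7       | 3.3         | -                   |
| new_variation   | ftir_alive | 66.7      | 90.0        | ... 1300 ↑ ...      |

recommended calibration samples: 13
between-group mean color distance: 9.32
dispersion ratio (treated / control): 1.78
```

Reading the numbers: the set with a changed 1000/1580 cm⁻¹ correlation
ratio signals more on T² than on SPEx (changed *modelled* variation),
while the set with new covariation at the previously inert 1300 cm⁻¹
band drives 90% of samples over the SPEx limit, and the contribution
profile marks 1300 cm⁻¹ (↑) among the common peaks. The variation curve
plateaus at 13 calibration samples for this draw, and the half-spotted
leaf group is 1.78× more dispersed in RGB space than the control after
cast correction — the colorimetric signature of heterogeneous pollution
damage.

Single operations are available as plain functions and sklearn-style
estimators:

```python
from leafspec import PCAMonitor, default_spec, generate_healthy

cal, _ = generate_healthy(default_spec(seed=0), 150, seed=1)
mon = PCAMonitor(n_components=9).fit(cal)
t2 = mon.t_squared(cal.matrix)   # per-sample Hotelling T²
```

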