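import numpy as np
import pytest

from leafspec.pretreat import (
    PretreatConfig,
    SpectralPretreater,
    baseline_iter_avg,
    baseline_polyfit,
    crop_roi,
    default_config,
    flip_absorbance,
    normalize,
    run_pretreatment,
    savgol,
)
from leafspec.synth import default_spec, generate_healthy

from conftest import make_set, make_spectrum


# ---------------------------------------------------------------------------
# baseline correction


def test_polyfit_removes_pure_polynomial_baseline():
    x = np.linspace(0, 1, 200)
    vals = 3.0 - 2.0 * x + 5.0 * x**2
    res = baseline_polyfit(make_spectrum(vals, axis=600 + 1000 * x), order=2)
    assert res.converged
    assert np.max(np.abs(res.corrected.values)) < 1e-8 * np.ptp(vals)


def test_polyfit_recovers_known_peak_height():
    x = np.linspace(0, 1, 400)
    axis = 600 + 1200 * x
    baseline = 1.0 + 0.8 * x + 2.0 * x**2
    peak = 1.0 * np.exp(-((axis - 1200.0) ** 2) / (2 * 8.0**2))
    res = baseline_polyfit(make_spectrum(baseline + peak, axis=axis), order=2)
    recovered = res.corrected.values[np.argmin(np.abs(axis - 1200.0))]
    assert recovered == pytest.approx(1.0, rel=0.02)


def test_polyfit_zero_iterations_is_plain_least_squares():
    x = np.linspace(-1, 1, 50)
    vals = x**3  # order-1 fit cannot converge in a single pass
    res = baseline_polyfit(make_spectrum(vals, axis=100 + 100 * (x + 1)), order=1, max_iter=0)
    c = np.polynomial.polynomial.polyfit(x, vals, 1)
    expected = np.polynomial.polynomial.polyval(x, c)
    assert res.iterations == 1
    np.testing.assert_allclose(res.baseline, expected, atol=1e-10)


@pytest.mark.parametrize("func,kwargs", [
    (baseline_polyfit, {"order": 3}),
    (baseline_iter_avg, {"half_window": 3}),
])
def test_baseline_additivity(rng, func, kwargs):
    s = make_spectrum(rng.normal(size=120).cumsum() + 50)
    res = func(s, **kwargs)
    np.testing.assert_allclose(res.corrected.values + res.baseline, s.values, rtol=0, atol=1e-10)


def test_iter_avg_constant_is_fixed_point():
    s = make_spectrum(np.full(30, 7.5))
    res = baseline_iter_avg(s, half_window=3)
    np.testing.assert_allclose(res.baseline, 7.5)
    np.testing.assert_allclose(res.corrected.values, 0.0, atol=1e-12)


def test_iter_avg_matches_bruteforce_on_toy():
    # independent re-implementation of the update rule with explicit loops
    vals = np.array([1.0, 1.0, 1.0, 1.0, 9.0, 1.0, 1.0, 1.0, 1.0])
    hw, iters = 2, 3
    work = vals.copy()
    for _ in range(iters):
        avg = np.empty_like(work)
        for i in range(work.size):
            lo, hi = max(0, i - hw), min(work.size, i + hw + 1)
            avg[i] = work[lo:hi].mean()
        work = np.minimum(work, avg)
    res = baseline_iter_avg(make_spectrum(vals), half_window=hw, max_iter=iters)
    np.testing.assert_allclose(res.baseline, work, atol=1e-12)
    # peak is retained, background level kept away from the peak
    assert res.corrected.values[4] > 5.0


def test_iter_avg_single_pass_and_never_exceeds_input(rng):
    vals = rng.normal(size=50) + 10
    res = baseline_iter_avg(make_spectrum(vals), half_window=4, max_iter=1)
    assert res.iterations == 1
    assert np.all(res.baseline <= vals + 1e-12)


# ---------------------------------------------------------------------------
# smoothing


def test_savgol_reproduces_cubic_on_interior():
    axis = np.linspace(100, 300, 101)
    vals = 1.0 - 0.5 * axis + 0.01 * axis**2 - 1e-5 * axis**3
    out = savgol(make_spectrum(vals, axis=axis), window=11, polyorder=3)
    np.testing.assert_allclose(out.values[5:-5], vals[5:-5], atol=1e-9 * np.ptp(vals))


def test_savgol_edges_use_truncated_windows():
    # on polynomial input even the one-sided edge refits are exact
    axis = np.linspace(100, 200, 51)
    vals = 2.0 + 0.3 * axis + 0.002 * axis**2
    out = savgol(make_spectrum(vals, axis=axis), window=9, polyorder=2)
    np.testing.assert_allclose(out.values, vals, rtol=1e-9)


def test_savgol_window_one_rejected():
    with pytest.raises(ValueError):
        savgol(make_spectrum(np.ones(20)), window=1, polyorder=0)


def test_savgol_reduces_noise_variance(rng):
    vals = rng.normal(size=1000)
    out = savgol(make_spectrum(vals, axis=np.arange(1000.0)), window=11, polyorder=2)
    assert out.values.var() < vals.var()


def test_savgol_requires_uniform_axis():
    axis = np.array([1.0, 2.0, 3.5, 4.0, 5.0, 6.0, 7.0])
    with pytest.raises(ValueError, match="harmonize_axis"):
        savgol(make_spectrum(np.ones(7), axis=axis), window=3, polyorder=1)


# ---------------------------------------------------------------------------
# normalization / cropping / flipping


def test_normalize_unit_length_345():
    out = normalize(make_spectrum([3.0, 4.0]), "unit_length")
    np.testing.assert_allclose(out.values, [0.6, 0.8])


def test_normalize_max_one():
    out = normalize(make_spectrum([2.0, 2.0, 2.0]), "max_one")
    np.testing.assert_allclose(out.values, 1.0)


@pytest.mark.parametrize("method", ["unit_length", "max_one", "area_one"])
def test_normalize_idempotent(rng, method):
    s = make_spectrum(np.abs(rng.normal(size=40)) + 0.1)
    once = normalize(s, method)
    twice = normalize(once, method)
    np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)


def test_normalize_zero_spectrum_rejected():
    with pytest.raises(ValueError):
        normalize(make_spectrum(np.zeros(5)))


def test_crop_roi_boundaries_inclusive():
    s = make_spectrum([1.0, 2.0, 3.0], axis=[100.0, 200.0, 300.0])
    out = crop_roi(s, 150.0, 300.0)
    np.testing.assert_array_equal(out.axis, [200.0, 300.0])


def test_crop_roi_full_range_identity(rng):
    s = make_spectrum(rng.normal(size=10))
    out = crop_roi(s, s.axis[0], s.axis[-1])
    np.testing.assert_array_equal(out.values, s.values)


def test_crop_roi_empty_is_error():
    s = make_spectrum(np.ones(5), axis=np.linspace(650, 4000, 5))
    with pytest.raises(ValueError):
        crop_roi(s, 5000.0, 6000.0)


def test_flip_affine_example_and_involution(rng):
    out = flip_absorbance(make_spectrum([0.2, 0.8]), "affine_flip")
    np.testing.assert_allclose(out.values, [0.6, 0.0])
    s = make_spectrum(rng.uniform(0.1, 1.0, 30))
    twice = flip_absorbance(flip_absorbance(s, "affine_flip"), "affine_flip")
    shifted = twice.values - twice.values.min()
    np.testing.assert_allclose(shifted, s.values - s.values.min(), atol=1e-12)


def test_flip_log_inverse():
    out = flip_absorbance(make_spectrum([1.0, 0.1]), "log_inverse")
    np.testing.assert_allclose(out.values, [0.0, 1.0])
    with pytest.raises(ValueError):
        flip_absorbance(make_spectrum([0.5, -0.1]), "log_inverse")


# ---------------------------------------------------------------------------
# pipeline


def test_empty_config_is_identity(rng):
    sset = make_set(rng.normal(size=(3, 20)))
    out, log = run_pretreatment(sset, PretreatConfig([]))
    assert log == []
    np.testing.assert_array_equal(out.matrix, sset.matrix)


def test_raman_default_pipeline_postconditions():
    spec = default_spec(seed=3)
    raw, _ = generate_healthy(spec, 5, seed=3)
    raw = make_set(raw.matrix + 5.0, axis=raw.axis, modality="raman")
    out, log = run_pretreatment(raw, default_config("raman"))
    assert [e["step"] for e in log] == ["baseline_polyfit", "normalize", "savgol", "crop_roi"]
    assert out.axis[0] >= 650.0 and out.axis[-1] <= 1800.0
    # unit-norm is applied before smoothing: norms stay close to 1 after ROI crop
    norms = np.linalg.norm(out.matrix, axis=1)
    assert np.all(np.abs(norms - 1.0) < 0.15)


def test_duplicate_crop_rejected():
    cfg = PretreatConfig([("crop_roi", {"lo": 1, "hi": 2}), ("crop_roi", {"lo": 1, "hi": 2})])
    with pytest.raises(ValueError, match="crop_roi"):
        cfg.validate("raman")


def test_flip_requires_dried_modality():
    cfg = PretreatConfig([("flip_absorbance", {})])
    with pytest.raises(ValueError, match="flip_absorbance"):
        cfg.validate("raman")
    cfg.validate("ftir_dried")  # fine
    PretreatConfig([("flip_absorbance", {"allow_any_modality": True})]).validate("raman")


def test_pipeline_deterministic(rng):
    sset = make_set(np.abs(rng.normal(size=(4, 60))) + 1.0)
    cfg = PretreatConfig([("baseline_polyfit", {"order": 2}), ("normalize", {}),
                          ("savgol", {"window": 7, "polyorder": 2})])
    a, _ = run_pretreatment(sset, cfg)
    b, _ = run_pretreatment(sset, cfg)
    assert np.array_equal(a.matrix, b.matrix)


def test_step_failure_names_sample_and_step():
    sset = make_set(np.zeros((2, 10)))
    with pytest.raises(RuntimeError, match="normalize.*acquisition_index=0"):
        run_pretreatment(sset, PretreatConfig([("normalize", {})]))


def test_sklearn_transformer_roundtrip(rng):
    from sklearn.base import clone

    X = np.abs(rng.normal(size=(4, 50))) + 1.0
    axis = np.linspace(600, 1090, 50)
    tr = SpectralPretreater(axis=axis, modality="raman",
                            steps=[("normalize", {}), ("savgol", {"window": 7, "polyorder": 2})])
    tr2 = clone(tr)
    out = tr2.fit_transform(X)
    assert out.shape == X.shape
    norms = np.linalg.norm(
        SpectralPretreater(axis=axis, steps=[("normalize", {})]).fit_transform(X), axis=1
    )
    np.testing.assert_allclose(norms, 1.0, rtol=1e-12)
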