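import warnings

import numpy as np
import pytest

from leafspec.mspc import (
    MonitorConfig,
    PCAModel,
    PCAMonitor,
    compare_scenario_b,
    compute_limits,
    compute_spex,
    compute_t2,
    fit_pca,
    monitor_scenario_a,
    spex_contributions,
    standardize,
    t2_contributions,
)
from leafspec.synth import default_spec, generate_healthy

from conftest import make_set


# ---------------------------------------------------------------------------
# independent brute-force oracle: explicit loops over the chart formulas


def oracle_decompose(X, n_components):
    """Eigendecomposition of the calibration correlation structure with
    explicit loops; returns mu, sigma, loadings, score variances."""
    X = np.asarray(X, float)
    m, q = X.shape
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    Z = (X - mu) / np.maximum(sigma, 1e-8)
    C = Z.T @ Z / (m - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:n_components]
    P = V[:, order]
    for j in range(P.shape[1]):
        i_star = int(np.argmax(np.abs(P[:, j])))
        if P[i_star, j] < 0:
            P[:, j] = -P[:, j]
    lam = np.empty(n_components)
    T = Z @ P
    for j in range(n_components):
        lam[j] = T[:, j].var(ddof=1)
    return mu, sigma, P, lam


def oracle_statistics(X, mu, sigma, P, lam):
    """T2, SPEx and both contribution formulas, one loop per index."""
    X = np.atleast_2d(np.asarray(X, float))
    m, q = X.shape
    n = P.shape[1]
    t2 = np.zeros(m)
    spex = np.zeros(m)
    spex_c = np.zeros((m, q))
    t2_c_printed = np.zeros((m, q))
    t2_c_free = np.zeros((m, q))
    for r in range(m):
        z = (X[r] - mu) / np.maximum(sigma, 1e-8)
        t = np.array([sum(z[i] * P[i, j] for i in range(q)) for j in range(n)])
        zhat = np.array([sum(t[j] * P[i, j] for j in range(n)) for i in range(q)])
        for j in range(n):
            t2[r] += t[j] ** 2 / lam[j]
        for i in range(q):
            spex_c[r, i] = (z[i] - zhat[i]) ** 2
            spex[r] += spex_c[r, i]
            for j in range(n):
                t2_c_printed[r, i] += t[j] / lam[j] * P[i, j] * (z[i] - zhat[i])
                t2_c_free[r, i] += t[j] / lam[j] * P[i, j] * z[i]
    return t2, spex, spex_c, t2_c_printed, t2_c_free


def test_oracle_equivalence_on_toy(rng, toy_set):
    """Implementation vs explicit-loop oracle on a seeded 8 x 6 matrix."""
    X = toy_set.matrix
    mon = PCAMonitor(n_components=2).fit(X)
    mu, sigma, P, lam = oracle_decompose(X, 2)
    np.testing.assert_allclose(mon.mu_, mu, atol=1e-10)
    np.testing.assert_allclose(np.abs(mon.loadings_), np.abs(P), atol=1e-8)
    np.testing.assert_allclose(mon.score_variances_, lam, atol=1e-8)
    Y = X + rng.normal(size=X.shape)  # monitored data differs from calibration
    t2, spex, spex_c, t2_cp, t2_cf = oracle_statistics(Y, mu, sigma, P, lam)
    np.testing.assert_allclose(mon.t_squared(Y), t2, atol=1e-8)
    np.testing.assert_allclose(mon.spex(Y), spex, atol=1e-8)
    np.testing.assert_allclose(mon.spex_contributions_matrix(Y), spex_c, atol=1e-8)
    np.testing.assert_allclose(mon.t2_contributions_matrix(Y, "as_printed"), t2_cp, atol=1e-8)
    np.testing.assert_allclose(mon.t2_contributions_matrix(Y, "residual_free"), t2_cf, atol=1e-8)


# ---------------------------------------------------------------------------
# standardization


def test_self_standardization(rng):
    X = rng.normal(size=(40, 6)) * 3 + 5
    Z = standardize(X, X.mean(0), X.std(0, ddof=1))
    np.testing.assert_allclose(Z.mean(0), 0.0, atol=1e-10)
    np.testing.assert_allclose(Z.std(0, ddof=1), 1.0, atol=1e-10)


def test_standardize_clamps_constant_column():
    X = np.column_stack([np.ones(5), np.arange(5.0)])
    with pytest.warns(RuntimeWarning, match="clamped"):
        Z = standardize(X, X.mean(0), X.std(0, ddof=1))
    np.testing.assert_allclose(Z[:, 0], 0.0)


def test_standardize_hand_example():
    Z = standardize(np.array([[1.0], [3.0]]), np.array([2.0]), np.array([1.0]))
    np.testing.assert_allclose(Z, [[-1.0], [1.0]])


def test_standardize_dimension_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        standardize(np.ones((2, 3)), np.zeros(2), np.ones(2))


# ---------------------------------------------------------------------------
# model fitting


def test_rank_one_data_single_component(rng):
    v = rng.normal(size=6)
    X = np.outer(rng.normal(size=10), v) + rng.normal(size=(10, 1)) * 0
    model = fit_pca(X, n_components=1)
    assert model.explained_fraction[0] > 0.999


def test_loadings_orthonormal_and_variances_sorted(rng):
    X = rng.normal(size=(20, 8))
    mon = PCAMonitor(n_components=5).fit(X)
    np.testing.assert_allclose(mon.loadings_.T @ mon.loadings_, np.eye(5), atol=1e-8)
    assert np.all(np.diff(mon.score_variances_) <= 1e-12)
    assert mon.explained_fraction_.sum() == pytest.approx(1.0)


def test_auto_threshold_one_gives_full_rank(rng):
    X = rng.normal(size=(10, 4))
    mon = PCAMonitor(n_components="auto", ev_threshold=1.0).fit(X)
    assert mon.n_components_ == min(10 - 1, 4)


def test_n_components_above_rank_rejected(rng):
    X = rng.normal(size=(5, 10))
    with pytest.raises(ValueError, match="rank"):
        PCAMonitor(n_components=5).fit(X)


# ---------------------------------------------------------------------------
# projection and statistics


def test_full_rank_projection_has_zero_residual(rng):
    X = rng.normal(size=(10, 4))
    mon = PCAMonitor(n_components=4).fit(X)
    _, _, E = mon.project(X)
    assert np.max(np.abs(E)) < 1e-8
    np.testing.assert_allclose(mon.spex(X), 0.0, atol=1e-10)


def test_mean_spectrum_has_zero_scores_and_t2(rng):
    X = rng.normal(size=(15, 6))
    mon = PCAMonitor(n_components=3).fit(X)
    T = mon.transform(X.mean(axis=0))
    np.testing.assert_allclose(T, 0.0, atol=1e-10)
    assert mon.t_squared(X.mean(axis=0))[0] == pytest.approx(0.0, abs=1e-10)


def test_spex_hand_value():
    # z - zhat = (0.2, 0.1) gives SPEx 0.05; realized via a residual vector
    model = PCAModel(
        mu=np.zeros(2), sigma=np.ones(2),
        loadings=np.array([[1.0], [0.0]]),
        score_variances=np.array([1.0]),
        n_components=1,
        cal_scores=np.zeros((3, 1)),
        explained_fraction=np.array([1.0]),
    )
    # x = (1.0, 0.1): score = 1.0, zhat = (1.0, 0); residual = (0, 0.1)
    # take x = (0.2, 0.1) projected on second-axis-free model:
    spex = compute_spex(model, np.array([[0.2, 0.1]]))
    # score = 0.2 -> zhat = (0.2, 0) -> residual (0, 0.1) -> 0.01;
    # combine with x = (0.0, 0.2): residual (0, 0.2) -> 0.04
    spex2 = compute_spex(model, np.array([[0.0, 0.2]]))
    assert spex[0] + spex2[0] == pytest.approx(0.05)


def test_t2_single_component_hand_value():
    model = PCAModel(
        mu=np.zeros(2), sigma=np.ones(2),
        loadings=np.array([[1.0], [0.0]]),
        score_variances=np.array([4.0]),
        n_components=1,
        cal_scores=np.zeros((3, 1)),
        explained_fraction=np.array([1.0]),
    )
    t2 = compute_t2(model, np.array([[2.0, 0.0]]))  # t = 2, lambda = 4
    assert t2[0] == pytest.approx(1.0)


def test_mean_calibration_t2_identity(rng):
    X = rng.normal(size=(25, 7))
    mon = PCAMonitor(n_components=3).fit(X)
    m = X.shape[0]
    assert mon._cal_t2_.mean() == pytest.approx(3 * (m - 1) / m, abs=1e-6)


def test_spex_contribution_additivity(rng):
    X = rng.normal(size=(12, 9))
    mon = PCAMonitor(n_components=4).fit(X)
    Y = rng.normal(size=(6, 9))
    C = mon.spex_contributions_matrix(Y)
    np.testing.assert_allclose(C.sum(axis=1), mon.spex(Y), rtol=1e-10)


def test_t2_contribution_hand_example():
    # one component, t = 1, lambda = 1, p = (1, 0), z - zhat = (0.5, 0.3):
    # as-printed contributions are (0.5, 0)
    P = np.array([[1.0], [0.0]])
    lam = np.array([1.0])
    t = np.array([1.0])
    e = np.array([0.5, 0.3])
    contrib = np.array(
        [sum(t[j] / lam[j] * P[i, j] * e[i] for j in range(1)) for i in range(2)]
    )
    np.testing.assert_allclose(contrib, [0.5, 0.0])


def test_t2_contribution_sign_semantics():
    """Broken-correlation scenario, two standardized variables with a
    perfect negative modelled correlation (loading (1, -1)/sqrt(2)): when
    variable B sits lower than the model predicts from variable A, the
    default (residual-weighted) contribution is positive at B — the
    variable that moved beyond expectation — and negative at its modelled
    partner A.  Expected values hand-computed from the formula:
    z = (0, -d), t = d/sqrt(2), e = (-d/2, -d/2),
    c_i = (t/lambda) p_i e_i = (-d^2/4, +d^2/4)."""
    d = 0.8
    model = PCAModel(
        mu=np.zeros(2), sigma=np.ones(2),
        loadings=np.array([[1.0], [-1.0]]) / np.sqrt(2),
        score_variances=np.array([1.0]),
        n_components=1,
        cal_scores=np.zeros((3, 1)),
        explained_fraction=np.array([0.5, 0.5]),
    )
    prof = t2_contributions(model, np.array([0.0, -d]), "as_printed")
    np.testing.assert_allclose(prof.contributions, [-d**2 / 4, d**2 / 4], atol=1e-12)
    assert prof.contributions[0] < 0 < prof.contributions[1]


def test_residual_free_sums_to_t2_in_span(rng):
    X = rng.normal(size=(15, 5))
    mon = PCAMonitor(n_components=2).fit(X)
    # construct a sample whose standardized vector lies in the span of P
    z = mon.loadings_ @ np.array([1.3, -0.4])
    x = z * mon.sigma_ + mon.mu_
    C = mon.t2_contributions_matrix(x, "residual_free")
    assert C.sum() == pytest.approx(mon.t_squared(x)[0], rel=1e-8)


# ---------------------------------------------------------------------------
# control limits


def test_empirical_limit_interpolated_quantile():
    vals = np.arange(1.0, 101.0)
    assert compute_limits(vals, 0.98, "empirical") == pytest.approx(98.02)
    assert compute_limits(vals, 0.5, "empirical") == pytest.approx(50.5)


def test_empirical_limit_warns_on_few_values():
    with pytest.warns(RuntimeWarning, match="unstable"):
        compute_limits(np.arange(10.0), 0.99, "empirical")


def test_t2_f_limit_asymptotic_chi2():
    import scipy.stats

    m, n = 100_000, 3
    model = PCAModel(
        mu=np.zeros(4), sigma=np.ones(4),
        loadings=np.eye(4)[:, :3], score_variances=np.array([3.0, 2.0, 1.0]),
        n_components=3, cal_scores=np.zeros((m, 3)),
        explained_fraction=np.full(4, 0.25),
    )
    lim = compute_limits(None, 0.98, "t2_f_dist", model=model)
    assert lim == pytest.approx(scipy.stats.chi2.ppf(0.98, n), rel=0.01)


def test_spex_chi2_moment_limit_matches_simulated_tail(rng):
    vals = rng.chisquare(8, size=200_000) * 0.5  # g=0.5, h=8 exactly
    lim = compute_limits(vals, 0.99, "spex_chi2_moment")
    emp = np.quantile(vals, 0.99)
    assert lim == pytest.approx(emp, rel=0.03)


def test_limit_level_bounds():
    with pytest.raises(ValueError):
        compute_limits(np.arange(30.0), 1.2, "empirical")


# ---------------------------------------------------------------------------
# contribution limits


def test_contribution_limits_extreme_level(rng):
    X = rng.normal(size=(20, 6))
    mon = PCAMonitor(n_components=2).fit(X)
    lims = mon.contribution_limits("spex", 1.0)
    C = np.abs(mon._calibration_contributions("spex"))
    np.testing.assert_allclose(lims, C.max(axis=0), rtol=1e-9)
    assert np.all(C <= lims + 1e-12)


def test_contribution_limit_false_exceed_rate(rng):
    spec = default_spec(seed=5)
    cal, _ = generate_healthy(spec, 5000, seed=55)
    mon = PCAMonitor(n_components=9).fit(cal.matrix)
    lims = mon.contribution_limits("spex", 0.998)
    C = np.abs(mon._calibration_contributions("spex"))
    rate = (C > lims).mean()
    assert rate == pytest.approx(0.002, abs=3 * np.sqrt(0.002 * 0.998 / 5000))


# ---------------------------------------------------------------------------
# scenario drivers


def test_monitor_self_test_signalling_rate(rng):
    spec = default_spec(seed=2)
    cal, _ = generate_healthy(spec, 150, seed=21)
    cfg = MonitorConfig(n_components=9, limit_basis="in_sample")
    rep = monitor_scenario_a(cal, cal, cfg)
    # flagging the calibration data against its own empirical quantile
    se = 100 * np.sqrt(0.02 * 0.98 / 150)
    assert abs(rep.t2_chart.percent_signalling - 2.0) <= 3 * se
    assert abs(rep.spex_chart.percent_signalling - 2.0) <= 3 * se


def test_monitor_summary_schema(rng):
    spec = default_spec(seed=2)
    cal, _ = generate_healthy(spec, 60, seed=22)
    test, _ = generate_healthy(spec, 10, seed=23)
    rep = monitor_scenario_a(cal, test, MonitorConfig(n_components=5, limit_basis="in_sample"))
    assert set(rep.summary) == {"method", "t2_up_pct", "spex_up_pct", "common_peaks"}
    assert rep.t2_chart.limits.keys() == {0.98, 0.997, 0.998}
    assert np.all(rep.t2_chart.values >= 0) and np.all(rep.spex_chart.values >= 0)


def test_full_rank_spex_degenerate_warns(rng):
    X = rng.normal(size=(12, 5))
    cal = make_set(X)
    cfg = MonitorConfig(n_components=5, limit_basis="in_sample",
                        limit_method="empirical")
    with pytest.warns(RuntimeWarning, match="uninformative"):
        rep = monitor_scenario_a(cal, cal, cfg)
    np.testing.assert_allclose(rep.spex_chart.values, 0.0, atol=1e-10)
    assert rep.spex_chart.warnings


def test_monitor_empty_test_rejected(rng):
    cal = make_set(rng.normal(size=(10, 4)))
    other = make_set(rng.normal(size=(3, 5)))
    with pytest.raises(ValueError, match="axis"):
        monitor_scenario_a(cal, other)


def test_scenario_b_identical_data_zero_differences(rng):
    spec = default_spec(seed=4)
    s, _ = generate_healthy(spec, 40, seed=41)
    rep = compare_scenario_b(s, s, MonitorConfig(n_components=3))
    np.testing.assert_allclose(rep.mean_difference, 0.0, atol=1e-12)
    for d in rep.loading_diffs:
        np.testing.assert_allclose(d, 0.0, atol=1e-8)
    for _, _, c in rep.pairs:
        assert c == pytest.approx(1.0)


def test_scenario_b_mean_difference_localized(rng):
    base = rng.normal(size=(20, 6))
    a = make_set(base)
    shifted = base.copy()
    shifted[:, 2] += 0.7
    b = make_set(shifted)
    rep = compare_scenario_b(a, b, MonitorConfig(n_components=2))
    np.testing.assert_allclose(rep.mean_difference[2], 0.7, atol=1e-12)
    others = np.delete(rep.mean_difference, 2)
    np.testing.assert_allclose(others, 0.0, atol=1e-12)


def test_scenario_b_pairing_sign_invariant(rng):
    spec = default_spec(seed=6)
    h, _ = generate_healthy(spec, 50, seed=61)
    p, _ = generate_healthy(spec, 50, seed=62)
    rep = compare_scenario_b(h, p, MonitorConfig(n_components=4))
    # flipping raw data signs flips loadings; pairing must be unchanged
    h2 = make_set(-h.matrix, axis=h.axis)
    p2 = make_set(-p.matrix, axis=p.axis)
    rep2 = compare_scenario_b(h2, p2, MonitorConfig(n_components=4))
    assert [(i, j) for i, j, _ in rep.pairs] == [(i, j) for i, j, _ in rep2.pairs]
    for (_, _, c1), (_, _, c2) in zip(rep.pairs, rep2.pairs):
        assert c1 == pytest.approx(c2, abs=1e-10)


def test_scenario_b_undersized_group_rejected(rng):
    small = make_set(rng.normal(size=(5, 6)))
    big = make_set(rng.normal(size=(30, 6)))
    with pytest.raises(ValueError, match="variographic"):
        compare_scenario_b(small, big, MonitorConfig(n_components=2, min_samples=10))
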