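"""PCA-based multivariate statistical process control for spectra.

A calibration set of healthy-plant spectra is standardized per wavenumber,

    z = (x - mu) / sigma,

and decomposed by singular values into scores ``T`` and orthonormal
loadings ``P`` with ``Z = T P' + E``.  Two complementary control charts
monitor new spectra projected through the calibration model:

* **Hotelling's T²** — ``sum_j t_j^2 / lambda_j`` over the retained
  components, with ``lambda_j`` the calibration score variance; it signals
  abnormal magnitude *within* the modelled variation (changed proportions
  between correlated wavenumbers).
* **SPEx (squared prediction error, Q)** — ``sum_i (z_i - zhat_i)^2``; it
  signals variation *outside* the model (new covariation at wavenumbers the
  healthy model left inert).

Per-wavenumber contribution decompositions attribute an out-of-control
value to individual wavenumbers, signed so that a peak sitting lower than
the model expects contributes negatively to T².

The sklearn-style estimator :class:`PCAMonitor` is the implementation; the
module-level functions (``fit_pca``, ``project``, ``compute_t2`` ...) are
thin wrappers over it that mirror the underlying formulas one-to-one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin

from .io import SpectraSet

__all__ = [
    "PCAMonitor",
    "PCAModel",
    "ControlChart",
    "ContributionProfile",
    "MonitoringReport",
    "LoadingDiffReport",
    "MonitorConfig",
    "standardize",
    "fit_pca",
    "project",
    "compute_spex",
    "compute_t2",
    "compute_limits",
    "spex_contributions",
    "t2_contributions",
    "contribution_limits",
    "monitor_scenario_a",
    "compare_scenario_b",
]


# ---------------------------------------------------------------------------
# standardization


def standardize(
    X: np.ndarray, mu: np.ndarray, sigma: np.ndarray, eps: float = 1e-8
) -> np.ndarray:
    """Columnwise centring and scaling, ``Z = (X - mu) / max(sigma, eps)``.

    Wavenumbers whose calibration standard deviation falls below ``eps``
    are clamped (and reported with a warning) rather than dropped, keeping
    the axis aligned across experiments.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = np.asarray(mu, dtype=float).ravel()
    sigma = np.asarray(sigma, dtype=float).ravel()
    if eps <= 0:
        raise ValueError("eps must be positive")
    if X.shape[1] != mu.size or X.shape[1] != sigma.size:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} columns, "
            f"mu has {mu.size}, sigma has {sigma.size}"
        )
    clamped = np.nonzero(sigma < eps)[0]
    if clamped.size:
        warnings.warn(
            f"{clamped.size} wavenumber column(s) with sigma < {eps} clamped: "
            f"indices {clamped[:10].tolist()}{'...' if clamped.size > 10 else ''}",
            RuntimeWarning,
            stacklevel=2,
        )
    return (X - mu) / np.maximum(sigma, eps)


# ---------------------------------------------------------------------------
# the monitor estimator


@dataclass
class PCAModel:
    """Frozen snapshot of a fitted calibration model.

    Holds the calibration means/standard deviations, orthonormal loadings
    (wavenumbers x components), per-component calibration score variances
    ``lambda_j`` (denominator m-1), calibration scores, explained-variance
    fractions and the wavenumber axis.
    """

    mu: np.ndarray
    sigma: np.ndarray
    loadings: np.ndarray
    score_variances: np.ndarray
    n_components: int
    cal_scores: np.ndarray
    explained_fraction: np.ndarray
    axis: np.ndarray | None = None
    eps: float = 1e-8

    @property
    def m(self) -> int:
        return self.cal_scores.shape[0]

    @property
    def q(self) -> int:
        return self.loadings.shape[0]


class PCAMonitor(BaseEstimator, TransformerMixin):
    """Healthy-plant PCA model with T²/SPEx monitoring.

    Parameters
    ----------
    n_components:
        number of retained components, or ``"auto"`` to take the smallest
        number whose cumulative explained fraction of the standardized
        variance reaches ``ev_threshold``.
    ev_threshold:
        cumulative explained-variance target for ``n_components="auto"``.
    eps:
        clamp for near-zero calibration standard deviations.

    Fitted attributes (trailing underscore) follow sklearn conventions:
    ``mu_``, ``sigma_``, ``loadings_`` (q x n), ``score_variances_``,
    ``cal_scores_``, ``explained_fraction_``, ``n_components_``.
    """

    def __init__(self, n_components="auto", ev_threshold: float = 0.95, eps: float = 1e-8):
        self.n_components = n_components
        self.ev_threshold = ev_threshold
        self.eps = eps

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None, axis: np.ndarray | None = None):
        if isinstance(X, SpectraSet):
            axis = X.axis if axis is None else axis
            X = X.matrix
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x wavenumbers)")
        m, q = X.shape
        if m < 3:
            raise ValueError("calibration needs at least 3 samples")
        self.mu_ = X.mean(axis=0)
        self.sigma_ = X.std(axis=0, ddof=1)
        Z = standardize(X, self.mu_, self.sigma_, self.eps)

        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        lam_all = S**2 / (m - 1)
        total = lam_all.sum()
        if total <= 0:
            raise ValueError("calibration matrix has no variance")
        self.explained_fraction_ = lam_all / total
        rank_cap = min(m - 1, q)

        if self.n_components == "auto":
            if not 0 < self.ev_threshold <= 1:
                raise ValueError("ev_threshold must be in (0, 1]")
            cum = np.cumsum(self.explained_fraction_)
            n = int(np.searchsorted(cum, self.ev_threshold - 1e-12) + 1)
            n = min(n, rank_cap)
        else:
            n = int(self.n_components)
            if n < 1:
                raise ValueError("n_components must be >= 1")
            if n > rank_cap:
                raise ValueError(
                    f"n_components={n} exceeds the model rank min(m-1, q)={rank_cap}"
                )
        P = Vt[:n].T.copy()
        T = U[:, :n] * S[:n]
        # sign convention: largest-|loading| element of each component positive
        for j in range(n):
            i_star = int(np.argmax(np.abs(P[:, j])))
            if P[i_star, j] < 0:
                P[:, j] = -P[:, j]
                T[:, j] = -T[:, j]
        lam = T.var(axis=0, ddof=1)
        if np.any(lam <= 0):
            raise ValueError(
                "degenerate model: a retained component has zero score variance"
            )
        self.loadings_ = P
        self.cal_scores_ = T
        self.score_variances_ = lam
        self.n_components_ = n
        self.n_features_in_ = q
        self.rank_ = rank_cap
        self.axis_ = None if axis is None else np.asarray(axis, dtype=float)
        # calibration residuals/statistics, cached for empirical limits and
        # contribution limits
        self._cal_residuals_ = Z - T @ P.T
        self._cal_spex_ = np.sum(self._cal_residuals_**2, axis=1)
        self._cal_t2_ = np.sum(T**2 / lam, axis=1)
        self._cal_X_ = X
        return self

    def cross_validated_statistics(self) -> tuple[np.ndarray, np.ndarray]:
        """Leave-one-out calibration T² and SPEx.

        Each calibration sample is projected through the model refitted
        without it, giving statistic values distributed like those of
        genuinely new healthy samples.  In-sample values are biased low
        (the fitted subspace and the estimated mu/sigma absorb part of
        each sample's own noise), so empirical limits taken from them
        over-flag independent data; limits from these cross-validated
        values hold their nominal false-alarm rate.  Results are cached.
        """
        self._check_fitted()
        if hasattr(self, "_cal_loo_"):
            return self._cal_loo_
        if not hasattr(self, "_cal_X_"):
            raise RuntimeError(
                "calibration data unavailable (model restored from snapshot); "
                "refit to compute cross-validated statistics"
            )
        X = self._cal_X_
        m = X.shape[0]
        n = self.n_components_
        t2 = np.empty(m)
        spex = np.empty(m)
        mask = np.ones(m, dtype=bool)
        for i in range(m):
            mask[i] = False
            sub = X[mask]
            mu = sub.mean(axis=0)
            sigma = sub.std(axis=0, ddof=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                Z = standardize(sub, mu, sigma, self.eps)
                z = standardize(X[i], mu, sigma, self.eps)[0]
            _, S, Vt = np.linalg.svd(Z, full_matrices=False)
            k = min(n, S.size)
            P = Vt[:k].T
            lam = S[:k] ** 2 / (m - 2)
            t = z @ P
            zhat = P @ t
            t2[i] = float(np.sum(t**2 / lam))
            spex[i] = float(np.sum((z - zhat) ** 2))
            mask[i] = True
        self._cal_loo_ = (t2, spex)
        return self._cal_loo_

    @property
    def model_(self) -> PCAModel:
        self._check_fitted()
        return PCAModel(
            mu=self.mu_,
            sigma=self.sigma_,
            loadings=self.loadings_,
            score_variances=self.score_variances_,
            n_components=self.n_components_,
            cal_scores=self.cal_scores_,
            explained_fraction=self.explained_fraction_,
            axis=self.axis_,
            eps=self.eps,
        )

    @classmethod
    def from_model(cls, model: PCAModel) -> "PCAMonitor":
        est = cls(n_components=model.n_components, eps=model.eps)
        est.mu_ = np.asarray(model.mu, float)
        est.sigma_ = np.asarray(model.sigma, float)
        est.loadings_ = np.asarray(model.loadings, float)
        est.score_variances_ = np.asarray(model.score_variances, float)
        est.cal_scores_ = np.asarray(model.cal_scores, float)
        est.explained_fraction_ = np.asarray(model.explained_fraction, float)
        est.n_components_ = int(model.n_components)
        est.n_features_in_ = est.loadings_.shape[0]
        est.rank_ = min(est.cal_scores_.shape[0] - 1, est.n_features_in_)
        est.axis_ = None if model.axis is None else np.asarray(model.axis, float)
        return est

    def _check_fitted(self):
        if not hasattr(self, "loadings_"):
            raise RuntimeError("PCAMonitor is not fitted")

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, SpectraSet):
            if self.axis_ is not None and (
                X.axis.size != self.axis_.size or not np.allclose(X.axis, self.axis_)
            ):
                bad = "length mismatch" if X.axis.size != self.axis_.size else (
                    f"first differing wavenumbers "
                    f"{X.axis[~np.isclose(X.axis, self.axis_)][:5].tolist()}"
                )
                raise ValueError(f"axis mismatch with the calibration model: {bad}")
            X = X.matrix
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} wavenumbers, model expects {self.n_features_in_}"
            )
        return X

    # -- projection and statistics ----------------------------------------

    def project(self, X):
        """Scores, reconstruction and residuals: ``T, Zhat, E`` with
        ``Z = T P' + E`` in standardized units."""
        self._check_fitted()
        Z = standardize(self._as_matrix(X), self.mu_, self.sigma_, self.eps)
        T = Z @ self.loadings_
        Zhat = T @ self.loadings_.T
        return T, Zhat, Z - Zhat

    def transform(self, X):
        """Scores of X in the calibration component basis."""
        return self.project(X)[0]

    def spex(self, X) -> np.ndarray:
        """Squared prediction error per sample (row sum of squared residuals)."""
        _, _, E = self.project(X)
        return np.sum(E**2, axis=1)

    def t_squared(self, X) -> np.ndarray:
        """Hotelling's T² per sample over the retained components."""
        T, _, _ = self.project(X)
        return np.sum(T**2 / self.score_variances_, axis=1)

    def spex_is_degenerate(self, tol: float = 1e-10) -> bool:
        """True when the model retains full rank so SPEx vanishes on
        calibration data and the SPEx chart is uninformative."""
        self._check_fitted()
        return self.n_components_ >= self.rank_

    # -- contributions -----------------------------------------------------

    def spex_contributions_matrix(self, X) -> np.ndarray:
        """Per-sample, per-wavenumber SPEx contributions ``(z_i - zhat_i)^2``;
        rows sum to SPEx exactly."""
        _, _, E = self.project(X)
        return E**2

    def t2_contributions_matrix(self, X, formula: str = "as_printed") -> np.ndarray:
        """Signed per-wavenumber T² contributions.

        ``as_printed``: ``sum_j (t_j/lambda_j) p_ij (z_i - zhat_i)``.
        ``residual_free`` (common alternative in the MSPC literature):
        ``sum_j (t_j/lambda_j) p_ij z_i``, which sums to T² whenever z lies
        in the span of the loadings.
        """
        if formula not in ("as_printed", "residual_free"):
            raise ValueError(f"unknown T2 contribution formula {formula!r}")
        T, Zhat, E = self.project(X)
        W = (T / self.score_variances_) @ self.loadings_.T
        return W * E if formula == "as_printed" else W * (Zhat + E)

    def contribution_limits(self, statistic: str, level: float = 0.998,
                            formula: str = "as_printed") -> np.ndarray:
        """Per-wavenumber empirical quantile of |contribution| over the
        calibration samples; level 1 gives the observed maximum."""
        self._check_fitted()
        if not 0 < level <= 1:
            raise ValueError("level must be in (0, 1]")
        C = self._calibration_contributions(statistic, formula)
        return np.quantile(np.abs(C), level, axis=0)

    def _calibration_contributions(self, statistic: str, formula: str = "as_printed"):
        T = self.cal_scores_
        Zhat = T @ self.loadings_.T
        # residuals of the calibration data in the component complement:
        # reconstruct from stored scores; E_cal = Z_cal - Zhat needs Z_cal,
        # recovered from scores only when full rank, so cache at fit time
        if not hasattr(self, "_cal_residuals_"):
            raise RuntimeError("calibration residuals unavailable; refit the monitor")
        E = self._cal_residuals_
        if statistic == "spex":
            return E**2
        if statistic == "t2":
            W = (T / self.score_variances_) @ self.loadings_.T
            return W * E if formula == "as_printed" else W * (Zhat + E)
        raise ValueError(f"unknown statistic {statistic!r}")


# ---------------------------------------------------------------------------
# control limits


def compute_limits(
    cal_values: np.ndarray | None = None,
    level: float = 0.98,
    method: str = "empirical",
    model: PCAModel | PCAMonitor | None = None,
) -> float:
    """Control-chart limit at a confidence level.

    ``empirical``
        linearly interpolated quantile of the calibration statistic values
        (order-statistic interpolation with ``h = (n-1) p + 1``).
    ``t2_f_dist``
        parametric T² limit ``n (m-1)(m+1) / (m (m-n)) F_level(n, m-n)``.
    ``spex_chi2_moment``
        moment-matched scaled chi-square ``g chi2_h(level)`` with
        ``g = v / (2 a)``, ``h = 2 a^2 / v`` from the mean ``a`` and
        variance ``v`` of the calibration SPEx values.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if method == "empirical":
        if cal_values is None:
            raise ValueError("empirical limits need calibration statistic values")
        vals = np.asarray(cal_values, dtype=float).ravel()
        if vals.size < 20 and level >= 0.95:
            warnings.warn(
                f"only {vals.size} calibration values for an empirical "
                f"{level:.3f} limit; the estimate is unstable",
                RuntimeWarning,
                stacklevel=2,
            )
        return float(np.quantile(vals, level))
    if method == "t2_f_dist":
        if model is None:
            raise ValueError("t2_f_dist needs the fitted model (m, n)")
        mon = model if isinstance(model, PCAMonitor) else PCAMonitor.from_model(model)
        m, n = mon.cal_scores_.shape[0], mon.n_components_
        if m <= n:
            raise ValueError("t2_f_dist requires more calibration samples than components")
        f_q = scipy.stats.f.ppf(level, n, m - n)
        return float(n * (m - 1) * (m + 1) / (m * (m - n)) * f_q)
    if method == "spex_chi2_moment":
        if cal_values is None:
            raise ValueError("spex_chi2_moment needs calibration SPEx values")
        vals = np.asarray(cal_values, dtype=float).ravel()
        a = float(vals.mean())
        v = float(vals.var(ddof=1))
        if a <= 0 or v <= 0:
            raise ValueError("degenerate calibration SPEx (zero mean or variance)")
        g = v / (2 * a)
        h = 2 * a**2 / v
        return float(g * scipy.stats.chi2.ppf(level, h))
    raise ValueError(f"unknown limit method {method!r}")


# ---------------------------------------------------------------------------
# chart / report containers


@dataclass
class ControlChart:
    """Per-sample chart statistic with limits, flags and percent signalling."""

    statistic: str  # "t2" | "spex"
    values: np.ndarray
    limits: dict[float, float]
    primary_level: float
    sample_ids: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def flags(self) -> np.ndarray:
        return self.values > self.limits[self.primary_level]

    @property
    def percent_signalling(self) -> float:
        return 100.0 * float(np.count_nonzero(self.flags)) / self.values.size


@dataclass
class ContributionProfile:
    """Signed per-wavenumber contributions of one sample to one statistic,
    with calibration contribution limits and exceed directions."""

    statistic: str
    sample_id: str
    contributions: np.ndarray
    limits_abs: np.ndarray
    directions: np.ndarray  # signs used for up/down annotation

    @property
    def exceed(self) -> np.ndarray:
        out = np.full(self.contributions.size, "none", dtype=object)
        over = np.abs(self.contributions) > self.limits_abs
        out[over & (self.directions >= 0)] = "up"
        out[over & (self.directions < 0)] = "down"
        return out


@dataclass
class MonitoringReport:
    """Scenario A outcome: both charts, per-flagged-sample contribution
    profiles, and the wavenumbers exceeding contribution limits in both
    charts (annotated with their direction)."""

    t2_chart: ControlChart
    spex_chart: ControlChart
    t2_profiles: dict[str, ContributionProfile]
    spex_profiles: dict[str, ContributionProfile]
    common_peaks: list[tuple[float, str]]
    summary: dict
    axis: np.ndarray | None = None


@dataclass
class LoadingDiffReport:
    """Scenario B outcome: paired loading differences between two models
    and the difference of the group mean spectra."""

    pairs: list[tuple[int, int, float]]  # (healthy comp, polluted comp, |cos|)
    loading_diffs: list[np.ndarray]
    mean_difference: np.ndarray
    notes: list[str] = field(default_factory=list)


@dataclass
class MonitorConfig:
    """Knobs for Scenario A monitoring.

    ``primary_level`` drives the flags (the 98% limit of the narrative);
    ``report_levels`` are additionally tabulated (99.7% chart reporting,
    99.8% contribution limits by default); all configurable.

    ``limit_basis`` selects the calibration statistic values that feed the
    empirical limits: ``"cross_validated"`` (leave-one-out, default — the
    nominal false-alarm rate then holds on independent healthy data) or
    ``"in_sample"``.
    """

    n_components: int | str = "auto"
    ev_threshold: float = 0.95
    primary_level: float = 0.98
    report_levels: tuple[float, ...] = (0.997, 0.998)
    contribution_level: float = 0.998
    limit_method: str = "empirical"
    limit_basis: str = "cross_validated"
    min_fraction: float = 0.5
    t2_formula: str = "as_printed"
    eps: float = 1e-8
    min_samples: int = 10


# ---------------------------------------------------------------------------
# scenario A / B drivers


def _build_chart(
    monitor: PCAMonitor,
    statistic: str,
    values: np.ndarray,
    cal_values: np.ndarray,
    cfg: MonitorConfig,
    sample_ids: list[str],
) -> ControlChart:
    levels = sorted({cfg.primary_level, *cfg.report_levels})
    limits = {}
    for lv in levels:
        if cfg.limit_method == "empirical":
            limits[lv] = compute_limits(cal_values, lv, "empirical")
        elif statistic == "t2":
            limits[lv] = compute_limits(None, lv, "t2_f_dist", model=monitor)
        else:
            limits[lv] = compute_limits(cal_values, lv, "spex_chi2_moment")
    notes = []
    if statistic == "spex" and monitor.spex_is_degenerate():
        msg = (
            "model retains full rank: SPEx is identically zero on calibration "
            "data and the SPEx chart is uninformative"
        )
        warnings.warn(msg, RuntimeWarning, stacklevel=3)
        notes.append(msg)
    return ControlChart(statistic, values, limits, cfg.primary_level, sample_ids, notes)


def monitor_scenario_a(
    cal: SpectraSet,
    test: SpectraSet,
    cfg: MonitorConfig | None = None,
    monitor: PCAMonitor | None = None,
) -> MonitoringReport:
    """Calibrate on healthy spectra, project test spectra, build both charts.

    Contribution profiles are computed for every flagged test sample.
    ``common_peaks`` are the wavenumbers whose contributions exceed the
    calibration contribution limits in *both* charts for at least
    ``cfg.min_fraction`` of the respective flagged samples; each is
    annotated up/down by the majority contribution sign.

    Pass a prefitted ``monitor`` (on the same calibration set) to reuse its
    cached cross-validated limits across several test sets.
    """
    cfg = cfg or MonitorConfig()
    if test.n_samples < 1:
        raise ValueError("empty test set")
    if cal.axis.size != test.axis.size or not np.allclose(cal.axis, test.axis):
        raise ValueError("calibration and test sets must share the wavenumber axis")

    if monitor is None:
        monitor = PCAMonitor(cfg.n_components, cfg.ev_threshold, cfg.eps).fit(cal)
    t2_vals = monitor.t_squared(test)
    spex_vals = monitor.spex(test)
    if cfg.limit_basis == "cross_validated":
        cal_t2, cal_spex = monitor.cross_validated_statistics()
    elif cfg.limit_basis == "in_sample":
        cal_t2, cal_spex = monitor._cal_t2_, monitor._cal_spex_
    else:
        raise ValueError(f"unknown limit_basis {cfg.limit_basis!r}")
    t2_chart = _build_chart(monitor, "t2", t2_vals, cal_t2, cfg, list(test.sample_ids))
    spex_chart = _build_chart(
        monitor, "spex", spex_vals, cal_spex, cfg, list(test.sample_ids)
    )

    t2_lim = monitor.contribution_limits("t2", cfg.contribution_level, cfg.t2_formula)
    sp_lim = monitor.contribution_limits("spex", cfg.contribution_level)
    _, _, E = monitor.project(test)
    t2_C = monitor.t2_contributions_matrix(test, cfg.t2_formula)
    sp_C = E**2

    t2_profiles, spex_profiles = {}, {}
    for i, sid in enumerate(test.sample_ids):
        if t2_chart.flags[i]:
            t2_profiles[sid] = ContributionProfile("t2", sid, t2_C[i], t2_lim, np.sign(t2_C[i]))
        if spex_chart.flags[i]:
            spex_profiles[sid] = ContributionProfile("spex", sid, sp_C[i], sp_lim, np.sign(E[i]))

    common_peaks = _common_peaks(test.axis, t2_profiles, spex_profiles, cfg.min_fraction)
    summary = {
        "method": cal.modality,
        "t2_up_pct": t2_chart.percent_signalling,
        "spex_up_pct": spex_chart.percent_signalling,
        "common_peaks": [f"{wn:g} {arrow}" for wn, arrow in common_peaks],
    }
    return MonitoringReport(
        t2_chart, spex_chart, t2_profiles, spex_profiles, common_peaks, summary, test.axis
    )


def _common_peaks(axis, t2_profiles, spex_profiles, min_fraction):
    if not t2_profiles or not spex_profiles:
        return []

    def exceed_stats(profiles):
        ex = np.vstack([p.exceed != "none" for p in profiles.values()])
        sgn = np.vstack([p.directions * (p.exceed != "none") for p in profiles.values()])
        return ex.mean(axis=0), sgn.sum(axis=0)

    t2_frac, t2_sign = exceed_stats(t2_profiles)
    sp_frac, sp_sign = exceed_stats(spex_profiles)
    common = (t2_frac >= min_fraction) & (sp_frac >= min_fraction)
    peaks = []
    for i in np.nonzero(common)[0]:
        arrow = "↑" if (t2_sign[i] + sp_sign[i]) >= 0 else "↓"
        peaks.append((float(axis[i]), arrow))
    return peaks


def compare_scenario_b(
    healthy: SpectraSet, polluted: SpectraSet, cfg: MonitorConfig | None = None
) -> LoadingDiffReport:
    """Fit separate models to healthy and polluted sets and compare them.

    Components are paired by maximal absolute cosine of their loadings
    (optimal one-to-one assignment), the polluted loading is sign-aligned
    to its healthy partner, and per-pair loading differences are reported
    together with the difference of the raw group mean spectra.
    """
    cfg = cfg or MonitorConfig()
    for name, s in (("healthy", healthy), ("polluted", polluted)):
        if s.n_samples < cfg.min_samples:
            raise ValueError(
                f"{name} set has {s.n_samples} samples < min_samples="
                f"{cfg.min_samples}; loading comparison from an undersized "
                "subset is misleading — run a variographic sample-size study first"
            )
    if healthy.axis.size != polluted.axis.size or not np.allclose(healthy.axis, polluted.axis):
        raise ValueError("both sets must share the wavenumber axis")

    mh = PCAMonitor(cfg.n_components, cfg.ev_threshold, cfg.eps).fit(healthy)
    mp = PCAMonitor(cfg.n_components, cfg.ev_threshold, cfg.eps).fit(polluted)
    Ph, Pp = mh.loadings_, mp.loadings_
    cos = Ph.T @ Pp  # columns are unit vectors
    rows, cols = linear_sum_assignment(-np.abs(cos))
    pairs, diffs = [], []
    for i, j in zip(rows, cols):
        sign = 1.0 if cos[i, j] >= 0 else -1.0
        pairs.append((int(i), int(j), float(abs(cos[i, j]))))
        diffs.append(sign * Pp[:, j] - Ph[:, i])
    mean_difference = polluted.matrix.mean(axis=0) - healthy.matrix.mean(axis=0)
    notes = [
        "polluted loadings sign-aligned to their paired healthy component "
        "(largest-|loading|-positive convention applied within each model)"
    ]
    return LoadingDiffReport(pairs, diffs, mean_difference, notes)


# ---------------------------------------------------------------------------
# thin functional wrappers (formula-level surface)


def fit_pca(
    cal: SpectraSet | np.ndarray,
    n_components="auto",
    ev_threshold: float = 0.95,
    eps: float = 1e-8,
) -> PCAModel:
    """Fit the calibration model; see :class:`PCAMonitor`."""
    return PCAMonitor(n_components, ev_threshold, eps).fit(cal).model_


def project(model: PCAModel | PCAMonitor, X):
    mon = model if isinstance(model, PCAMonitor) else PCAMonitor.from_model(model)
    return mon.project(X)


def compute_spex(model: PCAModel | PCAMonitor, X) -> np.ndarray:
    mon = model if isinstance(model, PCAMonitor) else PCAMonitor.from_model(model)
    return mon.spex(X)


def compute_t2(model: PCAModel | PCAMonitor, X) -> np.ndarray:
    mon = model if isinstance(model, PCAMonitor) else PCAMonitor.from_model(model)
    return mon.t_squared(X)


def spex_contributions(model: PCAModel | PCAMonitor, x, sample_id: str = "") -> ContributionProfile:
    mon = model if isinstance(model, PCAMonitor) else PCAMonitor.from_model(model)
    x = np.atleast_2d(np.asarray(x, float))
    _, _, E = mon.project(x)
    contrib = (E**2)[0]
    try:
        lim = mon.contribution_limits("spex")
    except RuntimeError:
        lim = np.full(contrib.size, np.inf)
    return ContributionProfile("spex", sample_id, contrib, lim, np.sign(E[0]))


def t2_contributions(
    model: PCAModel | PCAMonitor, x, formula: str = "as_printed", sample_id: str = ""
) -> ContributionProfile:
    mon = model if isinstance(model, PCAMonitor) else PCAMonitor.from_model(model)
    x = np.atleast_2d(np.asarray(x, float))
    C = mon.t2_contributions_matrix(x, formula)[0]
    try:
        lim = mon.contribution_limits("t2", formula=formula)
    except RuntimeError:
        lim = np.full(C.size, np.inf)
    return ContributionProfile("t2", sample_id, C, lim, np.sign(C))


def contribution_limits(
    model: PCAModel | PCAMonitor,
    cal: SpectraSet | np.ndarray | None = None,
    statistic: str = "spex",
    level: float = 0.998,
    formula: str = "as_printed",
) -> np.ndarray:
    """Per-wavenumber |contribution| quantile over the calibration set."""
    mon = model if isinstance(model, PCAMonitor) else PCAMonitor.from_model(model)
    if cal is not None and not hasattr(mon, "_cal_residuals_"):
        Xc = cal.matrix if isinstance(cal, SpectraSet) else np.asarray(cal, float)
        Z = standardize(Xc, mon.mu_, mon.sigma_, mon.eps)
        mon._cal_residuals_ = Z - (Z @ mon.loadings_) @ mon.loadings_.T
        mon.cal_scores_ = Z @ mon.loadings_
    return mon.contribution_limits(statistic, level, formula)
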