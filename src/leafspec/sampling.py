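"""Variographic sample-size design for healthy-plant model calibration.

A leaf surface is heterogeneous (age, position on the leaf, stem vs
extremity), so the calibration set must contain enough random samples to
represent that systematic variation.  Two complementary tools judge when
enough samples have been taken:

* :func:`variation_vs_n` — total variance of random size-``n`` subsets,
  raw and after reconstruction with the retained principal components.
  The raw curve rises continuously as samples are added; the reconstructed
  curve (which the PCA model keeps, noise excluded) levels off once the
  subsets cover all systematic variation.
* :func:`variogram_scores` — semivariance of PCA score vectors against
  acquisition-order lag; a flat variogram indicates no residual
  sample-to-sample drift.

:func:`recommend_n` turns the reconstructed-variance curve into a sample
count via a plateau rule: the smallest ``n`` after which the curve grows by
less than a relative threshold over a look-ahead window.

Variance convention: subsets are standardized internally (ddof=1 sigma)
and the "total variance" is the mean squared deviation (denominator ``n``).
Under this convention the raw curve is q(n-1)/n in expectation — rising
continuously and saturating — while the reconstructed curve additionally
tracks how much systematic structure the subset exposes to the retained
components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import SpectraSet
from .mspc import PCAMonitor, standardize

__all__ = [
    "VariationCurve",
    "VariogramResult",
    "SampleSizeRecommendation",
    "variation_vs_n",
    "variogram_scores",
    "recommend_n",
]


@dataclass
class VariationCurve:
    """Repeat-averaged total variance of random subsets vs subset size."""

    n_values: np.ndarray
    var_raw: np.ndarray
    var_reconstructed: np.ndarray
    repeats: int
    seed: int
    n_components: int


@dataclass
class VariogramResult:
    """Semivariance of PCA score vectors per acquisition-order lag."""

    lags: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray
    n_components: int


@dataclass
class SampleSizeRecommendation:
    n_required: int
    window: int
    tau: float
    converged: bool
    curve: VariationCurve


def variation_vs_n(
    sset: SpectraSet,
    n_components: int = 3,
    repeats: int = 20,
    seed: int = 0,
    n_min: int | None = None,
    eps: float = 1e-8,
) -> VariationCurve:
    """Total variance of random subsets, raw and PCA-reconstructed.

    For each subset size ``n`` (``n_min`` .. ``m``), draws ``repeats``
    seeded random subsets without replacement, standardizes each within the
    subset, and averages over repeats the total variance (sum of
    per-wavenumber mean squared deviations) of the standardized subset and
    of its ``n_components``-component reconstruction.

    ``n_min`` defaults to ``max(3, n_components + 1)`` — a PCA with ``k``
    components needs more than ``k`` samples.
    """
    m = sset.n_samples
    if m < 5:
        raise ValueError("variation_vs_n needs at least 5 samples")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if n_min is None:
        n_min = max(3, n_components + 1)
    if n_components >= n_min:
        raise ValueError(
            f"n_components={n_components} must be smaller than the smallest "
            f"subset size {n_min}"
        )
    if n_min > m:
        raise ValueError("smallest subset size exceeds the number of samples")

    rng = np.random.default_rng(seed)
    X = sset.matrix
    ns = np.arange(n_min, m + 1)
    var_raw = np.zeros(ns.size)
    var_rec = np.zeros(ns.size)
    for k, n in enumerate(ns):
        raw_acc = rec_acc = 0.0
        for _ in range(repeats):
            rows = rng.choice(m, size=n, replace=False)
            sub = X[rows]
            mu = sub.mean(axis=0)
            sigma = sub.std(axis=0, ddof=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                Z = standardize(sub, mu, sigma, eps)
            raw_acc += float(np.sum(Z.var(axis=0, ddof=0)))
            U, S, Vt = np.linalg.svd(Z, full_matrices=False)
            Zhat = (U[:, :n_components] * S[:n_components]) @ Vt[:n_components]
            rec_acc += float(np.sum(Zhat.var(axis=0, ddof=0)))
        var_raw[k] = raw_acc / repeats
        var_rec[k] = rec_acc / repeats
    return VariationCurve(ns, var_raw, var_rec, repeats, seed, n_components)


def variogram_scores(
    sset: SpectraSet, n_components: int = 3, max_lag: int | None = None
) -> VariogramResult:
    """Semivariance of PCA scores over acquisition-order lags.

    The full set is decomposed with ``n_components`` components; samples
    are ordered by ``acquisition_index`` and

        gamma(h) = 1 / (2 (m - h)) * sum_i ||t_{i+h} - t_i||^2

    is computed for integer lags ``h = 1 .. max_lag``.  For serially
    uncorrelated score vectors the variogram is flat at the total score
    variance; a rising variogram reveals drift along the acquisition order.
    """
    m = sset.n_samples
    if max_lag is None:
        max_lag = m - 1
    if not 1 <= max_lag < m:
        raise ValueError("require 1 <= max_lag < number of samples")
    order = np.argsort([meta.acquisition_index for meta in sset.metas])
    if np.allclose(sset.matrix.std(axis=0), 0.0):
        # identical samples: no variation, flat zero variogram
        lags = np.arange(1, max_lag + 1)
        return VariogramResult(lags, np.zeros(lags.size), m - lags, n_components)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        monitor = PCAMonitor(n_components=n_components).fit(sset.matrix)
    T = monitor.cal_scores_[order]
    lags = np.arange(1, max_lag + 1)
    gamma = np.empty(lags.size)
    counts = np.empty(lags.size, dtype=int)
    for k, h in enumerate(lags):
        d = T[h:] - T[:-h]
        counts[k] = m - h
        gamma[k] = np.sum(d**2) / (2.0 * (m - h))
    return VariogramResult(lags, gamma, counts, n_components)


def recommend_n(curve: VariationCurve, w: int = 5, tau: float = 0.02) -> SampleSizeRecommendation:
    """Plateau rule on the reconstructed-variance curve.

    Returns the smallest ``n`` such that every point in the look-ahead
    window ``(n, n + w]`` exceeds ``var_reconstructed(n)`` by a relative
    amount below ``tau``.  If no point satisfies the rule the largest
    ``n`` is returned with a not-converged warning.
    """
    if w < 2:
        raise ValueError("window w must be >= 2")
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    ns = np.asarray(curve.n_values)
    v = np.asarray(curve.var_reconstructed, dtype=float)
    if ns.size < w + 3:
        raise ValueError(f"curve has {ns.size} points; need at least w + 3 = {w + 3}")
    for k in range(ns.size - w):
        ref = v[k]
        if ref <= 0:
            # degenerate (no variation at all): any n suffices
            return SampleSizeRecommendation(int(ns[k]), w, tau, True, curve)
        if np.all(v[k + 1 : k + w + 1] / ref - 1.0 < tau):
            return SampleSizeRecommendation(int(ns[k]), w, tau, True, curve)
    warnings.warn(
        "variation curve did not plateau within the sampled range; "
        "returning the largest subset size",
        RuntimeWarning,
        stacklevel=2,
    )
    return SampleSizeRecommendation(int(ns[-1]), w, tau, False, curve)
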