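"""Spectral pretreatment: baseline correction, smoothing, normalization,
region-of-interest cropping and reflectance-to-absorbance conversion.

Raw handheld Raman and FTIR spectra carry slowly varying backgrounds
(fluorescence, scattering), fine noise, and instrument-dependent global
scale.  Pretreatment removes these before multivariate modelling so that
the PCA model captures plant chemistry rather than acquisition artifacts.

Each operation exists in two forms: a per-:class:`~leafspec.io.Spectrum`
function (the primitive) and a scikit-learn transformer over sample x
wavenumber matrices, so pipelines compose with ``sklearn.pipeline``.
`run_pretreatment` applies a configured step sequence to a whole
:class:`~leafspec.io.SpectraSet` and returns a provenance log.

Default step orders per modality follow the workflows the instruments
require:

* ``raman``: baseline_polyfit -> normalize -> savgol -> crop_roi
* ``ftir_dried``: crop_roi -> flip_absorbance -> savgol -> normalize
* ``ftir_alive``: savgol -> normalize
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from sklearn.base import BaseEstimator, TransformerMixin

from .io import SampleMeta, Spectrum, SpectraSet

__all__ = [
    "BaselineResult",
    "PretreatConfig",
    "baseline_polyfit",
    "baseline_iter_avg",
    "savgol",
    "normalize",
    "crop_roi",
    "flip_absorbance",
    "run_pretreatment",
    "default_config",
    "SpectralPretreater",
]

STEP_NAMES = (
    "baseline_polyfit",
    "baseline_iter_avg",
    "savgol",
    "normalize",
    "crop_roi",
    "flip_absorbance",
)

#: default step sequences per modality
DEFAULT_STEPS = {
    "raman": [
        ("baseline_polyfit", {"order": 5}),
        ("normalize", {}),
        ("savgol", {}),
        ("crop_roi", {"lo": 650.0, "hi": 1800.0}),
    ],
    "ftir_dried": [
        ("crop_roi", {"lo": 650.0, "hi": 1800.0}),
        ("flip_absorbance", {}),
        ("savgol", {}),
        ("normalize", {}),
    ],
    "ftir_alive": [
        ("savgol", {}),
        ("normalize", {}),
    ],
}


@dataclass
class BaselineResult:
    """Outcome of a baseline-correction pass.

    ``corrected.values + baseline`` reconstructs the input exactly (float
    tolerance) — the estimate is always reported additively.
    """

    corrected: Spectrum
    baseline: np.ndarray
    iterations: int
    converged: bool


@dataclass
class PretreatConfig:
    """Ordered pretreatment step list with per-step parameters."""

    steps: list[tuple[str, dict]] = field(default_factory=list)

    def validate(self, modality: str) -> None:
        names = [n for n, _ in self.steps]
        for n in names:
            if n not in STEP_NAMES:
                raise ValueError(f"unknown pretreatment step {n!r}")
        if names.count("crop_roi") > 1:
            raise ValueError("crop_roi may appear at most once")
        for n, params in self.steps:
            if (
                n == "flip_absorbance"
                and modality != "ftir_dried"
                and not params.get("allow_any_modality", False)
            ):
                raise ValueError(
                    "flip_absorbance is a reflectance->absorbance step for "
                    "ftir_dried spectra; pass allow_any_modality=True to override"
                )


def default_config(modality: str) -> PretreatConfig:
    """The per-modality default step order."""
    if modality not in DEFAULT_STEPS:
        raise ValueError(f"no default pretreatment for modality {modality!r}")
    return PretreatConfig([(n, dict(p)) for n, p in DEFAULT_STEPS[modality]])


# ---------------------------------------------------------------------------
# baseline correction


def baseline_polyfit(
    s: Spectrum, order: int = 5, max_iter: int = 100, tol: float = 1e-4
) -> BaselineResult:
    """Iterative clipped polynomial baseline (modified polyfit).

    Fits an order-``order`` polynomial to the working values by least
    squares, replaces working values lying above the fit with the fit, and
    repeats until the fitted baseline moves by less than ``tol`` times the
    input value range, or ``max_iter`` refits have run after the initial
    fit.  Peaks (which stick out above any smooth background) are thereby
    progressively excluded from the fit while the background is kept.

    With ``max_iter=0`` the baseline is the plain least-squares fit.
    """
    if not 0 <= order <= 9:
        raise ValueError("order must be in [0, 9]")
    if s.axis.size <= order + 1:
        raise ValueError("axis length must exceed order + 1")
    if max_iter < 0:
        raise ValueError("max_iter must be >= 0")

    x = s.axis
    # scale abscissa to [-1, 1] for conditioning
    xs = 2.0 * (x - x[0]) / max(x[-1] - x[0], np.finfo(float).tiny) - 1.0
    vrange = float(np.ptp(s.values))
    if vrange == 0.0:
        vrange = 1.0
    work = s.values.copy()
    fit = np.polynomial.polynomial.polyval(
        xs, np.polynomial.polynomial.polyfit(xs, work, order)
    )
    iterations = 1
    converged = False
    for _ in range(max_iter):
        work = np.minimum(work, fit)
        new_fit = np.polynomial.polynomial.polyval(
            xs, np.polynomial.polynomial.polyfit(xs, work, order)
        )
        iterations += 1
        delta = float(np.max(np.abs(new_fit - fit)))
        fit = new_fit
        if delta < tol * vrange:
            converged = True
            break
    return BaselineResult(s.replace_values(s.values - fit), fit, iterations, converged)


def baseline_iter_avg(
    s: Spectrum, half_window: int = 10, max_iter: int = 50
) -> BaselineResult:
    """Iterative minimum-suppression moving-average baseline.

    Each pass replaces every working value by the minimum of itself and the
    centered moving average over ``2*half_window + 1`` points (truncated at
    the edges).  Peaks are eroded pass by pass while flat background is a
    fixed point; the final working vector is the baseline, so the corrected
    spectrum is non-negative up to float tolerance.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if half_window >= s.axis.size:
        raise ValueError("half_window must be smaller than the axis length")

    n = s.axis.size
    work = s.values.copy()
    # truncated-window average via cumulative sums of values and counts
    kernel = np.ones(2 * half_window + 1)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    iterations = 0
    converged = False
    for _ in range(max_iter):
        avg = np.convolve(work, kernel, mode="same") / counts
        new = np.minimum(work, avg)
        iterations += 1
        if np.max(np.abs(new - work)) <= 1e-12:
            work = new
            converged = True
            break
        work = new
    return BaselineResult(s.replace_values(s.values - work), work, iterations, converged)


# ---------------------------------------------------------------------------
# smoothing


def _axis_is_uniform(axis: np.ndarray, rtol: float = 1e-6) -> bool:
    if axis.size < 3:
        return True
    d = np.diff(axis)
    return bool(np.all(np.abs(d - d[0]) <= rtol * np.abs(d[0])))


def savgol(s: Spectrum, window: int = 11, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing with truncated one-sided edge windows.

    Interior points use the standard centered local polynomial fit; points
    within ``window//2`` of either end are refit on the window truncated to
    the available points (no padding), which avoids reflection artifacts at
    region-of-interest boundaries.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if polyorder < 0 or polyorder >= window:
        raise ValueError("require 0 <= polyorder < window")
    if window > s.axis.size:
        raise ValueError("window exceeds the axis length")
    if not _axis_is_uniform(s.axis):
        raise ValueError(
            "savgol requires a uniformly spaced axis; run harmonize_axis first"
        )
    half = window // 2
    out = scipy.signal.savgol_filter(s.values, window, polyorder, mode="interp")
    # truncated one-sided refit at the edges
    n = s.values.size
    for i in range(half):
        sl = slice(0, i + half + 1)
        c = np.polynomial.polynomial.polyfit(s.axis[sl], s.values[sl], polyorder)
        out[i] = np.polynomial.polynomial.polyval(s.axis[i], c)
    for i in range(n - half, n):
        sl = slice(i - half, n)
        c = np.polynomial.polynomial.polyfit(s.axis[sl], s.values[sl], polyorder)
        out[i] = np.polynomial.polynomial.polyval(s.axis[i], c)
    return s.replace_values(out)


# ---------------------------------------------------------------------------
# normalization / cropping / absorbance


def normalize(s: Spectrum, method: str = "unit_length") -> Spectrum:
    """Scale a spectrum to remove instrument-dependent global intensity.

    ``unit_length`` divides by the Euclidean norm, ``max_one`` by the
    maximum, ``area_one`` by the trapezoidal integral over the axis.  All
    three are idempotent.
    """
    v = s.values
    if np.allclose(v, 0.0):
        raise ValueError("cannot normalize an all-zero spectrum")
    if method == "unit_length":
        scale = float(np.linalg.norm(v))
    elif method == "max_one":
        scale = float(np.max(v))
    elif method == "area_one":
        scale = float(np.trapezoid(v, s.axis))
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if scale == 0.0:
        raise ValueError(f"degenerate {method} scale (zero)")
    return s.replace_values(v / scale)


def crop_roi(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep the closed wavenumber interval [lo, hi]."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    mask = (s.axis >= lo) & (s.axis <= hi)
    if not mask.any():
        raise ValueError(
            f"ROI [{lo}, {hi}] does not overlap axis [{s.axis[0]}, {s.axis[-1]}]"
        )
    return Spectrum(s.axis[mask].copy(), s.values[mask].copy(), s.modality, s.meta)


def flip_absorbance(s: Spectrum, method: str = "affine_flip") -> Spectrum:
    """Convert reflectance-shaped spectra to absorbance-shaped ones.

    ``affine_flip`` reflects about the maximum (``max(v) - v``), preserving
    peak shapes with no positivity requirement; ``log_inverse`` is the
    physical absorbance ``log10(1/R)`` and requires strictly positive input.
    """
    v = s.values
    if method == "affine_flip":
        return s.replace_values(np.max(v) - v)
    if method == "log_inverse":
        if np.any(v <= 0):
            raise ValueError("log_inverse requires strictly positive reflectance")
        return s.replace_values(np.log10(1.0 / v))
    raise ValueError(f"unknown flip method {method!r}")


# ---------------------------------------------------------------------------
# pipeline

_STEP_FUNCS = {
    "baseline_polyfit": lambda sp, **p: baseline_polyfit(sp, **p).corrected,
    "baseline_iter_avg": lambda sp, **p: baseline_iter_avg(sp, **p).corrected,
    "savgol": savgol,
    "normalize": normalize,
    "crop_roi": crop_roi,
    "flip_absorbance": flip_absorbance,
}


def _strip_internal(params: dict) -> dict:
    return {k: v for k, v in params.items() if k != "allow_any_modality"}


def run_pretreatment(
    sset: SpectraSet, cfg: PretreatConfig | None = None
) -> tuple[SpectraSet, list[dict]]:
    """Apply a configured step sequence to every spectrum of a set.

    Returns the treated set and a provenance log: one record per step with
    the step name, parameters, and post-step summary statistics (axis
    length, mean/min/max intensity).  Deterministic: every step is a pure
    function of its input.
    """
    if cfg is None:
        cfg = default_config(sset.modality)
    cfg.validate(sset.modality)

    spectra = list(sset.spectra())
    log: list[dict] = []
    for name, params in cfg.steps:
        func = _STEP_FUNCS[name]
        call_params = _strip_internal(params)
        out = []
        for sp in spectra:
            try:
                out.append(func(sp, **call_params))
            except Exception as exc:
                raise RuntimeError(
                    f"pretreatment step {name!r} failed on sample "
                    f"acquisition_index={sp.meta.acquisition_index}: {exc}"
                ) from exc
        spectra = out
        stacked = np.vstack([sp.values for sp in spectra])
        log.append(
            {
                "step": name,
                "params": dict(call_params),
                "n_wavenumbers": int(spectra[0].axis.size),
                "mean": float(stacked.mean()),
                "min": float(stacked.min()),
                "max": float(stacked.max()),
            }
        )
    out_set = SpectraSet(
        spectra[0].axis.copy(),
        np.vstack([sp.values for sp in spectra]),
        list(sset.metas),
        sset.modality,
        list(sset.sample_ids),
    )
    return out_set, log


class SpectralPretreater(BaseEstimator, TransformerMixin):
    """scikit-learn transformer wrapping :func:`run_pretreatment`.

    Operates on sample x wavenumber matrices given a fixed wavenumber
    ``axis``; stateless (``fit`` only validates), so it can sit at the head
    of an ``sklearn.pipeline.Pipeline`` in front of the PCA monitor.
    """

    def __init__(self, axis=None, modality: str = "raman", steps=None):
        self.axis = axis
        self.modality = modality
        self.steps = steps

    def _config(self) -> PretreatConfig:
        if self.steps is None:
            return default_config(self.modality)
        return PretreatConfig([(n, dict(p)) for n, p in self.steps])

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x wavenumbers)")
        if self.axis is None:
            raise ValueError("SpectralPretreater requires the wavenumber axis")
        self._config().validate(self.modality)
        self.n_features_in_ = X.shape[1]
        out = self.transform(X)
        self.axis_out_ = self._last_axis_
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        if X.shape[1] != axis.size:
            raise ValueError("X column count does not match axis length")
        # placeholder metadata: plain-array transformer input carries none
        metas = [SampleMeta(acquisition_index=i) for i in range(X.shape[0])]
        sset = SpectraSet(axis, X, metas, self.modality)
        out, _ = run_pretreatment(sset, self._config())
        self._last_axis_ = out.axis
        return out.matrix
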