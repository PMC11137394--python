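"""Seeded synthetic data with the statistical structure the analysis assumes.

The healthy-leaf generator emulates what vibrational spectra of a healthy
plant look like to the chemometrics layer: a handful of Gaussian peaks
whose amplitudes co-vary through a small number of latent factors (leaf
age, acquisition point), a slowly varying per-spectrum polynomial baseline,
and white noise.  Sample ``i`` draws latent factors ``s`` and builds

    amplitude_k = base_k * (1 + sum_f L[k, f] * s_f)
    spectrum    = sum_k amplitude_k * exp(-(x - center_k)^2 / (2 width_k^2))
                  + baseline(x) + noise

Pollutant stress is injected as one of three effect classes:

``mean_shift``
    a peak appears, grows or shrinks on average (base amplitude offset);
``modelled_change``
    an existing covariation changes its proportionality (the factor
    loadings of the target peak are rescaled — e.g. a peak that used to
    drop two units per unit rise of its partner now drops three);
``new_variation``
    a previously inert peak starts co-varying with an active peak through
    a fresh latent factor.

The first class moves the mean, the second perturbs the *modelled*
correlation structure (a T²-chart signature), the third creates variation
outside the healthy model (an SPEx-chart signature).

Also here: synthetic leaf photographs with an in-frame reference chart,
the solution-molarity worked example, and detection scoring of a
monitoring report against the injected ground truth.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .color import (
    COLORCHECKER_SRGB,
    ColorCheckerLayout,
    grid_layout,
    linear_to_srgb,
    srgb_to_linear,
)
from .io import SampleMeta, SpectraSet
from .mspc import MonitoringReport

__all__ = [
    "Peak",
    "SyntheticSpectraSpec",
    "PollutionEffect",
    "SolutionSpec",
    "SyntheticGroundTruth",
    "LeafImageTruth",
    "default_spec",
    "saturating_spec",
    "generate_healthy",
    "apply_pollution",
    "generate_leaf_image",
    "solution_molarity",
    "detection_score",
    "analytic_covariance",
]


@dataclass(frozen=True)
class Peak:
    """Gaussian spectral band: center and width in cm^-1, unit-height base
    amplitude in intensity units."""

    center: float
    width: float
    base_amplitude: float


@dataclass
class SyntheticSpectraSpec:
    """Generator parameters for healthy-leaf spectra.

    ``factor_loadings`` is peaks x n_factors; ``factor_states`` optionally
    fixes the latent factors to a finite set of archetype vectors cycled
    over samples (used by sample-size saturation studies) instead of
    standard-normal draws.
    """

    axis_lo: float = 650.0
    axis_hi: float = 1800.0
    axis_step: float = 2.0
    peaks: list[Peak] = field(default_factory=list)
    n_factors: int = 2
    factor_loadings: np.ndarray | None = None
    baseline_order: int = 2
    baseline_coeff_sd: float = 0.05
    noise_sd: float = 0.02
    seed: int = 0
    factor_states: np.ndarray | None = None
    modality: str = "ftir_alive"

    def __post_init__(self) -> None:
        if self.axis_step <= 0 or self.axis_hi <= self.axis_lo:
            raise ValueError("invalid axis specification")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.factor_loadings is not None:
            self.factor_loadings = np.asarray(self.factor_loadings, dtype=float)
            if self.factor_loadings.shape != (len(self.peaks), self.n_factors):
                raise ValueError("factor_loadings must be n_peaks x n_factors")
        elif self.n_factors > 0 and self.peaks:
            raise ValueError("factor_loadings required when n_factors > 0")
        for p in self.peaks:
            if not self.axis_lo <= p.center <= self.axis_hi:
                raise ValueError(f"peak center {p.center} outside the axis range")
            if p.width <= 0:
                raise ValueError("peak widths must be positive")
        if self.factor_states is not None:
            self.factor_states = np.asarray(self.factor_states, dtype=float)
            if self.factor_states.ndim != 2 or self.factor_states.shape[1] != self.n_factors:
                raise ValueError("factor_states must be n_states x n_factors")

    @property
    def axis(self) -> np.ndarray:
        n = int(round((self.axis_hi - self.axis_lo) / self.axis_step)) + 1
        return self.axis_lo + self.axis_step * np.arange(n)

    def digest(self) -> str:
        h = hashlib.sha1()
        h.update(repr(self).encode())
        return h.hexdigest()[:12]


@dataclass
class PollutionEffect:
    """One injected pollutant effect; see the module docstring for the
    three classes."""

    kind: str  # mean_shift | modelled_change | new_variation
    target_wavenumbers: list[float]
    magnitude: float
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("mean_shift", "modelled_change", "new_variation"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if not self.target_wavenumbers:
            raise ValueError("effect needs at least one target wavenumber")


@dataclass
class SyntheticGroundTruth:
    """Record of what was injected, for scoring detection afterwards."""

    effects: list[PollutionEffect]
    group_labels: list[str]
    spec_digest: str
    seed: int
    axis: np.ndarray | None = None


# ---------------------------------------------------------------------------
# canonical specs


def default_spec(seed: int = 0, noise_sd: float = 0.02) -> SyntheticSpectraSpec:
    """The canonical demo generator.

    Peaks sit at the wavenumbers of the monitoring narrative: 1580 and
    1000 cm^-1 co-vary on factor 0 with a -2 proportionality (one unit up
    at 1580, two units down at 1000); 1170 and 1740 cm^-1 ride factor 1;
    1300 cm^-1 is inert (present but uncorrelated with everything) so a
    ``new_variation`` effect can target it.
    """
    peaks = [
        Peak(700.0, 14.0, 0.9),
        Peak(850.0, 12.0, 1.1),
        Peak(1000.0, 12.0, 1.5),
        Peak(1170.0, 12.0, 1.2),
        Peak(1300.0, 12.0, 0.8),
        Peak(1450.0, 16.0, 1.0),
        Peak(1580.0, 12.0, 1.0),
        Peak(1740.0, 12.0, 1.0),
    ]
    # factor 0: 1580 up one unit -> 1000 down two units
    # factor 1: 1170 / 1740 / 850 covariation
    # factors 2-5: small *individual* variability of the 1000, 1170, 1580
    # and 1740 bands.  The individual modes matter: they put the coordinate
    # direction of each major band inside the healthy model span, so a
    # changed proportionality between modelled bands (a ``modelled_change``
    # effect) inflates scores (T2) instead of residuals (SPEx).  1300 stays
    # fully inert so a ``new_variation`` effect can target it.
    L = np.zeros((len(peaks), 6))
    L[6, 0] = 0.15          # 1580: d(height)/ds = 1.0 * 0.15
    L[2, 0] = -0.20         # 1000: 1.5 * (-0.20) = -0.30 = -2 x 0.15
    L[0, 0] = 0.08
    L[3, 1] = 0.18
    L[7, 1] = 0.12
    L[1, 1] = -0.10
    L[5, 1] = 0.06
    L[2, 2] = 0.08          # individual modes
    L[3, 3] = 0.08
    L[6, 4] = 0.08
    L[7, 5] = 0.08
    return SyntheticSpectraSpec(
        peaks=peaks, n_factors=6, factor_loadings=L, noise_sd=noise_sd, seed=seed
    )


def saturating_spec(n_states: int = 15, seed: int = 7) -> SyntheticSpectraSpec:
    """Generator whose systematic variation saturates once all latent
    archetypes are represented.

    ``n_states`` fixed archetype vectors in a 3-factor latent space drive
    densely overlapping peaks (every wavenumber is factor-driven), with
    near-zero noise and no random baseline, so the subset variation curve
    levels off when the archetype set is covered.
    """
    rng = np.random.default_rng(seed)
    centers = np.arange(700.0, 1800.0, 80.0)
    peaks = [Peak(c, 40.0, 1.0) for c in centers]
    L = rng.normal(0.0, 0.12, size=(len(peaks), 3))
    states = rng.normal(0.0, 1.0, size=(n_states, 3))
    states -= states.mean(axis=0)
    return SyntheticSpectraSpec(
        axis_lo=650.0,
        axis_hi=1800.0,
        axis_step=8.0,
        peaks=peaks,
        n_factors=3,
        factor_loadings=L,
        baseline_order=0,
        baseline_coeff_sd=0.0,
        noise_sd=0.004,
        seed=seed,
        factor_states=states,
    )


# ---------------------------------------------------------------------------
# spectra generation


def _peak_matrix(spec: SyntheticSpectraSpec) -> np.ndarray:
    """q x n_peaks matrix of unit-height Gaussian profiles."""
    x = spec.axis
    return np.column_stack(
        [np.exp(-((x - p.center) ** 2) / (2.0 * p.width**2)) for p in spec.peaks]
    )


def _generate(
    spec: SyntheticSpectraSpec, n: int, seed: int | None, label: str,
    effects: list[PollutionEffect],
) -> tuple[SpectraSet, SyntheticGroundTruth]:
    if n < 1:
        raise ValueError("n must be >= 1")
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    x = spec.axis
    q = x.size
    G = _peak_matrix(spec)
    base = np.array([p.base_amplitude for p in spec.peaks])
    F = spec.n_factors

    if F > 0:
        if spec.factor_states is not None:
            idx = np.arange(n) % spec.factor_states.shape[0]
            s = spec.factor_states[idx]
        else:
            s = rng.standard_normal((n, F))
        amps = base * (1.0 + s @ spec.factor_loadings.T)
    else:
        amps = np.tile(base, (n, 1))

    n_clipped = int(np.count_nonzero(amps < 0))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} negative peak amplitude(s) clipped at 0",
            RuntimeWarning,
        )
        amps = np.maximum(amps, 0.0)

    M = amps @ G.T  # n x q systematic part

    if spec.baseline_coeff_sd > 0:
        u = (x - x[0]) / (x[-1] - x[0])
        powers = np.vstack([u**p for p in range(spec.baseline_order + 1)])
        coeffs = rng.normal(0.0, spec.baseline_coeff_sd, size=(n, spec.baseline_order + 1))
        M = M + coeffs @ powers

    if spec.noise_sd > 0:
        M = M + rng.normal(0.0, spec.noise_sd, size=(n, q))

    metas = [
        SampleMeta(
            treatment="control" if label == "healthy" else "other",
            acquisition_index=i,
        )
        for i in range(n)
    ]
    ids = [f"{label[:4]}{i}" for i in range(n)]
    sset = SpectraSet(x, M, metas, spec.modality, ids)
    truth = SyntheticGroundTruth(
        effects=list(effects),
        group_labels=[label] * n,
        spec_digest=spec.digest(),
        seed=seed,
        axis=x,
    )
    return sset, truth


def generate_healthy(
    spec: SyntheticSpectraSpec, n: int, seed: int | None = None
) -> tuple[SpectraSet, SyntheticGroundTruth]:
    """Draw ``n`` healthy-leaf spectra from the generator (seeded,
    bit-reproducible)."""
    return _generate(spec, n, seed, "healthy", [])


def _nearest_peak(spec: SyntheticSpectraSpec, wn: float) -> int:
    centers = np.array([p.center for p in spec.peaks])
    k = int(np.argmin(np.abs(centers - wn)))
    if abs(centers[k] - wn) > 1e-6:
        raise ValueError(
            f"effect target {wn} cm^-1 does not name a generator peak "
            f"(nearest: {centers[k]})"
        )
    return k


def apply_pollution(
    spec: SyntheticSpectraSpec,
    effects: list[PollutionEffect],
    n: int,
    seed: int | None = None,
) -> tuple[SpectraSet, SyntheticGroundTruth]:
    """Generate ``n`` polluted spectra by injecting the listed effects.

    With an empty effect list the output is bit-identical to
    :func:`generate_healthy` at the same seed.  ``new_variation`` couples
    the target (validated to be inert in the healthy model) to the most
    strongly loaded existing peak through an appended latent factor with
    the given weight on both peaks.
    """
    base_L = (
        spec.factor_loadings.copy()
        if spec.factor_loadings is not None
        else np.zeros((len(spec.peaks), 0))
    )
    L = base_L.copy()
    peaks = list(spec.peaks)
    row_norm = np.linalg.norm(base_L, axis=1) if base_L.size else np.zeros(len(peaks))
    new_cols: list[np.ndarray] = []

    for eff in effects:
        targets = [_nearest_peak(spec, wn) for wn in eff.target_wavenumbers]
        if eff.kind == "mean_shift":
            for k in targets:
                peaks[k] = replace(peaks[k], base_amplitude=peaks[k].base_amplitude + eff.magnitude)
        elif eff.kind == "modelled_change":
            for k in targets:
                L[k, :] = L[k, :] * eff.magnitude
        else:  # new_variation
            strong = float(row_norm.max()) if row_norm.size else 0.0
            partner = int(np.argmax(row_norm)) if row_norm.size else None
            for k in targets:
                if strong > 0 and row_norm[k] > 0.2 * strong:
                    raise ValueError(
                        f"new_variation target {spec.peaks[k].center} cm^-1 is "
                        "already strongly loaded in the healthy model"
                    )
                col = np.zeros(len(peaks))
                col[k] = eff.magnitude
                if partner is not None and partner != k:
                    col[partner] = eff.magnitude
                new_cols.append(col)

    if new_cols:
        L = np.hstack([L] + [c[:, None] for c in new_cols])
    polluted = replace(
        spec,
        peaks=peaks,
        factor_loadings=L if L.size else None,
        n_factors=L.shape[1] if L.size else 0,
        factor_states=(
            None
            if spec.factor_states is None or not new_cols
            else np.hstack(
                [spec.factor_states, np.zeros((spec.factor_states.shape[0], len(new_cols)))]
            )
        ),
    )
    label = "polluted" if effects else "healthy"
    return _generate(polluted, n, seed if seed is not None else spec.seed, label, effects)


def analytic_covariance(spec: SyntheticSpectraSpec) -> np.ndarray:
    """Population column covariance implied by peaks, loadings, baseline
    and noise (standard-normal factors)."""
    G = _peak_matrix(spec)
    base = np.array([p.base_amplitude for p in spec.peaks])
    cov = np.zeros((spec.axis.size, spec.axis.size))
    if spec.n_factors > 0 and spec.factor_loadings is not None:
        A = G @ (base[:, None] * spec.factor_loadings)  # q x F
        cov += A @ A.T
    if spec.baseline_coeff_sd > 0:
        x = spec.axis
        u = (x - x[0]) / (x[-1] - x[0])
        V = np.vstack([u**p for p in range(spec.baseline_order + 1)]).T
        cov += spec.baseline_coeff_sd**2 * (V @ V.T)
    cov += spec.noise_sd**2 * np.eye(spec.axis.size)
    return cov


# ---------------------------------------------------------------------------
# leaf images


@dataclass
class LeafImageTruth:
    """Ground truth of a rendered leaf photograph."""

    leaf_centers: list[tuple[int, int]]  # (y, x)
    leaf_radii: list[tuple[int, int]]  # (ry, rx)
    spotted: list[bool]
    cast: np.ndarray | None
    layout: ColorCheckerLayout
    chart_mask: np.ndarray
    seed: int


def generate_leaf_image(
    n_leaves: int = 6,
    leaf_color: tuple = (45, 115, 50),
    spot_fraction: float = 0.0,
    spot_offset: tuple = (40, 40, 0),
    cast: np.ndarray | None = None,
    seed: int = 0,
    shape: tuple = (480, 640),
    background: tuple = (128, 128, 128),
    color_jitter: float = 3.0,
    max_tries: int = 1000,
) -> tuple[np.ndarray, LeafImageTruth]:
    """Render a synthetic leaf photograph with an in-frame reference chart.

    Gray background, the 24-patch chart in the top-left corner, and
    ``n_leaves`` non-overlapping ellipses of ``leaf_color`` (each leaf's
    fill perturbed by a seeded normal jitter of sd ``color_jitter`` sRGB
    units, emulating natural leaf-to-leaf variation); the first
    ``round(spot_fraction * n_leaves)`` leaves carry brighter elliptical
    spots offset by ``spot_offset``.  If ``cast`` (a 3x4 affine in linear
    RGB) is given, the whole frame is passed through it to simulate an
    illumination cast.  Placement is seeded; failure to place a leaf
    within ``max_tries`` rejection draws is an error.
    """
    if not 0.0 <= spot_fraction <= 1.0:
        raise ValueError("spot_fraction must lie in [0, 1]")
    h, w = shape
    rng = np.random.default_rng(seed)
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = np.asarray(background, dtype=np.uint8)

    # chart in the top-left: 4 x 6 patches on a black card
    card_h, card_w = int(0.32 * h), int(0.36 * w)
    img[4 : 4 + card_h, 4 : 4 + card_w] = 0
    layout = grid_layout(8, 8, card_h - 8, card_w - 8)
    for (y0, x0, y1, x1), ref in zip(layout.patch_boxes, COLORCHECKER_SRGB):
        # draw the full cell (un-eroded) so the 10% interior is uniform
        gy = int(round((y1 - y0) / 0.8 * 0.1))
        gx = int(round((x1 - x0) / 0.8 * 0.1))
        img[y0 - gy : y1 + gy, x0 - gx : x1 + gx] = ref.astype(np.uint8)
    chart_mask = np.zeros((h, w), dtype=bool)
    chart_mask[0 : 8 + card_h, 0 : 8 + card_w] = True

    n_spotted = int(round(spot_fraction * n_leaves))
    centers, radii, spotted = [], [], []
    for i in range(n_leaves):
        placed = False
        for _ in range(max_tries):
            ry = int(rng.integers(int(0.05 * h), int(0.09 * h)))
            rx = int(rng.integers(int(0.05 * w), int(0.08 * w)))
            cy = int(rng.integers(ry + 1, h - ry - 1))
            cx = int(rng.integers(rx + 1, w - rx - 1))
            if cy - ry < 12 + card_h and cx - rx < 12 + card_w:
                continue  # keep clear of the chart card
            ok = all(
                (cy - oy) ** 2 / (ry + orr[0] + 4) ** 2
                + (cx - ox) ** 2 / (rx + orr[1] + 4) ** 2
                > 1.0
                for (oy, ox), orr in zip(centers, radii)
            )
            if ok:
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place leaf {i} without overlap after {max_tries} tries"
            )
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(h, w))
        this_color = np.clip(
            np.asarray(leaf_color, float) + rng.normal(0.0, color_jitter, 3)
            if color_jitter > 0
            else np.asarray(leaf_color, float),
            0,
            255,
        )
        img[rr, cc] = np.round(this_color).astype(np.uint8)
        is_spotted = i < n_spotted
        if is_spotted:
            spot_color = np.clip(
                this_color + np.asarray(spot_offset, float), 0, 255
            ).astype(np.uint8)
            for _ in range(4):
                sy = cy + int(rng.integers(-ry // 2, ry // 2 + 1))
                sx = cx + int(rng.integers(-rx // 2, rx // 2 + 1))
                srr, scc = draw_ellipse(sy, sx, max(3, ry // 3), max(3, rx // 3), shape=(h, w))
                inside = ((srr - cy) / ry) ** 2 + ((scc - cx) / rx) ** 2 <= 1.0
                img[srr[inside], scc[inside]] = spot_color
        centers.append((cy, cx))
        radii.append((ry, rx))
        spotted.append(is_spotted)

    if cast is not None:
        cast = np.asarray(cast, dtype=float)
        if cast.shape != (3, 4):
            raise ValueError("cast must be a 3 x 4 affine matrix (linear RGB)")
        lin = srgb_to_linear(img.astype(float) / 255.0).reshape(-1, 3)
        lin = lin @ cast[:, :3].T + cast[:, 3]
        img = np.round(
            linear_to_srgb(np.clip(lin, 0.0, 1.0)).reshape(h, w, 3) * 255.0
        ).astype(np.uint8)

    truth = LeafImageTruth(centers, radii, spotted, cast, layout, chart_mask, seed)
    return img, truth


# ---------------------------------------------------------------------------
# solution molarity worked example


@dataclass(frozen=True)
class SolutionSpec:
    """A salt dissolved in water: grams, litres, g/mol."""

    salt: str
    molar_mass: float
    mass: float
    volume: float

    def __post_init__(self) -> None:
        if self.molar_mass <= 0 or self.mass <= 0 or self.volume <= 0:
            raise ValueError("molar_mass, mass and volume must all be positive")


def solution_molarity(spec: SolutionSpec, sig_figs: int = 3) -> float:
    """Molar concentration ``(mass / molar_mass) / volume`` in mol/L,
    rounded to ``sig_figs`` significant figures."""
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    c = (spec.mass / spec.molar_mass) / spec.volume
    exponent = math.floor(math.log10(abs(c)))
    return round(c, -exponent + sig_figs - 1)


# ---------------------------------------------------------------------------
# detection scoring


def detection_score(
    report: MonitoringReport, truth: SyntheticGroundTruth, tol_points: int = 2
) -> dict:
    """Score a monitoring report against the injected ground truth.

    A wavenumber flagged by a contribution profile matches an injected
    target if it lies within ``tol_points`` grid points of it.  Returns,
    per chart, the precision and recall of flagged wavenumbers and the
    sample-level flag rate (recall over polluted samples).
    """
    if report.axis is None or truth.axis is None:
        raise ValueError("both report and truth must carry the wavenumber axis")
    if report.axis.size != truth.axis.size or not np.allclose(report.axis, truth.axis):
        raise ValueError("report and truth axes do not match")
    axis = report.axis
    step = float(np.median(np.diff(axis))) if axis.size > 1 else 1.0
    tol = tol_points * step + 1e-9

    targets = sorted({wn for eff in truth.effects for wn in eff.target_wavenumbers})

    out = {}
    for stat, chart, profiles in (
        ("t2", report.t2_chart, report.t2_profiles),
        ("spex", report.spex_chart, report.spex_profiles),
    ):
        flagged_wns: set[float] = set()
        for p in profiles.values():
            flagged_wns.update(axis[np.asarray(p.exceed) != "none"].tolist())
        if flagged_wns:
            hits = [wn for wn in flagged_wns if any(abs(wn - t) <= tol for t in targets)]
            precision = len(hits) / len(flagged_wns)
        else:
            precision = float("nan")
        if targets:
            recall = float(
                np.mean(
                    [any(abs(wn - t) <= tol for wn in flagged_wns) for t in targets]
                )
            )
        else:
            recall = float("nan")
        out[stat] = {
            "wn_precision": precision,
            "wn_recall": recall,
            "sample_recall": chart.percent_signalling / 100.0,
        }
    return out
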