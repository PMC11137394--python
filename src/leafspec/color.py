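"""Leaf colorimetry: chart-based color correction, leaf segmentation and
per-leaf color summaries.

Pollutant stress often discolors leaves unevenly; representing each leaf
as its mean color in RGB space makes that heterogeneity quantitative.
Because illumination varies between photographs, images are first
color-corrected against a 24-patch reference chart placed in frame: an
affine transform (3x4, gain + offset) is fitted in *linearized* sRGB
between the measured patch means and the chart's nominal values, then
applied per pixel.

Segmentation isolates leaves by the excess-green index ``2G - R - B``
(linear RGB) with a global Otsu threshold and 8-connected components;
small components are discarded.

Images are ``uint8`` H x W x 3 arrays in sRGB; :func:`load_image` /
:func:`save_image` wrap PNG/JPEG I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "COLORCHECKER_SRGB",
    "ColorCheckerLayout",
    "ColorCorrectionModel",
    "LeafRecord",
    "ColorReport",
    "srgb_to_linear",
    "linear_to_srgb",
    "grid_layout",
    "extract_patches",
    "fit_color_correction",
    "apply_color_correction",
    "segment_leaves",
    "summarize_leaf_colors",
    "compare_color_groups",
    "load_image",
    "save_image",
]

#: nominal sRGB values (0-255) of the classic 24-patch chart, row-major
#: 4 x 6: dark skin ... black (the widely published post-2005 nominals)
COLORCHECKER_SRGB = np.array(
    [
        [115, 82, 68], [194, 150, 130], [98, 122, 157], [87, 108, 67],
        [133, 128, 177], [103, 189, 170],
        [214, 126, 44], [80, 91, 166], [193, 90, 99], [94, 60, 108],
        [157, 188, 64], [224, 163, 46],
        [56, 61, 150], [70, 148, 73], [175, 54, 60], [231, 199, 31],
        [187, 86, 149], [8, 133, 161],
        [243, 243, 242], [200, 200, 200], [160, 160, 160], [122, 122, 121],
        [85, 85, 85], [52, 52, 52],
    ],
    dtype=float,
)


def srgb_to_linear(c: np.ndarray) -> np.ndarray:
    """Decode sRGB (0-1) to linear RGB (IEC 61966-2-1 transfer function)."""
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(c: np.ndarray) -> np.ndarray:
    """Encode linear RGB (0-1) to sRGB."""
    c = np.asarray(c, dtype=float)
    c = np.clip(c, 0.0, 1.0)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1 / 2.4) - 0.055)


@dataclass
class ColorCheckerLayout:
    """24 patch rectangles (row-major 4 x 6 grid) plus reference colors.

    Boxes are ``(y0, x0, y1, x1)`` half-open pixel rectangles.  Patch
    localization is configuration-supplied (chart corners -> grid), not
    auto-detected, which keeps the pipeline deterministic.
    """

    patch_boxes: list[tuple[int, int, int, int]]
    reference_rgb: np.ndarray = field(default_factory=lambda: COLORCHECKER_SRGB.copy())

    def __post_init__(self) -> None:
        if len(self.patch_boxes) != 24:
            raise ValueError("a ColorChecker layout needs exactly 24 patch boxes")
        self.reference_rgb = np.asarray(self.reference_rgb, dtype=float)
        if self.reference_rgb.shape != (24, 3):
            raise ValueError("reference_rgb must be 24 x 3")

    def bounding_box(self) -> tuple[int, int, int, int]:
        ys0, xs0, ys1, xs1 = zip(*self.patch_boxes)
        return min(ys0), min(xs0), max(ys1), max(xs1)


def grid_layout(
    y0: int, x0: int, height: int, width: int, gap_fraction: float = 0.1
) -> ColorCheckerLayout:
    """Build a 4 x 6 patch grid inside the chart rectangle.

    ``gap_fraction`` of each cell is left as inter-patch border on every
    side, mirroring the black separators of the physical chart.
    """
    rows, cols = 4, 6
    ch, cw = height / rows, width / cols
    boxes = []
    for r in range(rows):
        for c in range(cols):
            by0 = int(round(y0 + r * ch + gap_fraction * ch))
            by1 = int(round(y0 + (r + 1) * ch - gap_fraction * ch))
            bx0 = int(round(x0 + c * cw + gap_fraction * cw))
            bx1 = int(round(x0 + (c + 1) * cw - gap_fraction * cw))
            boxes.append((by0, bx0, by1, bx1))
    return ColorCheckerLayout(boxes)


@dataclass
class ColorCorrectionModel:
    """Affine correction in linear RGB: ``out = A @ [r, g, b, 1]``."""

    transform: np.ndarray  # 3 x 4
    fit_rmse: float

    def __post_init__(self) -> None:
        self.transform = np.asarray(self.transform, dtype=float)
        if self.transform.shape != (3, 4):
            raise ValueError("transform must be 3 x 4")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    return image


def extract_patches(image: np.ndarray, layout: ColorCheckerLayout) -> np.ndarray:
    """Mean sRGB (0-255) of each patch interior.

    Each box is eroded by 10% per side before averaging to guard against
    edge bleed; a box that erodes to nothing is a degenerate-box error.
    """
    image = _check_image(image)
    h, w = image.shape[:2]
    means = np.empty((24, 3))
    for k, (y0, x0, y1, x1) in enumerate(layout.patch_boxes):
        if not (0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
            raise ValueError(f"patch box {k} {(y0, x0, y1, x1)} outside image {h}x{w}")
        ey = max(1, int(round(0.1 * (y1 - y0))))
        ex = max(1, int(round(0.1 * (x1 - x0))))
        iy0, iy1 = y0 + ey, y1 - ey
        ix0, ix1 = x0 + ex, x1 - ex
        if iy1 - iy0 < 1 or ix1 - ix0 < 1:
            raise ValueError(f"patch box {k} degenerates to nothing after erosion")
        means[k] = image[iy0:iy1, ix0:ix1].reshape(-1, 3).mean(axis=0)
    return means


def fit_color_correction(
    measured: np.ndarray, reference: np.ndarray | None = None
) -> ColorCorrectionModel:
    """Least-squares affine fit in linear RGB from measured to reference
    patch colors (both given in sRGB 0-255)."""
    measured = np.asarray(measured, dtype=float)
    reference = COLORCHECKER_SRGB if reference is None else np.asarray(reference, float)
    if measured.shape != reference.shape or measured.ndim != 2 or measured.shape[1] != 3:
        raise ValueError("measured and reference must both be N x 3")
    if measured.shape[0] < 4:
        raise ValueError("need at least 4 patches to fit an affine transform")
    M = srgb_to_linear(measured / 255.0)
    R = srgb_to_linear(reference / 255.0)
    design = np.hstack([M, np.ones((M.shape[0], 1))])  # N x 4
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("patch colors are rank-deficient; cannot fit the transform")
    A, *_ = np.linalg.lstsq(design, R, rcond=None)  # 4 x 3
    pred = design @ A
    rmse = float(np.sqrt(np.mean((pred - R) ** 2)))
    return ColorCorrectionModel(A.T, rmse)


def apply_color_correction(image: np.ndarray, model: ColorCorrectionModel) -> np.ndarray:
    """Decode sRGB, apply the affine transform, clip to [0, 1], re-encode.

    Out-of-gamut values are clipped, never wrapped; output is uint8.
    """
    image = _check_image(image)
    lin = srgb_to_linear(image.astype(float) / 255.0)
    flat = lin.reshape(-1, 3)
    out = flat @ model.transform[:, :3].T + model.transform[:, 3]
    out = np.clip(out, 0.0, 1.0).reshape(image.shape)
    return np.round(linear_to_srgb(out) * 255.0).astype(np.uint8)


def segment_leaves(
    image: np.ndarray,
    min_area: int | None = None,
    method: str = "excess_green_otsu",
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Label individual leaves by the excess-green index.

    ``2G - R - B`` is computed per pixel in linear RGB, thresholded
    globally by Otsu's criterion, and 8-connected components smaller than
    ``min_area`` (default 0.1% of the image) are removed.  ``exclude``
    masks out regions that must never segment as plant material (e.g. the
    reference chart, whose green patches would otherwise be picked up).

    Returns an integer label image (0 = background, 1..K = leaves); an
    empty segmentation yields all zeros with a warning.
    """
    import warnings

    if method != "excess_green_otsu":
        raise ValueError(f"unknown segmentation method {method!r}")
    image = _check_image(image)
    h, w = image.shape[:2]
    if min_area is None:
        min_area = max(1, int(0.001 * h * w))
    lin = srgb_to_linear(image.astype(float) / 255.0)
    exg = 2.0 * lin[..., 1] - lin[..., 0] - lin[..., 2]
    if exclude is not None:
        exclude = np.asarray(exclude, dtype=bool)
        if exclude.shape != (h, w):
            raise ValueError("exclude mask must match the image shape")
        candidates = exg[~exclude]
    else:
        candidates = exg.ravel()
    if candidates.size == 0 or np.ptp(candidates) <= 1e-12:
        warnings.warn("flat excess-green image: nothing to segment", RuntimeWarning)
        return np.zeros((h, w), dtype=int)
    thr = threshold_otsu(candidates)
    mask = exg > thr
    if exclude is not None:
        mask &= ~exclude
    labels = cc_label(mask, connectivity=2)  # 8-connectivity
    out = np.zeros_like(labels)
    k = 0
    for region in regionprops(labels):
        if region.area >= min_area:
            k += 1
            out[labels == region.label] = k
    if k == 0:
        warnings.warn("no leaf component survived the min_area filter", RuntimeWarning)
    return out


@dataclass
class LeafRecord:
    """One segmented leaf summarized in sRGB."""

    label: int
    pixel_count: int
    mean_rgb: np.ndarray
    std_rgb: np.ndarray
    centroid: tuple[float, float]  # (x, y)


@dataclass
class ColorReport:
    """Per-leaf colors of one experiment group plus dispersion statistics."""

    leaves: list[LeafRecord]

    @property
    def mean_color(self) -> np.ndarray:
        if not self.leaves:
            raise ValueError("empty color report")
        return np.mean([lf.mean_rgb for lf in self.leaves], axis=0)

    @property
    def dispersion(self) -> float:
        """Mean pairwise Euclidean distance between leaf mean colors
        (0 for a single leaf)."""
        pts = np.array([lf.mean_rgb for lf in self.leaves])
        if len(pts) < 2:
            return 0.0
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        iu = np.triu_indices(len(pts), k=1)
        return float(d[iu].mean())


def summarize_leaf_colors(image: np.ndarray, labels: np.ndarray) -> ColorReport:
    """Mean/std sRGB and centroid of every labelled leaf."""
    image = _check_image(image)
    labels = np.asarray(labels)
    if labels.shape != image.shape[:2]:
        raise ValueError("labels must match the image shape")
    records = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        px = image[mask].astype(float)
        ys, xs = np.nonzero(mask)
        records.append(
            LeafRecord(
                label=int(lab),
                pixel_count=int(mask.sum()),
                mean_rgb=px.mean(axis=0),
                std_rgb=px.std(axis=0),
                centroid=(float(xs.mean()), float(ys.mean())),
            )
        )
    return ColorReport(records)


def compare_color_groups(control: ColorReport, treated: ColorReport) -> dict:
    """Between-group mean-color distance and dispersion ratio.

    ``dispersion_ratio`` is treated/control; when only the control
    dispersion is zero the ratio is reported as ``inf`` with
    ``degenerate_control=True`` rather than an error (two identical
    degenerate groups give ratio 1).
    """
    if not control.leaves or not treated.leaves:
        raise ValueError("both color reports must contain at least one leaf")
    between = float(np.linalg.norm(treated.mean_color - control.mean_color))
    cd, td = control.dispersion, treated.dispersion
    degenerate = cd == 0.0 and td > 0.0
    ratio = 1.0 if cd == td == 0.0 else (float("inf") if degenerate else td / cd)
    return {
        "between_distance": between,
        "dispersion_ratio": ratio,
        "degenerate_control": degenerate,
    }


def load_image(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(_check_image(image).astype(np.uint8)).save(path)
    return path
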