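"""Per-focus Gaussian modeling, adaptive thresholding and feature extraction.

Each candidate is modeled as an isotropic 2-D Gaussian on a local background,

    I(x, y) = b + A · exp(−((x − x0)² + (y − y0)²) / (2σ²)),

fit by least squares over a window around the candidate seed. The fit sets a
per-focus segmentation threshold b + f·A (default f = 0.5, the half
maximum, whose analytic contour radius is σ·√(−2 ln f)); the focus region is
the connected component of super-threshold pixels containing the seed.
Intensity and morphological features of the segmented region feed the
downstream classifier. Irregularity is captured by shape features
(eccentricity, solidity, circularity) rather than by anisotropic fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, optimize
from skimage import measure

from .detect import FocusCandidate

__all__ = [
    "GaussianFit",
    "FEATURE_NAMES",
    "fit_gaussian",
    "adaptive_threshold",
    "segment_focus",
    "extract_features",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)

FEATURE_NAMES = [
    "area",
    "equivalent_diameter",
    "eccentricity",
    "solidity",
    "circularity",
    "peak_intensity",
    "mean_intensity",
    "integrated_intensity",
    "local_background",
    "snr",
    "gauss_sigma",
    "gauss_rmse_norm",
]


@dataclass
class GaussianFit:
    """Result of the per-candidate isotropic Gaussian fit."""

    A: float
    x0: float  # column, subpixel
    y0: float  # row, subpixel
    sigma: float
    b: float
    rmse: float
    converged: bool
    window: tuple[int, int, int, int]  # (row_lo, row_hi, col_lo, col_hi), half-open
    clipped: bool = False  # window clipped at an image border


def _window_bounds(shape, seed, radius):
    r, c = seed
    rlo, rhi = r - radius, r + radius + 1
    clo, chi = c - radius, c + radius + 1
    clipped = rlo < 0 or clo < 0 or rhi > shape[0] or chi > shape[1]
    return (max(0, rlo), min(shape[0], rhi), max(0, clo), min(shape[1], chi)), clipped


def _moment_sigma(win: np.ndarray, b: float) -> float:
    w = np.clip(win - b, 0, None)
    tot = w.sum()
    if tot <= 0:
        return 1.0
    rr, cc = np.mgrid[0 : win.shape[0], 0 : win.shape[1]]
    r0 = (w * rr).sum() / tot
    c0 = (w * cc).sum() / tot
    var = ((w * ((rr - r0) ** 2 + (cc - c0) ** 2)).sum() / tot) / 2.0
    return float(np.sqrt(max(var, 0.25)))


def fit_gaussian(
    img: np.ndarray,
    candidate: FocusCandidate,
    window_radius: Optional[int] = None,
    max_window_radius: int = 30,
) -> GaussianFit:
    """Least-squares isotropic Gaussian fit in a window around the seed.

    Initialized from moments (b = window median, A = seed value − b, σ from
    second moments of the background-subtracted window). When
    ``window_radius`` is None it is max(5, 3× the initial σ estimate),
    capped at ``max_window_radius`` and clipped at image borders (clipped
    fits are flagged). ``converged`` is False if the solver fails, the
    amplitude collapses, or σ exceeds the window size.
    """
    img = np.asarray(img, dtype=float)
    seed = candidate.seed
    if window_radius is None:
        # provisional window wide enough to hold the candidate's own region
        # (large plateau foci yield big extended-maxima components)
        r_prov = int(max(5, np.ceil(2.0 * np.sqrt(candidate.area / np.pi))))
        r_prov = min(r_prov, max_window_radius)
        (rlo, rhi, clo, chi), _ = _window_bounds(img.shape, seed, r_prov)
        sig0 = _moment_sigma(img[rlo:rhi, clo:chi], np.median(img[rlo:rhi, clo:chi]))
        window_radius = int(min(max(5, np.ceil(3 * sig0), r_prov), max_window_radius))
    (rlo, rhi, clo, chi), clipped = _window_bounds(img.shape, seed, window_radius)
    if rhi - rlo < 3 or chi - clo < 3:
        raise ValueError("fit window smaller than 3x3")
    win = img[rlo:rhi, clo:chi]
    wsize = max(win.shape)
    span = float(np.ptp(win))

    b0 = float(np.median(win))
    A0 = max(float(img[seed]) - b0, 1e-6)
    sig0 = min(_moment_sigma(win, b0), wsize)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    rr = rr.ravel().astype(float)
    cc = cc.ravel().astype(float)
    z = win.ravel()

    def resid(p):
        A, x0, y0, sigma, b = p
        return b + A * np.exp(-((cc - x0) ** 2 + (rr - y0) ** 2) / (2 * sigma**2)) - z

    # bounds keep the solver off the degenerate broad-Gaussian mode
    # (sigma -> inf, b -> -inf) that can shadow a genuine narrow peak
    p0 = [A0, float(seed[1]), float(seed[0]), sig0, b0]
    lower = [0.0, clo - 1.0, rlo - 1.0, 0.2, float(win.min()) - span - 1.0]
    upper = [
        3.0 * span + 1.0, chi + 0.0, rhi + 0.0, float(wsize),
        float(win.max()) + 1.0,
    ]
    p0 = np.clip(p0, lower, upper)
    try:
        res = optimize.least_squares(resid, p0, bounds=(lower, upper), xtol=1e-10)
        A, x0, y0, sigma, b = res.x
        rmse = float(np.sqrt(np.mean(res.fun**2)))
        ok = bool(res.success) and np.isfinite(res.x).all()
    except Exception:
        A, x0, y0, sigma, b, rmse, ok = A0, seed[1], seed[0], sig0, b0, np.inf, False

    converged = ok and sigma < 0.99 * wsize and A > 1e-3
    return GaussianFit(
        A=float(A), x0=float(x0), y0=float(y0), sigma=float(sigma), b=float(b),
        rmse=rmse, converged=converged, window=(rlo, rhi, clo, chi), clipped=clipped,
    )


def adaptive_threshold(fit: GaussianFit, level_fraction: float = 0.5):
    """Per-focus segmentation threshold from the Gaussian model.

    Returns ``(threshold, expected_radius)`` with threshold = b + f·A and
    expected radius σ·√(−2 ln f) — the analytic contour of the model at
    level f. Returns ``None`` (candidate rejection) for a non-converged fit
    or a vanishing amplitude.
    """
    if not (0 < level_fraction < 1):
        raise ValueError("level_fraction must lie in (0, 1)")
    if not fit.converged or fit.A <= 0:
        return None
    threshold = fit.b + level_fraction * fit.A
    radius = fit.sigma * np.sqrt(-2.0 * np.log(level_fraction))
    return float(threshold), float(radius)


def segment_focus(
    img: np.ndarray, candidate: FocusCandidate, threshold: float,
    window: Optional[tuple[int, int, int, int]] = None,
) -> np.ndarray:
    """Segment the focus: the 8-connected component of pixels ≥ threshold
    containing the seed, restricted to the fit window.

    Returns a full-frame boolean mask; an all-False mask means the
    candidate is rejected (e.g. threshold above the peak).
    """
    img = np.asarray(img, dtype=float)
    out = np.zeros(img.shape, dtype=bool)
    r, c = candidate.seed
    if window is None:
        window = (0, img.shape[0], 0, img.shape[1])
    rlo, rhi, clo, chi = window
    win = img[rlo:rhi, clo:chi] >= threshold
    if not win[r - rlo, c - clo]:
        return out
    labels, _ = ndimage.label(win, structure=_STRUCT8)
    comp = labels == labels[r - rlo, c - clo]
    out[rlo:rhi, clo:chi] = comp
    return out


def extract_features(
    img: np.ndarray,
    region_mask: np.ndarray,
    fit: GaussianFit,
    noise_sd: float,
) -> dict[str, float]:
    """Intensity and morphological features of a segmented focus.

    Background-subtracted quantities use the fitted local background b, so
    all features except ``peak_intensity``/``mean_intensity``/
    ``local_background`` are invariant under adding a constant to the image.
    Circularity is 4πA/P² with the perimeter measured on the 8-connected
    boundary with the standard even/odd step weighting; a single-pixel
    region has circularity 1 by convention.
    """
    img = np.asarray(img, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask is empty")
    props = measure.regionprops(region_mask.astype(np.uint8), intensity_image=img)[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    if perimeter > 0:
        circularity = 4.0 * np.pi * area / perimeter**2
    else:
        circularity = 1.0
    vals = img[region_mask]
    peak = float(vals.max())
    return {
        "area": area,
        "equivalent_diameter": float(props.equivalent_diameter_area),
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
        "circularity": float(circularity),
        "peak_intensity": peak,
        "mean_intensity": float(vals.mean()),
        "integrated_intensity": float((vals - fit.b).sum()),
        "local_background": float(fit.b),
        "snr": float((peak - fit.b) / noise_sd) if noise_sd > 0 else np.inf,
        "gauss_sigma": float(fit.sigma),
        "gauss_rmse_norm": float(fit.rmse / fit.A) if fit.A > 0 else np.inf,
    }
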