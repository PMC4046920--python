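"""Synthetic tissue images and flow-cytometry event tables with ground truth.

The generator emulates the data the counting pipeline assumes: a compressed
whole organ imaged at low magnification as a 16-bit grayscale frame — a
homogeneous autofluorescent tissue background with smooth sample-to-sample
intensity variation, plus detection noise (Poisson shot noise and Gaussian
read noise) — on which fluorescent recombination foci of two morphological
classes are planted at configurable densities per cm²:

* small foci: dim, compact, possibly irregular Gaussian spots (recombination
  events in short-lived transit cells);
* large foci: bright, near-round plateaus with soft edges (clonally expanded
  events, e.g. fully converted colonic crypts or acinar clones).

For flow cytometry the generator emits event tables with forward/side scatter
and two fluorescence channels (green 515–545 nm, orange 562–588 nm) in which
autofluorescent cells form a correlated diagonal cloud and EGFP-positive
recombinant cells are shifted along the green axis, at planted frequencies
down to 1e-6.

Every draw is controlled by an explicit seed, and each simulated object is
recorded in a ground-truth table so detection recall, classifier accuracy,
quantification round trips and gate calibration are all measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FocusClassParams",
    "ImageSimConfig",
    "FlowSimConfig",
    "simulate_tissue_image",
    "simulate_flow_events",
    "simulate_cohort_counts",
    "IMAGE_PRESETS",
    "COHORT_PRESETS",
]

UINT16_MAX = 65535


@dataclass
class FocusClassParams:
    """Rendering parameters for one focus class.

    For small foci ``size_range`` is the Gaussian sigma range in px and
    ``irregularity`` the maximal random elliptical stretch (0 = isotropic).
    For large foci ``size_range`` is the disc *diameter* range in px,
    ``roundness`` the minimal axis ratio of the disc, and ``edge_sigma_px``
    the Gaussian blur applied to the disc edge.
    """

    amplitude_range: tuple[float, float] = (150.0, 400.0)
    size_range: tuple[float, float] = (1.0, 3.0)
    irregularity: float = 0.5
    roundness: float = 0.9
    edge_sigma_px: float = 1.0


@dataclass
class ImageSimConfig:
    """Configuration of one simulated whole-organ frame.

    Defaults put a ~1 cm² elliptical tissue in a 1176×1176 frame at
    10 µm/px, with noise levels such that the dimmest default small focus
    is >5× the total pixel noise SD.
    """

    pixel_size_um: float = 10.0
    shape_px: tuple[int, int] = (1176, 1176)
    tissue_shape: str | np.ndarray = "ellipse"  # "ellipse", "full", or a bool mask
    background_level: float = 500.0
    outside_level: float = 50.0
    sample_noise_sd: float = 20.0
    sample_noise_smooth_px: float = 20.0
    shot_noise_gain: float = 0.5
    read_noise_sd: float = 10.0
    small_foci_density: float = 0.0  # per cm²
    large_foci_density: float = 0.0  # per cm²
    small_focus_params: FocusClassParams = field(default_factory=FocusClassParams)
    large_focus_params: FocusClassParams = field(
        default_factory=lambda: FocusClassParams(
            amplitude_range=(300.0, 800.0), size_range=(5.0, 15.0)
        )
    )
    n_small: Optional[int] = None  # exact counts override Poisson sampling
    n_large: Optional[int] = None
    subpixel_jitter: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.small_foci_density < 0 or self.large_foci_density < 0:
            raise ValueError("foci densities must be non-negative")
        max_amp = max(
            self.small_focus_params.amplitude_range[1],
            self.large_focus_params.amplitude_range[1],
        )
        if self.background_level + max_amp >= UINT16_MAX:
            raise ValueError(
                "background_level + maximal focus amplitude exceeds the 16-bit ceiling"
            )


def _tissue_mask(cfg: ImageSimConfig) -> np.ndarray:
    if isinstance(cfg.tissue_shape, np.ndarray):
        mask = cfg.tissue_shape.astype(bool)
        if mask.shape != tuple(cfg.shape_px):
            raise ValueError("user tissue mask shape does not match shape_px")
        return mask
    h, w = cfg.shape_px
    if cfg.tissue_shape == "full":
        return np.ones((h, w), dtype=bool)
    if cfg.tissue_shape == "ellipse":
        rr, cc = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        ry, rx = 0.48 * h, 0.48 * w
        return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
    raise ValueError(f"unknown tissue_shape {cfg.tissue_shape!r}")


def _smooth_noise_field(
    shape: tuple[int, int],
    sd: float,
    smooth_px: float,
    rng: np.random.Generator,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Mean-zero Gaussian random field with exact pixel SD ``sd``.

    White noise is smoothed with a Gaussian kernel (correlation length
    ``smooth_px``) and renormalized so the realized field SD inside
    ``mask`` (the tissue, where the variance matters) equals ``sd``.
    """
    if sd <= 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    fld = ndimage.gaussian_filter(white, smooth_px, mode="reflect")
    ref = fld[mask] if mask is not None else fld
    fld -= ref.mean()
    s = ref.std()
    if s > 0:
        fld *= sd / s
    return fld


def _render_small(
    img: np.ndarray, r0: float, c0: float, amp: float, sigma: float, stretch: float, theta: float
) -> None:
    """Add an (optionally elliptically stretched) Gaussian spot in place."""
    smax = sigma * max(stretch, 1.0)
    rad = int(np.ceil(4 * smax)) + 1
    h, w = img.shape
    rlo, rhi = max(0, int(r0) - rad), min(h, int(r0) + rad + 1)
    clo, chi = max(0, int(c0) - rad), min(w, int(c0) + rad + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dy, dx = rr - r0, cc - c0
    # rotate into the stretched frame
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    img[rlo:rhi, clo:chi] += amp * np.exp(
        -(u**2 / (stretch**2) + v**2) / (2.0 * sigma**2)
    )


def _render_large(
    img: np.ndarray, r0: float, c0: float, amp: float, radius: float,
    axis_ratio: float, theta: float, edge_sigma: float,
) -> None:
    """Add a soft-edged, near-round bright disc (crypt-like clone) in place."""
    rad = int(np.ceil(radius + 4 * edge_sigma)) + 2
    h, w = img.shape
    rlo, rhi = max(0, int(r0) - rad), min(h, int(r0) + rad + 1)
    clo, chi = max(0, int(c0) - rad), min(w, int(c0) + rad + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dy, dx = rr - r0, cc - c0
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    disc = ((u / (radius * axis_ratio)) ** 2 + (v / radius) ** 2 <= 1.0).astype(float)
    if edge_sigma > 0:
        disc = ndimage.gaussian_filter(disc, edge_sigma, mode="constant")
    img[rlo:rhi, clo:chi] += amp * disc


def simulate_tissue_image(cfg: ImageSimConfig):
    """Simulate one whole-organ frame.

    Returns ``(raster, tissue_mask, ground_truth)`` where ``raster`` is a
    :class:`radr.io.Raster` (uint16), ``tissue_mask`` a boolean array and
    ``ground_truth`` a DataFrame with one row per planted focus
    (``row, col, size_class, amplitude, sigma_or_radius``).

    The noiseless signal is ``background + smooth sample-noise field +
    sum(foci)``; Poisson shot noise (scaled by ``shot_noise_gain`` counts per
    photon-equivalent) and Gaussian read noise are then applied, and the
    frame is clipped and quantized to 16 bits. Bit-identical given the seed.
    """
    from .io import Raster  # local import to avoid a cycle

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mask = _tissue_mask(cfg)
    area_px = int(mask.sum())
    if area_px == 0:
        raise ValueError("tissue mask is empty (zero tissue area)")
    area_cm2 = area_px * (cfg.pixel_size_um * 1e-4) ** 2

    img = np.full(cfg.shape_px, float(cfg.outside_level))
    img[mask] = cfg.background_level
    img += _smooth_noise_field(
        cfg.shape_px, cfg.sample_noise_sd, cfg.sample_noise_smooth_px, rng, mask
    )

    tissue_idx = np.flatnonzero(mask.ravel())
    records = []

    def _plant(size_class: str, density: float, n_fixed: Optional[int],
               params: FocusClassParams) -> None:
        n = n_fixed if n_fixed is not None else int(rng.poisson(density * area_cm2))
        if n == 0:
            return
        flat = rng.choice(tissue_idx, size=n, replace=True)
        rows = (flat // cfg.shape_px[1]).astype(float)
        cols = (flat % cfg.shape_px[1]).astype(float)
        if cfg.subpixel_jitter:
            rows += rng.uniform(-0.5, 0.5, n)
            cols += rng.uniform(-0.5, 0.5, n)
        amps = rng.uniform(*params.amplitude_range, n)
        sizes = rng.uniform(*params.size_range, n)
        thetas = rng.uniform(0, np.pi, n)
        if size_class == "small":
            stretch = 1.0 + rng.uniform(0.0, params.irregularity, n)
            for i in range(n):
                _render_small(img, rows[i], cols[i], amps[i], sizes[i],
                              stretch[i], thetas[i])
            size_out = sizes
        else:
            ratios = rng.uniform(params.roundness, 1.0, n)
            for i in range(n):
                _render_large(img, rows[i], cols[i], amps[i], sizes[i] / 2.0,
                              ratios[i], thetas[i], params.edge_sigma_px)
            size_out = sizes / 2.0
        for i in range(n):
            records.append(
                dict(row=rows[i], col=cols[i], size_class=f"{size_class}",
                     amplitude=amps[i], sigma_or_radius=size_out[i])
            )

    _plant("small", cfg.small_foci_density, cfg.n_small, cfg.small_focus_params)
    _plant("large", cfg.large_foci_density, cfg.n_large, cfg.large_focus_params)

    if img.max() >= UINT16_MAX:
        raise ValueError("noiseless signal exceeds the 16-bit ceiling")

    if cfg.shot_noise_gain > 0:
        img = rng.poisson(np.clip(img, 0, None) / cfg.shot_noise_gain).astype(float)
        img *= cfg.shot_noise_gain
    if cfg.read_noise_sd > 0:
        img += rng.normal(0.0, cfg.read_noise_sd, img.shape)

    pixels = np.clip(np.rint(img), 0, UINT16_MAX).astype(np.uint16)
    gt = pd.DataFrame.from_records(
        records, columns=["row", "col", "size_class", "amplitude", "sigma_or_radius"]
    )
    return Raster(pixels, cfg.pixel_size_um), mask, gt


# ---------------------------------------------------------------------------
# flow cytometry


@dataclass
class FlowSimConfig:
    """Configuration of a simulated flow-cytometry event table.

    ``autofluor_params`` sets the autofluorescent cloud: log10-scale means
    and SDs of the green/orange channels and their correlation (tissue
    autofluorescence is diagonal in the two-channel plane). EGFP-positive
    events are drawn from the same cloud and shifted ``positive_shift``-fold
    on the green channel. ``debris_fraction`` of events form a low-scatter
    cluster excluded by the live gate.
    """

    n_events: int = 1_000_000
    positive_frequency: float = 0.0
    autofluor_params: dict = field(
        default_factory=lambda: dict(
            mean_log_green=2.0, mean_log_orange=2.0, sd_log=0.3, correlation=0.9
        )
    )
    positive_shift: float = 30.0
    debris_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        if not (0.0 <= self.positive_frequency <= 1.0):
            raise ValueError("positive_frequency must lie in [0, 1]")
        rho = self.autofluor_params["correlation"]
        if not (-1.0 < rho < 1.0):
            raise ValueError("green-orange correlation must lie in (-1, 1)")


def simulate_flow_events(cfg: FlowSimConfig) -> pd.DataFrame:
    """Simulate an event table with columns ``fsc, ssc, green, orange`` plus
    ground-truth flags ``is_positive`` and ``is_debris``.

    Positives are Binomial(n_events, positive_frequency) among non-debris
    events; deterministic given the seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_events

    is_debris = rng.random(n) < cfg.debris_fraction
    is_positive = (~is_debris) & (rng.random(n) < cfg.positive_frequency)

    # scatter: live cells high, debris low (log10 scale)
    log_fsc = np.where(is_debris, rng.normal(1.5, 0.2, n), rng.normal(3.0, 0.2, n))
    log_ssc = np.where(is_debris, rng.normal(1.4, 0.2, n), rng.normal(2.8, 0.25, n))

    p = cfg.autofluor_params
    rho = p["correlation"]
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    lg = p["mean_log_green"] + p["sd_log"] * z1
    lo = p["mean_log_orange"] + p["sd_log"] * (rho * z1 + np.sqrt(1 - rho**2) * z2)
    lg = lg + np.where(is_positive, np.log10(cfg.positive_shift), 0.0)

    return pd.DataFrame(
        dict(
            fsc=10.0**log_fsc,
            ssc=10.0**log_ssc,
            green=10.0**lg,
            orange=10.0**lo,
            is_positive=is_positive,
            is_debris=is_debris,
        )
    )


# ---------------------------------------------------------------------------
# cohort-level count simulation (power analyses)


def simulate_cohort_counts(
    group_densities: dict[str, tuple[float, float]],
    n_per_group: int,
    area_cm2: float = 1.0,
    animal_cv: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-animal focus counts without rendering images.

    ``group_densities`` maps group name to (small_density, large_density)
    per cm². Each animal's realized density is the group density times an
    independent lognormal multiplier per class (coefficient of variation
    ``animal_cv``, mean 1) — the between-animal overdispersion that makes
    foci frequencies non-normal — and counts are Poisson given the realized
    density. Returns a per-animal table with total and large-only counts
    and frequencies.
    """
    rng = np.random.default_rng(seed)
    s = np.sqrt(np.log1p(animal_cv**2))
    rows = []
    for group, (d_small, d_large) in group_densities.items():
        for i in range(n_per_group):
            m_small = rng.lognormal(-0.5 * s**2, s)
            m_large = rng.lognormal(-0.5 * s**2, s)
            n_small = rng.poisson(d_small * m_small * area_cm2)
            n_large = rng.poisson(d_large * m_large * area_cm2)
            rows.append(
                dict(
                    animal_id=f"{group}-{i:02d}",
                    group=group,
                    n_foci_total=n_small + n_large,
                    n_foci_large=n_large,
                    tissue_area_cm2=area_cm2,
                    freq_total_per_cm2=(n_small + n_large) / area_cm2,
                    freq_large_per_cm2=n_large / area_cm2,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presets

# Planting densities anchor to reported organ-level frequencies: spontaneous
# pancreatic foci ~140/cm² (mixed small transit-cell and large clonal foci)
# and MNU/T3-induced pancreatic events ~400/cm² (dominated by small/faint
# de novo foci).
IMAGE_PRESETS: dict[str, dict] = {
    "spontaneous-pancreas": dict(small_foci_density=100.0, large_foci_density=40.0),
    "mnu-pancreas": dict(small_foci_density=300.0, large_foci_density=100.0),
}

# Cohorts for comparison studies: "aged-colon" differs only in large-focus
# (converted crypt) density between young and old; "mnu-pancreas" elevates
# total density versus control.
COHORT_PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "aged-colon": {"young": (200.0, 40.0), "old": (200.0, 120.0)},
    "mnu-pancreas": {"control": (100.0, 40.0), "treated": (300.0, 100.0)},
}


def preset_image_config(name: str, seed: int = 0, **overrides) -> ImageSimConfig:
    """Build an :class:`ImageSimConfig` from a named preset."""
    if name not in IMAGE_PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(IMAGE_PRESETS)}"
        )
    kw = dict(IMAGE_PRESETS[name])
    kw.update(overrides)
    return ImageSimConfig(seed=seed, **kw)
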