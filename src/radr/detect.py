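"""Focus-candidate detection: median prefilter and extended maxima transform.

A recombination focus appears as a local intensity "dome" above the tissue
background. After light median filtering, candidate foci are the extended
maxima of the image — the regional maxima of the h-maxima transform, i.e.
the domes whose height exceeds h — intersected with the tissue mask. A flat
background forms one giant plateau "maximum" under this definition; an area
cap removes it without introducing an arbitrary intensity floor.

The height parameter h defaults to 3× a robust noise SD (1.4826·MAD)
measured on the filtered tissue pixels, so detection stringency transfers
across exposure settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima, reconstruction

__all__ = [
    "DetectParams",
    "FocusCandidate",
    "median_filter",
    "extended_maxima",
    "estimate_noise_sd",
    "find_candidates",
]

# 8-connectivity for regional maxima and connected components, everywhere.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class DetectParams:
    """Detection parameters.

    ``h``: extended-maxima height threshold in counts; ``None`` means
    3× the robust noise SD of the (filtered) tissue pixels.
    ``max_candidate_area_frac``: components larger than this fraction of
    the tissue area are discarded (removes the background plateau).
    """

    median_radius: int = 1
    h: Optional[float] = None
    h_noise_factor: float = 3.0
    max_candidate_area_frac: float = 0.01
    min_candidate_area: int = 1

    def validate(self) -> None:
        if self.median_radius < 0:
            raise ValueError("median_radius must be >= 0")
        if self.h is not None and self.h <= 0:
            raise ValueError("h must be positive")
        if not (0 < self.max_candidate_area_frac <= 1):
            raise ValueError("max_candidate_area_frac must lie in (0, 1]")


@dataclass
class FocusCandidate:
    """One connected extended-maxima component proposed as a focus."""

    id: int
    seed: tuple[int, int]  # (row, col) of the component's maximum pixel
    rows: np.ndarray  # region pixel coordinates
    cols: np.ndarray

    @property
    def area(self) -> int:
        return len(self.rows)


def median_filter(img: np.ndarray, radius: int) -> np.ndarray:
    """Median over the (2r+1)² square neighborhood, edges replicated.

    radius 0 is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return img.copy()
    return ndimage.median_filter(img, size=2 * radius + 1, mode="nearest")


def extended_maxima(img: np.ndarray, h: float) -> np.ndarray:
    """Binary mask of image domes taller than ``h``.

    Computed as the regional maxima (8-connected, plateaus included) of the
    h-maxima transform — the morphological reconstruction by dilation of
    (img − h) under img. A constant image is one global plateau and returns
    an all-True mask.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    f = np.asarray(img, dtype=float)
    if np.ptp(f) == 0:
        return np.ones(f.shape, dtype=bool)
    rec = reconstruction(f - h, f, method="dilation", footprint=_STRUCT8)
    if np.ptp(rec) == 0:
        return np.ones(f.shape, dtype=bool)
    return local_maxima(rec, connectivity=2, allow_borders=True)


def estimate_noise_sd(img: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Robust pixel-noise SD: 1.4826 × median absolute deviation.

    Computed over tissue pixels when a mask is given; foci occupy a small
    area fraction, so the MAD is insensitive to them.
    """
    vals = img[mask] if mask is not None else np.asarray(img).ravel()
    med = np.median(vals)
    return 1.4826 * float(np.median(np.abs(vals - med)))


def find_candidates(
    img: np.ndarray,
    tissue_mask: np.ndarray,
    params: Optional[DetectParams] = None,
) -> list[FocusCandidate]:
    """Propose focus candidates on a *preprocessed* (median-filtered) image.

    Connected components of the extended-maxima mask are intersected with
    the tissue mask and filtered by ``min_candidate_area`` and
    ``max_candidate_area_frac``; the seed of each candidate is its maximum
    pixel, ties broken by smallest (row, col).
    """
    params = params or DetectParams()
    params.validate()
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    tissue_area = int(tissue_mask.sum())
    if tissue_area == 0:
        raise ValueError("tissue mask is empty")

    h = params.h
    if h is None:
        sd = estimate_noise_sd(img, tissue_mask)
        if sd <= 0:
            sd = 1.0
        h = params.h_noise_factor * sd

    mask = extended_maxima(img, h) & tissue_mask
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    max_area = params.max_candidate_area_frac * tissue_area

    candidates: list[FocusCandidate] = []
    if n == 0:
        return candidates
    objects = ndimage.find_objects(labels)
    cid = 0
    for lab, sl in enumerate(objects, start=1):
        region = labels[sl] == lab
        area = int(region.sum())
        if area < params.min_candidate_area or area > max_area:
            continue
        rr, cc = np.nonzero(region)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        vals = np.asarray(img)[rr, cc]
        vmax = vals.max()
        # tie-break: smallest (row, col) among maximal pixels
        at_max = np.flatnonzero(vals == vmax)
        order = np.lexsort((cc[at_max], rr[at_max]))
        k = at_max[order[0]]
        candidates.append(
            FocusCandidate(id=cid, seed=(int(rr[k]), int(cc[k])), rows=rr, cols=cc)
        )
        cid += 1
    return candidates
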