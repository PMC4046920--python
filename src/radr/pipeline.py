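"""End-to-end foci counting: detect → fit → segment → classify → count.

One call analyzes a whole-organ frame: median filtering, extended-maxima
candidate detection, per-candidate Gaussian fitting and adaptive-threshold
segmentation, feature extraction, and two-stage SVM classification. The
per-candidate table records every stage outcome so the survival of
candidates through the pipeline (detected → fit-converged → accepted →
large) is always auditable.

``train_simulated_classifier`` builds the default classifier entirely from
the synthetic-data generator: focus examples are harvested from simulated
images by matching candidates to planted ground truth, and noise examples
from focus-free images detected at a lowered height threshold so the
classifier sees spurious domes near the decision boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classify as _classify
from .classify import (LABEL_LARGE, LABEL_NOISE, LABEL_SMALL,
                       TwoStageClassifier, train_stage)
from .detect import DetectParams, estimate_noise_sd, find_candidates, median_filter
from .io import Raster, pixel_area_cm2
from .quantify import SampleResult, organ_frequency
from .segment import (FEATURE_NAMES, adaptive_threshold, extract_features,
                      fit_gaussian, segment_focus)
from .simulate import ImageSimConfig, simulate_tissue_image

__all__ = [
    "RuleBasedClassifier",
    "analyze_image",
    "count_image",
    "train_simulated_classifier",
    "build_annotation_table",
]

log = logging.getLogger("radr")


class RuleBasedClassifier:
    """Threshold fallback used when no trained SVM is available.

    Accepts a candidate as a focus when its peak rises well above the noise
    and the Gaussian model fits; calls it large when the segmented region
    is big and round. Cutoffs are deliberately conservative.
    """

    def __init__(self, min_snr: float = 5.0, max_rmse_norm: float = 0.6,
                 large_area_px: float = 25.0, min_circularity: float = 0.5):
        self.min_snr = min_snr
        self.max_rmse_norm = max_rmse_norm
        self.large_area_px = large_area_px
        self.min_circularity = min_circularity
        self.conservative_offset = 0.0

    def predict(self, features: pd.DataFrame, conservative: bool = False) -> np.ndarray:
        snr_cut = self.min_snr * (1.5 if conservative else 1.0)
        is_focus = (
            (features["snr"] >= snr_cut)
            & (features["gauss_rmse_norm"] <= self.max_rmse_norm)
            & (features["circularity"] >= (self.min_circularity if conservative else 0.0))
        )
        is_large = features["area"] >= self.large_area_px
        labels = np.where(
            ~is_focus, LABEL_NOISE, np.where(is_large, LABEL_LARGE, LABEL_SMALL)
        )
        return labels.astype(str)


def analyze_image(
    raster: Raster,
    tissue_mask: np.ndarray,
    detect_params: Optional[DetectParams] = None,
    level_fraction: float = 0.5,
    classifier: Optional[TwoStageClassifier | RuleBasedClassifier] = None,
    conservative: bool = True,
) -> pd.DataFrame:
    """Run the full pipeline on one frame; one row per detected candidate.

    Columns: candidate bookkeeping (id, seed, region area), Gaussian-fit
    parameters, segmentation status, the full feature vector, and —
    when a classifier is given — the predicted ``label`` and the final
    ``accepted`` flag (non-noise label with a converged fit and a nonempty
    segmentation).
    """
    detect_params = detect_params or DetectParams()
    img = raster.pixels.astype(float)
    filtered = median_filter(img, detect_params.median_radius)
    noise_sd = estimate_noise_sd(filtered, tissue_mask)
    candidates = find_candidates(filtered, tissue_mask, detect_params)
    log.info("detected %d candidates (noise_sd=%.2f)", len(candidates), noise_sd)

    rows = []
    for cand in candidates:
        rec: dict = {
            "candidate_id": cand.id,
            "seed_row": cand.seed[0],
            "seed_col": cand.seed[1],
            "region_area_px": cand.area,
        }
        fit = fit_gaussian(filtered, cand)
        rec.update(
            fit_A=fit.A, fit_x0=fit.x0, fit_y0=fit.y0, fit_sigma=fit.sigma,
            fit_b=fit.b, fit_rmse=fit.rmse, fit_converged=fit.converged,
            fit_clipped=fit.clipped,
        )
        thr = adaptive_threshold(fit, level_fraction) if fit.converged else None
        if thr is None:
            rec["status"] = "rejected_fit"
            rows.append(rec)
            continue
        threshold, _ = thr
        region = segment_focus(filtered, cand, threshold, window=fit.window)
        if not region.any():
            rec["status"] = "rejected_empty_segmentation"
            rows.append(rec)
            continue
        rec.update(extract_features(filtered, region, fit, noise_sd))
        rec["status"] = "segmented"
        rows.append(rec)

    columns = (
        ["candidate_id", "seed_row", "seed_col", "region_area_px", "fit_A",
         "fit_x0", "fit_y0", "fit_sigma", "fit_b", "fit_rmse", "fit_converged",
         "fit_clipped", "status"] + FEATURE_NAMES
    )
    df = pd.DataFrame(rows, columns=columns)
    n_fit = int((df["status"] != "rejected_fit").sum()) if len(df) else 0
    log.info("fit-converged candidates: %d", n_fit)

    if classifier is not None and len(df):
        ok = df["status"] == "segmented"
        labels = np.full(len(df), LABEL_NOISE, dtype=object)
        if ok.any():
            labels[ok.to_numpy()] = classifier.predict(
                df.loc[ok], conservative=conservative
            )
        df["label"] = labels.astype(str)
        df["accepted"] = ok.to_numpy() & (df["label"] != LABEL_NOISE)
        log.info(
            "accepted foci: %d (large: %d)",
            int(df["accepted"].sum()),
            int((df.loc[df["accepted"], "label"] == LABEL_LARGE).sum()),
        )
    return df


def count_image(
    raster: Raster,
    tissue_mask: np.ndarray,
    classifier: TwoStageClassifier | RuleBasedClassifier,
    detect_params: Optional[DetectParams] = None,
    level_fraction: float = 0.5,
    conservative: bool = True,
    animal_id: str = "",
    organ: str = "",
) -> tuple[SampleResult, pd.DataFrame]:
    """Count accepted foci on one frame and report the organ frequency."""
    df = analyze_image(
        raster, tissue_mask, detect_params, level_fraction, classifier, conservative
    )
    n_total = int(df["accepted"].sum()) if len(df) else 0
    n_large = (
        int((df.loc[df.get("accepted", pd.Series(dtype=bool)), "label"] == LABEL_LARGE).sum())
        if len(df)
        else 0
    )
    result = organ_frequency(
        [n_total], [n_large],
        tile_areas_cm2=[tissue_mask.sum() * pixel_area_cm2(raster.pixel_size_um)],
        animal_id=animal_id, organ=organ,
    )
    return result, df


def _match_to_ground_truth(
    df: pd.DataFrame, gt: pd.DataFrame, tolerance_px: float = 3.0
) -> np.ndarray:
    """Label each candidate row by its nearest planted focus.

    A candidate matches a planted focus when its seed lies within the
    focus footprint (sigma-or-radius) plus ``tolerance_px``. Returns labels
    in {small_focus, large_focus, ""} ("" = unmatched).
    """
    labels = np.full(len(df), "", dtype=object)
    if len(gt) == 0 or len(df) == 0:
        return labels
    gt_pos = gt[["row", "col"]].to_numpy(dtype=float)
    gt_tol = gt["sigma_or_radius"].to_numpy(dtype=float) + tolerance_px
    seeds = df[["seed_row", "seed_col"]].to_numpy(dtype=float)
    for i, s in enumerate(seeds):
        d = np.hypot(gt_pos[:, 0] - s[0], gt_pos[:, 1] - s[1])
        j = int(np.argmin(d))
        if d[j] <= gt_tol[j]:
            labels[i] = (
                LABEL_SMALL if gt["size_class"].iloc[j] == "small" else LABEL_LARGE
            )
    return labels


def build_annotation_table(
    n_focus_images: int = 3,
    n_noise_images: int = 3,
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    small_density: float = 600.0,
    large_density: float = 250.0,
    noise_h_factor: float = 1.3,
) -> pd.DataFrame:
    """Build a labeled feature table from the simulator.

    Focus examples come from images planted at elevated densities, labeled
    by matching candidates to ground truth (unmatched candidates on focus
    images are dropped as ambiguous). Noise examples come from focus-free
    images detected at a lowered height threshold (``noise_h_factor`` × the
    robust noise SD) so spurious domes near the decision boundary are
    represented.
    """
    tables = []
    for i in range(n_focus_images):
        cfg = ImageSimConfig(
            shape_px=image_shape, small_foci_density=small_density,
            large_foci_density=large_density, seed=seed * 1000 + i,
        )
        raster, mask, gt = simulate_tissue_image(cfg)
        df = analyze_image(raster, mask)
        df = df[df["status"] == "segmented"].reset_index(drop=True)
        df["label"] = _match_to_ground_truth(df, gt)
        df = df[df["label"] != ""]
        tables.append(df)
    for i in range(n_noise_images):
        cfg = ImageSimConfig(shape_px=image_shape, seed=seed * 1000 + 500 + i)
        raster, mask, _ = simulate_tissue_image(cfg)
        params = DetectParams(h_noise_factor=noise_h_factor)
        df = analyze_image(raster, mask, detect_params=params)
        df = df[df["status"] == "segmented"].reset_index(drop=True)
        df["label"] = LABEL_NOISE
        tables.append(df)
    out = pd.concat(tables, ignore_index=True)
    return out[FEATURE_NAMES + ["label"]]


def train_simulated_classifier(
    seed: int = 0,
    annotations: Optional[pd.DataFrame] = None,
    conservative_quantile: float = 0.999,
    **annotation_kwargs,
) -> tuple[TwoStageClassifier, pd.DataFrame]:
    """Train the default two-stage classifier from simulator annotations.

    The conservative stage-1 offset is set at the ``conservative_quantile``
    of the noise-class decision values (floored at 0), so in conservative
    mode essentially no noise candidate clears stage 1. Returns the model
    and the annotation table used.
    """
    if annotations is None:
        annotations = build_annotation_table(seed=seed, **annotation_kwargs)
    stage1 = train_stage(annotations, "noise-vs-focus", seed=seed)
    stage2 = train_stage(annotations, "small-vs-large", seed=seed)
    noise_rows = annotations[annotations["label"] == LABEL_NOISE]
    d_noise = stage1.decision(noise_rows[stage1.feature_names].to_numpy(dtype=float))
    offset = max(0.0, float(np.quantile(d_noise, conservative_quantile)))
    model = TwoStageClassifier(stage1=stage1, stage2=stage2,
                               conservative_offset=offset)
    log.info(
        "trained classifier: stage1 CV acc %.3f, stage2 CV acc %.3f, offset %.3f",
        stage1.cv_accuracy, stage2.cv_accuracy, offset,
    )
    return model, annotations
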