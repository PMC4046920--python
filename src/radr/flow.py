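"""Rare-event flow-cytometry gating and recombinant-cell frequency.

Events carry forward/side scatter and two fluorescence channels: green
(515–545 nm) and orange (562–588 nm). Autofluorescent cells form a
correlated diagonal cloud in the (log green, log orange) plane; EGFP
expression shifts an event off the diagonal along the green axis. The gate
is therefore a sloped discriminant

    d = log10(green) − k · log10(orange),

with the slope k fit as the principal axis of the autofluorescent reference
cloud and the threshold t calibrated so the expected fraction of
autofluorescent events crossing it equals a target false-positive rate
(default 1e-6, the assay's detection floor). Calibration is empirical when
the reference is large enough, otherwise by Gaussian tail extrapolation of
the discriminant distribution. Recombinant-cell frequency is reported per
million live-gated events with an exact (Clopper–Pearson) binomial 95%
interval.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

__all__ = [
    "GateSpec",
    "FrequencyEstimate",
    "live_gate",
    "calibrate_gate",
    "recombinant_frequency",
    "percent_positive",
]

REQUIRED_COLUMNS = ("fsc", "ssc", "green", "orange")


def _check_events(events: pd.DataFrame) -> None:
    if len(events) == 0:
        raise ValueError("event table is empty")
    for col in REQUIRED_COLUMNS:
        if col not in events.columns:
            raise ValueError(f"event table missing column {col!r}")


@dataclass
class GateSpec:
    """Live-scatter bounds plus the calibrated fluorescence discriminant."""

    live_quantiles: tuple[float, float] = (0.05, 0.995)
    slope_k: float = 1.0
    threshold_t: float = float("inf")
    target_fpr: float = 1e-6
    reference_size: int = 0
    tail_mode: str = "gaussian"  # calibration mode actually used

    def discriminant(self, events: pd.DataFrame) -> np.ndarray:
        g = np.clip(events["green"].to_numpy(dtype=float), 1e-12, None)
        o = np.clip(events["orange"].to_numpy(dtype=float), 1e-12, None)
        return np.log10(g) - self.slope_k * np.log10(o)

    def is_positive(self, events: pd.DataFrame) -> np.ndarray:
        return self.discriminant(events) >= self.threshold_t

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "live_quantiles": list(self.live_quantiles),
            "slope_k": self.slope_k,
            "threshold_t": self.threshold_t,
            "target_fpr": self.target_fpr,
            "reference_size": self.reference_size,
            "tail_mode": self.tail_mode,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "GateSpec":
        d = json.loads(Path(path).read_text())
        return cls(
            live_quantiles=tuple(d["live_quantiles"]),
            slope_k=float(d["slope_k"]),
            threshold_t=float(d["threshold_t"]),
            target_fpr=float(d["target_fpr"]),
            reference_size=int(d["reference_size"]),
            tail_mode=d["tail_mode"],
        )


@dataclass
class FrequencyEstimate:
    """Recombinant-cell frequency with an exact binomial 95% interval."""

    positives: int
    total_gated: int
    per_million: float
    ci_low_per_million: float
    ci_high_per_million: float

    @property
    def percent(self) -> float:
        return self.per_million / 1e4


def _split_debris(log_fsc: np.ndarray) -> np.ndarray:
    """Boolean mask of events judged debris from the low-scatter mode.

    Otsu's threshold on log FSC separates a distinct low-scatter cluster;
    if the putative debris cluster is implausibly large (the split bisected
    a unimodal population) no event is flagged.
    """
    try:
        thr = threshold_otsu(log_fsc)
    except ValueError:
        return np.zeros(len(log_fsc), dtype=bool)
    debris = log_fsc < thr
    frac = debris.mean()
    if frac == 0 or frac > 0.35:
        return np.zeros(len(log_fsc), dtype=bool)
    return debris


def live_gate(events: pd.DataFrame, spec: Optional[GateSpec] = None) -> pd.DataFrame:
    """Retain live cells: a quantile box on (FSC, SSC) excluding debris.

    The low-scatter debris cluster is identified first and quantile bounds
    are computed on the remaining population, then applied to all events.
    Quantile bounds (0, 1) on both axes make the gate (after debris
    exclusion is bypassed for a debris-free table) the identity.
    """
    if spec is None:
        spec = GateSpec()
    _check_events(events)
    lo_q, hi_q = spec.live_quantiles
    fsc = events["fsc"].to_numpy(dtype=float)
    ssc = events["ssc"].to_numpy(dtype=float)
    if (lo_q, hi_q) == (0.0, 1.0):
        keep = np.ones(len(events), dtype=bool)
    else:
        debris = _split_debris(np.log10(np.clip(fsc, 1e-12, None)))
        ref_fsc, ref_ssc = fsc[~debris], ssc[~debris]
        f_lo, f_hi = np.quantile(ref_fsc, [lo_q, hi_q])
        s_lo, s_hi = np.quantile(ref_ssc, [lo_q, hi_q])
        keep = (fsc >= f_lo) & (fsc <= f_hi) & (ssc >= s_lo) & (ssc <= s_hi)
    if not keep.any():
        warnings.warn("live gate retained no events")
    return events.loc[keep]


def calibrate_gate(
    wt_reference: pd.DataFrame,
    target_fpr: float = 1e-6,
    tail_mode: str = "auto",
    live_quantiles: tuple[float, float] = (0.05, 0.995),
) -> GateSpec:
    """Calibrate the fluorescence gate on an autofluorescent-only reference.

    The slope k is the principal axis of the (log orange, log green)
    reference cloud; the threshold t is set so the expected fraction of
    reference events with discriminant >= t equals ``target_fpr`` —
    empirically (an order-statistic quantile) when the reference holds at
    least 10/target_fpr events, otherwise by Gaussian tail extrapolation of
    the discriminant distribution. ``tail_mode`` is "auto", "empirical"
    (error if the reference is too small) or "gaussian".

    ``target_fpr = 1`` puts the threshold at the reference minimum so every
    event passes.
    """
    if not (0 < target_fpr <= 1):
        raise ValueError("target_fpr must lie in (0, 1]")
    _check_events(wt_reference)
    spec = GateSpec(live_quantiles=live_quantiles, target_fpr=target_fpr)
    live = live_gate(wt_reference, spec)
    n = len(live)
    if n < 10:
        raise ValueError("reference too small to calibrate a gate")

    lg = np.log10(np.clip(live["green"].to_numpy(dtype=float), 1e-12, None))
    lo = np.log10(np.clip(live["orange"].to_numpy(dtype=float), 1e-12, None))
    cov = np.cov(np.vstack([lo, lg]))
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    if major[0] == 0:
        raise ValueError("degenerate reference: no orange-channel variation")
    spec.slope_k = float(major[1] / major[0])

    d = lg - spec.slope_k * lo
    empirical_ok = n >= 10.0 / target_fpr
    if tail_mode == "auto":
        mode = "empirical" if empirical_ok else "gaussian"
    elif tail_mode == "empirical":
        if not empirical_ok:
            raise ValueError(
                f"reference of {n} events cannot support empirical calibration at "
                f"target_fpr={target_fpr:g} (needs >= {10 / target_fpr:.0f}); "
                "use tail_mode='gaussian' for tail extrapolation"
            )
        mode = "empirical"
    elif tail_mode == "gaussian":
        mode = "gaussian"
    else:
        raise ValueError(f"unknown tail_mode {tail_mode!r}")

    if target_fpr == 1.0:
        t = float(d.min())
    elif mode == "empirical":
        t = float(np.quantile(d, 1.0 - target_fpr))
    else:
        z = stats.norm.ppf(1.0 - target_fpr)
        t = float(d.mean() + z * d.std())
    spec.threshold_t = t
    spec.reference_size = n
    spec.tail_mode = mode
    return spec


def _estimate(positives: int, total: int, scale: float) -> FrequencyEstimate:
    ci = stats.binomtest(positives, total).proportion_ci(
        confidence_level=0.95, method="exact"
    )
    return FrequencyEstimate(
        positives=positives,
        total_gated=total,
        per_million=positives / total * scale,
        ci_low_per_million=ci.low * scale,
        ci_high_per_million=ci.high * scale,
    )


def recombinant_frequency(events: pd.DataFrame, gate: GateSpec) -> FrequencyEstimate:
    """Recombinant-cell frequency per million live-gated events."""
    _check_events(events)
    live = live_gate(events, gate)
    total = len(live)
    if total == 0:
        raise ValueError("no events passed the live gate")
    positives = int(gate.is_positive(live).sum())
    return _estimate(positives, total, 1e6)


def percent_positive(events: pd.DataFrame, gate: GateSpec) -> FrequencyEstimate:
    """As :func:`recombinant_frequency` but scaled to percent, for
    high-frequency (positive-control) samples; the ``per_million`` fields
    of the returned estimate hold percentages."""
    _check_events(events)
    live = live_gate(events, gate)
    total = len(live)
    if total == 0:
        raise ValueError("no events passed the live gate")
    positives = int(gate.is_positive(live).sum())
    return _estimate(positives, total, 100.0)
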