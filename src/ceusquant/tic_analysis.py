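"""Time-intensity curves and per-ROI bolus-kinetics metrics.

Given a cine loop and an ROI, this module extracts the time-intensity
curve (TIC) — the per-frame mean 8-bit intensity over the ROI mask,
reported on the [0, 1] scale (mean / 255) — and computes the perfusion
metrics used to compare tissue types:

- peak enhancement (PE): the maximum of the TIC, with the earliest
  maximal frame as peak time;
- AUC: trapezoidal integral of the TIC over seconds (no baseline
  subtraction by default; optional);
- artery-normalized AUC: tissue AUC / artery AUC from the same clip,
  compensating for differing acquisition durations;
- contrast arrival time: first run of frames exceeding the baseline
  mean by k standard deviations of the baseline window;
- a five-phase segmentation of the bolus passage (baseline, wash-in,
  peak, early wash-out, late wash-out);
- intensity threshold highlighting and a frame-to-frame motion score.

Working in [0, 1] units makes the cohort-level PE magnitudes directly
comparable to enhancement values reported in arbitrary units by 8-bit
CEUS quantification software.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ceusquant.cine_io import CineLoop
from ceusquant.roi_geometry import Roi, rasterize

MOTION_FLAG_THRESHOLD = 25.0  # 8-bit mean-absolute-difference units


@dataclass
class TimeIntensityCurve:
    """Mean ROI intensity versus time, on the [0, 1] scale."""

    times_s: np.ndarray
    intensities: np.ndarray
    roi_label: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.shape != self.intensities.shape:
            raise ValueError("times_s and intensities must have equal length")
        if self.times_s.size == 0:
            raise ValueError("TIC must contain at least one sample")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")
        if self.intensities.min() < 0 or self.intensities.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass
class PhaseSegmentation:
    """Frame-index boundaries of the five bolus phases.

    Phases partition [0, last_frame]:
    baseline = [0, baseline_end), wash_in = [baseline_end, washin_end),
    peak = {washin_end}, early_wash_out = (washin_end, early_washout_end],
    late_wash_out = (early_washout_end, last_frame].
    """

    baseline_end: int
    washin_end: int
    early_washout_end: int
    last_frame: int

    def __post_init__(self) -> None:
        if not 0 <= self.baseline_end <= self.washin_end <= self.early_washout_end <= self.last_frame:
            raise ValueError(
                f"phase boundaries must be ordered: 0 <= {self.baseline_end} <= "
                f"{self.washin_end} <= {self.early_washout_end} <= {self.last_frame}"
            )

    def labels(self) -> list[str]:
        """Per-frame phase label for every frame of the clip."""
        out = []
        for k in range(self.last_frame + 1):
            if k < self.baseline_end:
                out.append("baseline")
            elif k < self.washin_end:
                out.append("wash_in")
            elif k == self.washin_end:
                out.append("peak")
            elif k <= self.early_washout_end:
                out.append("early_wash_out")
            else:
                out.append("late_wash_out")
        return out


@dataclass
class TicSummary:
    """Per-ROI metric bundle for one clip."""

    roi_label: str
    patient_id: str
    peak_enhancement: float
    peak_time_s: float
    baseline: float
    arrival_time_s: float | None
    auc: float
    normalized_auc: float | None = None
    phases: PhaseSegmentation | None = None
    motion_flag: bool | None = None


def extract_tic(cine: CineLoop, roi: Roi, patient_id: str = "") -> TimeIntensityCurve:
    """Mean masked intensity per frame, divided by 255.

    Raises a ``ValueError`` naming the ROI label when the ROI does not
    rasterize to at least one pixel within the cine's frame shape.
    """
    try:
        mask = rasterize(roi, cine.frame_shape)
    except ValueError as exc:
        raise ValueError(f"cannot extract TIC for ROI {roi.label!r}: {exc}") from exc
    means = cine.frames[:, mask.mask].mean(axis=1)
    return TimeIntensityCurve(
        times_s=cine.times_s(),
        intensities=means / 255.0,
        roi_label=roi.label,
        patient_id=patient_id,
    )


def peak_enhancement(tic: TimeIntensityCurve) -> tuple[float, float]:
    """(PE, peak time): the TIC maximum and the earliest frame attaining it."""
    idx = int(np.argmax(tic.intensities))  # argmax returns the first maximum
    return float(tic.intensities[idx]), float(tic.times_s[idx])


def auc(
    tic: TimeIntensityCurve,
    baseline_subtract: bool = False,
    baseline: float = 0.0,
) -> float:
    """Trapezoidal integral of the TIC over seconds.

    With ``baseline_subtract`` the integrand is max(intensity - baseline, 0);
    the default integrates the raw curve.
    """
    if len(tic) < 2:
        raise ValueError("AUC requires a TIC with >= 2 samples")
    y = tic.intensities
    if baseline_subtract:
        y = np.maximum(y - baseline, 0.0)
    return float(np.trapezoid(y, tic.times_s))


def normalized_auc(
    tissue_tic: TimeIntensityCurve, artery_tic: TimeIntensityCurve
) -> float:
    """Tissue AUC divided by the artery AUC from the same clip."""
    if tissue_tic.times_s.shape != artery_tic.times_s.shape or not np.allclose(
        tissue_tic.times_s, artery_tic.times_s
    ):
        raise ValueError("tissue and artery TICs must share the same time axis")
    artery_auc = auc(artery_tic)
    if artery_auc == 0:
        raise ValueError("artery AUC is zero: degenerate normalization reference")
    return auc(tissue_tic) / artery_auc


def detect_arrival(
    tic: TimeIntensityCurve,
    baseline_frames: int = 10,
    k_sigma: float = 4.0,
    min_consecutive: int = 3,
) -> tuple[float | None, float]:
    """Detect contrast arrival against the pre-bolus baseline.

    The baseline level is the mean of the first ``baseline_frames``
    samples; arrival is the time of the first frame that begins a run of
    at least ``min_consecutive`` frames all exceeding
    ``baseline + k_sigma * sd(baseline window)`` (sample sd, n-1).
    Returns ``(arrival_time_s or None, baseline)``; ``None`` means no
    detectable enhancement (e.g. a clip started after the bolus, or a
    flat curve).
    """
    if baseline_frames < 2:
        raise ValueError("baseline_frames must be >= 2")
    if len(tic) <= baseline_frames:
        raise ValueError(
            f"TIC length {len(tic)} must exceed baseline window {baseline_frames}"
        )
    window = tic.intensities[:baseline_frames]
    baseline = float(window.mean())
    threshold = baseline + k_sigma * float(window.std(ddof=1))
    above = tic.intensities > threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_consecutive:
            start = i - min_consecutive + 1
            return float(tic.times_s[start]), baseline
    return None, baseline


def segment_phases(
    tic: TimeIntensityCurve,
    arrival_time_s: float,
    baseline: float,
    washout_fraction: float = 0.5,
) -> PhaseSegmentation:
    """Split the clip into the five bolus phases.

    Baseline runs up to the arrival frame; wash-in from arrival to the
    earliest peak frame; early wash-out from the peak until the
    intensity first falls below ``baseline + washout_fraction * (PE -
    baseline)``; late wash-out is the remainder.  If the intensity never
    falls below the cut, early wash-out extends to the last frame and
    late wash-out is empty.
    """
    if arrival_time_s is None:
        raise ValueError("cannot segment phases without a detected arrival")
    if not 0 < washout_fraction < 1:
        raise ValueError(f"washout_fraction must be in (0, 1), got {washout_fraction}")
    arrival_idx = int(np.searchsorted(tic.times_s, arrival_time_s))
    peak_idx = int(np.argmax(tic.intensities))
    if peak_idx < arrival_idx:
        raise ValueError("peak precedes detected arrival; cannot segment phases")
    pe = float(tic.intensities[peak_idx])
    cut = baseline + washout_fraction * (pe - baseline)
    after_peak = tic.intensities[peak_idx + 1 :]
    below = np.nonzero(after_peak < cut)[0]
    last = len(tic) - 1
    if below.size:
        early_end = peak_idx + 1 + int(below[0]) - 1
        early_end = max(early_end, peak_idx)
    else:
        early_end = last
    return PhaseSegmentation(
        baseline_end=arrival_idx,
        washin_end=peak_idx,
        early_washout_end=early_end,
        last_frame=last,
    )


def apply_threshold(frames: np.ndarray, lower: int, upper: int) -> np.ndarray:
    """Highlight enhancing pixels: >= upper -> 255 (white), <= lower -> 0.

    Intermediate gray levels pass through unchanged.  Idempotent.
    """
    if not (0 <= lower <= upper <= 255):
        raise ValueError(f"need 0 <= lower <= upper <= 255, got {lower}, {upper}")
    arr = np.asarray(frames)
    out = arr.copy()
    out[arr <= lower] = 0
    out[arr >= upper] = 255  # upper rule wins when lower == upper
    return out


def motion_score(cine: CineLoop) -> np.ndarray:
    """Mean absolute intensity difference between consecutive frames.

    Returned in 8-bit units, one score per frame pair (length
    n_frames - 1).  A clip is flagged for motion review when any score
    exceeds a caller threshold (default ``MOTION_FLAG_THRESHOLD``);
    flagged clips are reported, never silently dropped.
    """
    if cine.n_frames < 2:
        raise ValueError("motion score requires >= 2 frames")
    f = cine.frames.astype(np.float64)
    return np.abs(np.diff(f, axis=0)).mean(axis=(1, 2))


def motion_flag(cine: CineLoop, threshold: float = MOTION_FLAG_THRESHOLD) -> bool:
    """True when any frame-pair motion score exceeds the threshold."""
    return bool(np.any(motion_score(cine) > threshold))


def summarize_tic(
    tic: TimeIntensityCurve,
    artery_tic: TimeIntensityCurve | None = None,
    baseline_frames: int = 10,
    k_sigma: float = 4.0,
    min_consecutive: int = 3,
    washout_fraction: float = 0.5,
    motion: bool | None = None,
) -> TicSummary:
    """Compute the full per-ROI metric bundle for one TIC.

    When arrival cannot be detected (recordings started after the
    bolus), the summary degrades gracefully: PE and AUC are still
    reported, arrival and phases are absent.
    """
    pe, peak_t = peak_enhancement(tic)
    arrival, baseline = detect_arrival(tic, baseline_frames, k_sigma, min_consecutive)
    phases = None
    if arrival is not None:
        peak_idx = int(np.argmax(tic.intensities))
        arrival_idx = int(np.searchsorted(tic.times_s, arrival))
        if peak_idx >= arrival_idx:
            phases = segment_phases(tic, arrival, baseline, washout_fraction)
    nauc = normalized_auc(tic, artery_tic) if artery_tic is not None else None
    return TicSummary(
        roi_label=tic.roi_label,
        patient_id=tic.patient_id,
        peak_enhancement=pe,
        peak_time_s=peak_t,
        baseline=baseline,
        arrival_time_s=arrival,
        auc=auc(tic),
        normalized_auc=nauc,
        phases=phases,
        motion_flag=motion,
    )


def tics_to_csv(tics: Sequence[TimeIntensityCurve], path: str | Path) -> None:
    """Write TICs as long-format CSV (patient_id, roi_label, frame_index, time_s, intensity)."""
    rows = []
    for tic in tics:
        for k, (t, y) in enumerate(zip(tic.times_s, tic.intensities)):
            rows.append(
                {
                    "patient_id": tic.patient_id,
                    "roi_label": tic.roi_label,
                    "frame_index": k,
                    "time_s": round(float(t), 6),
                    "intensity": round(float(y), 6),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def summaries_to_csv(summaries: Sequence[TicSummary], path: str | Path) -> None:
    """Write per-ROI summaries as CSV, one row per (patient, ROI)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "patient_id": s.patient_id,
                "roi_label": s.roi_label,
                "peak_enhancement": s.peak_enhancement,
                "peak_time_s": s.peak_time_s,
                "baseline": s.baseline,
                "arrival_time_s": s.arrival_time_s,
                "auc": s.auc,
                "normalized_auc": s.normalized_auc,
                "motion_flag": s.motion_flag,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
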