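"""Trace cleaning, baseline correction and trial summarization.

The cleaning chain applies, in order: exclusion of the first trial of
each block, a gross-artifact filter (pupil < 0.1 mm or more than 1 mm
from the trial median), a velocity filter (samples changing faster than
2.5 mm/s plus a 20 ms epoch around them), down-sampling to 10 Hz by
averaging within non-overlapping 100 ms windows, baseline subtraction
(mean of the first 200 ms), and a 40 %-missing validity gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import TrialCondition

__all__ = [
    "RawTrace",
    "TrialRecord",
    "PreprocessingParams",
    "ScreenGeometry",
    "BinnedTrace",
    "CleanTrace",
    "TrialSummary",
    "filter_gross",
    "filter_speed",
    "downsample",
    "baseline_correct",
    "summarize_trial",
    "gaze_to_degrees",
    "preprocess_trial",
    "preprocess_session",
]


@dataclass
class RawTrace:
    """One trial's eye-tracker samples, time-locked to stimulus onset.

    ``pupil_mm`` may contain NaN for samples the tracker lost; those are
    treated as already-missing and removed by the gross filter.
    """

    t_ms: np.ndarray
    pupil_mm: np.ndarray
    gaze_x_px: np.ndarray
    gaze_y_px: np.ndarray
    nominal_rate_hz: float = 500.0

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.pupil_mm = np.asarray(self.pupil_mm, dtype=float)
        self.gaze_x_px = np.asarray(self.gaze_x_px, dtype=float)
        self.gaze_y_px = np.asarray(self.gaze_y_px, dtype=float)
        n = len(self.t_ms)
        if not (len(self.pupil_mm) == len(self.gaze_x_px) == len(self.gaze_y_px) == n):
            raise ValueError("trace channels must have equal length")
        if n > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_ms)

    def take(self, keep: np.ndarray) -> "RawTrace":
        """Return a copy restricted to the boolean/int index ``keep``."""
        return RawTrace(
            t_ms=self.t_ms[keep],
            pupil_mm=self.pupil_mm[keep],
            gaze_x_px=self.gaze_x_px[keep],
            gaze_y_px=self.gaze_y_px[keep],
            nominal_rate_hz=self.nominal_rate_hz,
        )


@dataclass
class TrialRecord:
    """A trial's condition labels, verbal size report and raw trace."""

    participant_id: str
    condition: TrialCondition
    report_mm: float
    trace: RawTrace


@dataclass(frozen=True)
class PreprocessingParams:
    """Thresholds of the cleaning chain (defaults as used in the analysis)."""

    median_dev_max_mm: float = 1.0
    pupil_min_mm: float = 0.1
    speed_max_mm_per_s: float = 2.5
    speed_excision_ms: float = 20.0
    bin_ms: float = 100.0
    baseline_ms: float = 200.0
    missing_frac_max: float = 0.40
    exclude_first_trial_per_block: bool = True
    trial_duration_ms: float = 4000.0

    def __post_init__(self) -> None:
        for name in ("median_dev_max_mm", "pupil_min_mm", "speed_max_mm_per_s",
                     "speed_excision_ms", "bin_ms", "baseline_ms",
                     "trial_duration_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.missing_frac_max <= 1:
            raise ValueError("missing_frac_max must lie in (0, 1]")


@dataclass(frozen=True)
class ScreenGeometry:
    """Linear pixel-to-degree mapping of the display."""

    width_px: int = 1024
    height_px: int = 768
    width_deg: float = 40.0
    height_deg: float = 30.0

    @property
    def center_px(self) -> tuple[float, float]:
        return self.width_px / 2.0, self.height_px / 2.0


@dataclass
class BinnedTrace:
    """10 Hz series after down-sampling; NaN marks empty bins."""

    bin_start_ms: np.ndarray
    pupil_mm: np.ndarray
    gaze_x_px: np.ndarray
    gaze_y_px: np.ndarray


@dataclass
class CleanTrace:
    """Baseline-corrected 10 Hz pupil-change series with gaze in degrees."""

    bin_start_ms: np.ndarray
    pupil_change_mm: np.ndarray  # NaN = missing; never zero-filled
    gaze_x_deg: np.ndarray
    gaze_y_deg: np.ndarray
    baseline_pupil_mm: float  # NaN when no baseline bin was observed
    missing_fraction: float


@dataclass
class TrialSummary:
    """Scalar per-trial outcome row consumed by the statistics layer."""

    participant_id: str
    block: int
    trial: int
    size_level: int
    location: str
    report_mm: float
    pupil_response_mm: float  # NaN for invalid trials
    baseline_pupil_mm: float
    gaze_x_deg: float
    gaze_y_deg: float
    missing_fraction: float
    n_removed_gross: int
    n_removed_speed: int
    valid: bool
    reason: str  # '', 'too_missing', 'no_baseline', 'first_trial', 'empty_trace'


def filter_gross(
    trace: RawTrace, params: PreprocessingParams | None = None
) -> tuple[RawTrace, np.ndarray]:
    """Remove implausibly small or deviant pupil samples.

    A sample is removed when its pupil value is below ``pupil_min_mm``,
    deviates from the trial median by more than ``median_dev_max_mm``, or
    is not finite.  The median is computed once, over all finite raw
    samples of the trial, before any removal.
    """
    params = params or PreprocessingParams()
    if len(trace) == 0:
        return trace, np.array([], dtype=int)
    pupil = trace.pupil_mm
    finite = np.isfinite(pupil)
    med = np.median(pupil[finite]) if finite.any() else np.nan
    bad = ~finite
    with np.errstate(invalid="ignore"):
        bad |= pupil < params.pupil_min_mm
        if np.isfinite(med):
            bad |= np.abs(pupil - med) > params.median_dev_max_mm
    removed = np.flatnonzero(bad)
    return trace.take(~bad), removed


def filter_speed(
    trace: RawTrace, params: PreprocessingParams | None = None
) -> tuple[RawTrace, np.ndarray]:
    """Excise epochs around implausibly fast pupil-size changes.

    The speed at each retained sample is |delta pupil| / delta t versus
    its retained predecessor.  Every sample whose speed exceeds
    ``speed_max_mm_per_s`` marks all samples within +-``speed_excision_ms``/2
    of its own timestamp for removal (a single pass, no iteration).
    """
    params = params or PreprocessingParams()
    n = len(trace)
    if n < 2:
        return trace, np.array([], dtype=int)
    dt_s = np.diff(trace.t_ms) / 1000.0
    speed = np.abs(np.diff(trace.pupil_mm)) / dt_s
    offenders = np.flatnonzero(speed > params.speed_max_mm_per_s) + 1
    if offenders.size == 0:
        return trace, np.array([], dtype=int)
    half = params.speed_excision_ms / 2.0
    bad = np.zeros(n, dtype=bool)
    for i in offenders:
        bad |= np.abs(trace.t_ms - trace.t_ms[i]) <= half
    removed = np.flatnonzero(bad)
    return trace.take(~bad), removed


def downsample(
    trace: RawTrace, params: PreprocessingParams | None = None
) -> BinnedTrace:
    """Average retained samples within non-overlapping 100 ms windows.

    Bins are half-open ``[k*bin_ms, (k+1)*bin_ms)`` from stimulus onset;
    a bin with no retained sample becomes NaN in every channel.
    """
    params = params or PreprocessingParams()
    n_bins = int(round(params.trial_duration_ms / params.bin_ms))
    edges = np.arange(n_bins + 1) * params.bin_ms
    starts = edges[:-1]
    out = {}
    for name in ("pupil_mm", "gaze_x_px", "gaze_y_px"):
        values = getattr(trace, name)
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        if len(trace):
            idx = np.floor_divide(trace.t_ms, params.bin_ms).astype(int)
            ok = (idx >= 0) & (idx < n_bins) & np.isfinite(values)
            np.add.at(sums, idx[ok], values[ok])
            np.add.at(counts, idx[ok], 1)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out[name] = means
    return BinnedTrace(
        bin_start_ms=starts,
        pupil_mm=out["pupil_mm"],
        gaze_x_px=out["gaze_x_px"],
        gaze_y_px=out["gaze_y_px"],
    )


def gaze_to_degrees(
    x_px, y_px, screen: ScreenGeometry | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Map screen pixels to degrees of deviation from screen center.

    The y-axis is flipped so that positive degrees point upward (screen
    rows increase downward).
    """
    screen = screen or ScreenGeometry()
    cx, cy = screen.center_px
    x_deg = (np.asarray(x_px, dtype=float) - cx) * screen.width_deg / screen.width_px
    y_deg = -(np.asarray(y_px, dtype=float) - cy) * screen.height_deg / screen.height_px
    return x_deg, y_deg


def baseline_correct(
    binned: BinnedTrace,
    params: PreprocessingParams | None = None,
    screen: ScreenGeometry | None = None,
) -> CleanTrace:
    """Subtract the mean pupil of bins starting before ``baseline_ms``.

    When every baseline bin is missing, the baseline is NaN and the trial
    is later gated out with reason ``no_baseline``.  Gaze channels are
    converted to degrees from screen center (not baseline-corrected).
    """
    params = params or PreprocessingParams()
    is_baseline = binned.bin_start_ms < params.baseline_ms
    base_vals = binned.pupil_mm[is_baseline]
    base_vals = base_vals[np.isfinite(base_vals)]
    baseline = float(np.mean(base_vals)) if base_vals.size else np.nan
    change = binned.pupil_mm - baseline
    gx, gy = gaze_to_degrees(binned.gaze_x_px, binned.gaze_y_px, screen)
    missing = float(np.mean(~np.isfinite(binned.pupil_mm)))
    return CleanTrace(
        bin_start_ms=binned.bin_start_ms,
        pupil_change_mm=change,
        gaze_x_deg=gx,
        gaze_y_deg=gy,
        baseline_pupil_mm=baseline,
        missing_fraction=missing,
    )


def summarize_trial(
    clean: CleanTrace, params: PreprocessingParams | None = None
) -> tuple[float, float, float, bool, str]:
    """Collapse a clean trace to its response-window summary.

    Returns ``(pupil_response_mm, gaze_x_deg, gaze_y_deg, valid, reason)``.
    The response window is every bin starting at or after ``baseline_ms``;
    a trial is invalid when 40 % or more of its bins are missing or when
    no baseline could be estimated.
    """
    params = params or PreprocessingParams()
    valid = True
    reason = ""
    if not np.isfinite(clean.baseline_pupil_mm):
        valid, reason = False, "no_baseline"
    elif clean.missing_fraction >= params.missing_frac_max:
        valid, reason = False, "too_missing"
    window = clean.bin_start_ms >= params.baseline_ms
    def _window_mean(values: np.ndarray) -> float:
        v = values[window]
        v = v[np.isfinite(v)]
        return float(np.mean(v)) if v.size else np.nan
    if valid:
        pupil_response = _window_mean(clean.pupil_change_mm)
        if not np.isfinite(pupil_response):
            valid, reason = False, "too_missing"
    else:
        pupil_response = np.nan
    return (
        pupil_response,
        _window_mean(clean.gaze_x_deg),
        _window_mean(clean.gaze_y_deg),
        valid,
        reason,
    )


def preprocess_trial(
    record: TrialRecord,
    params: PreprocessingParams | None = None,
    screen: ScreenGeometry | None = None,
) -> TrialSummary:
    """Run steps 2-4 plus baseline correction and gating on one trial."""
    params = params or PreprocessingParams()
    cond = record.condition
    if len(record.trace) == 0:
        return TrialSummary(
            participant_id=record.participant_id, block=cond.block,
            trial=cond.trial_index_in_block, size_level=cond.size_level,
            location=cond.location, report_mm=record.report_mm,
            pupil_response_mm=np.nan, baseline_pupil_mm=np.nan,
            gaze_x_deg=np.nan, gaze_y_deg=np.nan, missing_fraction=1.0,
            n_removed_gross=0, n_removed_speed=0, valid=False,
            reason="empty_trace",
        )
    after_gross, removed_gross = filter_gross(record.trace, params)
    after_speed, removed_speed = filter_speed(after_gross, params)
    binned = downsample(after_speed, params)
    clean = baseline_correct(binned, params, screen)
    pupil_response, gx, gy, valid, reason = summarize_trial(clean, params)
    return TrialSummary(
        participant_id=record.participant_id,
        block=cond.block,
        trial=cond.trial_index_in_block,
        size_level=cond.size_level,
        location=cond.location,
        report_mm=record.report_mm,
        pupil_response_mm=pupil_response,
        baseline_pupil_mm=clean.baseline_pupil_mm,
        gaze_x_deg=gx,
        gaze_y_deg=gy,
        missing_fraction=clean.missing_fraction,
        n_removed_gross=int(removed_gross.size),
        n_removed_speed=int(removed_speed.size),
        valid=valid,
        reason=reason,
    )


def preprocess_session(
    trials: Sequence[TrialRecord],
    params: PreprocessingParams | None = None,
    screen: ScreenGeometry | None = None,
) -> tuple[list[TrialSummary], pd.DataFrame]:
    """Preprocess a whole session; returns summaries and the exclusion log.

    The first trial of each block is dropped before any filtering (it is
    logged with reason ``first_trial`` but yields no summary).  The log
    has one row per input trial.
    """
    params = params or PreprocessingParams()
    summaries: list[TrialSummary] = []
    log_rows: list[dict] = []
    for record in trials:
        cond = record.condition
        row = {
            "participant_id": record.participant_id,
            "block": cond.block,
            "trial": cond.trial_index_in_block,
            "n_removed_gross": 0,
            "n_removed_speed": 0,
            "missing_fraction": np.nan,
            "valid": False,
            "reason": "",
        }
        if params.exclude_first_trial_per_block and cond.trial_index_in_block == 1:
            row["reason"] = "first_trial"
            log_rows.append(row)
            continue
        summary = preprocess_trial(record, params, screen)
        summaries.append(summary)
        row.update(
            n_removed_gross=summary.n_removed_gross,
            n_removed_speed=summary.n_removed_speed,
            missing_fraction=summary.missing_fraction,
            valid=summary.valid,
            reason=summary.reason,
        )
        log_rows.append(row)
    return summaries, pd.DataFrame(log_rows)


def summaries_to_frame(summaries: Sequence[TrialSummary]) -> pd.DataFrame:
    """Tabulate trial summaries for the statistics layer."""
    return pd.DataFrame([s.__dict__ for s in summaries])
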