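"""Synthetic session generator with ground truth.

Produces 500 Hz pupil/gaze traces whose light-response amplitude is
driven by the *perceived* (context-inflated) stimulus size, plus verbal
size reports, blink/spike artifacts, gaze offsets tied to location and
size, and AQ scores that modulate the contextual gain of the pupil
pathway.  Every quantity needed to verify the downstream pipeline is
recorded as ground truth.

The generative model per trial is

    pupil(t) = baseline - A(p) * K(t - latency) + noise,

with a unit-peak gamma kernel K and a saturating amplitude
``A(p) = a_max * (1 - exp(-g * p^2 / a_max))`` in the perceived height
``p`` (degrees).  Constriction scaling with perceived *area* (p^2)
reflects light-flux scaling; the saturation produces a size-by-location
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import AQScore, StimulusSet, TrialCondition, build_trial_list
from .preprocess import RawTrace, TrialRecord

__all__ = [
    "SimulationConfig",
    "SimulatedSession",
    "context_gain",
    "perceived_height",
    "pupil_amplitude",
    "gamma_kernel",
    "expected_pupil_response",
    "simulate_trial_trace",
    "inject_artifacts",
    "simulate_report",
    "simulate_session",
    "simulate_dataset",
    "simulate_summary_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator (defaults emulate a realistic study).

    ``context_gain_c0`` is the fractional perceived-size inflation of far
    stimuli for a participant at the minimum AQ; it decays linearly in
    normalized AQ with slope ``aq_coupling_beta`` and is floored at 0.
    ``report_context_gain`` is the (AQ-independent) inflation used for
    the verbal-report pathway; set it to ``None`` to couple reports to
    the same AQ-dependent gain as the pupil.
    """

    n_participants: int = 50
    seed: int = 0

    # participant-level sampling
    aq_min: int = 2
    aq_max: int = 31
    p_female: float = 0.66

    # timeline & acquisition
    sampling_rate_hz: float = 500.0
    fixation_s: float = 1.0
    stimulus_s: float = 4.0

    # pupil dynamics
    baseline_pupil_mm: float = 4.26
    baseline_between_sd_mm: float = 0.7
    baseline_trial_sd_mm: float = 0.05
    response_latency_s: float = 0.2
    kernel_shape: float = 2.0
    kernel_tau_s: float = 0.5
    gain_g: float = 0.015
    saturation_a_max: float = 1.0
    amplitude_jitter_mm: float = 0.05

    # contextual (illusory) size inflation
    context_gain_c0: float = 0.15
    aq_coupling_beta: float = 2.0
    report_context_gain: float | None = 0.15

    # verbal reports
    report_scale_mm_per_deg: float = 10.0
    report_weber: float = 0.10

    # gaze
    pixels_per_degree: float = 25.6
    gaze_near_deg: tuple[float, float] = (0.0, -4.0)
    gaze_far_deg: tuple[float, float] = (4.0, 4.0)
    gaze_size_gain: float = 0.3  # deg of vertical gaze per deg of height above base
    gaze_jitter_deg: float = 0.3

    # artifacts & noise
    blink_rate_hz: float = 0.10
    blink_dur_ms: float = 120.0
    loss_rate_hz: float = 0.08
    loss_dur_ms: float = 2000.0
    spike_rate_hz: float = 0.05
    spike_amp_mm: float = 2.0
    blink_as_gap: bool = False  # emit NaN gaps instead of sub-0.1 mm runs
    noise_sd_mm: float = 0.01
    noise_knot_ms: float = 100.0

    stimulus_set: StimulusSet = field(default_factory=StimulusSet)
    keep_clean_traces: bool = False

    def __post_init__(self) -> None:
        for name in ("sampling_rate_hz", "stimulus_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gain_g", "saturation_a_max", "context_gain_c0",
                     "aq_coupling_beta", "report_weber", "blink_rate_hz",
                     "spike_rate_hz", "loss_rate_hz", "noise_sd_mm",
                     "amplitude_jitter_mm", "response_latency_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.aq_max <= self.aq_min:
            raise ValueError("aq_max must exceed aq_min")

    @property
    def n_samples(self) -> int:
        return int(round(self.stimulus_s * self.sampling_rate_hz))

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz


@dataclass
class SimulatedSession:
    """One participant's trials plus generator ground truth."""

    participant_id: str
    aq_score: AQScore
    gender: str  # 'F' or 'M'
    baseline_mm: float
    trials: list[TrialRecord]
    ground_truth: pd.DataFrame  # one row per trial
    clean_traces: list[np.ndarray] | None = None


def context_gain(aq: int | AQScore, cfg: SimulationConfig) -> float:
    """AQ-dependent fractional size inflation for far stimuli (>= 0)."""
    score = aq.score if isinstance(aq, AQScore) else int(aq)
    norm = (score - cfg.aq_min) / (cfg.aq_max - cfg.aq_min)
    return cfg.context_gain_c0 * max(0.0, 1.0 - cfg.aq_coupling_beta * norm)


def perceived_height(
    physical_deg: float,
    location: str,
    aq: int | AQScore,
    cfg: SimulationConfig,
) -> float:
    """Perceived height driving the pupil pathway.

    Near stimuli are the reference (perceived = physical); far stimuli
    are inflated by the participant's contextual gain.
    """
    if physical_deg <= 0:
        raise ValueError("physical_deg must be positive")
    if location == "near":
        return float(physical_deg)
    if location == "far":
        return float(physical_deg * (1.0 + context_gain(aq, cfg)))
    raise ValueError(f"unknown location: {location!r}")


def _perceived_for_report(
    physical_deg: float, location: str, aq: int | AQScore, cfg: SimulationConfig
) -> float:
    """Perceived height driving the verbal report pathway."""
    if cfg.report_context_gain is None:
        return perceived_height(physical_deg, location, aq, cfg)
    if location == "near":
        return float(physical_deg)
    return float(physical_deg * (1.0 + cfg.report_context_gain))


def pupil_amplitude(perceived_deg: float, cfg: SimulationConfig) -> float:
    """Saturating constriction amplitude A(p), strictly increasing in p."""
    if cfg.gain_g == 0:
        return 0.0
    a = cfg.saturation_a_max
    return float(a * (1.0 - np.exp(-cfg.gain_g * perceived_deg**2 / a)))


def gamma_kernel(t_s: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Unit-peak gamma impulse response; zero for t <= 0.

    Peaks at ``kernel_shape * kernel_tau_s`` seconds.
    """
    t = np.asarray(t_s, dtype=float)
    peak = cfg.kernel_shape * cfg.kernel_tau_s
    with np.errstate(invalid="ignore", divide="ignore"):
        k = (t / peak) ** cfg.kernel_shape * np.exp(
            cfg.kernel_shape * (1.0 - t / peak)
        )
    return np.where(t > 0, k, 0.0)


def _kernel_window_mean(cfg: SimulationConfig, baseline_ms: float = 200.0,
                        bin_ms: float = 100.0) -> float:
    """Mean of the binned kernel over the response window, baseline-corrected.

    Mirrors the pipeline exactly: bin the 500 Hz kernel into 100 ms
    windows, subtract the mean of the bins before ``baseline_ms``, then
    average the remaining bins.
    """
    t_ms = np.arange(cfg.n_samples) * cfg.dt_ms
    k = gamma_kernel(t_ms / 1000.0 - cfg.response_latency_s, cfg)
    n_bins = int(round(cfg.stimulus_s * 1000.0 / bin_ms))
    idx = np.floor_divide(t_ms, bin_ms).astype(int)
    binned = np.bincount(idx, weights=k, minlength=n_bins) / np.bincount(
        idx, minlength=n_bins
    )
    starts = np.arange(n_bins) * bin_ms
    base = binned[starts < baseline_ms].mean()
    return float(binned[starts >= baseline_ms].mean() - base)


def expected_pupil_response(
    perceived_deg: float, cfg: SimulationConfig
) -> float:
    """Noise-free pupil response (mm) the pipeline recovers for this trial."""
    return -pupil_amplitude(perceived_deg, cfg) * _kernel_window_mean(cfg)


def _smooth_noise(n: int, dt_ms: float, sd: float, knot_ms: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise: normal knots, linearly interpolated."""
    if sd == 0:
        return np.zeros(n)
    t = np.arange(n) * dt_ms
    knots = np.arange(0.0, t[-1] + knot_ms, knot_ms)
    values = rng.normal(0.0, sd, size=len(knots))
    return np.interp(t, knots, values)


def simulate_trial_trace(
    condition: TrialCondition,
    perceived_deg: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    baseline_mm: float | None = None,
) -> tuple[RawTrace, dict]:
    """Simulate one artifact-free trial trace.

    Returns the trace and a ground-truth dict with the clean pupil
    vector, the realized amplitude and the gaze means.
    """
    baseline = cfg.baseline_pupil_mm if baseline_mm is None else baseline_mm
    baseline = baseline + rng.normal(0.0, cfg.baseline_trial_sd_mm)
    t_ms = np.arange(cfg.n_samples) * cfg.dt_ms
    kernel = gamma_kernel(t_ms / 1000.0 - cfg.response_latency_s, cfg)
    amplitude = pupil_amplitude(perceived_deg, cfg)
    amplitude += rng.normal(0.0, cfg.amplitude_jitter_mm)
    clean = baseline - amplitude * kernel
    pupil = clean + _smooth_noise(
        cfg.n_samples, cfg.dt_ms, cfg.noise_sd_mm, cfg.noise_knot_ms, rng
    )

    mean_deg = cfg.gaze_near_deg if condition.location == "near" else cfg.gaze_far_deg
    height = cfg.stimulus_set.height_for_level(condition.size_level)
    gx_deg = mean_deg[0]
    gy_deg = mean_deg[1] + cfg.gaze_size_gain * (
        height - cfg.stimulus_set.base_height_deg
    )
    ppd = cfg.pixels_per_degree
    gx = 512.0 + (gx_deg + _smooth_noise(cfg.n_samples, cfg.dt_ms,
                                         cfg.gaze_jitter_deg, 200.0, rng)) * ppd
    gy = 384.0 - (gy_deg + _smooth_noise(cfg.n_samples, cfg.dt_ms,
                                         cfg.gaze_jitter_deg, 200.0, rng)) * ppd
    trace = RawTrace(t_ms=t_ms, pupil_mm=pupil, gaze_x_px=gx, gaze_y_px=gy,
                     nominal_rate_hz=cfg.sampling_rate_hz)
    truth = {
        "clean_pupil_mm": clean,
        "amplitude_mm": amplitude,
        "baseline_mm": baseline,
        "gaze_x_deg": gx_deg,
        "gaze_y_deg": gy_deg,
    }
    return trace, truth


def inject_artifacts(
    trace: RawTrace, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[RawTrace, np.ndarray]:
    """Corrupt a trace with blinks, long signal losses and spikes.

    Blinks and losses are contiguous runs driven below 0.1 mm (or set to
    NaN when ``blink_as_gap``); spikes are isolated +-``spike_amp_mm``
    displacements.  Returns the corrupted trace and the exact sample
    indices touched.
    """
    n = len(trace)
    pupil = trace.pupil_mm.copy()
    duration_s = n / cfg.sampling_rate_hz
    corrupted = np.zeros(n, dtype=bool)

    for rate, dur_ms in ((cfg.blink_rate_hz, cfg.blink_dur_ms),
                         (cfg.loss_rate_hz, cfg.loss_dur_ms)):
        if rate <= 0:
            continue
        n_events = rng.poisson(rate * duration_s)
        run = max(1, int(round(dur_ms * cfg.sampling_rate_hz / 1000.0)))
        for _ in range(n_events):
            start = int(rng.integers(0, n))
            stop = min(n, start + run)
            pupil[start:stop] = np.nan if cfg.blink_as_gap else 0.0
            corrupted[start:stop] = True

    if cfg.spike_rate_hz > 0:
        n_spikes = rng.poisson(cfg.spike_rate_hz * duration_s)
        for _ in range(n_spikes):
            i = int(rng.integers(0, n))
            pupil[i] += cfg.spike_amp_mm * rng.choice((-1.0, 1.0))
            corrupted[i] = True
    # trackers never report negative diameters
    with np.errstate(invalid="ignore"):
        np.clip(pupil, 0.0, None, out=pupil)

    out = RawTrace(t_ms=trace.t_ms, pupil_mm=pupil, gaze_x_px=trace.gaze_x_px,
                   gaze_y_px=trace.gaze_y_px, nominal_rate_hz=trace.nominal_rate_hz)
    return out, np.flatnonzero(corrupted)


def simulate_report(
    perceived_deg: float, cfg: SimulationConfig, rng: np.random.Generator
) -> float:
    """Verbal size estimate in mm: multiplicative Weber-like noise."""
    noise = rng.normal(0.0, cfg.report_weber) if cfg.report_weber > 0 else 0.0
    return float(cfg.report_scale_mm_per_deg * perceived_deg * (1.0 + noise))


def _participant_rng(cfg: SimulationConfig, participant_index: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, participant_index])


def _draw_participant(cfg: SimulationConfig, rng: np.random.Generator):
    aq = AQScore(int(rng.integers(cfg.aq_min, cfg.aq_max + 1)))
    gender = "F" if rng.random() < cfg.p_female else "M"
    baseline = float(rng.normal(cfg.baseline_pupil_mm, cfg.baseline_between_sd_mm))
    baseline = float(np.clip(baseline, 2.0, 8.0))
    return aq, gender, baseline


def simulate_session(
    cfg: SimulationConfig, participant_index: int
) -> SimulatedSession:
    """Simulate one participant's full 100-trial session.

    Fully reproducible from ``(cfg.seed, participant_index)``.
    """
    rng = _participant_rng(cfg, participant_index)
    pid = f"p{participant_index:03d}"
    aq, gender, baseline = _draw_participant(cfg, rng)
    trial_seed = int(rng.integers(0, 2**31 - 1))
    conditions = build_trial_list(trial_seed)

    records: list[TrialRecord] = []
    truth_rows: list[dict] = []
    clean_traces: list[np.ndarray] | None = [] if cfg.keep_clean_traces else None
    for cond in conditions:
        height = cfg.stimulus_set.height_for_level(cond.size_level)
        p_pupil = perceived_height(height, cond.location, aq, cfg)
        p_report = _perceived_for_report(height, cond.location, aq, cfg)
        trace, truth = simulate_trial_trace(cond, p_pupil, cfg, rng, baseline)
        trace, corrupted = inject_artifacts(trace, cfg, rng)
        report = simulate_report(p_report, cfg, rng)
        records.append(TrialRecord(participant_id=pid, condition=cond,
                                   report_mm=report, trace=trace))
        truth_rows.append({
            "participant_id": pid,
            "block": cond.block,
            "trial": cond.trial_index_in_block,
            "size_level": cond.size_level,
            "location": cond.location,
            "physical_height_deg": height,
            "perceived_height_deg": p_pupil,
            "perceived_report_deg": p_report,
            "context_gain": context_gain(aq, cfg),
            "amplitude_mm": truth["amplitude_mm"],
            "baseline_mm": truth["baseline_mm"],
            "gaze_x_deg": truth["gaze_x_deg"],
            "gaze_y_deg": truth["gaze_y_deg"],
            "n_corrupted": int(corrupted.size),
            "corrupted_sample_indices": ";".join(map(str, corrupted)),
        })
        if clean_traces is not None:
            clean_traces.append(truth["clean_pupil_mm"])
    return SimulatedSession(
        participant_id=pid,
        aq_score=aq,
        gender=gender,
        baseline_mm=baseline,
        trials=records,
        ground_truth=pd.DataFrame(truth_rows),
        clean_traces=clean_traces,
    )


def simulate_dataset(cfg: SimulationConfig) -> list[SimulatedSession]:
    """Simulate all participants of a study."""
    return [simulate_session(cfg, i) for i in range(cfg.n_participants)]


def simulate_summary_dataset(
    cfg: SimulationConfig,
    trial_noise_sd_mm: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast trial-summary-level simulation (no traces).

    Draws per-trial pupil responses directly from the marginal of the
    trace model: ``response = -(A(p) + jitter) * Kbar + 0`` where
    ``Kbar`` is the baseline-corrected response-window mean of the
    kernel, and jitter is the amplitude noise.  Reports use the same
    model as the trace path.  Used for large parameter-recovery sweeps;
    equivalence with the trace path is asserted in the tests.

    Returns ``(trial table, participant table)`` in the same layout the
    preprocessing layer emits.
    """
    kbar = _kernel_window_mean(cfg)
    noise_sd = (cfg.amplitude_jitter_mm * abs(kbar)
                if trial_noise_sd_mm is None else trial_noise_sd_mm)
    trial_rows: list[dict] = []
    part_rows: list[dict] = []
    for i in range(cfg.n_participants):
        rng = _participant_rng(cfg, i)
        pid = f"p{i:03d}"
        aq, gender, baseline = _draw_participant(cfg, rng)
        trial_seed = int(rng.integers(0, 2**31 - 1))
        part_rows.append({"participant_id": pid, "aq": aq.score,
                          "gender": gender, "baseline_mm": baseline})
        for cond in build_trial_list(trial_seed):
            if cond.trial_index_in_block == 1:
                continue  # dropped by the pipeline anyway
            height = cfg.stimulus_set.height_for_level(cond.size_level)
            p_pupil = perceived_height(height, cond.location, aq, cfg)
            p_report = _perceived_for_report(height, cond.location, aq, cfg)
            response = -pupil_amplitude(p_pupil, cfg) * kbar + rng.normal(0, noise_sd)
            trial_rows.append({
                "participant_id": pid,
                "block": cond.block,
                "trial": cond.trial_index_in_block,
                "size_level": cond.size_level,
                "location": cond.location,
                "report_mm": simulate_report(p_report, cfg, rng),
                "pupil_response_mm": response,
                "baseline_pupil_mm": baseline + rng.normal(0, cfg.baseline_trial_sd_mm),
                "gaze_x_deg": (cfg.gaze_near_deg if cond.location == "near"
                               else cfg.gaze_far_deg)[0] + rng.normal(0, 0.1),
                "gaze_y_deg": (cfg.gaze_near_deg if cond.location == "near"
                               else cfg.gaze_far_deg)[1]
                + cfg.gaze_size_gain * (height - cfg.stimulus_set.base_height_deg)
                + rng.normal(0, 0.1),
                "missing_fraction": 0.0,
                "n_removed_gross": 0,
                "n_removed_speed": 0,
                "valid": True,
                "reason": "",
            })
    return pd.DataFrame(trial_rows), pd.DataFrame(part_rows)
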