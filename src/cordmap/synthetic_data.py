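"""Synthetic intraoperative stimulation cohorts with known ground truth.

Emulates the mapping protocol: at each participant, an intensity ramp
(0–8 mA, >= 5 MEPs per intensity) at the most caudal exposed segment for the
midline and lateral electrode positions, followed by fixed-intensity blocks
(~15 sweeps each) at 120 % of the midline threshold at every exposed segment
and both positions.  Stimulation uses trains of three pulses every 2 s;
recording emulates 6–10.4 kHz sampling with 10–2,000 Hz band-pass character
and optional hardware clipping at 0.5 mV.

Ground truth is defined on the AUC scale: each (participant, muscle,
segment, position) carries softplus recruitment parameters (offset, slope,
threshold); the template amplitude of each simulated MEP is solved so that
the rectified windowed integral of the clean trace equals the target AUC.
The lateral-over-midline advantage is planted both as a threshold shift
(midline = lateral + shift) and a slope attenuation (midline = factor x
lateral), mirroring the observation that lateral stimulation has both lower
threshold and steeper recruitment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
import numpy as np
from scipy import signal

from .features import DEFAULT_WINDOW_MS, window_mask
from .sweeps import SEGMENT_INDEX, SEGMENTS, ConfigurationError, SweepRecord

logger = logging.getLogger(__name__)

DEFAULT_ARM_MUSCLES = ("deltoid", "biceps", "triceps", "APB", "ADM", "FDI")
DEFAULT_LEG_MUSCLES = ("TA", "EDB", "AH")

#: Segment of dominant innervation used to tune per-segment slopes.
INNERVATION_CENTER = {
    "deltoid": "C5",
    "biceps": "C5",
    "triceps": "C7",
    "APB": "T1",
    "ADM": "C8",
    "FDI": "C8",
}

#: Mean onset latency per muscle, ms (increasing arm < hand < leg).
LATENCY_MEAN_MS = {
    "deltoid": 11.0,
    "biceps": 12.0,
    "triceps": 13.0,
    "APB": 19.0,
    "ADM": 18.5,
    "FDI": 18.0,
    "TA": 30.0,
    "EDB": 38.0,
    "AH": 40.0,
}

#: Template shapes: (dominant frequency Hz, decay time constant ms).
TEMPLATE_SHAPES = {0: (140.0, 7.0), 1: (90.0, 10.0), 2: (190.0, 5.0)}


@dataclass(frozen=True)
class CohortConfig:
    """Stated world of a simulated cohort.

    Defaults follow the intraoperative protocol: 14 participants (the
    midline-vs-lateral comparison cohort), segments C4–T1, six arm and three
    leg muscles on both sides, 6 kHz sampling, triple-pulse stimulation,
    ramped 0–8 mA sweeps with 5 MEPs per intensity and 15-sweep
    fixed-intensity blocks, hardware clipping at 500 µV.
    """

    n_participants: int = 14
    segments_per_participant: tuple[str, ...] = SEGMENTS
    arm_muscles: tuple[str, ...] = DEFAULT_ARM_MUSCLES
    leg_muscles: tuple[str, ...] = DEFAULT_LEG_MUSCLES
    sides: tuple[str, ...] = ("left", "right")
    sampling_rate: float = 6000.0
    pulse_count: int = 3
    interpulse_interval_ms: float = 3.0
    sweeps_per_fixed_block: int = 15
    ramp_intensities: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
    sweeps_per_intensity: int = 5
    clip_level: float = 500.0  # µV
    noise_sd: float = 3.0  # µV trace noise
    auc_cv: float = 0.2  # trial-to-trial MEP size coefficient of variation
    artifact_rate: float = 0.015
    seed: int = 0
    # planted lateral-over-midline advantage
    midline_slope_attenuation: float = 0.75  # midline slope = factor * lateral
    midline_threshold_shift: float = 1.9  # mA added to lateral threshold
    # recording window
    pre_stim_s: float = 0.030
    post_stim_s: float = 0.100
    # secondary realism knobs
    contralateral_factor: float = 0.15
    leg_response_prob: float = 0.45

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not (self.arm_muscles or self.leg_muscles):
            raise ConfigurationError("muscle list is empty")
        unknown = [s for s in self.segments_per_participant if s not in SEGMENT_INDEX]
        if unknown:
            raise ConfigurationError(f"unknown segment labels: {unknown}")
        if not self.segments_per_participant:
            raise ConfigurationError("segments_per_participant is empty")
        if any(x < 0 or x > 8 for x in self.ramp_intensities):
            raise ConfigurationError("ramp intensities must lie within [0, 8] mA")
        if self.sweeps_per_intensity < 5:
            raise ConfigurationError("sweeps_per_intensity must be >= 5")
        if not (6000.0 <= self.sampling_rate <= 10400.0):
            raise ConfigurationError("sampling_rate must lie in [6000, 10400] Hz")
        if self.pulse_count not in (1, 3):
            raise ConfigurationError("pulse_count must be 1 or 3")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ConfigurationError("artifact_rate must be a probability")

    @property
    def muscles(self) -> tuple[str, ...]:
        return tuple(self.arm_muscles) + tuple(self.leg_muscles)

    @property
    def ordered_segments(self) -> tuple[str, ...]:
        return tuple(sorted(self.segments_per_participant, key=SEGMENT_INDEX.get))


@dataclass
class RecruitParams:
    """Softplus recruitment ground truth for one muscle x site."""

    offset: float  # µVs, shared across locations within (participant, muscle)
    slope: float  # µVs/mA
    threshold: float  # mA

    def auc_at(self, x: float, k: float = 20.0) -> float:
        return self.offset + self.slope / k * float(np.logaddexp(0.0, k * (x - self.threshold)))


@dataclass
class GroundTruth:
    """Planted parameters of a simulated cohort plus per-sweep artifact labels."""

    config: CohortConfig
    params: dict  # (pid, muscle, segment, position) -> RecruitParams
    latency_ms: dict  # (pid, muscle) -> float
    shape_id: dict  # (pid, muscle) -> int
    stimulated_side: dict  # pid -> side
    midline_threshold: dict  # pid -> mA used to set the fixed intensity
    fixed_intensity: dict  # pid -> mA (120 % of midline threshold)
    artifact_labels: dict = field(default_factory=dict)  # sweep_id -> bool

    def expected_auc(self, pid, muscle, segment, position, side, intensity, k=20.0):
        """Ground-truth mean AUC (µVs) for a channel at a stimulus intensity."""
        p = self.params[(pid, muscle, segment, position)]
        slope = p.slope
        if side != self.stimulated_side[pid]:
            slope *= self.config.contralateral_factor
        return p.offset + slope / k * float(
            np.logaddexp(0.0, k * (intensity - p.threshold))
        )

    def to_json(self) -> dict:
        return {
            "params": {
                "|".join(map(str, k)): asdict(v) for k, v in self.params.items()
            },
            "latency_ms": {"|".join(k): v for k, v in self.latency_ms.items()},
            "shape_id": {"|".join(k): v for k, v in self.shape_id.items()},
            "stimulated_side": self.stimulated_side,
            "midline_threshold": self.midline_threshold,
            "fixed_intensity": self.fixed_intensity,
            "artifact_labels": {str(k): bool(v) for k, v in self.artifact_labels.items()},
        }


# ---------------------------------------------------------------------------
# MEP template


def mep_template(
    latency_ms: float,
    amplitude_uv: float,
    shape_id: int,
    sampling_rate: float,
    duration_ms: float = 100.0,
) -> np.ndarray:
    """Compact biphasic/triphasic MEP waveform aligned to the first pulse.

    Zero before ``latency_ms``; peak-peak equals ``amplitude_uv`` exactly
    (by normalization).  The waveform is a decaying sinusoid whose dominant
    frequency and decay constant depend on ``shape_id``.
    """
    if latency_ms >= duration_ms:
        raise ValueError(
            f"latency {latency_ms} ms is outside the {duration_ms} ms recording window"
        )
    freq, tau = TEMPLATE_SHAPES[int(shape_id) % len(TEMPLATE_SHAPES)]
    n = int(round(duration_ms / 1000.0 * sampling_rate))
    t = np.arange(n) / sampling_rate * 1000.0  # ms
    rel = t - latency_ms
    w = np.where(
        rel >= 0,
        np.sin(2 * np.pi * freq * rel / 1000.0) * np.exp(-np.maximum(rel, 0.0) / tau),
        0.0,
    )
    pp = w.max() - w.min()
    if amplitude_uv == 0 or pp == 0:
        return np.zeros(n)
    return w * (amplitude_uv / pp)


def template_unit_auc(
    latency_ms: float,
    shape_id: int,
    sampling_rate: float,
    pre_stim_s: float,
    post_stim_s: float,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> float:
    """Rectified windowed AUC (µVs) of a unit-amplitude template on the trace grid.

    Computed with the same trapezoid rule and window mask as the feature
    extractor, so an amplitude of ``target_auc / unit_auc`` reproduces the
    target AUC exactly in the noiseless case.
    """
    pre = int(round(pre_stim_s * sampling_rate))
    w = mep_template(latency_ms, 1.0, shape_id, sampling_rate, post_stim_s * 1000.0)
    trace = np.concatenate([np.zeros(pre), w])
    t = (np.arange(trace.size) - pre) / sampling_rate * 1000.0
    m = window_mask(t, window_ms)
    return float(np.trapezoid(np.abs(trace[m]), t[m] / 1000.0))


# ---------------------------------------------------------------------------
# Artifacts


@dataclass(frozen=True)
class ArtifactSpec:
    """Amplitudes of the four contamination classes, µV."""

    rate: float = 0.05
    drift_uv: float = 200.0
    stim_tail_uv: float = 300.0
    line_uv: float = 80.0
    transient_uv: float = 150.0

    classes: tuple[str, ...] = ("drift", "stim_tail", "line_noise", "transient")


def artifact_waveform(
    kind: str,
    n_samples: int,
    stim_onset_index: int,
    sampling_rate: float,
    amplitude_uv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One artifact realization of the given class on the trace grid."""
    t = np.arange(n_samples) / sampling_rate
    if kind == "drift":
        sign = rng.choice([-1.0, 1.0])
        return sign * amplitude_uv * t / t[-1]
    if kind == "stim_tail":
        tau = 0.008 * (0.5 + rng.random())  # 4–8 ms decay into the window
        rel = t - stim_onset_index / sampling_rate
        return amplitude_uv * np.where(rel >= 0, np.exp(-np.maximum(rel, 0) / tau), 0.0)
    if kind == "line_noise":
        phase = rng.uniform(0, 2 * np.pi)
        return amplitude_uv * np.sin(2 * np.pi * 60.0 * t + phase)
    if kind == "transient":
        center = rng.uniform(0.1, 0.9) * t[-1]
        width = 0.002 * (0.5 + rng.random())
        sign = rng.choice([-1.0, 1.0])
        return sign * amplitude_uv * np.exp(-0.5 * ((t - center) / width) ** 2)
    raise ValueError(f"unknown artifact class {kind!r}")


def inject_artifacts(
    trace: np.ndarray,
    artifact_spec: ArtifactSpec,
    rng: np.random.Generator,
    stim_onset_index: int = 0,
    sampling_rate: float = 6000.0,
) -> tuple[np.ndarray, bool]:
    """Contaminate a trace with probability ``artifact_spec.rate``.

    Returns ``(trace, label)`` where ``label`` is True iff an artifact was
    injected (the ground truth for rejection tests).  The input trace is not
    modified.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    if artifact_spec.rate <= 0 or rng.random() >= artifact_spec.rate:
        return trace, False
    kind = artifact_spec.classes[rng.integers(len(artifact_spec.classes))]
    amp = {
        "drift": artifact_spec.drift_uv,
        "stim_tail": artifact_spec.stim_tail_uv,
        "line_noise": artifact_spec.line_uv,
        "transient": artifact_spec.transient_uv,
    }[kind]
    w = artifact_waveform(kind, trace.size, stim_onset_index, sampling_rate, amp, rng)
    return trace + w, True


# ---------------------------------------------------------------------------
# Ground-truth construction


def _draw_ground_truth(config: CohortConfig, rng: np.random.Generator) -> GroundTruth:
    params: dict = {}
    latency: dict = {}
    shapes: dict = {}
    stim_side: dict = {}
    mid_thr: dict = {}
    fixed: dict = {}
    segs = config.ordered_segments
    for ip in range(config.n_participants):
        pid = f"P{ip + 1:02d}"
        stim_side[pid] = "left" if "left" in config.sides else config.sides[0]
        p_scale = float(np.exp(rng.normal(0.0, 0.4)))
        base_lat_thr = float(np.clip(rng.normal(1.75, 0.3), 0.8, 3.0))
        for m in config.muscles:
            is_leg = m in config.leg_muscles
            latency[(pid, m)] = float(
                max(5.0, rng.normal(LATENCY_MEAN_MS.get(m, 15.0), 1.0))
            )
            shapes[(pid, m)] = int(rng.integers(len(TEMPLATE_SHAPES)))
            offset = float(rng.uniform(0.01, 0.08))
            if is_leg:
                responds = rng.random() < config.leg_response_prob
                base_slope = 0.5 * p_scale if responds else 0.0
                center_idx = None
            else:
                base_slope = 2.0 * p_scale
                center = INNERVATION_CENTER.get(m)
                center_idx = (
                    SEGMENT_INDEX[center]
                    if center is not None
                    else int(rng.integers(len(SEGMENTS)))
                )
            for seg in segs:
                if center_idx is None:
                    tuning = 1.0  # leg responses: remote, not segmentally tuned
                else:
                    d = abs(SEGMENT_INDEX[seg] - center_idx)
                    tuning = float(np.exp(-(d**2) / (2 * 1.2**2)))
                jitter = float(np.exp(rng.normal(0.0, 0.3)))
                b_lat = base_slope * tuning * jitter
                thr_lat = float(
                    np.clip(
                        base_lat_thr
                        + 0.3 * (abs(SEGMENT_INDEX[seg] - SEGMENT_INDEX[segs[-1]]))
                        * rng.uniform(0.0, 1.0)
                        + rng.normal(0.0, 0.15),
                        0.3,
                        7.0,
                    )
                )
                shift = max(0.0, config.midline_threshold_shift + rng.normal(0.0, 0.2))
                params[(pid, m, seg, "lateral")] = RecruitParams(offset, b_lat, thr_lat)
                params[(pid, m, seg, "midline")] = RecruitParams(
                    offset,
                    b_lat * config.midline_slope_attenuation,
                    min(thr_lat + shift, 8.5),
                )
        # midline threshold of the most responsive muscle at the most caudal segment
        caudal = segs[-1]
        candidates = [
            (params[(pid, m, caudal, "midline")].threshold, m)
            for m in config.muscles
            if params[(pid, m, caudal, "midline")].slope > 1e-9
        ]
        thr = min(candidates)[0] if candidates else 4.0
        mid_thr[pid] = thr
        fixed[pid] = float(min(1.2 * thr, 8.0))
    return GroundTruth(config, params, latency, shapes, stim_side, mid_thr, fixed)


# ---------------------------------------------------------------------------
# Cohort generation


_SOS_CACHE: dict = {}


def _bandlimited_noise(
    n: int, sd: float, sampling_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise band-limited to the 10–2,000 Hz acquisition character."""
    if sd <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if sampling_rate not in _SOS_CACHE:
        hi = min(2000.0, 0.45 * sampling_rate)
        _SOS_CACHE[sampling_rate] = signal.butter(
            2, [10.0, hi], btype="bandpass", fs=sampling_rate, output="sos"
        )
    x = signal.sosfiltfilt(_SOS_CACHE[sampling_rate], white)
    s = x.std()
    return x * (sd / s) if s > 0 else np.zeros(n)


def generate_cohort(config: CohortConfig) -> tuple[list[SweepRecord], GroundTruth]:
    """Simulate a cohort of intraoperative stimulation experiments.

    For each participant: a midline intensity ramp at the most caudal exposed
    segment, the equivalent lateral ramp, then fixed-intensity blocks (120 %
    of the simulated midline threshold) at every exposed segment for both
    electrode positions.  One sweep is emitted per recorded (muscle, side)
    channel per stimulation event.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_ground_truth(config, rng)
    art_spec = ArtifactSpec(rate=config.artifact_rate)

    fs = config.sampling_rate
    pre = int(round(config.pre_stim_s * fs))
    post = int(round(config.post_stim_s * fs))
    onset_time = pre / fs
    n_samples = pre + post

    # cache the unit-amplitude template and its windowed AUC per (latency, shape)
    template_cache: dict = {}

    def unit_template(lat: float, shape: int) -> tuple[np.ndarray, float]:
        key = (round(lat, 6), shape)
        if key not in template_cache:
            w = mep_template(lat, 1.0, shape, fs, config.post_stim_s * 1000.0)
            u = template_unit_auc(lat, shape, fs, config.pre_stim_s, config.post_stim_s)
            template_cache[key] = (w, u)
        return template_cache[key]

    sweeps: list[SweepRecord] = []
    sweep_id = 0
    sigma = float(np.sqrt(np.log1p(config.auc_cv**2))) if config.auc_cv > 0 else 0.0
    segs = config.ordered_segments
    caudal = segs[-1]

    for ip in range(config.n_participants):
        pid = f"P{ip + 1:02d}"
        clock = 0.0

        events: list[tuple[str, str, float, str]] = []  # (segment, position, mA, block)
        for pos in ("midline", "lateral"):
            for x in config.ramp_intensities:
                events.extend([(caudal, pos, float(x), "ramp")] * config.sweeps_per_intensity)
        fx = truth.fixed_intensity[pid]
        for seg in segs:
            for pos in ("midline", "lateral"):
                events.extend([(seg, pos, fx, "fixed")] * config.sweeps_per_fixed_block)

        for seg, pos, x, block in events:
            for m in config.muscles:
                lat = truth.latency_ms[(pid, m)]
                shape = truth.shape_id[(pid, m)]
                w_unit, u = unit_template(lat, shape)
                for side in config.sides:
                    target = truth.expected_auc(pid, m, seg, pos, side, x)
                    if sigma > 0:
                        target *= float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
                    # scale so the windowed rectified integral equals `target`
                    resp = w_unit * (target / u if u > 0 else 0.0)
                    trace = np.concatenate([np.zeros(pre), resp])
                    trace += _bandlimited_noise(n_samples, config.noise_sd, fs, rng)
                    trace, label = inject_artifacts(trace, art_spec, rng, pre, fs)
                    trace = np.clip(trace, -config.clip_level, config.clip_level)
                    sweeps.append(
                        SweepRecord(
                            sweep_id=sweep_id,
                            participant_id=pid,
                            muscle=m,
                            side=side,
                            segment=seg,
                            position=pos,
                            intensity=x,
                            pulse_count=config.pulse_count,
                            stim_onset_time=onset_time,
                            sampling_rate=fs,
                            trace=trace,
                            block=block,
                            acquisition_time=clock,
                        )
                    )
                    truth.artifact_labels[sweep_id] = bool(label)
                    sweep_id += 1
            clock += 2.0  # one stimulation event every 2 s

    logger.info(
        "generated cohort: %d participants, %d sweeps, %d artifact-contaminated",
        config.n_participants, len(sweeps), sum(truth.artifact_labels.values()),
    )
    return sweeps, truth
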