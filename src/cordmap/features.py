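"""Per-MEP feature extraction.

Motor evoked potentials (MEPs) are quantified by the rectified area under
the curve (AUC, µV·s) of the baseline-corrected trace in a window 6.5–75 ms
after the first stimulation pulse.  Presence of an MEP is operationalized as
AUC exceeding an AUC-equivalent of the conventional 50 µV peak-peak
threshold, obtained by regressing AUC on peak-peak size.  Onset latency is
the first deflection of the site-average waveform exceeding 10 µV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sweeps import SweepRecord, metadata_table

logger = logging.getLogger(__name__)

#: Analysis window in ms after the first stimulation pulse.
DEFAULT_WINDOW_MS: tuple[float, float] = (6.5, 75.0)

#: Baseline reference interval: 25 ms long, ending 2 ms before the pulse,
#: expressed as (start, end) in ms *before* the pulse.
DEFAULT_BASELINE_MS: tuple[float, float] = (27.0, 2.0)

#: Conventional noninvasive peak-peak presence criterion, µV.
REFERENCE_PEAK_PEAK_UV = 50.0

#: Onset criterion on the absolute site-average waveform, µV.
ONSET_CRITERION_UV = 10.0


def window_mask(times_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    """Boolean mask of samples inside ``window_ms`` (inclusive)."""
    lo, hi = window_ms
    return (times_ms >= lo) & (times_ms <= hi)


def _check_window(sweep: SweepRecord, window_ms: tuple[float, float]) -> np.ndarray:
    t = sweep.times_ms
    if window_ms[1] > t[-1] + 1e-9:
        raise ValueError(
            f"sweep {sweep.sweep_id}: analysis window {window_ms} ms exceeds trace "
            f"(last sample at {t[-1]:.2f} ms after pulse)"
        )
    return t


def baseline_level(
    sweep: SweepRecord, baseline_ms: tuple[float, float] = DEFAULT_BASELINE_MS
) -> float:
    """Mean of the pre-stimulus reference interval; 0.0 if none is recorded."""
    t = sweep.times_ms
    pre = (t >= -baseline_ms[0]) & (t <= -baseline_ms[1])
    if not pre.any():
        return 0.0
    return float(sweep.trace[pre].mean())


def rectified_auc(
    sweep: SweepRecord,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    baseline_ms: tuple[float, float] = DEFAULT_BASELINE_MS,
) -> float:
    """Rectified area under the curve in µV·s over the analysis window.

    The trace is baseline-corrected by the mean of the pre-stimulus reference
    interval, rectified, and integrated by the trapezoid rule at the native
    sampling rate.
    """
    t = _check_window(sweep, window_ms)
    m = window_mask(t, window_ms)
    y = np.abs(sweep.trace[m] - baseline_level(sweep, baseline_ms))
    return float(np.trapezoid(y, t[m] / 1000.0))


def peak_to_peak(
    sweep: SweepRecord,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    baseline_ms: tuple[float, float] = DEFAULT_BASELINE_MS,
) -> float:
    """Max minus min of the baseline-corrected trace in the window, µV."""
    t = _check_window(sweep, window_ms)
    m = window_mask(t, window_ms)
    y = sweep.trace[m] - baseline_level(sweep, baseline_ms)
    return float(y.max() - y.min())


def windowed_trace(
    sweep: SweepRecord,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    baseline_ms: tuple[float, float] = DEFAULT_BASELINE_MS,
) -> np.ndarray:
    """Baseline-corrected samples inside the analysis window (for PCA etc.)."""
    t = _check_window(sweep, window_ms)
    m = window_mask(t, window_ms)
    return sweep.trace[m] - baseline_level(sweep, baseline_ms)


def compute_features(
    sweeps: Iterable[SweepRecord],
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    baseline_ms: tuple[float, float] = DEFAULT_BASELINE_MS,
    presence_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-sweep feature table: metadata + ``auc``, ``peak_peak``.

    ``rejected`` is initialized False (see the artifact-rejection stage);
    ``present`` is filled if ``presence_threshold`` (µVs) is given.
    """
    sweeps = list(sweeps)
    df = metadata_table(sweeps)
    df["auc"] = [rectified_auc(s, window_ms, baseline_ms) for s in sweeps]
    df["peak_peak"] = [peak_to_peak(s, window_ms, baseline_ms) for s in sweeps]
    df["rejected"] = False
    if presence_threshold is not None:
        df["present"] = df["auc"] > presence_threshold
    return df


@dataclass
class PresenceCalibration:
    """AUC-equivalent of the 50 µV peak-peak presence criterion."""

    threshold_auc: float  # µVs at the reference peak-peak
    slope: float  # µVs per µV
    intercept: float  # µVs
    r_squared: float
    n: int
    reference_pp: float


def calibrate_presence_threshold(
    features: pd.DataFrame,
    reference_pp: float = REFERENCE_PEAK_PEAK_UV,
    min_n: int = 10,
) -> PresenceCalibration:
    """Least-squares line of AUC on peak-peak, evaluated at ``reference_pp``.

    Uses non-rejected sweeps only.  Ordinary least squares with intercept;
    raises on degenerate (constant peak-peak) input.
    """
    d = features.loc[~features["rejected"]]
    if len(d) < min_n:
        raise ValueError(f"need >= {min_n} non-rejected sweeps, got {len(d)}")
    pp = d["peak_peak"].to_numpy(float)
    auc = d["auc"].to_numpy(float)
    if np.ptp(pp) == 0:
        raise ValueError("peak-peak values are constant; calibration line is degenerate")
    A = np.column_stack([np.ones_like(pp), pp])
    (intercept, slope), *_ = np.linalg.lstsq(A, auc, rcond=None)
    fit = intercept + slope * pp
    ss_res = float(np.sum((auc - fit) ** 2))
    ss_tot = float(np.sum((auc - auc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    thr = float(intercept + slope * reference_pp)
    logger.info(
        "presence calibration: AUC = %.4g + %.4g * pp, threshold %.4g uVs at %.0f uV (n=%d, R2=%.3f)",
        intercept, slope, thr, reference_pp, len(d), r2,
    )
    return PresenceCalibration(thr, float(slope), float(intercept), r2, len(d), reference_pp)


def onset_latency(
    mean_waveform: np.ndarray,
    sampling_rate: float,
    stim_onset_index: int,
    criterion_uv: float = ONSET_CRITERION_UV,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> float | None:
    """Onset latency of an average waveform, ms after the first pulse.

    First sample with ``|value| > criterion_uv`` searched from the start of
    the analysis window; ``None`` if the criterion is never exceeded.  The
    waveform is expected to be an average over >= 1 baseline-corrected sweeps.
    """
    w = np.asarray(mean_waveform, dtype=float)
    t = (np.arange(w.size) - stim_onset_index) / sampling_rate * 1000.0
    m = window_mask(t, window_ms)
    idx = np.nonzero(m & (np.abs(w) > criterion_uv))[0]
    if idx.size == 0:
        return None
    return float(t[idx[0]])


def average_waveform(
    sweeps: Sequence[SweepRecord],
    baseline_ms: tuple[float, float] = DEFAULT_BASELINE_MS,
) -> tuple[np.ndarray, float, int]:
    """Baseline-corrected mean waveform of time-aligned sweeps.

    Returns ``(waveform, sampling_rate, stim_onset_index)``.  All sweeps must
    share sampling rate, length and stimulus alignment.
    """
    if not sweeps:
        raise ValueError("cannot average an empty set of sweeps")
    fs = {s.sampling_rate for s in sweeps}
    onsets = {s.stim_onset_index for s in sweeps}
    lens = {s.trace.size for s in sweeps}
    if len(fs) != 1 or len(onsets) != 1 or len(lens) != 1:
        raise ValueError("sweeps must share sampling rate, length and alignment")
    stack = np.stack([s.trace - baseline_level(s, baseline_ms) for s in sweeps])
    return stack.mean(axis=0), fs.pop(), onsets.pop()
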