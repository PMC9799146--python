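"""Size-matched waveform similarity across electrode conditions.

MEP shape depends on MEP size, so waveforms are only compared after matching
their AUC: a fixed-intensity site-average MEP (reference) is paired with the
recruitment-curve site-average MEP of closest AUC, provided the difference is
below 0.5 µVs.  Similarity is the maximum Pearson correlation over time lags
within ±12.5 ms (lag grid = native sample period); latency differences come
from the 10 µV onset criterion on the site averages.  An outside condition
(e.g. anterior stimulation) is ranked against the midline-lateral similarity
distribution and reported as a percentile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .features import average_waveform, onset_latency, rectified_auc
from .group_stats import report_mean_2se, wilcoxon_rank_sum, wilcoxon_signed_rank
from .sweeps import SEGMENT_INDEX, SweepRecord

logger = logging.getLogger(__name__)

SIZE_MATCH_TOLERANCE_UVS = 0.5
MAX_LAG_MS = 12.5
MIN_OVERLAP_FRACTION = 0.5


@dataclass
class SiteWaveform:
    """Site-average MEP: mean waveform plus its AUC and provenance."""

    participant_id: str
    muscle: str
    side: str
    segment: str
    position: str
    block: str
    intensity: float
    auc: float
    waveform: np.ndarray
    sampling_rate: float
    stim_onset_index: int
    acquisition_time: float  # earliest sweep time; deterministic tie-break
    n_sweeps: int


@dataclass
class MatchedPair:
    reference: SiteWaveform
    comparison: SiteWaveform
    auc_difference: float
    r_max: float | None
    best_lag_ms: float | None
    latency_difference_ms: float | None
    condition: str


def site_average_waveforms(
    sweeps: Sequence[SweepRecord],
    features: pd.DataFrame,
) -> list[SiteWaveform]:
    """Average non-rejected sweeps per site.

    Sites are (participant, muscle, side, segment, position, block,
    intensity); ramp sweeps therefore yield one average per tested intensity
    (the candidates for size matching), fixed blocks one average per site.
    """
    ok_ids = set(features.loc[~features["rejected"], "sweep_id"])
    groups: dict = {}
    for s in sweeps:
        if s.sweep_id not in ok_ids:
            continue
        key = (s.participant_id, s.muscle, s.side, s.segment, s.position, s.block,
               float(s.intensity))
        groups.setdefault(key, []).append(s)
    out = []
    for key, grp in sorted(groups.items()):
        w, fs, onset = average_waveform(grp)
        mean_sweep = SweepRecord(
            sweep_id=-1, participant_id=key[0], muscle=key[1], side=key[2],
            segment=key[3], position=key[4], intensity=key[6],
            pulse_count=grp[0].pulse_count, stim_onset_time=grp[0].stim_onset_time,
            sampling_rate=fs, trace=w, block=key[5],
        )
        out.append(
            SiteWaveform(
                *key[:6], key[6], auc=rectified_auc(mean_sweep), waveform=w,
                sampling_rate=fs, stim_onset_index=onset,
                acquisition_time=min(s.acquisition_time for s in grp),
                n_sweeps=len(grp),
            )
        )
    return out


def size_match(
    reference: SiteWaveform,
    candidates: Sequence[SiteWaveform],
    tolerance: float = SIZE_MATCH_TOLERANCE_UVS,
    condition: str = "",
) -> MatchedPair | None:
    """Pair a reference MEP with the candidate of closest AUC under tolerance.

    Candidates must share the muscle.  Ties in |AUC difference| are broken by
    earliest acquisition time.  Returns None (with a log entry) if no
    candidate qualifies.
    """
    cands = [c for c in candidates if c.muscle == reference.muscle]
    if not cands:
        logger.info("size match: no candidates for %s/%s",
                    reference.participant_id, reference.muscle)
        return None
    cands.sort(key=lambda c: (abs(c.auc - reference.auc), c.acquisition_time))
    best = cands[0]
    diff = best.auc - reference.auc
    if abs(diff) >= tolerance:
        logger.info(
            "size match: closest candidate off by %.3f uVs (>= %.2f) for %s/%s",
            abs(diff), tolerance, reference.participant_id, reference.muscle,
        )
        return None
    r_max, lag = lag_correlation(reference.waveform, best.waveform,
                                 reference.sampling_rate)
    lat_ref = onset_latency(reference.waveform, reference.sampling_rate,
                            reference.stim_onset_index)
    lat_cmp = onset_latency(best.waveform, best.sampling_rate, best.stim_onset_index)
    lat_diff = None if lat_ref is None or lat_cmp is None else lat_cmp - lat_ref
    return MatchedPair(reference, best, float(diff), r_max, lag, lat_diff, condition)


def lag_correlation(
    w1: np.ndarray,
    w2: np.ndarray,
    sampling_rate: float,
    max_lag_ms: float = MAX_LAG_MS,
    min_overlap: float = MIN_OVERLAP_FRACTION,
) -> tuple[float | None, float | None]:
    """Maximum Pearson correlation over integer-sample lags within ±max_lag_ms.

    At each lag the correlation is computed on the overlapping segment;
    lags with overlap below ``min_overlap`` of the shorter waveform are not
    tested.  Ties are broken toward the smallest |lag|, then the smaller lag.
    Returns (None, None) if no lag admits a defined correlation (e.g. a
    constant waveform).
    """
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    max_shift = int(np.floor(max_lag_ms * sampling_rate / 1000.0))
    n = min(w1.size, w2.size)
    best: tuple[float, int] | None = None
    for lag in range(-max_shift, max_shift + 1):
        # positive lag: w2 delayed relative to w1
        if lag >= 0:
            a, b = w1[: w1.size - lag], w2[lag:]
        else:
            a, b = w1[-lag:], w2[: w2.size + lag]
        m = min(a.size, b.size)
        if m < max(2, int(np.ceil(min_overlap * n))):
            continue
        a, b = a[:m], b[:m]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        if (
            best is None
            or r > best[0] + 1e-15
            or (abs(r - best[0]) <= 1e-15
                and (abs(lag) < abs(best[1])
                     or (abs(lag) == abs(best[1]) and lag < best[1])))
        ):
            best = (r, lag)
    if best is None:
        return None, None
    return best[0], best[1] * 1000.0 / sampling_rate


def percentile_rank(value: float, reference: Sequence[float]) -> float:
    """Percentile of ``value`` in a reference distribution.

    Strictly-smaller reference values count fully, ties count half.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size < 2:
        raise ValueError("reference distribution needs >= 2 values")
    below = np.sum(ref < value) + 0.5 * np.sum(ref == value)
    return float(100.0 * below / ref.size)


def condition_contrast(
    midlat_pairs: Sequence[MatchedPair],
    rostrocaudal_pairs: Sequence[MatchedPair],
    paired: bool = False,
    alpha: float = 0.05,
) -> dict:
    """Pooled latency-difference and r_max contrasts between the two conditions.

    Reports mean ± 2 SE per condition for the latency differences and the
    lag-optimized correlations, and a Wilcoxon contrast (signed-rank if
    ``paired`` with equal lengths, rank-sum otherwise).  Individual muscles
    are treated as independent units.  Empty conditions skip the contrast
    with a log entry.
    """
    out: dict = {"alpha": alpha}
    for name, pairs in (("midline_lateral", midlat_pairs),
                        ("rostrocaudal", rostrocaudal_pairs)):
        lat = [p.latency_difference_ms for p in pairs if p.latency_difference_ms is not None]
        rs = [p.r_max for p in pairs if p.r_max is not None]
        entry = {"n_pairs": len(pairs)}
        if len(lat) >= 2:
            m, hw = report_mean_2se(lat)
            entry["latency_diff_ms"] = {"mean": m, "two_se": hw, "n": len(lat)}
        if len(rs) >= 2:
            m, hw = report_mean_2se(rs)
            entry["r_max"] = {"mean": m, "two_se": hw, "n": len(rs)}
        out[name] = entry
    for metric, getter in (
        ("latency_difference_ms", lambda p: p.latency_difference_ms),
        ("r_max", lambda p: p.r_max),
    ):
        a = np.array([getter(p) for p in midlat_pairs if getter(p) is not None])
        b = np.array([getter(p) for p in rostrocaudal_pairs if getter(p) is not None])
        if a.size < 2 or b.size < 2:
            logger.info("contrast on %s skipped: a condition is empty/too small", metric)
            continue
        if paired and a.size == b.size:
            res = wilcoxon_signed_rank(a - b)
            test = "signed-rank"
        else:
            res = wilcoxon_rank_sum(a, b)
            test = "rank-sum"
        out[f"contrast_{metric}"] = {
            "test": test, "statistic": res.statistic, "p": res.pvalue,
            "n_midlat": int(a.size), "n_rostrocaudal": int(b.size),
            "significant": bool(res.pvalue < alpha),
        }
    return out


def build_matched_pairs(
    sites: Sequence[SiteWaveform],
    tolerance: float = SIZE_MATCH_TOLERANCE_UVS,
) -> tuple[list[MatchedPair], list[MatchedPair]]:
    """Construct midline-lateral and rostro-caudal matched pairs.

    Midline-lateral: at the most caudal stimulated segment of each
    participant, the fixed-intensity midline site average is matched against
    that participant's lateral recruitment-curve averages at the same
    segment.  Rostro-caudal: the fixed-intensity lateral site average at
    each more rostral segment is matched against the lateral
    recruitment-curve averages (recorded at the most caudal segment).
    """
    midlat: list[MatchedPair] = []
    rostro: list[MatchedPair] = []
    by_part: dict = {}
    for s in sites:
        by_part.setdefault((s.participant_id, s.muscle, s.side), []).append(s)
    for (pid, muscle, side), ss in sorted(by_part.items()):
        ramps_lat = [s for s in ss if s.block == "ramp" and s.position == "lateral"]
        if not ramps_lat:
            continue
        ramp_seg = max({s.segment for s in ramps_lat}, key=SEGMENT_INDEX.get)
        cands = [s for s in ramps_lat if s.segment == ramp_seg]
        fixed = [s for s in ss if s.block == "fixed"]
        ref_mid = [s for s in fixed if s.position == "midline" and s.segment == ramp_seg]
        for ref in ref_mid:
            p = size_match(ref, cands, tolerance, condition="midline_lateral")
            if p is not None:
                midlat.append(p)
        ref_rc = [
            s for s in fixed
            if s.position == "lateral"
            and SEGMENT_INDEX[s.segment] < SEGMENT_INDEX[ramp_seg]
        ]
        for ref in ref_rc:
            p = size_match(ref, cands, tolerance, condition="rostrocaudal")
            if p is not None:
                rostro.append(p)
    logger.info("matched pairs: %d midline-lateral, %d rostro-caudal",
                len(midlat), len(rostro))
    return midlat, rostro


def pairs_table(pairs: Sequence[MatchedPair]) -> pd.DataFrame:
    """Tidy matched-pair table for CSV export."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "participant_id": p.reference.participant_id,
                "muscle": p.reference.muscle,
                "side": p.reference.side,
                "reference_segment": p.reference.segment,
                "reference_position": p.reference.position,
                "comparison_segment": p.comparison.segment,
                "comparison_position": p.comparison.position,
                "comparison_intensity": p.comparison.intensity,
                "auc_difference": p.auc_difference,
                "r_max": p.r_max,
                "best_lag_ms": p.best_lag_ms,
                "latency_difference_ms": p.latency_difference_ms,
                "condition": p.condition,
            }
        )
    return pd.DataFrame(rows)
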