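"""Nonparametric group statistics for midline-vs-lateral comparisons.

Wilcoxon rank-sum and signed-rank tests (two-sided, α = 0.05 convention),
Bonferroni correction over participants, the percent-larger summary, the
mean ± 2 SE reporting convention, and the design-stage sample-size
computation for a Wilcoxon signed-rank test via the noncentral-t paired
t-test sample size corrected by the asymptotic relative efficiency (ARE)
3/π of the Wilcoxon test under a normal parent.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

ALPHA = 0.05

#: Combined-n bound below which the rank-sum test is computed exactly.
RANKSUM_EXACT_MAX_N = 12
#: Pair-count bound below which the signed-rank test is computed exactly.
SIGNED_RANK_EXACT_MAX_N = 15

#: Asymptotic relative efficiency of the Wilcoxon signed-rank test vs the
#: paired t-test for a normal parent (and its distribution-free minimum).
ARE_NORMAL = 3.0 / math.pi
ARE_MIN = 0.864


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n: int
    n_zeros_dropped: int = 0


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration for combined n <= 12 without ties; normal approximation
    with tie correction (and continuity correction) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    exact = (pooled.size <= RANKSUM_EXACT_MAX_N) and not _has_ties(pooled)
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(float(res.statistic), float(res.pvalue), method, int(pooled.size))


def wilcoxon_signed_rank(diffs) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (classic convention) and counted; exact
    distribution for n <= 15 remaining pairs without tied magnitudes, normal
    approximation with tie/continuity correction otherwise.  All-zero input
    yields p = 1 with a warning.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need >= 2 paired differences")
    nonzero = d[d != 0]
    n_zeros = int(d.size - nonzero.size)
    if n_zeros:
        logger.info("signed-rank: dropped %d zero difference(s)", n_zeros)
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult(0.0, 1.0, "degenerate", 0, n_zeros)
    exact = nonzero.size <= SIGNED_RANK_EXACT_MAX_N and not _has_ties(np.abs(nonzero))
    method = "exact" if exact else "approx"
    res = stats.wilcoxon(
        nonzero, alternative="two-sided", zero_method="wilcox",
        correction=not exact, method="exact" if exact else "approx",
    )
    return TestResult(float(res.statistic), float(res.pvalue), method, int(nonzero.size), n_zeros)


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    return float(min(1.0, p_raw * n_comparisons))


def per_participant_midlat_tests(
    features: pd.DataFrame,
    muscle: str,
    presence_threshold: float = 0.33,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Within-participant midline vs lateral rank-sum tests, Bonferroni corrected.

    For each participant, fixed-intensity non-rejected AUC samples of
    ``muscle`` (stimulated side) at the comparison segment — the most caudal
    segment with both electrode positions and a lateral response above the
    presence threshold — are compared with the Wilcoxon rank-sum test.
    p-values are Bonferroni corrected for the number of included
    participants.
    """
    d = features[
        (features["muscle"] == muscle)
        & (features["block"] == "fixed")
        & (~features["rejected"])
    ]
    rows = []
    for pid, g in d.groupby("participant_id", sort=True):
        seg = _comparison_segment(g, presence_threshold)
        if seg is None:
            logger.info("participant %s lacks a responsive midline/lateral segment", pid)
            continue
        gs = g[g["segment"] == seg]
        mid = gs.loc[gs["position"] == "midline", "auc"].to_numpy()
        lat = gs.loc[gs["position"] == "lateral", "auc"].to_numpy()
        res = wilcoxon_rank_sum(mid, lat)
        rows.append(
            {
                "participant_id": pid,
                "segment": seg,
                "n_midline": mid.size,
                "n_lateral": lat.size,
                "statistic": res.statistic,
                "p_raw": res.pvalue,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = out["p_raw"].apply(lambda p: bonferroni(p, len(out)))
        out["significant"] = out["p_bonferroni"] < alpha
    return out


def _comparison_segment(g: pd.DataFrame, presence_threshold: float) -> str | None:
    """Most caudal segment with both positions tested and a present lateral MEP."""
    from .sweeps import SEGMENT_INDEX

    candidates = []
    for seg, gs in g.groupby("segment"):
        pos = set(gs["position"])
        if {"midline", "lateral"} <= pos:
            lat_mean = gs.loc[gs["position"] == "lateral", "auc"].mean()
            if lat_mean > presence_threshold:
                candidates.append(seg)
    if not candidates:
        return None
    return max(candidates, key=SEGMENT_INDEX.get)


def percent_larger(pairs: pd.DataFrame) -> float:
    """Percentage of matched (participant, segment, muscle) pairs with
    lateral AUC strictly larger than midline AUC."""
    if not {"lateral", "midline"} <= set(pairs.columns):
        raise ValueError("pairs table needs 'lateral' and 'midline' columns")
    if len(pairs) == 0:
        raise ValueError("no matched pairs")
    return float(100.0 * np.mean(pairs["lateral"].to_numpy() > pairs["midline"].to_numpy()))


def midlat_pairs(features: pd.DataFrame) -> pd.DataFrame:
    """Mean fixed-intensity AUC per (participant, segment, muscle, side) and
    position, paired midline vs lateral (pairs with both positions only)."""
    d = features[(features["block"] == "fixed") & (~features["rejected"])]
    cell = (
        d.groupby(["participant_id", "segment", "muscle", "side", "position"])["auc"]
        .mean()
        .unstack("position")
    )
    cell = cell.dropna(subset=["midline", "lateral"]).reset_index()
    return cell


@dataclass
class SampleSizeResult:
    n: int
    n_t_continuous: float
    are: float
    floored: bool


def wilcoxon_sample_size(
    effect_d: float,
    alpha: float = ALPHA,
    power: float = 0.90,
    are: float = ARE_NORMAL,
    two_sided: bool = True,
) -> SampleSizeResult:
    """Participants required for a Wilcoxon signed-rank test at given power.

    The paired t-test sample size is solved as a continuous root of the
    noncentral-t power equation, divided by the ARE (3/π for a normal parent;
    pass ``are=ARE_MIN`` for the distribution-free 0.864 convention) and
    rounded up.  Sample sizes below the minimum supported n = 2 are floored
    and flagged.
    """
    if effect_d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if power <= alpha:
        raise ValueError("target power must exceed alpha")

    tail = alpha / 2 if two_sided else alpha

    def power_at(n: float) -> float:
        df = n - 1
        nc = effect_d * math.sqrt(n)
        tcrit = stats.t.ppf(1 - tail, df)
        p = 1 - stats.nct.cdf(tcrit, df, nc)
        if two_sided:
            p += stats.nct.cdf(-tcrit, df, nc)
        if math.isnan(p):  # scipy nct is unstable for extreme noncentrality
            p = stats.norm.sf(tcrit - nc)
            if two_sided:
                p += stats.norm.cdf(-tcrit - nc)
        return p

    n_min = 2.0
    floored = False
    if power_at(n_min) >= power:
        n_t = n_min
        floored = True
        logger.warning("effect size %.3g reaches target power at the minimum n", effect_d)
    else:
        hi = 8.0
        while power_at(hi) < power:  # power is increasing in n
            hi *= 2.0
            if hi > 1e7:
                raise ValueError("sample size solver failed to bracket the root")
        n_t = optimize.brentq(lambda n: power_at(n) - power, n_min, hi)
    n = max(2, math.ceil(n_t / are))
    return SampleSizeResult(n, float(n_t), are, floored)


def report_mean_2se(values) -> tuple[float, float]:
    """Arithmetic mean and 2 x standard error of the mean half-width."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    return float(v.mean()), float(2.0 * v.std(ddof=1) / math.sqrt(v.size))
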