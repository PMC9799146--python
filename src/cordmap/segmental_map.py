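"""Segment x muscle activation map, segmental similarity and gradients.

The activation map summarizes fixed-intensity MEP sizes on a segments
(C4→T1) x muscles grid: per-participant arithmetic means per cell, combined
across participants by the geometric mean (MEP sizes are approximately
log-normal across people).  Cross-segment similarity is the Spearman rank
correlation of the per-participant muscle-AUC vectors, averaged across
participants, and is summarized by single-linkage agglomerative clustering
on the distance 1 − correlation with a flat cut at 70 % of the maximum merge
height.  Per-mm gradients convert AUC differences into µVs/mm using
cadaveric normalizers: 12.5 mm between neighboring cervical roots
(rostro-caudal) and 6.7 mm from midline to the root entry zone
(midline-lateral).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .group_stats import TestResult, wilcoxon_signed_rank
from .sweeps import SEGMENT_INDEX, ConfigurationError

logger = logging.getLogger(__name__)

#: AUC-equivalent presence threshold, µVs (50 µV peak-peak calibration).
PRESENCE_THRESHOLD = 0.33
#: Zero cells are replaced by half the presence threshold before log-averaging.
ZERO_SUBSTITUTE = PRESENCE_THRESHOLD / 2

#: Cadaveric distance normalizers, mm.
INTERROOT_DISTANCE_MM = 12.5
MIDLINE_LATERAL_DISTANCE_MM = 6.7

CLUSTER_CUTOFF_FRACTION = 0.70

ARM_AND_HAND_MUSCLES = ("deltoid", "biceps", "triceps", "APB", "ADM", "FDI")


def _ordered(segments) -> list[str]:
    return sorted(set(segments), key=SEGMENT_INDEX.get)


@dataclass
class SegmentMuscleMatrix:
    """AUC summaries on a segments x muscles grid.

    ``values``: group-level geometric-mean AUC (µVs), rows in rostro-caudal
    order, NaN where no participant contributed.  ``support``: participants
    per cell.  ``per_participant``: the per-participant arithmetic-mean
    matrices the group level was built from.
    """

    values: pd.DataFrame
    support: pd.DataFrame
    per_participant: dict = field(default_factory=dict)
    n_zero_substituted: int = 0


def group_auc_matrix(
    features: pd.DataFrame,
    position: str = "lateral",
    muscles: tuple[str, ...] | None = None,
    side: str | None = None,
    zero_substitute: float = ZERO_SUBSTITUTE,
) -> SegmentMuscleMatrix:
    """Build the segments x muscles activation map from fixed-intensity sweeps.

    Per participant, each (segment, muscle) cell is the arithmetic mean AUC
    over that participant's non-rejected fixed-intensity sweeps (stimulated
    side, requested electrode position).  Group cells are geometric means
    across contributing participants; zero cells are replaced by
    ``zero_substitute`` before log-averaging (logged).  Cells no participant
    contributed to are NaN (missing, not zero).
    """
    d = features[
        (features["block"] == "fixed")
        & (~features["rejected"])
        & (features["position"] == position)
    ]
    if muscles is not None:
        d = d[d["muscle"].isin(muscles)]
    if side is not None:
        d = d[d["side"] == side]
    if d.empty:
        raise ValueError("no fixed-intensity sweeps after filtering")
    segs = _ordered(d["segment"])
    cols = list(muscles) if muscles is not None else sorted(d["muscle"].unique())

    per_part: dict[str, pd.DataFrame] = {}
    for pid, g in d.groupby("participant_id", sort=True):
        cell = g.groupby(["segment", "muscle"])["auc"].mean().unstack("muscle")
        per_part[pid] = cell.reindex(index=segs, columns=cols)

    values = pd.DataFrame(np.nan, index=segs, columns=cols)
    support = pd.DataFrame(0, index=segs, columns=cols, dtype=int)
    n_zero = 0
    for seg in segs:
        for mus in cols:
            vals = np.array(
                [m.loc[seg, mus] for m in per_part.values() if np.isfinite(m.loc[seg, mus])]
            )
            if vals.size == 0:
                continue
            nz = int(np.sum(vals <= 0))
            n_zero += nz
            vals = np.where(vals <= 0, zero_substitute, vals)
            values.loc[seg, mus] = float(np.exp(np.mean(np.log(vals))))
            support.loc[seg, mus] = vals.size
    if n_zero:
        logger.info("geometric mean: substituted %d zero cell value(s)", n_zero)
    return SegmentMuscleMatrix(values, support, per_part, n_zero)


def segment_correlation_matrix(
    matrix: SegmentMuscleMatrix,
    muscles: tuple[str, ...] = ARM_AND_HAND_MUSCLES,
    min_shared_muscles: int = 3,
    fisher_z: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Averaged segment x segment Spearman correlation of muscle-AUC vectors.

    For each participant and each pair of segments they were stimulated at,
    the Spearman correlation across the shared (arm and hand) muscles is
    computed; pair values are averaged across contributing participants
    (optionally through Fisher z).  Pairs with fewer than
    ``min_shared_muscles`` shared muscles are excluded and logged.
    """
    segs = list(next(iter(matrix.per_participant.values())).index)
    avail = [m for m in muscles if m in next(iter(matrix.per_participant.values())).columns]
    corr = pd.DataFrame(np.nan, index=segs, columns=segs, dtype=float)
    support = pd.DataFrame(0, index=segs, columns=segs, dtype=int)
    np.fill_diagonal(corr.values, 1.0)
    for s1, s2 in itertools.combinations(segs, 2):
        vals = []
        for pid, m in matrix.per_participant.items():
            v1 = m.loc[s1, avail].to_numpy(float)
            v2 = m.loc[s2, avail].to_numpy(float)
            ok = np.isfinite(v1) & np.isfinite(v2)
            if ok.sum() < min_shared_muscles:
                logger.debug("pair (%s, %s) participant %s: <%d shared muscles",
                             s1, s2, pid, min_shared_muscles)
                continue
            rho = stats.spearmanr(v1[ok], v2[ok]).statistic
            if np.isfinite(rho):
                vals.append(rho)
        if vals:
            vals = np.asarray(vals, dtype=float)
            if fisher_z:
                z = np.arctanh(np.clip(vals, -0.999999, 0.999999))
                avg = float(np.tanh(z.mean()))
            else:
                avg = float(vals.mean())
            corr.loc[s1, s2] = corr.loc[s2, s1] = avg
            support.loc[s1, s2] = support.loc[s2, s1] = len(vals)
    return corr, support


@dataclass
class ClusterTree:
    """Single-linkage merge sequence over segments on distance 1 − correlation."""

    merges: list  # (members_a, members_b, height) with segment-name tuples
    heights: np.ndarray
    cutoff: float
    labels: dict  # segment -> flat cluster id

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def cluster_segments(
    corr: pd.DataFrame, cutoff_fraction: float = CLUSTER_CUTOFF_FRACTION
) -> ClusterTree:
    """Single-linkage agglomeration of segments on distance 1 − correlation.

    Flat clusters are cut at ``cutoff_fraction`` x the maximum merge height.
    The input must be symmetric with unit diagonal; segments with any missing
    pairwise correlation are not clusterable and raise.
    """
    M = corr.to_numpy(float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-10, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(M), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.isnan(M).any():
        raise ValueError("correlation matrix contains missing pairs")
    segs = list(corr.index)
    dist = 1.0 - M
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="single")
    heights = Z[:, 2]
    cutoff = float(cutoff_fraction * heights.max()) if len(heights) else 0.0
    flat = hierarchy.fcluster(Z, t=cutoff, criterion="distance") if len(heights) else np.ones(1, int)
    labels = {seg: int(c) for seg, c in zip(segs, flat)}

    # resolve merge membership in segment names
    members: dict[int, tuple[str, ...]] = {i: (s,) for i, s in enumerate(segs)}
    merges = []
    for step, (ia, ib, h, _) in enumerate(Z):
        a, b = members[int(ia)], members[int(ib)]
        merges.append((a, b, float(h)))
        members[len(segs) + step] = a + b
    return ClusterTree(merges, heights, cutoff, labels)


def map_summary(
    matrix: SegmentMuscleMatrix, presence_threshold: float = PRESENCE_THRESHOLD
) -> pd.DataFrame:
    """Summarize the group map as per-segment muscle fractions.

    Cells at or below the presence threshold are suppressed; fractions are
    per-segment percentages of the total surviving AUC.  Segments where no
    muscle survives are reported empty (one row, ``muscle`` = None).
    """
    rows = []
    for seg in matrix.values.index:
        row = matrix.values.loc[seg]
        surviving = row[row > presence_threshold]
        if surviving.empty:
            rows.append(
                {"segment": seg, "muscle": None, "auc": np.nan,
                 "fraction_pct": np.nan, "n_participants": 0, "empty": True}
            )
            continue
        total = surviving.sum()
        for mus, v in surviving.items():
            rows.append(
                {
                    "segment": seg, "muscle": mus, "auc": float(v),
                    "fraction_pct": float(100.0 * v / total),
                    "n_participants": int(matrix.support.loc[seg, mus]),
                    "empty": False,
                }
            )
    return pd.DataFrame(rows)


def sensitivity_exclude(
    features: pd.DataFrame,
    flags: pd.DataFrame,
    flag_column: str = "t2_change",
    position: str = "lateral",
    muscles: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, float, SegmentMuscleMatrix, SegmentMuscleMatrix]:
    """Re-analysis excluding flagged (participant, segment) responses.

    ``flags`` has columns ``participant_id``, ``segment`` and boolean flag
    columns (e.g. ``t2_change``, ``severe_stenosis``).  Returns the filtered
    feature table, the Pearson correlation between group maps with and
    without the exclusion (over cells finite in both), and both matrices.
    """
    unknown = set(flags["segment"]) - set(SEGMENT_INDEX)
    if unknown:
        raise ConfigurationError(f"flags reference unknown segments: {sorted(unknown)}")
    flagged = flags.loc[flags[flag_column], ["participant_id", "segment"]]
    key = set(map(tuple, flagged.to_numpy()))
    drop = features.apply(
        lambda r: (r["participant_id"], r["segment"]) in key, axis=1
    )
    filtered = features[~drop]
    full = group_auc_matrix(features, position=position, muscles=muscles)
    if filtered[(filtered["block"] == "fixed") & (filtered["position"] == position)].empty:
        logger.error("sensitivity exclusion removed every segment; map is empty")
        raise ValueError("all segments excluded; no map to compare")
    excl = group_auc_matrix(filtered, position=position, muscles=muscles)
    a = full.values.reindex_like(full.values).to_numpy(float).ravel()
    b = excl.values.reindex(index=full.values.index, columns=full.values.columns).to_numpy(float).ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 shared cells between maps")
    r = float(stats.pearsonr(a[ok], b[ok]).statistic)
    logger.info("sensitivity exclusion (%s): map correlation r = %.3f over %d cells",
                flag_column, r, int(ok.sum()))
    return filtered, r, full, excl


@dataclass
class GradientEstimate:
    """Per-participant MEP change per mm of electrode movement."""

    participant_id: str
    rostrocaudal: float  # µVs/mm, normalizer 12.5 mm
    midline_lateral: float  # µVs/mm, normalizer 6.7 mm
    n_muscles: int


def gradient_per_mm(
    features: pd.DataFrame,
    interroot_mm: float = INTERROOT_DISTANCE_MM,
    midlat_mm: float = MIDLINE_LATERAL_DISTANCE_MM,
    muscles: tuple[str, ...] | None = None,
    side: str | None = None,
) -> tuple[pd.DataFrame, TestResult | None]:
    """Per-mm MEP gradients along the rostro-caudal and midline-lateral axes.

    Per muscle: the segment of maximum lateral AUC is found (ties broken
    toward the more caudal segment); the differences from that maximum to
    the neighboring segment(s) are averaged and divided by the interroot
    distance, and the (lateral − midline) difference at the maximum segment
    is divided by the midline-lateral distance.  Muscle values are averaged
    within participants; the group comparison is a Wilcoxon signed-rank test
    on the paired per-participant values.
    """
    d = features[(features["block"] == "fixed") & (~features["rejected"])]
    if muscles is not None:
        d = d[d["muscle"].isin(muscles)]
    if side is not None:
        d = d[d["side"] == side]
    rows = []
    for pid, g in d.groupby("participant_id", sort=True):
        cell = (
            g.groupby(["muscle", "segment", "position"])["auc"].mean().unstack("position")
        )
        rc_vals, ml_vals = [], []
        for mus, gm in cell.groupby(level="muscle"):
            gm = gm.droplevel("muscle")
            lat = gm["lateral"].dropna() if "lateral" in gm else pd.Series(dtype=float)
            if lat.size < 2:
                logger.debug("participant %s muscle %s: <2 lateral segments", pid, mus)
                continue
            order = sorted(lat.index, key=SEGMENT_INDEX.get)
            vals = lat.loc[order]
            vmax = vals.max()
            # tie-break toward the more caudal segment
            max_seg = [s for s in order if vals[s] == vmax][-1]
            i = order.index(max_seg)
            neighbors = [order[j] for j in (i - 1, i + 1) if 0 <= j < len(order)]
            # only segments adjacent in the rostro-caudal sequence count
            neighbors = [
                s for s in neighbors
                if abs(SEGMENT_INDEX[s] - SEGMENT_INDEX[max_seg]) == 1
            ]
            if not neighbors:
                logger.debug("participant %s muscle %s: no adjacent segment", pid, mus)
                continue
            diffs = [vmax - vals[s] for s in neighbors]
            mid = gm["midline"] if "midline" in gm else pd.Series(dtype=float)
            if max_seg not in mid.index or not np.isfinite(mid[max_seg]):
                logger.debug("participant %s muscle %s: no midline pair at %s",
                             pid, mus, max_seg)
                continue
            rc_vals.append(float(np.mean(diffs)) / interroot_mm)
            ml_vals.append(float(vmax - mid[max_seg]) / midlat_mm)
        if rc_vals:
            rows.append(
                GradientEstimate(
                    pid, float(np.mean(rc_vals)), float(np.mean(ml_vals)), len(rc_vals)
                ).__dict__
            )
    table = pd.DataFrame(rows)
    test = None
    if len(table) >= 2:
        test = wilcoxon_signed_rank(
            table["midline_lateral"].to_numpy() - table["rostrocaudal"].to_numpy()
        )
    return table, test
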