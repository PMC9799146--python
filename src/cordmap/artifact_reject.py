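"""PCA-based artifact ranking and rejection.

For each (muscle, electrode location) group of sweeps pooled across
stimulation intensities, principal components of the windowed waveforms
capture the dominant MEP shape.  Each waveform is regressed on the leading
components; the root-mean-square of the regression residual ranks the sweeps
from most to least dissimilar to the group shape.  The components are
estimated on the half of the group closest to the median waveform, so rare
contaminated sweeps cannot define the shape they are ranked against.  A
deterministic cutoff
(fraction of sweeps, or an absolute RMS level) replaces the human observer's
sliding scale of the original semi-automated procedure.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .features import DEFAULT_BASELINE_MS, DEFAULT_WINDOW_MS, windowed_trace
from .sweeps import SweepRecord

logger = logging.getLogger(__name__)

#: Components retained: smallest number explaining this variance fraction...
VARIANCE_EXPLAINED = 0.95
#: ...capped at this many.
MAX_COMPONENTS = 5


def pca_artifact_rank(
    traces: np.ndarray,
    sweep_ids: Sequence[int] | None = None,
    variance_explained: float = VARIANCE_EXPLAINED,
    max_components: int = MAX_COMPONENTS,
    fit_fraction: float = 0.5,
) -> pd.DataFrame:
    """Rank time-aligned waveforms by dissimilarity to their principal shape.

    The principal components are estimated robustly: the PCA is fit on the
    ``fit_fraction`` of sweeps closest (RMS) to the pointwise-median
    waveform, so that a minority of contaminated sweeps cannot define the
    components they are then ranked against.  Every waveform is regressed on
    the retained components and sweeps are sorted by the RMS of the
    regression residual, most dissimilar first.

    Parameters
    ----------
    traces : (n_sweeps, n_samples) array
        Windowed, baseline-corrected waveforms of one muscle x electrode
        location group (all intensities pooled).
    sweep_ids : sequence of int, optional
        Identifiers; defaults to ``0..n-1``.  Used for deterministic
        tie-breaking (ascending id among equal residuals).

    Returns
    -------
    DataFrame with columns ``sweep_id``, ``rms_error``, sorted descending by
    ``rms_error`` (most artifact-like first).
    """
    X = np.asarray(traces, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need >= 3 equal-length, time-aligned sweeps")
    ids = np.arange(X.shape[0]) if sweep_ids is None else np.asarray(sweep_ids)
    if ids.size != X.shape[0]:
        raise ValueError("sweep_ids length mismatch")
    n = X.shape[0]

    # robust reference subset: sweeps nearest the pointwise-median waveform
    median_w = np.median(X, axis=0)
    dist = np.sqrt(np.mean((X - median_w) ** 2, axis=1))
    n_fit = max(2, int(np.ceil(fit_fraction * n)))
    fit_idx = np.lexsort((ids, dist))[:n_fit]
    Xf = X[fit_idx]
    center = Xf.mean(axis=0, keepdims=True)

    _, s, Vt = np.linalg.svd(Xf - center, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        comps = np.empty((0, X.shape[1]))
    else:
        frac = np.cumsum(var) / total
        k = int(np.searchsorted(frac, variance_explained) + 1)
        if k > max_components:
            logger.debug(
                "capping principal components at %d (%.0f%% variance needed %d)",
                max_components, 100 * variance_explained, k,
            )
            k = max_components
        k = min(k, n_fit - 1) if n_fit > 1 else 1
        comps = Vt[:k]

    # regression of each waveform on the leading components = projection
    Xc = X - center
    resid = Xc - (Xc @ comps.T) @ comps if comps.size else Xc
    rms = np.sqrt(np.mean(resid**2, axis=1))

    order = np.lexsort((ids, -rms))  # descending rms, ascending id on ties
    return pd.DataFrame({"sweep_id": ids[order], "rms_error": rms[order]})


def reject_artifacts(
    ranked: pd.DataFrame,
    cutoff_fraction: float | None = None,
    rms_threshold: float | None = None,
) -> pd.DataFrame:
    """Flag the most artifact-like sweeps of a ranked group.

    Exactly one of ``cutoff_fraction`` (fraction of sweeps rejected, in
    [0, 1]) or ``rms_threshold`` (absolute RMS level above which sweeps are
    rejected) must be given.  Returns the ranking with a boolean ``rejected``
    column added.
    """
    if (cutoff_fraction is None) == (rms_threshold is None):
        raise ValueError("give exactly one of cutoff_fraction or rms_threshold")
    out = ranked.copy()
    if cutoff_fraction is not None:
        if not (0.0 <= cutoff_fraction <= 1.0):
            raise ValueError(f"cutoff_fraction {cutoff_fraction} outside [0, 1]")
        n_reject = int(round(cutoff_fraction * len(out)))
        flags = np.zeros(len(out), dtype=bool)
        flags[:n_reject] = True  # ranked is sorted most-dissimilar first
    else:
        flags = out["rms_error"].to_numpy() > rms_threshold
    out["rejected"] = flags
    return out


def flag_artifacts(
    features: pd.DataFrame,
    sweeps: Sequence[SweepRecord],
    cutoff_fraction: float | None = None,
    rms_threshold: float | None = None,
    pool_positions: bool = False,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    baseline_ms: tuple[float, float] = DEFAULT_BASELINE_MS,
) -> tuple[pd.DataFrame, dict]:
    """Run ranking per (participant, muscle, side, location) group, then flag.

    The electrode location is (segment, position); ``pool_positions`` merges
    midline and lateral sweeps of a segment into one group.  RMS residuals
    are normalized within their group (divided by the group median, so that
    large-MEP groups are not over-penalized) and ``cutoff_fraction`` is
    applied cohort-wide on the normalized values; ``rms_threshold`` is
    applied on the raw per-group RMS.  Adds ``rejected``, ``rms_error`` and
    ``rms_error_norm`` columns to a copy of the feature table and returns it
    with a rejection report (counts per group).
    """
    by_id = {s.sweep_id: s for s in sweeps}
    out = features.copy()
    out["rejected"] = False
    out["rms_error"] = np.nan
    out["rms_error_norm"] = np.nan
    group_cols = ["participant_id", "muscle", "side", "segment"]
    if not pool_positions:
        group_cols.append("position")
    report: dict = {"groups": [], "n_total": len(out), "n_rejected": 0}
    group_keys: list = []
    for key, idx in out.groupby(group_cols, sort=True).groups.items():
        ids = out.loc[idx, "sweep_id"].to_numpy()
        if ids.size < 3:
            logger.warning("group %s has %d sweeps; skipping rejection", key, ids.size)
            continue
        X = np.stack([windowed_trace(by_id[i], window_ms, baseline_ms) for i in ids])
        ranked = pca_artifact_rank(X, ids)
        sel = out["sweep_id"].isin(ids)
        rms_map = dict(zip(ranked["sweep_id"], ranked["rms_error"]))
        out.loc[sel, "rms_error"] = out.loc[sel, "sweep_id"].map(rms_map)
        med = float(ranked["rms_error"].median())
        norm = ranked["rms_error"] / med if med > 0 else ranked["rms_error"]
        out.loc[sel, "rms_error_norm"] = out.loc[sel, "sweep_id"].map(
            dict(zip(ranked["sweep_id"], norm))
        )
        group_keys.append((key, ids))
    scored = out[np.isfinite(out["rms_error_norm"])]
    if rms_threshold is not None:
        rejected_ids = set(scored.loc[scored["rms_error"] > rms_threshold, "sweep_id"])
    else:
        if cutoff_fraction is None:
            raise ValueError("give exactly one of cutoff_fraction or rms_threshold")
        if not (0.0 <= cutoff_fraction <= 1.0):
            raise ValueError(f"cutoff_fraction {cutoff_fraction} outside [0, 1]")
        n_reject = int(round(cutoff_fraction * len(scored)))
        ranked_all = scored.sort_values(
            ["rms_error_norm", "sweep_id"], ascending=[False, True]
        )
        rejected_ids = set(ranked_all["sweep_id"].iloc[:n_reject])
    out["rejected"] = out["sweep_id"].isin(rejected_ids)
    for key, ids in group_keys:
        report["groups"].append(
            {
                "group": [str(k) for k in (key if isinstance(key, tuple) else (key,))],
                "n": int(ids.size),
                "n_rejected": int(sum(i in rejected_ids for i in ids)),
            }
        )
    report["n_rejected"] = int(out["rejected"].sum())
    logger.info(
        "artifact rejection: %d / %d sweeps flagged (%.2f%%)",
        report["n_rejected"], len(out),
        100 * report["n_rejected"] / max(len(out), 1),
    )
    return out, report
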