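"""Softplus recruitment-curve fitting with a shared offset.

MEP size as a function of stimulus intensity is modeled as

    y = o + (b / k) * log(1 + exp(k * (x - x_th)))

with offset ``o`` (µVs), slope ``b`` (µVs/mA), threshold ``x_th`` (mA) and
``k = 20`` fixed, which makes the curve an arbitrarily-close smooth
approximation of a rectified linear recruitment while staying numerically
stable.  Within one (participant, muscle), the curves of all electrode
locations are fit jointly with a single shared offset — some recordings
never tested a sub-threshold intensity, so the offset is not identifiable
per location.  The sum of squared residuals is minimized by a derivative-free
generalized pattern search (coordinate polling with an expanding/contracting
mesh), restarted from a fixed table of jittered initializations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOFTPLUS_K = 20.0

#: Parameter bounds: offset >= 0, slope >= 0, threshold within [-1, 9] mA.
THRESHOLD_BOUNDS = (-1.0, 9.0)

#: Pattern-search mesh schedule.
MESH_START = 0.5
MESH_CONTRACTION = 0.5
MESH_EXPANSION = 2.0
MESH_TOL = 1e-4

N_STARTS = 5


def softplus_response(
    x, o: float, b: float, x_th: float, k: float = SOFTPLUS_K
) -> np.ndarray | float:
    """Softplus recruitment curve, overflow-safe for large ``k * (x - x_th)``."""
    x = np.asarray(x, dtype=float)
    y = o + (b / k) * np.logaddexp(0.0, k * (x - x_th))
    return float(y) if y.ndim == 0 else y


def pattern_search(
    objective,
    x0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    mesh0: np.ndarray,
    contraction: float = MESH_CONTRACTION,
    expansion: float = MESH_EXPANSION,
    mesh_tol: float = MESH_TOL,
    max_iter: int = 20000,
) -> tuple[np.ndarray, float, bool]:
    """Generalized pattern search with coordinate polling.

    Polls the 2n coordinate directions scaled by the current mesh; moves to
    the best improving point (expanding the mesh up to its starting size),
    otherwise contracts the mesh.  Stops when every mesh size falls below
    ``mesh_tol``.  Deterministic given the start point and mesh schedule.
    The incumbent objective value never increases.
    """
    x = np.clip(np.asarray(x0, dtype=float), lower, upper)
    mesh = np.asarray(mesh0, dtype=float).copy()
    mesh_cap = mesh.copy()
    f = float(objective(x))
    n = x.size
    converged = False
    for _ in range(max_iter):
        if np.all(mesh < mesh_tol):
            converged = True
            break
        best_f, best_x = f, None
        for i in range(n):
            for sgn in (1.0, -1.0):
                cand = x.copy()
                cand[i] = np.clip(cand[i] + sgn * mesh[i], lower[i], upper[i])
                if cand[i] == x[i]:
                    continue
                fc = float(objective(cand))
                if fc < best_f:
                    best_f, best_x = fc, cand
        if best_x is not None:
            x, f = best_x, best_f
            mesh = np.minimum(mesh * expansion, mesh_cap)
        else:
            mesh = mesh * contraction
    return x, f, converged


@dataclass
class RecruitmentFit:
    """Fitted recruitment parameters for one (participant, muscle, location)."""

    participant_id: str
    muscle: str
    side: str
    location: str  # electrode position, e.g. midline / lateral
    offset: float  # µVs, shared across locations of the (participant, muscle)
    slope: float  # µVs/mA
    threshold: float  # mA
    k: float
    residual_rms: float  # µVs
    n_points: int
    converged: bool
    at_bounds: bool
    #: False when the slope collapsed to ~0 (flat data) or the threshold sits
    #: on a bound; the threshold value is then arbitrary.
    threshold_identifiable: bool = True


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Heuristic (threshold, slope) start: intensity at half-max, upper-segment slope."""
    y_rng = y.max() - y.min()
    if y_rng <= 0:
        return float(np.median(x)), 0.0
    half = y.min() + 0.5 * y_rng
    x_th0 = float(x[int(np.argmin(np.abs(y - half)))])
    # slope of the upper linear segment (top half of tested intensities)
    upper = x >= np.median(x)
    if upper.sum() >= 2 and np.ptp(x[upper]) > 0:
        b0 = float(np.polyfit(x[upper], y[upper], 1)[0])
    else:
        b0 = float(y_rng / max(np.ptp(x), 1.0))
    return x_th0, max(b0, 0.0)


def fit_recruitment(
    samples: pd.DataFrame,
    k: float = SOFTPLUS_K,
    n_starts: int = N_STARTS,
) -> pd.DataFrame:
    """Fit shared-offset softplus curves per (participant, muscle, side).

    Parameters
    ----------
    samples : DataFrame
        Non-rejected ramp sweeps with columns ``participant_id``, ``muscle``,
        ``side``, ``position`` (electrode location), ``intensity``, ``auc``.

    Returns
    -------
    DataFrame of :class:`RecruitmentFit` rows, one per (participant, muscle,
    side, location), sharing one offset within each (participant, muscle,
    side) group.
    """
    required = {"participant_id", "muscle", "side", "position", "intensity", "auc"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples table lacks columns: {sorted(missing)}")
    fits: list[RecruitmentFit] = []
    for (pid, muscle, side), g in samples.groupby(
        ["participant_id", "muscle", "side"], sort=True
    ):
        locations = sorted(g["position"].unique())
        xs, ys = [], []
        for loc in locations:
            gl = g[g["position"] == loc]
            x = gl["intensity"].to_numpy(float)
            y = gl["auc"].to_numpy(float)
            if np.unique(x).size < 2:
                raise ValueError(
                    f"({pid}, {muscle}, {side}, {loc}): need >= 2 distinct intensities"
                )
            xs.append(x)
            ys.append(y)
        fits.extend(
            _fit_group(pid, muscle, side, locations, xs, ys, k, n_starts)
        )
    return pd.DataFrame([f.__dict__ for f in fits])


def _fit_group(pid, muscle, side, locations, xs, ys, k, n_starts):
    n_loc = len(locations)
    all_y = np.concatenate(ys)
    o0 = float(min(y.min() for y in ys))
    inits = [o0]
    lower = [0.0]
    upper = [np.inf]
    mesh0 = [MESH_START]
    for x, y in zip(xs, ys):
        x_th0, b0 = _initial_guess(x, y)
        inits.extend([b0, x_th0])
        lower.extend([0.0, THRESHOLD_BOUNDS[0]])
        upper.extend([np.inf, THRESHOLD_BOUNDS[1]])
        mesh0.extend([MESH_START, MESH_START])
    inits = np.array(inits)
    lower = np.array(lower)
    upper = np.array(upper)
    mesh0 = np.array(mesh0)

    def objective(theta):
        sse = 0.0
        o = theta[0]
        for i in range(n_loc):
            b, x_th = theta[1 + 2 * i], theta[2 + 2 * i]
            r = ys[i] - softplus_response(xs[i], o, b, x_th, k)
            sse += float(r @ r)
        return sse

    # fixed jitter table: multi-start is deterministic regardless of caller state
    jitter_rng = np.random.default_rng(20_220_914)
    best = None
    any_converged = False
    for start in range(n_starts):
        x0 = inits.copy()
        if start > 0:
            x0 = x0 + jitter_rng.normal(0.0, 1.0, size=x0.size) * np.maximum(
                0.2 * np.abs(x0), 0.2
            )
        sol, f, conv = pattern_search(objective, x0, lower, upper, mesh0)
        any_converged = any_converged or conv
        if best is None or f < best[1]:
            best = (sol, f, conv)
    theta, sse, conv = best
    if not any_converged:
        logger.warning("(%s, %s, %s): pattern search did not converge", pid, muscle, side)
    rms = float(np.sqrt(sse / all_y.size))
    out = []
    for i, loc in enumerate(locations):
        b, x_th = float(theta[1 + 2 * i]), float(theta[2 + 2 * i])
        at_bounds = bool(
            np.isclose(x_th, THRESHOLD_BOUNDS[0]) or np.isclose(x_th, THRESHOLD_BOUNDS[1])
        )
        identifiable = (b > 1e-9) and not at_bounds
        if not identifiable:
            logger.warning(
                "(%s, %s, %s, %s): threshold %.3f mA not identifiable (slope %.3g, "
                "at_bounds=%s)", pid, muscle, side, loc, x_th, b, at_bounds,
            )
        out.append(
            RecruitmentFit(
                pid, muscle, side, loc,
                offset=float(theta[0]), slope=b, threshold=x_th, k=k,
                residual_rms=rms, n_points=int(all_y.size),
                converged=bool(conv), at_bounds=at_bounds,
                threshold_identifiable=identifiable,
            )
        )
    return out


def threshold_and_slope_ratios(
    fits: pd.DataFrame,
    midline: str = "midline",
    lateral: str = "lateral",
) -> tuple[pd.DataFrame, dict]:
    """Per-participant midline/lateral threshold and slope ratios + group tests.

    Ratios (midline_threshold / lateral_threshold and lateral_slope /
    midline_slope) are averaged across segments, muscles and sides within
    each participant; the group-level comparison is a Wilcoxon signed-rank
    test on the per-participant paired differences (midline − lateral
    threshold; lateral − midline slope).  Participants lacking one location
    are excluded with a log entry.
    """
    from .group_stats import wilcoxon_signed_rank

    rows = []
    for pid, g in fits.groupby("participant_id", sort=True):
        pairs = []
        for (muscle, side), gm in g.groupby(["muscle", "side"]):
            locs = dict(zip(gm["location"], gm.index))
            if midline not in locs or lateral not in locs:
                continue
            m = gm.loc[locs[midline]]
            l = gm.loc[locs[lateral]]
            if "threshold_identifiable" in gm.columns and not (
                m["threshold_identifiable"] and l["threshold_identifiable"]
            ):
                continue
            if l["threshold"] <= 0 or m["slope"] <= 0:
                continue
            pairs.append(
                {
                    "thr_ratio": m["threshold"] / l["threshold"],
                    "slope_ratio": l["slope"] / m["slope"],
                    "thr_diff": m["threshold"] - l["threshold"],
                    "slope_diff": l["slope"] - m["slope"],
                }
            )
        if not pairs:
            logger.info("participant %s lacks a midline/lateral fitted pair; excluded", pid)
            continue
        d = pd.DataFrame(pairs).mean()
        rows.append({"participant_id": pid, **d.to_dict()})
    table = pd.DataFrame(rows)
    tests = {}
    if len(table) >= 2:
        thr = wilcoxon_signed_rank(table["thr_diff"].to_numpy())
        slp = wilcoxon_signed_rank(table["slope_diff"].to_numpy())
        tests = {
            "threshold": {"statistic": thr.statistic, "p": thr.pvalue, "n": len(table)},
            "slope": {"statistic": slp.statistic, "p": slp.pvalue, "n": len(table)},
        }
    return table, tests
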