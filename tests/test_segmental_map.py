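"""Activation map, Spearman similarity, clustering, sensitivity, gradients."""

import numpy as np
import pandas as pd
import pytest

from cordmap import ConfigurationError
from cordmap.segmental_map import (
    SegmentMuscleMatrix,
    cluster_segments,
    gradient_per_mm,
    group_auc_matrix,
    map_summary,
    segment_correlation_matrix,
    sensitivity_exclude,
)


def _features(cells, position="lateral", block="fixed"):
    """cells: list of (pid, segment, muscle, auc) expanded to single sweeps."""
    rows = [
        {"participant_id": p, "segment": s, "muscle": m, "side": "left",
         "position": position, "block": block, "auc": a, "rejected": False}
        for (p, s, m, a) in cells
    ]
    return pd.DataFrame(rows)


class TestGroupMatrix:
    def test_identical_values_passthrough(self):
        feats = _features([("P01", "C7", "biceps", 2.5), ("P02", "C7", "biceps", 2.5)])
        m = group_auc_matrix(feats)
        assert m.values.loc["C7", "biceps"] == pytest.approx(2.5)
        assert m.support.loc["C7", "biceps"] == 2

    def test_geometric_mean(self):
        """Participants at 1 and 4 µVs combine to sqrt(1*4) = 2 µVs."""
        feats = _features([("P01", "C7", "biceps", 1.0), ("P02", "C7", "biceps", 4.0)])
        assert group_auc_matrix(feats).values.loc["C7", "biceps"] == pytest.approx(2.0)

    def test_zero_cell_substitution(self):
        feats = _features([("P01", "C7", "biceps", 0.0), ("P02", "C7", "biceps", 4.0)])
        m = group_auc_matrix(feats)
        assert m.n_zero_substituted == 1
        assert m.values.loc["C7", "biceps"] == pytest.approx(np.sqrt(0.165 * 4.0))

    def test_missing_cell_is_nan_not_zero(self):
        feats = _features([("P01", "C7", "biceps", 1.0), ("P01", "C8", "triceps", 2.0)])
        m = group_auc_matrix(feats)
        assert np.isnan(m.values.loc["C7", "triceps"])

    def test_rows_in_rostrocaudal_order(self):
        feats = _features(
            [("P01", "T1", "biceps", 1.0), ("P01", "C4", "biceps", 1.0),
             ("P01", "C7", "biceps", 1.0)]
        )
        assert list(group_auc_matrix(feats).values.index) == ["C4", "C7", "T1"]

    def test_am_gm_inequality(self, small_cohort):
        """Group geometric-mean cells never exceed the arithmetic mean."""
        _, _, _, features = small_cohort
        m = group_auc_matrix(features)
        d = features[(features["block"] == "fixed") & (features["position"] == "lateral")]
        for seg in m.values.index:
            for mus in m.values.columns:
                gm = m.values.loc[seg, mus]
                if not np.isfinite(gm):
                    continue
                am = np.mean(
                    [g[(g["segment"] == seg) & (g["muscle"] == mus)]["auc"].mean()
                     for _, g in d.groupby("participant_id")]
                )
                assert gm <= am + 1e-12


def _matrix_from_vectors(vectors_by_pid, segments, muscles):
    per_part = {
        pid: pd.DataFrame(v, index=segments, columns=muscles, dtype=float)
        for pid, v in vectors_by_pid.items()
    }
    any_m = next(iter(per_part.values()))
    return SegmentMuscleMatrix(any_m, any_m.notna().astype(int), per_part)


class TestSpearman:
    muscles = ["m1", "m2", "m3", "m4", "m5", "m6"]

    def test_identical_vectors_unit_correlation(self):
        v = [[1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6]]
        m = _matrix_from_vectors({"P01": v}, ["C4", "C5"], self.muscles)
        corr, support = segment_correlation_matrix(m, muscles=tuple(self.muscles))
        assert corr.loc["C4", "C5"] == pytest.approx(1.0)
        assert support.loc["C4", "C5"] == 1

    def test_perfect_antirank(self):
        v = [[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1]]
        m = _matrix_from_vectors({"P01": v}, ["C4", "C5"], self.muscles)
        corr, _ = segment_correlation_matrix(m, muscles=tuple(self.muscles))
        assert corr.loc["C4", "C5"] == pytest.approx(-1.0)

    def test_rank_formula_toy_case(self):
        """(1,2,3,4) vs (2,1,4,3): rho = 1 - 6*4/(4*15) = 0.6."""
        muscles = ["m1", "m2", "m3", "m4"]
        v = [[1, 2, 3, 4], [2, 1, 4, 3]]
        m = _matrix_from_vectors({"P01": v}, ["C4", "C5"], muscles)
        corr, _ = segment_correlation_matrix(m, muscles=tuple(muscles))
        assert corr.loc["C4", "C5"] == pytest.approx(0.6)

    def test_average_across_participants(self):
        muscles = ["m1", "m2", "m3", "m4"]
        m = _matrix_from_vectors(
            {"P01": [[1, 2, 3, 4], [1, 2, 3, 4]],
             "P02": [[1, 2, 3, 4], [2, 1, 4, 3]]},
            ["C4", "C5"], muscles,
        )
        corr, support = segment_correlation_matrix(m, muscles=tuple(muscles))
        assert corr.loc["C4", "C5"] == pytest.approx((1.0 + 0.6) / 2)
        assert support.loc["C4", "C5"] == 2

    def test_insufficient_shared_muscles_excluded(self):
        muscles = ["m1", "m2", "m3", "m4"]
        v = [[1, 2, np.nan, np.nan], [2, 1, np.nan, np.nan]]
        m = _matrix_from_vectors({"P01": v}, ["C4", "C5"], muscles)
        corr, support = segment_correlation_matrix(m, muscles=tuple(muscles))
        assert np.isnan(corr.loc["C4", "C5"])
        assert support.loc["C4", "C5"] == 0


def brute_force_single_linkage(D, labels):
    """Exhaustive single-linkage agglomeration oracle."""
    clusters = [frozenset([l]) for l in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = min(
                    D.loc[a, b] for a in clusters[i] for b in clusters[j]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i] | clusters[j], d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
            clusters[i] | clusters[j]
        ]
    return merges


class TestClustering:
    def _corr(self, segs, fill):
        M = pd.DataFrame(fill, index=segs, columns=segs, dtype=float)
        np.fill_diagonal(M.values, 1.0)
        return M

    def test_two_perfect_blocks(self):
        segs = ["C4", "C5", "C7", "C8"]
        M = self._corr(segs, 0.0)
        for a, b in (("C4", "C5"), ("C7", "C8")):
            M.loc[a, b] = M.loc[b, a] = 1.0
        tree = cluster_segments(M)
        assert tree.n_clusters == 2
        assert tree.labels["C4"] == tree.labels["C5"]
        assert tree.labels["C7"] == tree.labels["C8"]
        assert tree.labels["C4"] != tree.labels["C7"]

    def test_reported_cluster_structure(self):
        """Within-caudal 0.85, within-rostral 0.57, between 0.5: the caudal
        triple (C7, C8, T1) merges before any rostral-caudal merge."""
        segs = ["C4", "C5", "C6", "C7", "C8", "T1"]
        caudal = {"C7", "C8", "T1"}
        M = self._corr(segs, 0.5)
        for i, a in enumerate(segs):
            for b in segs[i + 1:]:
                if a in caudal and b in caudal:
                    M.loc[a, b] = M.loc[b, a] = 0.85
                elif a not in caudal and b not in caudal:
                    M.loc[a, b] = M.loc[b, a] = 0.57
        tree = cluster_segments(M)
        caudal_done = False
        for a, b, h in tree.merges:
            members = set(a) | set(b)
            if members == caudal:
                caudal_done = True
            if (members & caudal) and (members - caudal):
                assert caudal_done, "mixed merge before the caudal triple formed"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        segs = ["C4", "C5", "C7", "T1"]
        for _ in range(10):
            v = rng.uniform(-0.5, 0.95, 6)
            M = self._corr(segs, 0.0)
            idx = 0
            for i in range(4):
                for j in range(i + 1, 4):
                    M.iloc[i, j] = M.iloc[j, i] = v[idx]
                    idx += 1
            tree = cluster_segments(M)
            oracle = brute_force_single_linkage(1.0 - M, segs)
            for (a, b, h), (members, d) in zip(tree.merges, oracle):
                assert h == pytest.approx(d)
                assert set(a) | set(b) <= members

    def test_input_order_invariance(self):
        rng = np.random.default_rng(1)
        segs = ["C4", "C5", "C7", "T1"]
        M = self._corr(segs, 0.0)
        vals = rng.uniform(0, 0.9, 6)
        idx = 0
        for i in range(4):
            for j in range(i + 1, 4):
                M.iloc[i, j] = M.iloc[j, i] = vals[idx]
                idx += 1
        t1 = cluster_segments(M)
        perm = ["C7", "C4", "T1", "C5"]
        t2 = cluster_segments(M.loc[perm, perm])
        part1 = {frozenset(s for s in segs if t1.labels[s] == c) for c in t1.labels.values()}
        part2 = {frozenset(s for s in segs if t2.labels[s] == c) for c in t2.labels.values()}
        assert part1 == part2

    def test_asymmetric_errors(self):
        M = self._corr(["C4", "C5"], 0.3)
        M.iloc[0, 1] = 0.9
        with pytest.raises(ValueError, match="symmetric"):
            cluster_segments(M)


class TestMapSummary:
    def _matrix(self, cells):
        segs = sorted({s for s, _, _ in cells}, key=["C4", "C5", "C6", "C7", "C8", "T1"].index)
        muscles = sorted({m for _, m, _ in cells})
        values = pd.DataFrame(np.nan, index=segs, columns=muscles)
        support = pd.DataFrame(0, index=segs, columns=muscles)
        for s, m, v in cells:
            values.loc[s, m] = v
            support.loc[s, m] = 3
        return SegmentMuscleMatrix(values, support)

    def test_single_survivor_full_fraction(self):
        out = map_summary(self._matrix([("C7", "biceps", 2.0), ("C7", "triceps", 0.1)]))
        assert len(out) == 1
        assert out.iloc[0]["fraction_pct"] == 100.0

    def test_equal_split(self):
        out = map_summary(self._matrix([("C7", "biceps", 2.0), ("C7", "triceps", 2.0)]))
        assert sorted(out["fraction_pct"]) == [50.0, 50.0]

    def test_all_below_threshold_empty_segment(self):
        out = map_summary(self._matrix([("C7", "biceps", 0.2), ("C7", "triceps", 0.33)]))
        assert out.iloc[0]["empty"] and out.iloc[0]["muscle"] is None


class TestSensitivity:
    def _flags(self, entries):
        return pd.DataFrame(
            [{"participant_id": p, "segment": s, "t2_change": f} for p, s, f in entries]
        )

    def test_no_flags_unit_correlation(self, small_cohort):
        _, _, _, features = small_cohort
        flags = self._flags([("P01", "C7", False)])
        filtered, r, full, excl = sensitivity_exclude(features, flags)
        assert len(filtered) == len(features)
        assert r == pytest.approx(1.0)

    def test_unknown_segment_errors(self, small_cohort):
        _, _, _, features = small_cohort
        with pytest.raises(ConfigurationError, match="unknown segments"):
            sensitivity_exclude(features, self._flags([("P01", "C9", True)]))

    def test_all_flagged_errors(self, small_cohort):
        cfg, _, _, features = small_cohort
        entries = [
            (p, s, True)
            for p in features["participant_id"].unique()
            for s in cfg.segments_per_participant
        ]
        with pytest.raises(ValueError, match="excluded"):
            sensitivity_exclude(features, self._flags(entries))

    def test_matches_oracle_recomputation(self, small_cohort):
        """Exclusion correlation equals a from-scratch recomputation."""
        _, _, _, features = small_cohort
        flags = self._flags([("P01", "C7", True), ("P02", "C8", True)])
        _, r, full, excl = sensitivity_exclude(features, flags)
        manual = features[
            ~features.apply(
                lambda x: (x["participant_id"], x["segment"]) in
                {("P01", "C7"), ("P02", "C8")}, axis=1)
        ]
        oracle_excl = group_auc_matrix(manual)
        a = full.values.to_numpy().ravel()
        b = oracle_excl.values.reindex(
            index=full.values.index, columns=full.values.columns
        ).to_numpy().ravel()
        ok = np.isfinite(a) & np.isfinite(b)
        oracle_r = np.corrcoef(a[ok], b[ok])[0, 1]
        assert r == pytest.approx(oracle_r, rel=1e-12)


class TestGradients:
    def _grad_features(self, lat, mid, pid="P01", muscle="triceps"):
        cells = [(pid, s, muscle, a) for s, a in lat.items()]
        feats = _features(cells)
        mid_feats = _features(
            [(pid, s, muscle, a) for s, a in mid.items()], position="midline"
        )
        return pd.concat([feats, mid_feats], ignore_index=True)

    def test_hand_computed_example(self):
        """Lateral C6=3, C7=5 (max), C8=2; midline C7=1:
        RC = ((5-3)+(5-2))/2 / 12.5 = 0.2; ML = (5-1)/6.7."""
        feats = self._grad_features(
            {"C6": 3.0, "C7": 5.0, "C8": 2.0}, {"C7": 1.0}
        )
        table, _ = gradient_per_mm(feats)
        assert table.iloc[0]["rostrocaudal"] == pytest.approx(0.2)
        assert table.iloc[0]["midline_lateral"] == pytest.approx(4.0 / 6.7)

    def test_flat_profile_zero_gradients(self):
        feats = self._grad_features(
            {"C6": 2.0, "C7": 2.0, "C8": 2.0}, {"C6": 2.0, "C7": 2.0, "C8": 2.0}
        )
        table, _ = gradient_per_mm(feats)
        assert table.iloc[0]["rostrocaudal"] == 0.0
        assert table.iloc[0]["midline_lateral"] == 0.0

    def test_scaling_property(self):
        feats = self._grad_features({"C6": 3.0, "C7": 5.0, "C8": 2.0}, {"C7": 1.0})
        t1, _ = gradient_per_mm(feats)
        feats2 = feats.copy()
        feats2["auc"] *= 3.0
        t2, _ = gradient_per_mm(feats2)
        assert t2.iloc[0]["rostrocaudal"] == pytest.approx(3 * t1.iloc[0]["rostrocaudal"])
        assert t2.iloc[0]["midline_lateral"] == pytest.approx(
            3 * t1.iloc[0]["midline_lateral"]
        )

    def test_caudal_tiebreak(self):
        """Equal maxima resolve toward the more caudal segment."""
        feats = self._grad_features(
            {"C6": 5.0, "C7": 5.0, "C8": 1.0}, {"C6": 9.0, "C7": 2.0}
        )
        table, _ = gradient_per_mm(feats)
        # max at C7 (caudal tie-break): ML uses midline C7 = 2 -> (5-2)/6.7
        assert table.iloc[0]["midline_lateral"] == pytest.approx(3.0 / 6.7)

    def test_no_neighbors_skipped(self):
        feats = self._grad_features({"C7": 5.0}, {"C7": 1.0})
        table, _ = gradient_per_mm(feats)
        assert len(table) == 0

    def test_muscle_order_invariance(self):
        f1 = pd.concat(
            [self._grad_features({"C6": 3.0, "C7": 5.0}, {"C7": 1.0}, muscle="a"),
             self._grad_features({"C6": 1.0, "C7": 4.0}, {"C7": 2.0}, muscle="b")],
            ignore_index=True,
        )
        t1, _ = gradient_per_mm(f1)
        t2, _ = gradient_per_mm(f1.iloc[::-1].reset_index(drop=True))
        assert t1.iloc[0]["rostrocaudal"] == pytest.approx(t2.iloc[0]["rostrocaudal"])
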