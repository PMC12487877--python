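import numpy as np
import pandas as pd
import pytest

from qdpi import qc_filter as qc
from qdpi.io_core import KeypointTable
from qdpi.qc_filter import QCConfig
from qdpi.synthetic import (
    KeypointSimConfig,
    ViolationSpec,
    simulate_keypoints,
    simulate_pose_tracks,
)


def track_from_positions(positions):
    return pd.DataFrame(
        {
            "frame": range(len(positions)),
            "x": [p[0] for p in positions],
            "y": [p[1] for p in positions],
        }
    )


class TestJumpFilter:
    def test_isolated_31px_glitch_flagged(self):
        track = track_from_positions([(0, 0), (0, 0), (31, 0), (0, 0), (0, 0)])
        flags = qc.jump_filter(track, max_jump=30.0)
        assert flags.tolist() == [False, False, True, False, False]

    def test_exact_30px_step_kept(self):
        """The jump rule is strict: 'more than 30 pixels'."""
        track = track_from_positions([(0, 0), (0, 0), (30, 0), (0, 0)])
        assert not qc.jump_filter(track, max_jump=30.0).any()

    def test_boundary_frames_use_single_neighbor(self):
        track = track_from_positions([(100, 0), (0, 0), (0, 0)])
        flags = qc.jump_filter(track, max_jump=30.0)
        assert flags.tolist() == [True, False, False]

    def test_bounded_random_walk_has_zero_flags(self, rng):
        steps = rng.uniform(-15, 15, size=(200, 2))  # |step| < 30 always
        positions = np.cumsum(steps, axis=0)
        track = track_from_positions(positions)
        assert not qc.jump_filter(track, max_jump=30.0).any()

    def test_any_neighbor_rule_flags_both_sides(self):
        track = track_from_positions([(0, 0), (0, 0), (31, 0), (0, 0)])
        flags = qc.jump_filter(track, max_jump=30.0, rule="any_neighbor")
        assert flags.tolist() == [False, True, True, True]

    def test_missing_coordinates_skipped_in_neighbor_chain(self):
        track = track_from_positions([(0, 0), (np.nan, np.nan), (5, 0), (40, 0), (5, 0), (5, 0)])
        flags = qc.jump_filter(track, max_jump=30.0)
        assert flags.tolist() == [False, False, False, True, False, False]


class TestValidityThresholds:
    def test_low_anchor_values(self):
        assert qc.validity_thresholds(0.7) == (75.0, 5.0)

    def test_full_confidence_values(self):
        assert qc.validity_thresholds(1.0) == (25.0, 15.0)

    def test_midpoint_interpolation(self):
        assert qc.validity_thresholds(0.85) == pytest.approx((50.0, 10.0))

    def test_scores_below_anchor_clamped(self):
        assert qc.validity_thresholds(0.3) == (75.0, 5.0)

    def test_knee_anchor_at_half(self):
        knee = QCConfig.knee()
        assert qc.validity_thresholds(0.5, knee) == (75.0, 5.0)
        assert qc.validity_thresholds(0.75, knee) == pytest.approx((50.0, 10.0))

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            qc.validity_thresholds(1.2)


class TestValidityDecisions:
    """Peak/distance pairs against the confidence-scaled thresholds."""

    @pytest.mark.parametrize(
        "score,peak,dist,valid",
        [
            (1.0, 30.0, 10.0, True),  # thresholds (25, 15)
            (0.7, 30.0, 2.0, False),  # peak below the 75 a.u. anchor
            (0.7, 80.0, 6.0, False),  # distance above the 5 px anchor
            (0.7, 80.0, 5.0, True),
        ],
    )
    def test_anchor_cases(self, score, peak, dist, valid):
        min_peak, max_dist = qc.validity_thresholds(score)
        assert (peak >= min_peak and dist <= max_dist) is valid


class TestDropBudget:
    @pytest.mark.parametrize(
        "n,expected",
        [(0, 0), (3, 0), (10, 3), (12, 3), (7, 1), (5, 0), (8, 2), (9, 2)],
    )
    def test_budget_values(self, n, expected):
        assert qc.drop_budget(n) == expected

    def test_budget_monotone_in_n(self):
        budgets = [qc.drop_budget(n) for n in range(15)]
        assert budgets == sorted(budgets)


class TestPairwiseDistance:
    def test_301px_pair_flagged(self):
        assert qc.pairwise_distance_flag(np.array([[0.0, 0.0], [301.0, 0.0]]))

    def test_exact_300px_pair_kept(self):
        assert not qc.pairwise_distance_flag(np.array([[0.0, 0.0], [300.0, 0.0]]))

    def test_matches_all_pairs_oracle(self, rng):
        points = rng.uniform(0, 400, size=(12, 2))
        expected = any(
            np.hypot(*(points[i] - points[j])) > 300.0
            for i in range(12)
            for j in range(i + 1, 12)
        )
        assert qc.pairwise_distance_flag(points) == expected

    def test_single_point_never_flagged(self):
        assert not qc.pairwise_distance_flag(np.array([[0.0, 0.0]]))


def rank2_table(n_frames=40, outlier_frame=None, seed=0):
    """Exactly rank-2 pose data over the 10 standard nodes (20 dims)."""
    rng = np.random.default_rng(seed)
    base = np.array([crd for node in qc.STANDARD_NODES for crd in (np.array([1.0, 0.5]),)])
    mode1 = rng.normal(0, 1, 20)
    mode2 = rng.normal(0, 1, 20)
    mode2 -= (mode2 @ mode1) / (mode1 @ mode1) * mode1
    rows = []
    for f in range(n_frames):
        pose = 200.0 + 30.0 * np.sin(f / 3.0) * mode1 + 30.0 * np.cos(f / 5.0) * mode2
        if f == outlier_frame:
            ortho = rng.normal(0, 1, 20)
            for m in (mode1, mode2, np.ones(20)):
                ortho -= (ortho @ m) / (m @ m) * m
            pose = pose + 40.0 * ortho / np.abs(ortho).max()
        for i, node in enumerate(qc.STANDARD_NODES):
            rows.append(
                {
                    "frame": f,
                    "camera": "cam0",
                    "node": node,
                    "x": pose[2 * i],
                    "y": pose[2 * i + 1],
                    "score": 0.95,
                }
            )
    return pd.DataFrame(rows)


class TestPCAOutlierFilter:
    def test_rank2_data_selects_two_components_no_flags(self):
        flags, k, skipped = qc.pca_outlier_filter(rank2_table())
        assert not skipped
        assert k == 2
        assert not flags["excluded_pca"].any()

    def test_identical_frames_zero_flags(self):
        df = rank2_table(n_frames=1)
        df = pd.concat([df.assign(frame=f) for f in range(5)], ignore_index=True)
        flags, _, skipped = qc.pca_outlier_filter(df)
        assert not skipped and not flags["excluded_pca"].any()

    def test_orthogonal_outlier_frame_flagged_exactly(self):
        flags, k, _ = qc.pca_outlier_filter(rank2_table(outlier_frame=17))
        assert k == 2
        assert flags.loc[flags["frame"] == 17, "excluded_pca"].all()
        assert flags["excluded_pca"].sum() == 1

    def test_insufficient_complete_frames_skips_stage(self):
        df = rank2_table(n_frames=1)
        with pytest.warns(UserWarning, match="skipped"):
            _, _, skipped = qc.pca_outlier_filter(df)
        assert skipped


def benchmark_report(seed=0, violations=ViolationSpec(1, 1, 1, 1, 1, 1, 1, 0), config=None):
    cfg = KeypointSimConfig(seed=seed, violations=violations)
    table, labels = simulate_keypoints(simulate_pose_tracks(cfg), cfg)
    report = qc.run_cascade(table, config or QCConfig())
    return report, labels, table


class TestCascade:
    def test_clean_dataset_fully_survives(self):
        report, _, table = benchmark_report(violations=ViolationSpec())
        assert report.counts["n_surviving"] == len(table.records)

    def test_one_exclusion_per_injected_rule(self):
        report, labels, _ = benchmark_report(seed=5)
        c = report.counts
        assert c["excluded_jump"] == 1
        assert c["invisible"] == 1
        assert c["invalid_distance"] == 1
        assert c["excluded_pca"] == 1
        assert c["excluded_drop_budget"] == 1
        assert c["excluded_pairwise"] == 1
        # the validity violation plus the five evidence-starved budget records
        assert c["invalid_fluor"] == 6

    def test_no_false_exclusions_and_full_recall(self):
        report, labels, _ = benchmark_report(seed=2)
        df = report.records
        excluded = set()
        for _, r in df.iterrows():
            if r[list(qc.RECORD_FLAGS)].any():
                excluded.add((r["frame"], r["node"]))
        bad_frames = report.frame_flags[report.frame_flags[list(qc.FRAME_FLAGS)].any(axis=1)]
        for _, r in bad_frames.iterrows():
            for _, q in df[df["frame"] == r["frame"]].iterrows():
                excluded.add((q["frame"], q["node"]))
        labeled = set(zip(labels["frame"], labels["node"]))
        assert excluded == labeled

    def test_knee_config_skips_pca(self):
        df = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(5), 2),
                "camera": "cam0",
                "node": np.tile(["knee_left", "knee_right"], 5),
                "x": 100.0,
                "y": np.tile([100.0, 140.0], 5),
                "score": 0.9,
                "peak_value": 150.0,
                "center_distance": 1.0,
            }
        )
        table = KeypointTable(records=df[["frame", "camera", "node", "x", "y", "score"]])
        table.records = df
        report = qc.run_cascade(table, QCConfig.knee())
        assert report.pca_skipped
        assert report.counts["n_surviving"] == len(df)

    def test_missing_evidence_is_invalid_with_reason(self):
        df = pd.DataFrame(
            {
                "frame": [0],
                "camera": ["cam0"],
                "node": ["back_top"],
                "x": [10.0],
                "y": [10.0],
                "score": [0.9],
            }
        )
        table = KeypointTable(records=df)
        report = qc.run_cascade(table, QCConfig(pca_enabled=False))
        assert report.counts["missing_evidence"] == 1
        assert report.counts["n_surviving"] == 0

    def test_deterministic_for_fixed_config(self):
        r1, _, _ = benchmark_report(seed=3)
        r2, _, _ = benchmark_report(seed=3)
        assert r1.counts == r2.counts
        pd.testing.assert_frame_equal(r1.records, r2.records)

    def test_loosening_thresholds_never_shrinks_survivors(self):
        report_tight, _, table = benchmark_report(seed=4)
        # PCA is turned off rather than loosened: relaxing the jump stage hands
        # its outliers to the PCA stage, which rightly flags them, so global
        # monotonicity only holds when a downstream stage is not newly exposed
        loose = QCConfig(
            max_jump=100.0,
            visibility_score=0.01,
            fluor_peak_at_low_anchor=30.0,
            fluor_peak_at_score1=1.0,
            max_dist_at_low_anchor=30.0,
            max_dist_at_score1=50.0,
            budget_max_drops=10,
            max_pair_distance=1000.0,
            pca_enabled=False,
        )
        report_loose = qc.run_cascade(table, loose)
        tight_keys = set(
            zip(report_tight.surviving.records["frame"], report_tight.surviving.records["node"])
        )
        loose_keys = set(
            zip(report_loose.surviving.records["frame"], report_loose.surviving.records["node"])
        )
        assert tight_keys <= loose_keys

    def test_reason_counts_consistent_with_sets(self):
        report, _, _ = benchmark_report(seed=6)
        df = report.records
        for flag in qc.RECORD_FLAGS:
            assert report.counts[flag] == int(df[flag].sum())
        assert report.counts["n_surviving"] == len(report.surviving.records)
        # survivors carry no exclusion flags
        surv = set(zip(report.surviving.records["frame"], report.surviving.records["node"]))
        flagged = set(
            zip(df.loc[df[list(qc.RECORD_FLAGS)].any(axis=1), "frame"],
                df.loc[df[list(qc.RECORD_FLAGS)].any(axis=1), "node"])
        )
        assert not (surv & flagged)


class TestConfigValidation:
    def test_threshold_direction_enforced(self):
        with pytest.raises(ValueError):
            QCConfig(fluor_peak_at_low_anchor=20.0)  # would increase with score
        with pytest.raises(ValueError):
            QCConfig(max_dist_at_low_anchor=20.0)

    def test_anchor_must_be_below_one(self):
        with pytest.raises(ValueError):
            QCConfig(low_anchor_score=1.0)
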