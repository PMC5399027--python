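"""Trajectory and principal-curve MDS: linear limits, generative-angle
recovery, orientation symmetry and hand-computed areas."""

import numpy as np
import pandas as pd
import pytest

from metaboeval.deregulation import (
    MdsResult,
    compute_mds,
    compute_trajectory,
    fit_principal_curve,
    mds_auc,
)
from metaboeval.multivariate import fit_pca
from metaboeval.stats import spearman_rho

rng = np.random.default_rng(2024)


def meta_frame(index, groups, days, animals=None, sample_type="study"):
    return pd.DataFrame(
        {
            "group": groups,
            "animal_id": animals or [f"A{i}" for i in range(len(index))],
            "day": days,
            "sample_type": sample_type,
        },
        index=index,
    )


class TestTrajectory:
    def test_group_means_match_bruteforce(self):
        scores = pd.DataFrame(
            rng.normal(size=(12, 2)),
            columns=["PC1", "PC2"],
            index=[f"S{i}" for i in range(12)],
        )
        groups = ["A"] * 6 + ["B"] * 6
        days = [0, 0, 1, 1, 2, 2] * 2
        meta = meta_frame(scores.index, groups, days)
        traj = compute_trajectory(scores, meta).table
        for g in ("A", "B"):
            for d in (0, 1, 2):
                rows = [
                    i
                    for i in range(12)
                    if groups[i] == g and days[i] == d
                ]
                expect = scores.iloc[rows].mean()
                got = traj[(traj.group == g) & (traj.day == d)].iloc[0]
                assert got["pc1"] == pytest.approx(expect["PC1"])
                assert got["pc2"] == pytest.approx(expect["PC2"])
        # baseline displacement is zero by construction
        assert (traj.groupby("group").first()["displacement"] == 0).all()

    def test_six_groups_five_days_thirty_points(self, preprocessed):
        from metaboeval.config import PipelineConfig
        from metaboeval.pipeline import stage_trajectory

        clean, *_ = preprocessed
        _, traj = stage_trajectory(clean, PipelineConfig(seed=11))
        assert len(traj.table) == 6 * 5

    def test_stationary_group_displacements_near_zero(self):
        """A time-stationary cloud yields displacements at noise scale only."""
        n = 40
        scores = pd.DataFrame(
            rng.normal(0, 1, size=(n, 2)), columns=["PC1", "PC2"],
            index=[f"S{i}" for i in range(n)],
        )
        days = np.tile([0, 1, 2, 3], n // 4)
        meta = meta_frame(scores.index, ["A"] * n, days)
        traj = compute_trajectory(scores, meta).table
        # displacement of group means of 10 samples: sd ~ sqrt(2)/sqrt(10)
        assert traj["displacement"].max() < 1.5

    def test_qc_rows_excluded(self):
        scores = pd.DataFrame(
            rng.normal(size=(4, 2)), columns=["PC1", "PC2"],
            index=["S0", "S1", "Q0", "Q1"],
        )
        meta = meta_frame(
            scores.index, ["A", "A", "QC", "QC"], [0, 1, 0, 0],
            sample_type=["study", "study", "qc", "qc"],
        )
        traj = compute_trajectory(scores, meta).table
        assert set(traj["group"]) == {"A"}


class TestPrincipalCurve:
    def test_collinear_limit_matches_pc1(self):
        """On exactly collinear data the MDS ranking equals the PC1 ranking."""
        t = np.sort(rng.uniform(-2, 2, 40))
        X = np.column_stack([t, 2 * t, -0.5 * t])
        df = pd.DataFrame(X, index=[f"S{i}" for i in range(40)])
        healthy = df.index[:5]  # low-t end
        curve = fit_principal_curve(df, healthy_ids=healthy, n_pcs=2)
        mds = compute_mds(curve, df).samples["mds"]
        pc1 = fit_pca(X, 1).scores.iloc[:, 0]
        order_mds = np.argsort(mds.to_numpy(), kind="stable")
        order_pc1 = np.argsort(np.sign(pc1.iloc[-1] - pc1.iloc[0]) * pc1.to_numpy(),
                               kind="stable")
        assert np.array_equal(order_mds, order_pc1)
        # arc-length positions are monotone in t (affine up to end smoothing)
        assert spearman_rho(mds, t) == pytest.approx(1.0)

    def test_quarter_circle_angle_ordering(self):
        """Arc-length ordering recovers the generative angle on a bent cloud."""
        angles = np.sort(rng.uniform(0, np.pi / 2, 120))
        X = np.column_stack([np.cos(angles), np.sin(angles)])
        X = X + rng.normal(0, 0.03, X.shape)
        df = pd.DataFrame(X, index=[f"S{i}" for i in range(120)])
        healthy = df.index[:10]
        curve = fit_principal_curve(df, healthy_ids=healthy, n_pcs=2, span=0.2)
        lam = compute_mds(curve, df).samples["mds"].to_numpy()
        assert spearman_rho(lam, angles) > 0.95

    def test_orientation_flip_symmetry(self):
        t = np.sort(rng.uniform(0, 1, 30))
        X = np.column_stack([t, t**2]) + rng.normal(0, 0.01, (30, 2))
        df = pd.DataFrame(X, index=[f"S{i}" for i in range(30)])
        low = fit_principal_curve(df, healthy_ids=df.index[:5], n_pcs=2)
        high = fit_principal_curve(df, healthy_ids=df.index[-5:], n_pcs=2)
        m_low = compute_mds(low, df).samples["mds"].to_numpy()
        m_high = compute_mds(high, df).samples["mds"].to_numpy()
        assert m_low == pytest.approx(1.0 - m_high, abs=0.02)

    def test_mds_within_unit_interval_and_anchors(self):
        t = np.sort(rng.uniform(0, 1, 25))
        X = np.column_stack([t, 0.5 * t])
        df = pd.DataFrame(X, index=[f"S{i}" for i in range(25)])
        curve = fit_principal_curve(df, healthy_ids=df.index[:3], n_pcs=1)
        mds = compute_mds(curve, df).samples["mds"]
        assert mds.min() >= 0 and mds.max() <= 1
        assert mds.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert mds.iloc[-1] == pytest.approx(1.0, abs=1e-9)

    def test_rigid_rotation_invariance(self):
        """MDS is unchanged when curve space is rotated jointly with samples."""
        t = np.sort(rng.uniform(0, 1, 40))
        X = np.column_stack([t, np.sin(2 * t)]) + rng.normal(0, 0.02, (40, 2))
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        df = pd.DataFrame(X, index=[f"S{i}" for i in range(40)])
        dfR = pd.DataFrame(X @ R.T, index=df.index)
        c1 = fit_principal_curve(df, healthy_ids=df.index[:5], n_pcs=2)
        c2 = fit_principal_curve(dfR, healthy_ids=df.index[:5], n_pcs=2)
        m1 = compute_mds(c1, df).samples["mds"].to_numpy()
        m2 = compute_mds(c2, dfR).samples["mds"].to_numpy()
        assert m1 == pytest.approx(m2, abs=1e-6)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            fit_principal_curve(np.ones((5, 3)), healthy_ids=[0])
        with pytest.raises(ValueError):
            fit_principal_curve(np.eye(2), healthy_ids=[0])


class TestMdsAuc:
    def _result(self, mds_by_day, days, group="G"):
        rows = []
        for a, series in mds_by_day.items():
            for d, v in zip(days, series):
                rows.append((f"{a}_d{d}", v, 0.0, group, a, d))
        df = pd.DataFrame(
            rows, columns=["sid", "mds", "residual", "group", "animal_id", "day"]
        ).set_index("sid")
        return MdsResult(samples=df)

    def test_constant_one_rectangle(self):
        res = self._result({"A1": [1, 1, 1, 1, 1]}, [-1, 1, 4, 7, 10])
        auc, _ = mds_auc(res)
        assert auc["auc"].iloc[0] == pytest.approx(11.0)

    def test_hand_trapezoid_and_null(self):
        res = self._result({"A1": [0, 1, 0], "A2": [0, 0, 0]}, [0, 1, 2])
        auc, _ = mds_auc(res)
        auc = auc.set_index("animal_id")["auc"]
        assert auc["A1"] == pytest.approx(1.0)
        assert auc["A2"] == pytest.approx(0.0)

    def test_group_tests_emitted(self):
        res_a = {f"A{i}": [0.1, 0.2, 0.1] for i in range(4)}
        res_b = {f"B{i}": [0.7, 0.9, 0.8] for i in range(4)}
        rows = []
        for g, d in (("GA", res_a), ("GB", res_b)):
            for a, series in d.items():
                for day, v in zip([0, 1, 2], series):
                    rows.append((f"{a}_d{day}", v, 0.0, g, a, day))
        df = pd.DataFrame(
            rows, columns=["sid", "mds", "residual", "group", "animal_id", "day"]
        ).set_index("sid")
        auc, tests = mds_auc(MdsResult(samples=df))
        assert len(tests) == 1
        assert tests["p"].iloc[0] < 0.05

    def test_single_day_animal_errors(self):
        res = self._result({"A1": [0.5]}, [4])
        with pytest.raises(ValueError):
            mds_auc(res)


def test_synthetic_group_ordering_day4(preprocessed):
    """Mean MDS at day 4: toxin > treated > control, given ordered attenuation."""
    from metaboeval.config import PipelineConfig
    from metaboeval.pipeline import stage_mds, stage_screen

    clean, phenotypes, truth, _ = preprocessed
    cfg = PipelineConfig(seed=11)
    endo, _, markers = stage_screen(clean, phenotypes, cfg)
    _, mds, auc_df, _ = stage_mds(endo, markers.selected, cfg)
    day4 = mds.samples[mds.samples.day == 4].groupby("group")["mds"].mean()
    assert day4["T"] > day4["T/HQD"] > day4["C"]
    assert day4["T"] > day4["T/SS"] > day4["C"]
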