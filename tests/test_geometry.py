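"""Rigid orientation: PCA long axis, landmark sign/roll, isometry."""

import numpy as np
import pytest

from wormtrace import (LandmarkGroups, RigidTransform, apply_transform,
                       circular_mean, fit_orientation, random_table,
                       simulate_embryo, tables_allclose)
from wormtrace.geometry import wrap_angle
from wormtrace.synthetic import SimulationParams, random_rotation

from conftest import make_table, rowd


def grid_roll_oracle(angles, step=0.001):
    """Brute-force minimizer of the summed squared (wrapped) angular
    deviation over a fine grid: the independent check for the circular-mean
    roll."""
    grid = np.arange(-np.pi, np.pi, step)
    dev = wrap_angle(np.subtract.outer(grid, np.asarray(angles)))
    cost = (dev ** 2).sum(axis=1)
    return float(grid[np.argmin(cost)])


def positions(table):
    return table.data[["x", "y", "z"]].to_numpy(dtype=float)


class TestFitOrientation:
    def test_canonical_embryo_is_fixed_point(self, canonical_table):
        tf = fit_orientation(canonical_table, 1)
        assert np.allclose(tf.center, 0.0, atol=1e-9)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_recovers_random_pose(self, canonical_table, seed):
        rng = np.random.default_rng(seed)
        Q = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        df = canonical_table.data.copy()
        df[["x", "y", "z"]] = positions(canonical_table) @ Q.T + t
        moved = canonical_table.with_data(df)
        tf = fit_orientation(moved, 1)
        recovered = apply_transform(moved, tf)
        rmsd = np.sqrt(((positions(recovered) - positions(canonical_table)) ** 2).mean())
        assert rmsd < 1e-6

    def test_synthetic_embryo_recovery(self, sim_default):
        acq, truth = sim_default
        tf = fit_orientation(acq, truth.transform.reference_time)
        recovered = apply_transform(acq, tf)
        diff = positions(recovered) - positions(truth.canonical)
        assert np.sqrt((diff ** 2).mean()) < 1e-6

    def test_fit_apply_idempotent(self, sim_default):
        acq, truth = sim_default
        tf = fit_orientation(acq, truth.transform.reference_time)
        once = apply_transform(acq, tf)
        tf2 = fit_orientation(once, truth.transform.reference_time)
        assert tf2.is_identity(1e-6)

    def test_single_roll_landmark_exact(self, canonical_table):
        """With one roll group, its centroid lands exactly on the target
        half-axis after transformation."""
        rng = np.random.default_rng(3)
        Q = random_rotation(rng)
        df = canonical_table.data.copy()
        df[["x", "y", "z"]] = positions(canonical_table) @ Q.T + rng.uniform(-5, 5, 3)
        moved = canonical_table.with_data(df)
        groups = LandmarkGroups(posterior=("Cxp",), dorsal=("Cxaa",))
        out = apply_transform(moved, fit_orientation(moved, 1, groups))
        dorsal = out.data[out.data["cell"].isin(["Caaa", "Cpaa"])]
        centroid = dorsal[["x", "y", "z"]].mean().to_numpy()
        assert abs(centroid[1]) < 1e-9   # y component vanishes
        assert centroid[2] > 0           # on +z

    def test_consistent_roll_groups_agree(self):
        """Dorsal and left groups placed exactly 90 degrees apart give equal
        candidate angles, and the mean equals either."""
        rows = [
            rowd("ABal", 10, x=20.0), rowd("ABpl", 10, x=-20.0),
            rowd("Cap", 10, x=-18.0), rowd("Cpp", 10, x=-22.0),
            # dorsal and left centroids rolled by the same angle, 90 deg apart
            rowd("Caaa", 10, x=-1.0, y=-4.0, z=3.0),
            rowd("MSpp", 10, x=-1.0, y=3.0, z=4.0),
            # mirror partners keep the covariance cross-terms exactly zero
            rowd("Dap", 10, x=-1.0, y=4.0, z=-3.0),
            rowd("Dpp", 10, x=-1.0, y=-3.0, z=-4.0),
        ]
        t = make_table(rows, units="micron", expr_columns=())
        groups = LandmarkGroups(posterior=("Cxp",), dorsal=("Cxaa",),
                                left=("MSpp",))
        out = apply_transform(t, fit_orientation(t, 10, groups))
        caaa = out.data[out.data["cell"] == "Caaa"][["y", "z"]].to_numpy()[0]
        mspp = out.data[out.data["cell"] == "MSpp"][["y", "z"]].to_numpy()[0]
        assert abs(caaa[0]) < 1e-9 and caaa[1] > 0
        assert abs(mspp[1]) < 1e-9 and mspp[0] > 0

    def test_degenerate_pca_error(self):
        rows = [rowd(c, 1, x=x, y=y) for c, x, y in
                [("ABa", 1, 0), ("ABp", -1, 0), ("Ca", 0, 1), ("Cp", 0, -1)]]
        t = make_table(rows, units="micron", expr_columns=())
        with pytest.raises(ValueError, match="ambiguous long axis"):
            fit_orientation(t, 1, LandmarkGroups(posterior=("Cx",), dorsal=("ABx",)))

    def test_empty_landmark_group_named(self, canonical_table):
        groups = LandmarkGroups(posterior=("Cxp",), dorsal=("Dxx",))
        with pytest.raises(ValueError, match="dorsal"):
            fit_orientation(canonical_table, 1, groups)

    def test_requires_micron_units(self, rng):
        t = random_table(rng)
        with pytest.raises(ValueError, match="micron"):
            fit_orientation(t, 1)


class TestRollAveraging:
    @pytest.mark.parametrize("seed", range(20))
    def test_circular_mean_matches_grid_minimizer(self, seed):
        """For candidate spreads < 30 degrees the circular mean agrees with
        grid minimization of summed squared angular deviation."""
        rng = np.random.default_rng(seed)
        center = rng.uniform(-np.pi, np.pi)
        n = rng.integers(2, 5)
        angles = wrap_angle(center + rng.uniform(-np.radians(30), np.radians(30), n))
        assert abs(wrap_angle(circular_mean(angles) - grid_roll_oracle(angles))) < 0.01


class TestApplyTransform:
    def test_identity_unchanged(self, sim_default):
        acq, _ = sim_default
        tf = RigidTransform(np.zeros(3), np.eye(3), reference_time=1)
        assert tables_allclose(apply_transform(acq, tf), acq, tol=1e-12)

    def test_isometry_random_tables(self, rng):
        for _ in range(5):
            t = random_table(rng, n_cells=8, n_times=3)
            t = t.with_data(t.data, units="micron")
            Q = random_rotation(rng)
            tf = RigidTransform(rng.uniform(-5, 5, 3), Q, reference_time=1)
            out = apply_transform(t, tf)
            for tp in t.times():
                a = t.at_time(tp)[["x", "y", "z"]].to_numpy()
                b = out.at_time(tp)[["x", "y", "z"]].to_numpy()
                da = np.linalg.norm(a[:, None] - a[None], axis=-1)
                db = np.linalg.norm(b[:, None] - b[None], axis=-1)
                assert np.allclose(da, db, atol=1e-9)

    def test_inverse_restores(self, sim_default, rng):
        acq, _ = sim_default
        tf = RigidTransform(rng.uniform(-5, 5, 3), random_rotation(rng), 1)
        back = apply_transform(apply_transform(acq, tf), tf.inverse())
        assert np.allclose(positions(back), positions(acq), atol=1e-9)

    def test_reference_scope(self, sim_default):
        acq, truth = sim_default
        t_ref = truth.transform.reference_time
        tf = fit_orientation(acq, t_ref)
        out = apply_transform(acq, tf, scope="reference")
        early = acq.data["time"] < t_ref
        assert np.allclose(out.data.loc[early, ["x", "y", "z"]],
                           acq.data.loc[early, ["x", "y", "z"]])
        assert not np.allclose(out.at_time(t_ref)[["x", "y", "z"]],
                               acq.at_time(t_ref)[["x", "y", "z"]])

    def test_reference_scope_missing_time(self, sim_default):
        acq, _ = sim_default
        tf = RigidTransform(np.zeros(3), np.eye(3), reference_time=999)
        with pytest.raises(ValueError, match="999"):
            apply_transform(acq, tf, scope="reference")


class TestTransformFile:
    def test_round_trip(self, tmp_path, rng):
        tf = RigidTransform(rng.uniform(-5, 5, 3), random_rotation(rng), 17)
        p = tmp_path / "tf.txt"
        tf.save(p)
        back = RigidTransform.load(p)
        assert np.array_equal(back.center, tf.center)
        assert np.array_equal(back.rotation, tf.rotation)
        assert back.reference_time == tf.reference_time

    def test_truncated_file(self, tmp_path):
        p = tmp_path / "tf.txt"
        p.write_text("wormtrace-rigid-transform v1\ncenter: 0 0 0\n")
        with pytest.raises(Exception, match="truncated|malformed"):
            RigidTransform.load(p)

    def test_improper_rotation_rejected(self):
        M = np.diag([1.0, 1.0, -1.0])  # reflection
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(np.zeros(3), M, 1)
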