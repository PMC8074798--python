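"""Allometric and QSM-volume AGB estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from harvestledger import agb_estimators as est
from harvestledger.density import DensityEstimate
from harvestledger.errors import DomainError, ValidationError
from harvestledger.fixtures import (four_tree_estimates_fixture,
                                    four_tree_fixture)


def _random_qsm(rng, n=50, orders=(0, 1, 2)):
    axis = rng.normal(size=(n, 3))
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    return est.QSMModel(
        tree_id="Q",
        start=rng.uniform(-5, 5, size=(n, 3)),
        axis=axis,
        radius=rng.uniform(0.01, 0.5, size=n),
        length=rng.uniform(0.1, 2.0, size=n),
        branch_order=rng.choice(orders, size=n),
    )


class TestAllometric:
    def test_reproduces_campaign_estimates(self):
        ests = {e.tree_id: e.agb_allometric
                for e in four_tree_estimates_fixture()}
        for t in four_tree_fixture():
            agb = est.allometric_agb(t.stem_diameter_m * 100.0, t.height_m,
                                     t.density_mass_weighted / 1000.0)
            assert agb == pytest.approx(ests[t.tree_id], rel=1e-3)

    def test_identity_model(self):
        model = est.AllometricModel(coefficient=1.0, exponent=1.0)
        assert est.allometric_agb(50.0, 30.0, 0.6, model) == \
            pytest.approx(50.0 ** 2 * 30.0 * 0.6)

    def test_vanishes_with_diameter(self):
        assert est.allometric_agb(1e-9, 30.0, 0.6) < 1e-10
        with pytest.raises(DomainError):
            est.allometric_agb(0.0, 30.0, 0.6)

    @given(st.floats(10, 200), st.floats(5, 60), st.floats(0.1, 1.2),
           st.floats(1.01, 3.0))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_each_input(self, d, h, rho, factor):
        base = est.allometric_agb(d, h, rho)
        assert est.allometric_agb(d * factor, h, rho) > base
        assert est.allometric_agb(d, h * factor, rho) > base
        assert est.allometric_agb(d, h, rho * factor) > base

    @given(st.floats(10, 150), st.floats(5, 60), st.floats(0.2, 1.0),
           st.floats(0.2, 4.0))
    @settings(max_examples=100, deadline=None)
    def test_scale_covariance_in_diameter(self, d, h, rho, k):
        model = est.DEFAULT_ALLOMETRIC_MODEL
        lhs = est.allometric_agb(k * d, h, rho, model)
        rhs = k ** (2.0 * model.exponent) * est.allometric_agb(d, h, rho,
                                                               model)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_rounded_coefficient_sits_half_percent_low(self):
        t2 = four_tree_fixture()[1]
        full = est.allometric_agb(t2.stem_diameter_m * 100, t2.height_m,
                                  t2.density_mass_weighted / 1000)
        rounded = est.allometric_agb(t2.stem_diameter_m * 100, t2.height_m,
                                     t2.density_mass_weighted / 1000,
                                     est.ROUNDED_ALLOMETRIC_MODEL)
        assert (full - rounded) / full == pytest.approx(0.0045, abs=1e-3)


class TestQSMVolume:
    def test_single_and_double_cylinder(self):
        qsm = est.QSMModel("Q", start=[[0, 0, 0]], axis=[[0, 0, 1]],
                           radius=[0.1], length=[2.0], branch_order=[0])
        assert est.qsm_total_volume(qsm) == pytest.approx(0.06283, abs=1e-5)
        two = est.QSMModel("Q", start=[[0, 0, 0], [0, 0, 2]],
                           axis=[[0, 0, 1]] * 2, radius=[0.1] * 2,
                           length=[2.0] * 2, branch_order=[0, 0])
        assert est.qsm_total_volume(two) == pytest.approx(
            2.0 * est.qsm_total_volume(qsm))

    def test_matches_per_cylinder_loop_oracle(self, rng):
        qsm = _random_qsm(rng)
        oracle = 0.0
        for i in range(qsm.n_cylinders):
            oracle += math.pi * qsm.radius[i] ** 2 * qsm.length[i]
        assert est.qsm_total_volume(qsm) == pytest.approx(oracle, rel=1e-12)

    def test_invariant_under_rigid_motion(self, rng):
        qsm = _random_qsm(rng)
        before = est.qsm_total_volume(qsm)
        rot = Rotation.from_euler(
            "xyz", rng.uniform(0, 2 * math.pi, size=3)).as_matrix()
        shift = rng.normal(size=3) * 10.0
        moved = est.QSMModel("Q", start=qsm.start @ rot.T + shift,
                             axis=qsm.axis @ rot.T, radius=qsm.radius,
                             length=qsm.length, branch_order=qsm.branch_order)
        assert est.qsm_total_volume(moved) == pytest.approx(before, rel=1e-12)

    def test_empty_model_rejected(self):
        qsm = est.QSMModel("Q", start=np.empty((0, 3)), axis=np.empty((0, 3)),
                           radius=[], length=[], branch_order=[])
        with pytest.raises(DomainError):
            est.qsm_total_volume(qsm)

    def test_validation_catches_bad_axes_and_missing_stem(self):
        bad_axis = est.QSMModel("Q", start=[[0, 0, 0]], axis=[[0, 0, 2.0]],
                                radius=[0.1], length=[1.0], branch_order=[0])
        with pytest.raises(ValidationError, match="unit-norm"):
            bad_axis.validate()
        no_stem = est.QSMModel("Q", start=[[0, 0, 0]], axis=[[0, 0, 1.0]],
                               radius=[0.1], length=[1.0], branch_order=[1])
        with pytest.raises(ValidationError, match="order-0"):
            no_stem.validate()


class TestPartitionAndAGB:
    def test_all_stem_model_has_empty_crown(self):
        qsm = est.QSMModel("Q", start=[[0, 0, 0]], axis=[[0, 0, 1]],
                           radius=[0.1], length=[2.0], branch_order=[0])
        split = est.partition_stem_crown(qsm)
        assert split["crown"] == 0.0
        assert split["stem"] == pytest.approx(est.qsm_total_volume(qsm))

    def test_equal_volume_split_is_half(self):
        qsm = est.QSMModel("Q", start=[[0, 0, 0], [0, 0, 2]],
                           axis=[[0, 0, 1]] * 2, radius=[0.1] * 2,
                           length=[2.0] * 2, branch_order=[0, 1])
        split = est.partition_stem_crown(qsm)
        total = split["stem"] + split["crown"]
        assert split["stem"] / total == pytest.approx(0.5)

    def test_qsm_agb_is_volume_times_density(self, rng):
        qsm = _random_qsm(rng)
        dens = DensityEstimate("Q", "mass_weighted", 575.0,
                               g2d_mass_ratio=1.6, g2d_volume_ratio=1.1)
        out = est.qsm_agb(qsm, dens)
        assert out.agb_est == pytest.approx(est.qsm_total_volume(qsm) * 575.0)
        assert sum(out.pool_split.values()) == pytest.approx(out.agb_est,
                                                             rel=1e-12)

    def test_noiseless_synthetic_qsm_with_true_density_recovers_truth(
            self, noiseless_tree):
        truth = noiseless_tree.truth
        dens = DensityEstimate(truth.tree_id, "mass_weighted",
                               truth.volumetric_density,
                               g2d_mass_ratio=truth.g2d_mass_ratio,
                               g2d_volume_ratio=truth.g2d_volume_ratio)
        out = est.qsm_agb(noiseless_tree.qsm, dens)
        assert out.agb_est == pytest.approx(truth.dry_mass, rel=1e-9)

    def test_campaign_stem_fractions_reproduced_from_published_splits(self):
        # published stem shares of lidar AGB vs harvest AGB per tree
        for t in four_tree_fixture():
            diff = 100.0 * (t.stem_mass_fraction_lidar
                            - t.stem_mass_fraction_harvest)
            assert abs(diff) <= 6.0 + 1e-9


class TestQSMIO:
    def test_csv_round_trip(self, tmp_path, rng):
        qsm = _random_qsm(rng, n=20)
        qsm.branch_id = np.arange(20)
        qsm.parent_id = np.full(20, -1)
        est.write_qsm_table(qsm, tmp_path / "qsm.csv")
        back = est.read_qsm_tables(tmp_path / "qsm.csv")["Q"]
        assert np.allclose(back.start, qsm.start)
        assert np.allclose(back.radius, qsm.radius)
        assert (back.branch_order == qsm.branch_order).all()
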