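"""Crown-form metrics from QSMs and point clouds."""

import math

import numpy as np
import pytest

from harvestledger import structure_metrics as sm
from harvestledger.agb_estimators import QSMModel
from harvestledger.errors import DomainError, SchemaError, ValidationError
from harvestledger.fixtures import four_tree_fixture
from harvestledger.reference_agb import ReferenceAGB
from harvestledger.agb_estimators import AGBEstimate


def _fork_qsm(fork=13.5, height=30.0, tip_radius=0.0):
    """Stem to ``fork``, two opposite branches reaching the tree top."""
    run = (height - fork) / 2.0
    length = math.hypot(run, height - fork)
    axis1 = np.array([run, 0.0, height - fork]) / length
    axis2 = np.array([-run, 0.0, height - fork]) / length
    return QSMModel(
        tree_id="F",
        start=[[0, 0, 0], [0, 0, fork], [0, 0, fork]],
        axis=[[0, 0, 1], axis1, axis2],
        radius=[0.3, max(tip_radius, 0.05), max(tip_radius, 0.05)],
        length=[fork, length, length],
        branch_order=[0, 1, 1],
    )


class TestQSMMetrics:
    def test_fork_at_045_height_gives_crown_ratio_055(self):
        qsm = _fork_qsm(fork=0.45 * 30.0, height=30.0)
        m = sm.crown_metrics_from_qsm(qsm, tree_height=30.0)
        assert m.crown_base_height == pytest.approx(13.5)
        assert m.crown_to_tree_height_ratio == pytest.approx(0.55)

    def test_spherical_crown_has_unit_aspect(self):
        # crown spanning 10 m vertically with 10 m horizontal major axis
        height, fork = 25.0, 15.0
        qsm = QSMModel(
            tree_id="S",
            start=[[0, 0, 0], [-5, 0, fork], [0, 0, fork]],
            axis=[[0, 0, 1], [1, 0, 0], [0, 0, 1]],
            radius=[0.3, 0.05, 0.05],
            length=[fork, 10.0, height - fork],
            branch_order=[0, 1, 1],
        )
        m = sm.crown_metrics_from_qsm(qsm, tree_height=height)
        # major axis includes the endpoint radii: 10 m span + 2 x 0.05
        assert m.crown_major_axis_diameter == pytest.approx(10.1)
        assert m.crown_aspect_ratio == pytest.approx(1.01)

    def test_stem_only_model_rejected(self):
        qsm = QSMModel("X", start=[[0, 0, 0]], axis=[[0, 0, 1]],
                       radius=[0.3], length=[20.0], branch_order=[0])
        with pytest.raises(ValidationError, match="no crown"):
            sm.crown_metrics_from_qsm(qsm, 30.0)

    def test_campaign_crown_ratios_are_plausible(self):
        for t in four_tree_fixture():
            assert 0.3 < t.crown_to_tree_height_ratio < 0.7
            assert 1.0 < t.crown_aspect_ratio < 2.0


class TestCloudMetrics:
    def test_box_crown_aspect(self, rng):
        # 10 m wide, 5 m tall crown above a 10 m stem
        pts = rng.uniform([-5, -5, 10], [5, 5, 15], size=(500, 3))
        corners = np.array([[-5, -5, 10], [5, 5, 15], [-5, 5, 12],
                            [5, -5, 13]])
        pts = np.vstack([pts, corners])
        m = sm.crown_metrics_from_cloud(pts, crown_base_height=10.0,
                                        tree_height=15.0)
        assert m.crown_major_axis_diameter == pytest.approx(
            10.0 * math.sqrt(2.0), rel=1e-6)
        assert m.crown_height == pytest.approx(5.0)

    def test_rotation_about_z_leaves_metrics_unchanged(self, rng):
        pts = rng.uniform([-4, -2, 8], [4, 2, 20], size=(300, 3))
        theta = 1.1
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
        a = sm.crown_metrics_from_cloud(pts, 8.0, 20.0)
        b = sm.crown_metrics_from_cloud(pts @ rot.T, 8.0, 20.0)
        assert b.crown_major_axis_diameter == pytest.approx(
            a.crown_major_axis_diameter, rel=1e-9)
        assert b.crown_aspect_ratio == pytest.approx(a.crown_aspect_ratio,
                                                     rel=1e-9)

    def test_metrics_scale_linearly_with_the_cloud(self, rng):
        pts = rng.uniform([-4, -4, 5], [4, 4, 18], size=(200, 3))
        a = sm.crown_metrics_from_cloud(pts, 5.0, 18.0)
        b = sm.crown_metrics_from_cloud(2.0 * pts, 10.0, 36.0)
        assert b.crown_major_axis_diameter == pytest.approx(
            2.0 * a.crown_major_axis_diameter, rel=1e-9)
        assert b.crown_aspect_ratio == pytest.approx(a.crown_aspect_ratio,
                                                     rel=1e-9)

    def test_hull_diameter_matches_brute_force(self, rng):
        pts = rng.normal(size=(1500, 3)) * [4.0, 2.0, 3.0] + [0, 0, 10]
        m = sm.crown_metrics_from_cloud(pts, crown_base_height=5.0,
                                        tree_height=20.0)
        above = pts[pts[:, 2] >= 5.0][:, :2]
        brute = 0.0
        for i in range(len(above)):
            d = np.hypot(above[i + 1:, 0] - above[i, 0],
                         above[i + 1:, 1] - above[i, 1])
            if len(d):
                brute = max(brute, float(d.max()))
        assert m.crown_major_axis_diameter == pytest.approx(brute, rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            sm.crown_metrics_from_cloud(np.zeros((2, 3)), 0.0, 10.0)


class TestPointCloudIO:
    def test_xyz_reader(self, tmp_path):
        path = tmp_path / "tree.xyz"
        path.write_text("0 0 0\n1 2 3\n4 5 6\n")
        pts = sm.read_point_cloud(path)
        assert pts.shape == (3, 3)
        assert pts[1, 2] == 3.0

    def test_ascii_ply_reader(self, tmp_path):
        path = tmp_path / "tree.ply"
        path.write_text(
            "ply\nformat ascii 1.0\nelement vertex 2\n"
            "property float x\nproperty float y\nproperty float z\n"
            "end_header\n0.5 1.5 2.5\n3.0 4.0 5.0\n")
        pts = sm.read_point_cloud(path)
        assert pts.shape == (2, 3)
        assert pts[0].tolist() == [0.5, 1.5, 2.5]

    def test_binary_ply_reader_round_trip(self, tmp_path, rng):
        pts = rng.normal(size=(10, 3)).astype("<f4")
        path = tmp_path / "tree.ply"
        header = ("ply\nformat binary_little_endian 1.0\n"
                  "element vertex 10\nproperty float x\nproperty float y\n"
                  "property float z\nend_header\n")
        path.write_bytes(header.encode() + pts.tobytes())
        back = sm.read_point_cloud(path)
        assert np.allclose(back, pts.astype(float))

    def test_non_ply_content_rejected(self, tmp_path):
        path = tmp_path / "bad.ply"
        path.write_text("not a ply\n")
        with pytest.raises(SchemaError):
            sm.read_point_cloud(path)


class TestMassDistribution:
    def test_campaign_stem_share_differences(self):
        refs = [ReferenceAGB(t.tree_id, t.agb_ref,
                             crown_mass_ratio=1.0 - t.stem_mass_fraction_harvest)
                for t in four_tree_fixture()]
        ests = [AGBEstimate(t.tree_id, "qsm", agb_est=100.0,
                            pool_split={"stem": 100.0 * t.stem_mass_fraction_lidar,
                                        "crown": 100.0 * (1 - t.stem_mass_fraction_lidar)})
                for t in four_tree_fixture()]
        df = sm.mass_distribution_report(refs, ests)
        diffs = dict(zip(df.tree_id, df.difference_points))
        assert diffs["T1"] == pytest.approx(0.0, abs=1e-9)
        assert diffs["T2"] == pytest.approx(4.0)
        assert diffs["T3"] == pytest.approx(4.0)
        assert diffs["T4"] == pytest.approx(6.0)

    def test_identical_splits_give_zero_vector(self):
        refs = [ReferenceAGB("a", 100.0, crown_mass_ratio=0.5)]
        ests = [AGBEstimate("a", "qsm", 90.0,
                            pool_split={"stem": 45.0, "crown": 45.0})]
        df = sm.mass_distribution_report(refs, ests)
        assert df.difference_points.tolist() == [0.0]

    def test_missing_split_reported_absent(self):
        refs = [ReferenceAGB("a", 100.0, crown_mass_ratio=0.5)]
        ests = [AGBEstimate("a", "allometric", 90.0)]
        df = sm.mass_distribution_report(refs, ests)
        assert df.stem_fraction_estimate.isna().all()
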