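"""Domain geometry, superposition and ensemble statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ipet import laws, phantom
from ipet.core import FAB1, FAB2, FC, Conformation
from ipet.geometry import (HistogramFit, angle_between,
                           build_histogram_and_fit, conformation_from_atoms,
                           conformation_geometry, ensemble_report,
                           fold_to_90, kabsch, mass_center, principal_axes,
                           superpose_on_fc)
from scipy.spatial.transform import Rotation


class TestMassCenter:
    def test_two_point_midpoint(self):
        c = mass_center(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        np.testing.assert_allclose(c, [1.0, 0, 0])

    def test_translation_equivariance(self, rng):
        pts = rng.random((30, 3))
        v = np.array([3.0, -1.0, 7.0])
        np.testing.assert_allclose(mass_center(pts + v),
                                   mass_center(pts) + v, atol=1e-12)

    def test_matches_brute_force_weighted_sum(self, rng):
        pts = rng.random((100, 3))
        w = rng.random(100)
        oracle = sum(wi * p for wi, p in zip(w, pts)) / w.sum()
        np.testing.assert_allclose(mass_center(pts, w), oracle, atol=1e-12)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            mass_center(np.empty((0, 3)))


class TestPrincipalAxes:
    def test_rod_minimum_inertia_axis_along_rod(self, rng):
        pts = np.zeros((50, 3))
        pts[:, 0] = np.linspace(-10, 10, 50)
        pts += 0.01 * rng.standard_normal(pts.shape)
        mn, _, _ = principal_axes(pts)
        assert abs(mn @ [1, 0, 0]) > 0.99

    def test_plate_maximum_inertia_axis_normal_to_plate(self, rng):
        pts = rng.uniform(-10, 10, (200, 3))
        pts[:, 2] *= 0.01
        _, _, mx = principal_axes(pts)
        assert abs(mx @ [0, 0, 1]) > 0.99

    def test_matches_brute_force_inertia_eigensolve(self, rng):
        pts = rng.random((40, 3)) * 10
        m = rng.random(40)
        c = (pts * m[:, None]).sum(axis=0) / m.sum()
        inertia = np.zeros((3, 3))
        for p, mi in zip(pts, m):
            r = p - c
            inertia += mi * ((r @ r) * np.eye(3) - np.outer(r, r))
        evals, evecs = np.linalg.eigh(inertia)
        axes = principal_axes(pts, m)
        for k in range(3):
            assert abs(axes[k] @ evecs[:, k]) == pytest.approx(1.0,
                                                               abs=1e-8)

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            principal_axes(pts)


def make_conformation(centers, rotations=None):
    if rotations is None:
        rotations = np.stack([np.eye(3)] * 3)
    return Conformation.from_poses(np.asarray(centers, float), rotations)


class TestConformationGeometry:
    def test_equilateral_gives_exact_60_degrees(self):
        conf = make_conformation([[82.0, 0, 0],
                                  [41.0, 41 * np.sqrt(3), 0],
                                  [0.0, 0, 0]])
        rec = conformation_geometry(conf)
        assert rec.vertex_angle == pytest.approx(60.0, abs=1e-9)
        assert rec.dist_fab_fab == pytest.approx(82.0)

    def test_collinear_centers_give_180(self):
        conf = make_conformation([[80.0, 0, 0], [-90.0, 0, 0], [0.0, 0, 0]])
        assert conformation_geometry(conf).vertex_angle == pytest.approx(
            180.0)

    def test_normal_angle_folding_135_becomes_45(self):
        r_fab1 = Rotation.from_euler("x", 135, degrees=True).as_matrix()
        conf = make_conformation([[50.0, 40, 0], [50.0, -40, 0], [0, 0, 0]],
                                 np.stack([r_fab1, np.eye(3), np.eye(3)]))
        rec = conformation_geometry(conf)
        assert rec.normal_angle_fab1_fc == pytest.approx(45.0, abs=1e-9)

    def test_coincident_centers_raise(self):
        conf = make_conformation([[0.0, 0, 0], [50.0, 0, 0], [0.0, 0, 0]])
        with pytest.raises(ValueError, match="coincident"):
            conformation_geometry(conf)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        conf = phantom.sample_conformation(
            phantom.ConformationDistribution(orientations="uniform"), rng)
        rec = conformation_geometry(conf)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-50, 50, 3)
        moved = Conformation(conf.centers @ R.T + t,
                             conf.direction_vectors @ R.T,
                             conf.normal_vectors @ R.T)
        rec2 = conformation_geometry(moved)
        for field in rec.as_dict():
            assert rec2.as_dict()[field] == pytest.approx(
                rec.as_dict()[field], abs=1e-6), field

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_fab_label_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        conf = phantom.sample_conformation(
            phantom.ConformationDistribution(orientations="uniform"), rng)
        swap = [FAB2, FAB1, FC]
        swapped = Conformation(conf.centers[swap],
                               conf.direction_vectors[swap],
                               conf.normal_vectors[swap])
        a = conformation_geometry(conf)
        b = conformation_geometry(swapped)
        assert b.dist_fab_fab == pytest.approx(a.dist_fab_fab)
        assert b.vertex_angle == pytest.approx(a.vertex_angle)
        assert b.dir_angle_fab_fab == pytest.approx(a.dir_angle_fab_fab)
        assert b.normal_angle_fab_fab == pytest.approx(
            a.normal_angle_fab_fab)
        assert b.dist_fab1_fc == pytest.approx(a.dist_fab2_fc)
        assert b.normal_angle_fab1_fc == pytest.approx(
            a.normal_angle_fab2_fc)

    @given(angle=st.floats(0, 360))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_folding_idempotent_and_bounded(self, angle):
        folded = fold_to_90(angle)
        assert 0 <= folded <= 90
        assert fold_to_90(folded) == pytest.approx(folded, abs=1e-9)


class TestGeometryRoundTrip:
    def test_phantom_atoms_recover_sampled_conformation(self):
        rng = np.random.default_rng(21)
        dist = phantom.ConformationDistribution()
        for _ in range(5):
            conf = phantom.sample_conformation(dist, rng)
            p = phantom.build_phantom(conf)
            measured = conformation_from_atoms(p.atom_coords, p.atom_chains,
                                               p.atom_res_ids)
            truth = p.conformation
            a = conformation_geometry(measured)
            b = conformation_geometry(truth)
            vox = p.density.voxel_size
            assert abs(a.dist_fab_fab - b.dist_fab_fab) <= vox
            assert abs(a.dist_fab1_fc - b.dist_fab1_fc) <= vox
            assert abs(a.vertex_angle - b.vertex_angle) <= 2.0


class TestSuperposeOnFc:
    @staticmethod
    def _structure(rng, transform=None):
        conf = phantom.sample_conformation(
            phantom.ConformationDistribution.equilateral(82),
            np.random.default_rng(0))
        p = phantom.build_phantom(conf)
        coords = p.atom_coords
        if transform is not None:
            R, t = transform
            coords = coords @ R.T + t
        return coords, p.atom_chains, p.atom_res_ids

    def test_identical_structures_align_with_zero_rmsd(self, rng):
        s = self._structure(rng)
        aligned, transforms, rmsds = superpose_on_fc([s, s, s])
        assert max(rmsds) < 1e-9
        for R, t in transforms:
            np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_rotated_translated_copy_realigns(self, rng):
        s = self._structure(rng)
        R = Rotation.from_euler("zyx", [30, -40, 100],
                                degrees=True).as_matrix()
        moved = self._structure(rng, transform=(R, np.array([10., -5., 3.])))
        aligned, _, rmsds = superpose_on_fc([s, moved])
        assert rmsds[1] < 1e-6
        np.testing.assert_allclose(aligned[1], aligned[0], atol=1e-6)

    def test_kabsch_matches_brute_force_svd_oracle(self, rng):
        mobile = rng.random((10, 3)) * 20
        Rtrue = Rotation.random(rng=rng).as_matrix()
        reference = mobile @ Rtrue.T + np.array([5.0, 6.0, 7.0])
        R, t = kabsch(mobile, reference)
        # independent oracle: direct SVD of the covariance
        cm, cr = mobile.mean(0), reference.mean(0)
        U, S, Vt = np.linalg.svd((mobile - cm).T @ (reference - cr))
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R_oracle = Vt.T @ np.diag([1, 1, d]) @ U.T
        np.testing.assert_allclose(R, R_oracle, atol=1e-10)
        np.testing.assert_allclose(mobile @ R.T + t, reference, atol=1e-9)

    def test_missing_fc_raises(self, rng):
        coords = rng.random((10, 3))
        chains = np.full(10, "A")
        res = np.arange(1, 11)
        with pytest.raises(ValueError, match="Fc"):
            superpose_on_fc([(coords, chains, res)])


class TestHistogramFit:
    def test_identical_values_single_bin_population_one(self):
        fit = build_histogram_and_fit(np.full(50, 82.0), 5.0)
        assert fit.peak_population == 1.0
        assert fit.counts.sum() == 50

    def test_triangular_sample_peak_near_mode(self, rng):
        vals = rng.triangular(40, 82, 100, size=4000)
        fit = build_histogram_and_fit(vals, 5.0)
        assert abs(fit.peak_location - 82.0) <= 5.0

    def test_n120_gaussian_sample_recovers_mode(self):
        rng = np.random.default_rng(17)
        vals = rng.normal(82.0, 8.0, 120)
        fit = build_histogram_and_fit(vals, 5.0)
        assert abs(fit.peak_location - 82.0) <= 2.5

    def test_too_few_bins_raises(self, rng):
        vals = rng.uniform(0, 10, 100)
        with pytest.raises(ValueError, match="bins"):
            build_histogram_and_fit(vals, 5.0)


class TestEnsembleReport:
    @staticmethod
    def _records(dist, n, seed):
        from ipet.geometry import conformation_geometry as geom
        rng = np.random.default_rng(seed)
        return [geom(phantom.sample_conformation(dist, rng))
                for _ in range(n)]

    def test_degenerate_ensemble_peaks_with_full_population(self):
        recs = self._records(phantom.ConformationDistribution.equilateral(),
                            20, 0)
        fits, table = ensemble_report(recs)
        row = table.set_index("measure").loc["dist_fab_fab"]
        assert row["peak_population_pct"] == pytest.approx(100.0)
        assert abs(row["peak"] - 82.0) <= 5.0

    def test_generating_modes_recovered_at_study_scale(self):
        """120 sampled conformations recover each generating mode within
        one histogram bin."""
        dist = phantom.ConformationDistribution(
            fab_fc_distance_law=laws.gaussian(85.0, 8.0, lo=60, hi=110),
            vertex_angle_law=laws.gaussian(56.6, 8.0, lo=30, hi=85),
            direction_angle_law=laws.gaussian(124.7, 12.0, lo=95, hi=160),
            normal_angle_law=laws.uniform(10.0, 90.0))
        recs = self._records(dist, 120, 3)
        fits, table = ensemble_report(
            recs, windows={"vertex_angle": (40.0, 72.0)})
        t = table.set_index("measure")
        assert abs(t.loc["dist_fab_fc", "peak"] - 85.0) <= 5.0
        assert abs(t.loc["vertex_angle", "peak"] - 56.6) <= 8.0
        assert abs(t.loc["dir_angle_fab_fc", "peak"] - 124.7) <= 10.0
        assert t.loc["vertex_angle", "window_fraction_pct"] >= 80.0

    def test_normal_angles_respect_generator_support(self):
        dist = phantom.ConformationDistribution(
            normal_angle_law=laws.uniform(10.0, 90.0))
        recs = self._records(dist, 100, 5)
        vals = [r.normal_angle_fab1_fc for r in recs] \
            + [r.normal_angle_fab2_fc for r in recs]
        assert min(vals) >= 10.0 - 1e-9
        assert max(vals) <= 90.0 + 1e-9

    def test_single_record_rejected(self):
        recs = self._records(phantom.ConformationDistribution(), 1, 0)
        with pytest.raises(ValueError):
            ensemble_report(recs)


def test_angle_between_is_symmetric_and_bounded(rng):
    u, v = rng.standard_normal(3), rng.standard_normal(3)
    a = angle_between(u, v)
    assert 0 <= a <= 180
    assert angle_between(v, u) == pytest.approx(a)
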