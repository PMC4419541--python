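"""Domain segmentation, Fc identification and rigid-body fitting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import sphere_map
from ipet import phantom, posefit
from ipet.core import DensityMap, FC, Conformation
from ipet.masks import lowpass, mass_to_volume_A3
from ipet.posefit import (Blob, ContourPair, DomainPose, ParticleExcluded,
                          contour_levels_for_mass, hole_score, identify_fc,
                          linker_feasibility, rigid_fit_domain,
                          segment_domains)


class TestContourLevels:
    def test_smoothed_sphere_threshold_at_surface_value(self):
        radius = 40.0
        dm = sphere_map(box=64, voxel=2.0, radius_A=radius, value=3.0)
        smooth = DensityMap(lowpass(dm.data, 20.0, 2.0), 2.0)
        sphere_vol = 4 / 3 * np.pi * radius**3
        mass = sphere_vol / mass_to_volume_A3(1.0)
        pair = contour_levels_for_mass(smooth, mass, multiples=(0.9, 1.0))
        # the level enclosing the sphere's own volume sits at the blurred
        # surface: close to half the plateau value
        plateau = smooth.data.max()
        assert 0.25 * plateau < pair.outer_threshold < 0.75 * plateau
        vox = (smooth.data > pair.outer_threshold).sum() * 8.0
        assert vox == pytest.approx(sphere_vol, rel=0.05)

    def test_enclosed_volume_ratio_matches_multiples(self, default_particle):
        dm = default_particle.density
        pair = contour_levels_for_mass(dm, 150.0, multiples=(0.6, 1.6))
        vox = dm.voxel_size**3
        inner_vol = (dm.data > pair.inner_threshold).sum() * vox
        outer_vol = (dm.data > pair.outer_threshold).sum() * vox
        assert outer_vol / inner_vol == pytest.approx(1.6 / 0.6, rel=0.05)

    def test_flat_map_raises(self):
        flat = DensityMap(np.ones((32, 32, 32)), 2.0)
        with pytest.raises(ValueError):
            contour_levels_for_mass(flat, 150.0)

    def test_contour_pair_ordering_enforced(self):
        with pytest.raises(ValueError):
            ContourPair(inner_threshold=1.0, outer_threshold=2.0)


class TestSegmentDomains:
    def test_phantom_blob_centers_match_ground_truth(self, default_particle):
        dm = default_particle.density
        blobs = segment_domains(dm, contour_levels_for_mass(dm))
        truth = default_particle.conformation.centers
        # blob centers are contour centroids; a couple of voxels is the
        # expected agreement with the template mass centers
        for b in blobs:
            nearest = np.linalg.norm(truth - b.center_A, axis=1).min()
            assert nearest <= 2.5 * dm.voxel_size

    def test_blob_diameters_within_expected_domain_range(
            self, default_particle):
        dm = default_particle.density
        blobs = segment_domains(dm, contour_levels_for_mass(dm))
        for b in blobs:
            assert 45.0 <= b.diameter_A <= 80.0

    def test_merged_domains_are_excluded(self):
        """Two spheres closer than a domain radius cannot be split."""
        ax = (np.arange(128) - 63.5) * 2.0
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        data = ((np.sqrt(zz**2 + yy**2 + (xx - 10) ** 2) < 25)
                | (np.sqrt(zz**2 + yy**2 + (xx + 10) ** 2) < 25)
                ).astype(np.float32)
        dm = DensityMap(data, 2.0)
        with pytest.raises(ParticleExcluded) as exc:
            segment_domains(dm, contour_levels_for_mass(dm, 150.0))
        assert exc.value.reason == "merged-domains"


def blob_from_mask(mask, voxel):
    pts = np.argwhere(mask)
    c = (np.array(mask.shape) - 1) / 2.0
    center = (pts.mean(axis=0)[::-1] - c[::-1]) * voxel
    diam = (pts.max(axis=0) - pts.min(axis=0)).max() * voxel
    return Blob(center, float(diam), mask, float(mask.sum() * voxel**3))


class TestIdentifyFc:
    def test_ring_template_outscores_dumbbell(self, template_maps):
        """Hole score criterion on noise-free template rasterizations."""
        scores = {}
        for name in ("Fab1", "Fc"):
            dm = template_maps[name]
            mask = dm.data > np.quantile(dm.data, 0.93)
            scores[name] = hole_score(dm, blob_from_mask(mask,
                                                         dm.voxel_size))
        assert scores["Fc"] > scores["Fab1"] + 0.05

    def test_three_identical_spheres_flagged_ambiguous(self):
        ax = (np.arange(128) - 63.5) * 2.0
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        data = np.zeros((128, 128, 128), dtype=np.float32)
        # touching spheres: one connected body at the outer contour
        for cx, cy in ((28, 0), (-14, 24), (-14, -24)):
            data += (np.sqrt(zz**2 + (yy - cy) ** 2 + (xx - cx) ** 2)
                     < 25).astype(np.float32)
        dm = DensityMap(data, 2.0)
        blobs = segment_domains(dm, contour_levels_for_mass(dm, 150.0))
        with pytest.raises(ParticleExcluded) as exc:
            identify_fc(blobs, dm)
        assert exc.value.reason == "ambiguous-fc"

    def test_labels_fc_correctly_on_phantom(self, default_particle):
        dm = default_particle.density
        blobs = segment_domains(dm, contour_levels_for_mass(dm))
        labels = identify_fc(blobs, dm)
        err = np.linalg.norm(labels["Fc"].center_A
                             - default_particle.conformation.centers[FC])
        assert err <= 2.5 * dm.voxel_size

    def test_label_stability_under_global_rotation(self, default_particle):
        """Fc identification is invariant under 90-degree map rotations."""
        base = default_particle.density
        truth_fc = default_particle.conformation.centers[FC]
        for k, axes in ((1, (1, 2)), (2, (1, 2)), (1, (0, 2))):
            data = np.rot90(base.data, k=k, axes=axes).copy()
            dm = DensityMap(data, base.voxel_size)
            blobs = segment_domains(dm, contour_levels_for_mass(dm))
            labels = identify_fc(blobs, dm)
            # the rotated Fc must keep the same distance from the origin
            assert np.linalg.norm(labels["Fc"].center_A) == pytest.approx(
                np.linalg.norm(truth_fc), abs=2.5 * dm.voxel_size)

    def test_noisy_phantom_monte_carlo_identification(self, small_particle):
        """Fc found in nearly all noisy realizations of the phantom map.

        The noise level (0.15x the map maximum) is three times the
        background deviation measured on actual refined reconstructions of
        raw SNR-0.2 tilt series, so this is a conservative stand-in for
        identification on reconstructed maps.
        """
        dm = small_particle.density
        truth_fc = small_particle.conformation.centers[FC]
        sigma = 0.15 * dm.data.max()
        hits = 0
        n_trials = 12
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            noisy = DensityMap(dm.data + rng.normal(0, sigma, dm.shape),
                               dm.voxel_size)
            try:
                blobs = segment_domains(noisy,
                                        contour_levels_for_mass(noisy))
                labels = identify_fc(blobs, noisy)
            except ParticleExcluded:
                continue
            if np.linalg.norm(labels["Fc"].center_A - truth_fc) < 15.0:
                hits += 1
        assert hits >= n_trials - 1


class TestRigidFit:
    def test_template_fit_to_itself_is_identity(self, template_maps):
        tpl = template_maps["Fab1"]
        n = 101
        target = np.zeros((n, n, n), dtype=np.float32)
        h = tpl.box_size // 2
        c = n // 2
        target[c - h:c + h + 1, c - h:c + h + 1, c - h:c + h + 1] = tpl.data
        pose = rigid_fit_domain(tpl, DensityMap(target, tpl.voxel_size),
                                DomainPose("Fab1", np.zeros(3), np.eye(3)),
                                rot_range_deg=15.0)
        assert pose.fit_cc == pytest.approx(1.0, abs=1e-3)
        assert np.linalg.norm(pose.center) <= 1.0
        np.testing.assert_allclose(pose.rotation, np.eye(3), atol=0.05)

    def test_known_rotation_recovered_within_5_degrees(self, template_maps):
        tpl = template_maps["Fab1"]
        axis = np.array([0.0, 0.0, 1.0])
        R_true = Rotation.from_rotvec(np.deg2rad(20.0) * axis).as_matrix()
        n = 101
        target = np.zeros((n, n, n), dtype=np.float32)
        h = tpl.box_size // 2
        c = n // 2
        from ipet.posefit import _rotate_vol
        target[c - h:c + h + 1, c - h:c + h + 1, c - h:c + h + 1] = \
            _rotate_vol(tpl.data, R_true)
        pose = rigid_fit_domain(tpl, DensityMap(target, tpl.voxel_size),
                                DomainPose("Fab1", np.zeros(3), np.eye(3)))
        geo = Rotation.from_matrix(pose.rotation @ R_true.T).magnitude()
        assert np.degrees(geo) <= 5.0

    def test_fit_score_not_below_initial(self, default_particle,
                                         template_maps):
        dm = default_particle.density
        blobs = segment_domains(dm, contour_levels_for_mass(dm))
        labels = identify_fc(blobs, dm)
        blob = labels["Fc"]
        init = DomainPose("Fc", blob.center_A, np.eye(3))
        pose = rigid_fit_domain(template_maps["Fc"], dm, init,
                                blob_mask=blob.voxel_mask)
        assert pose.fit_cc >= 0.0
        assert np.isfinite(pose.fit_cc)

    def test_init_outside_box_raises(self, template_maps):
        dm = DensityMap(np.random.default_rng(0).random((64, 64, 64)), 2.0)
        with pytest.raises(ValueError):
            rigid_fit_domain(template_maps["Fab1"], dm,
                             DomainPose("Fab1", np.array([500.0, 0, 0]),
                                        np.eye(3)))

    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError, match="proper"):
            DomainPose("Fc", np.zeros(3), -np.eye(3))


class TestLinkerFeasibility:
    @staticmethod
    def _conf_with_gap(gap):
        # anchors at 0.8 * (30 + 35) = 52 A of center distance
        d = gap + 52.0
        centers = np.array([[d, 0, 0], [0, d, 0], [0.0, 0, 0]])
        return Conformation.from_poses(centers, np.stack([np.eye(3)] * 3))

    def test_adjacent_domains_pass(self):
        ok, gaps = linker_feasibility(self._conf_with_gap(20.0))
        assert ok
        assert gaps[0] == pytest.approx(20.0)

    def test_70A_gap_fails(self):
        ok, gaps = linker_feasibility(self._conf_with_gap(70.0))
        assert not ok

    def test_zero_gap_passes(self):
        ok, gaps = linker_feasibility(self._conf_with_gap(0.0))
        assert ok
        assert gaps[0] == 0.0

    def test_boundary_is_16_residues_times_3_8(self):
        assert posefit.LINKER_RESIDUES * posefit.MAX_EXTENSION_PER_RESIDUE_A \
            == pytest.approx(60.8)
        ok_in, _ = linker_feasibility(self._conf_with_gap(60.0))
        ok_out, _ = linker_feasibility(self._conf_with_gap(61.5))
        assert ok_in and not ok_out
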