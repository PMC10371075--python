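"""Body frame, spherical binning, HJD computation and fusion."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from babykin import hjd, synthetic as syn
from babykin.core_io import MarkerTrajectorySet
from babykin.windows import WindowPlan


def _frame_session(points: dict[str, tuple], n_frames: int = 1) -> MarkerTrajectorySet:
    labels = list(points)
    pos = np.tile(np.array([points[m] for m in labels], dtype=float), (n_frames, 1, 1))
    return MarkerTrajectorySet("t", 100.0, labels, pos)


CANONICAL = {
    "C_Pelvis": (0, 0, 0),
    "L_Hip": (-50, 0, 0),
    "R_Hip": (50, 0, 0),
    "Head": (0, 0, 200),  # head along lab z -> longitudinal axis is z
    "L_Foot": (100, 0, 0),
}


class TestBodyFrame:
    def test_canonical_axes(self):
        frame = hjd.body_frame_at(_frame_session(CANONICAL), 0)
        np.testing.assert_allclose(frame.lateral, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(frame.longitudinal, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(frame.normal, np.cross([1, 0, 0], [0, 0, 1]), atol=1e-12)

    def test_rotated_configuration(self):
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        rotated = {m: tuple(rot @ np.array(p, dtype=float)) for m, p in CANONICAL.items()}
        f0 = hjd.body_frame_at(_frame_session(CANONICAL), 0)
        f1 = hjd.body_frame_at(_frame_session(rotated), 0)
        np.testing.assert_allclose(f1.lateral, rot @ f0.lateral, atol=1e-12)
        # body-frame coordinates of any joint are unchanged
        p = np.array([30.0, -20.0, 10.0])
        np.testing.assert_allclose(f1.to_body(rot @ p), f0.to_body(p), atol=1e-9)

    def test_head_collinear_is_geometry_error(self):
        bad = dict(CANONICAL, Head=(120, 0, 0))
        with pytest.raises(hjd.GeometryError):
            hjd.body_frame_at(_frame_session(bad), 0)

    def test_orthonormal_right_handed(self, small_session):
        session, _ = small_session
        f = hjd.body_frame_at(session, 100)
        axes = np.stack([f.lateral, f.longitudinal, f.normal])
        np.testing.assert_allclose(axes @ axes.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(axes) > 0


class TestCenterToRoot:
    def test_pelvis_maps_to_zero(self, small_session):
        session, _ = small_session
        disp = hjd.center_to_root(session, ["C_Pelvis"])
        np.testing.assert_allclose(disp["C_Pelvis"], 0.0, atol=1e-9)

    def test_lateral_offset(self):
        pts = dict(CANONICAL)
        pts["L_Foot"] = (100, 0, 0)  # 100 mm along the lateral axis
        disp = hjd.center_to_root(_frame_session(pts, n_frames=3), ["L_Foot"])
        np.testing.assert_allclose(disp["L_Foot"], [[100, 0, 0]] * 3, atol=1e-9)

    def test_rigid_motion_invariance(self, small_session, rng):
        session, _ = small_session
        joints = ["L_Foot", "R_Hand"]
        base = hjd.center_to_root(session, joints)
        rot = Rotation.random(random_state=123).as_matrix()
        shift = rng.uniform(-500, 500, 3)
        moved = MarkerTrajectorySet(
            "r", session.rate_hz, list(session.marker_labels),
            session.positions @ rot.T + shift,
        )
        after = hjd.center_to_root(moved, joints)
        for j in joints:
            np.testing.assert_allclose(after[j], base[j], atol=1e-9)

    def test_unknown_joint(self, small_session):
        session, _ = small_session
        with pytest.raises(KeyError):
            hjd.center_to_root(session, ["Tail"])


class TestToBin:
    def test_unit_x_maps_to_centre_cell(self):
        assert hjd.to_bin(np.array([1.0, 0, 0]), hjd.SphericalBinning(8, 8)) == 36

    def test_radius_invariance(self, rng):
        binning = hjd.SphericalBinning(8, 8)
        v = rng.standard_normal((200, 3))
        np.testing.assert_array_equal(
            hjd.bin_indices(v, binning), hjd.bin_indices(2.0 * v, binning)
        )

    def test_tiling_against_edge_enumeration(self, rng):
        """Every direction lands in exactly the cell an explicit edge scan finds."""
        binning = hjd.SphericalBinning(8, 8)
        v = rng.standard_normal((20000, 3))
        got = hjd.bin_indices(v, binning)
        assert got.min() >= 0 and got.max() < 64
        assert len(np.unique(got)) == 64  # all bins realised
        az_edges = -np.pi + 2 * np.pi * np.arange(9) / 8
        el_edges = -np.pi / 2 + np.pi * np.arange(9) / 8
        alpha = np.arctan2(v[:, 1], v[:, 0])
        theta = np.arcsin(v[:, 2] / np.linalg.norm(v, axis=1))
        for i in rng.choice(len(v), 500, replace=False):
            a_bin = next(k for k in range(8)
                         if az_edges[k] <= alpha[i] < az_edges[k + 1] or
                         (k == 7 and alpha[i] == np.pi))
            e_bin = next(k for k in range(8)
                         if el_edges[k] <= theta[i] < el_edges[k + 1] or
                         (k == 7 and theta[i] == np.pi / 2))
            assert got[i] == e_bin * 8 + a_bin

    def test_zero_vector_counted(self):
        binning = hjd.SphericalBinning(8, 8)
        assert hjd.to_bin(np.zeros(3), binning) == 36
        assert binning.zero_vector_count == 1


class TestComputeHJD:
    def test_stationary_joint_single_bin(self):
        disp = np.tile([10.0, 0, 0], (500, 1))
        h = hjd.compute_hjd(disp, (0, 500), hjd.SphericalBinning())
        assert h.counts[36] == 500 and h.counts.sum() == 500

    def test_alternating_positions_split_counts(self):
        disp = np.tile([[10.0, 0, 0], [-10.0, 0, 0]], (250, 1))
        h = hjd.compute_hjd(disp, (0, 500), hjd.SphericalBinning())
        assert sorted(h.counts[h.counts > 0].tolist()) == [250, 250]

    def test_conservation_1000_frames(self, rng):
        disp = rng.standard_normal((1200, 3))
        h = hjd.compute_hjd(disp, (100, 1100), hjd.SphericalBinning())
        assert h.counts.sum() == 1000

    def test_empty_window_errors(self, rng):
        with pytest.raises(ValueError):
            hjd.compute_hjd(rng.standard_normal((10, 3)), (5, 5), hjd.SphericalBinning())


class TestFusion:
    def _hjds(self, rng, parts=("L_Foot", "R_Foot")):
        binning = hjd.SphericalBinning()
        return [
            hjd.HJD(p, rng.integers(0, 50, binning.n_bins), (0, 500), binning)
            for p in parts
        ]

    def test_fuse_1d_blocks(self, rng):
        hjds = self._hjds(rng)
        v = hjd.fuse_1d(hjds)
        assert v.shape == (128,)
        np.testing.assert_array_equal(v[:64], hjds[0].counts)
        np.testing.assert_array_equal(v[64:], hjds[1].counts)

    def test_single_part_identity(self, rng):
        (h,) = self._hjds(rng, parts=("L_Foot",))
        np.testing.assert_array_equal(hjd.fuse_1d([h]), h.counts)

    def test_part_order_permutes_blocks(self, rng):
        hjds = self._hjds(rng)
        np.testing.assert_array_equal(
            hjd.fuse_1d(hjds[::-1]),
            np.concatenate([hjds[1].counts, hjds[0].counts]),
        )

    def test_fuse_2d_rows_and_reshape_consistency(self, rng):
        hjds = self._hjds(rng, parts=hjd.PART_SETS["full_body"])
        m = hjd.fuse_2d(hjds)
        assert m.shape == (6, 64)
        for i, h in enumerate(hjds):
            np.testing.assert_array_equal(m[i], h.counts)
        np.testing.assert_array_equal(m, hjd.fuse_1d(hjds).reshape(6, 64))

    def test_mismatched_binning_rejected(self, rng):
        a = hjd.HJD("L", rng.integers(0, 5, 64), (0, 500), hjd.SphericalBinning(8, 8))
        b = hjd.HJD("R", rng.integers(0, 5, 16), (0, 500), hjd.SphericalBinning(4, 4))
        with pytest.raises(ValueError):
            hjd.fuse_1d([a, b])


class TestBuildDataset:
    def test_window_counts_and_boundaries(self):
        cfg = syn.SyntheticConfig(
            n_frames={"B1": 1894, "B2": 499, "CR1": 600, "CR2": 600, "DC": 600}, seed=3
        )
        ds = hjd.build_dataset([syn.generate_session(cfg)], "fused1d", "feet")
        b1 = ds.window_starts[ds.labels == 0]
        np.testing.assert_array_equal(b1, [0, 400, 800, 1200])  # floor((1894-500)/400)+1
        assert (ds.labels == 1).sum() == 0  # 499-frame segment yields nothing
        for lab in (2, 3, 4):
            assert (ds.labels == lab).sum() == 1

    def test_all_stage_labels_present(self, small_cohort):
        ds = hjd.build_dataset(small_cohort, "fused1d", "feet")
        assert set(np.unique(ds.labels)) == {0, 1, 2, 3, 4}
        assert set(ds.subjects) == {"S1", "S2", "S3"}

    def test_fused2d_shape(self, small_cohort):
        ds = hjd.build_dataset(small_cohort, "fused2d", "full_body")
        assert ds.features.shape[1:] == (6, 64)

    def test_missing_values_rejected(self, small_cohort):
        session, ann = small_cohort[0]
        dirty = syn.inject_missing(session, 1.0, (5, 10), seed=1)
        with pytest.raises(ValueError, match="missing"):
            hjd.build_dataset([(dirty, ann)], "fused1d", "feet")


class TestInvariances:
    def test_view_invariance_of_hjds(self, small_session, rng):
        """A rigid rotation + translation of the lab changes no bin count."""
        session, ann = small_session
        ds = hjd.build_dataset([(session, ann)], "fused1d", "feet")
        rot = Rotation.random(random_state=7).as_matrix()
        moved = MarkerTrajectorySet(
            "m", session.rate_hz, list(session.marker_labels),
            session.positions @ rot.T + np.array([1000.0, -2000.0, 500.0]),
        )
        ds_m = hjd.build_dataset([(moved, ann)], "fused1d", "feet")
        np.testing.assert_array_equal(ds.features, ds_m.features)

    def test_sagittal_mirror_swaps_lr_with_azimuth_reflection(self, small_session):
        """Mirroring the body across the sagittal plane swaps left/right
        joint histograms under the azimuth-reflection bin permutation
        a -> (n_az/2 - 1 - a) mod n_az."""
        session, _ = small_session
        sub = MarkerTrajectorySet(
            "s", session.rate_hz, list(session.marker_labels),
            session.positions[:800].copy(),
        )
        mirrored_pos = sub.positions * np.array([-1.0, 1.0, 1.0])
        swap = {"L": "R", "R": "L"}
        mlabels = [
            swap[m[0]] + m[1:] if m[:2] in ("L_", "R_") else m
            for m in sub.marker_labels
        ]
        mirrored = MarkerTrajectorySet("m", sub.rate_hz, mlabels, mirrored_pos)
        binning = hjd.SphericalBinning(8, 8)
        d = hjd.center_to_root(sub, ["L_Foot", "R_Foot"])
        dm = hjd.center_to_root(mirrored, ["L_Foot", "R_Foot"])
        perm_az = (8 // 2 - 1 - np.arange(8)) % 8
        for orig, mirr in (("L_Foot", "R_Foot"), ("R_Foot", "L_Foot")):
            h = hjd.compute_hjd(d[orig], (0, 800), binning).counts.reshape(8, 8)
            hm = hjd.compute_hjd(dm[mirr], (0, 800), binning).counts.reshape(8, 8)
            np.testing.assert_array_equal(hm, h[:, perm_az])

    def test_normalisation_flag(self, rng):
        binning = hjd.SphericalBinning()
        h = hjd.HJD("L_Foot", rng.multinomial(500, np.ones(64) / 64), (0, 500), binning)
        prop = hjd.fuse_1d([h], normalise="proportion")
        assert abs(prop.sum() - 1.0) < 1e-12
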