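"""Particle geometry: dedup, orientations, projections, wedge weighting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage
from scipy.spatial.transform import Rotation

import memflat as mf
from memflat.particles import (ProjectionSpec, align_particle, attach_geometry,
                               build_3dctf, dedup_picks, euler_to_matrix,
                               extract_2dctf, inplane_from_class2d,
                               match_template_rotation, matrix_to_euler,
                               orientation_matrix, project_particle,
                               projection_basis)
from memflat.volio import VoxelVolume

unit_vectors = st.builds(
    lambda v: v / np.linalg.norm(v),
    st.tuples(*[st.floats(-1, 1).filter(lambda x: abs(x) > 1e-3)] * 3).map(np.array),
)


class TestDedup:
    def test_close_pair_keeps_higher_score(self):
        picks = pd.DataFrame({"u": [10.0, 10.5], "v": [10.0, 10.5], "w": [5.0, 5.5],
                              "score": [0.9, 0.8]})
        out = dedup_picks(picks, min_spacing=5.0)
        assert len(out) == 1 and out.iloc[0]["score"] == 0.9

    def test_all_far_apart_all_kept(self, rng):
        picks = pd.DataFrame({"u": np.arange(10) * 20.0, "v": np.zeros(10),
                              "w": np.zeros(10), "score": rng.random(10)})
        assert len(dedup_picks(picks, min_spacing=5.0)) == 10

    def test_matches_greedy_oracle(self, rng):
        n = 200
        picks = pd.DataFrame({"u": rng.uniform(0, 60, n), "v": rng.uniform(0, 60, n),
                              "w": rng.uniform(0, 10, n), "score": rng.random(n)})
        min_spacing = 8.0
        out = dedup_picks(picks, min_spacing=min_spacing)
        # brute-force greedy oracle
        order = picks.sort_values(["score", "w", "u", "v"],
                                  ascending=[False, True, True, True]).index
        kept = []
        for i in order:
            p = picks.loc[i, ["u", "v", "w"]].to_numpy()
            if all(np.linalg.norm(p - q) >= min_spacing for q in kept):
                kept.append(p)
        np.testing.assert_allclose(out[["u", "v", "w"]].to_numpy(), np.array(kept))

    def test_input_order_invariance(self, rng):
        n = 100
        picks = pd.DataFrame({"u": rng.uniform(0, 40, n), "v": rng.uniform(0, 40, n),
                              "w": rng.uniform(0, 8, n), "score": rng.random(n)})
        out1 = dedup_picks(picks, min_spacing=6.0)
        out2 = dedup_picks(picks.sample(frac=1, random_state=7), min_spacing=6.0)
        np.testing.assert_allclose(out1[["u", "v", "w", "score"]].to_numpy(),
                                   out2[["u", "v", "w", "score"]].to_numpy())

    def test_min_score_and_max_count(self, rng):
        picks = pd.DataFrame({"u": np.arange(20) * 30.0, "v": np.zeros(20),
                              "w": np.zeros(20), "score": np.linspace(1, 0, 20)})
        out = dedup_picks(picks, min_spacing=5.0, min_score=0.25, max_count=10)
        assert len(out) == 10 and out["score"].min() >= 0.25
        assert out["score"].is_monotonic_decreasing


class TestAttachGeometry:
    def test_node_pick(self, cylinder_flat):
        fm = cylinder_flat["fm"]
        picks = pd.DataFrame({"u": [12.0], "v": [15.0], "w": [float(fm.w_c)],
                              "score": [1.0]})
        out = attach_geometry(picks, fm)
        np.testing.assert_allclose(out[["X", "Y", "Z"]].to_numpy()[0], fm.S[12, 15],
                                   atol=1e-9)
        np.testing.assert_allclose(out[["nx", "ny", "nz"]].to_numpy()[0], fm.N[12, 15],
                                   atol=1e-9)

    def test_planar_flatmap_normals(self, plane_flat):
        fm = plane_flat["fm"]
        picks = pd.DataFrame({"u": [5.0, 10.0], "v": [5.0, 20.0], "w": [3.0, 7.0],
                              "score": [1.0, 1.0]})
        out = attach_geometry(picks, fm)
        np.testing.assert_allclose(out[["nx", "ny", "nz"]].to_numpy(),
                                   [[0, 0, 1], [0, 0, 1]], atol=1e-6)

    def test_round_trip_through_raw(self, cylinder_flat, rng):
        fm = cylinder_flat["fm"]
        nu, nv = fm.shape
        picks = pd.DataFrame({"u": rng.uniform(3, nu - 4, 20),
                              "v": rng.uniform(3, nv - 4, 20),
                              "w": rng.uniform(2, 2 * fm.w_t - 2, 20),
                              "score": np.ones(20)})
        out = attach_geometry(picks, fm)
        uvw, _ = mf.raw_to_flat(fm, out[["X", "Y", "Z"]].to_numpy())
        np.testing.assert_allclose(uvw, out[["u", "v", "w"]].to_numpy(), atol=0.5)

    def test_outside_grid_dropped(self, plane_flat):
        picks = pd.DataFrame({"u": [5.0, 1e4], "v": [5.0, 5.0], "w": [3.0, 3.0],
                              "score": [1.0, 1.0]})
        with pytest.warns(UserWarning, match="dropped"):
            out = attach_geometry(picks, plane_flat["fm"])
        assert len(out) == 1


class TestOrientation:
    def test_canonical_identity(self):
        np.testing.assert_allclose(orientation_matrix([0, 0, 1], [1, 0, 0]), np.eye(3),
                                   atol=1e-12)

    def test_perpendicular_component_rule(self):
        """A labeled direction with a normal component gives the same rotation
        as its in-plane part alone."""
        np.testing.assert_allclose(orientation_matrix([0, 0, 1], [1, 0, 1]), np.eye(3),
                                   atol=1e-12)

    def test_degenerate_direction_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            orientation_matrix([0, 0, 1], [0, 0, 2.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(n=unit_vectors, v=unit_vectors)
    def test_proper_rotation_with_normal_third_column(self, n, v):
        if abs(abs(n @ v) - 1) < 1e-3:
            return
        R = orientation_matrix(n, v)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(R[:, 2], n, atol=1e-9)

    def test_euler_identity_and_pure_z(self):
        assert matrix_to_euler(np.eye(3)) == (0.0, 0.0, 0.0)
        R = Rotation.from_euler("Z", 30, degrees=True).as_matrix()
        rot, tilt, psi = matrix_to_euler(R)
        assert (rot, tilt, psi) == (pytest.approx(30.0), 0.0, 0.0)

    def test_euler_round_trip_random(self, rng):
        for _ in range(500):
            R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            np.testing.assert_allclose(euler_to_matrix(*matrix_to_euler(R)), R,
                                       atol=1e-9)

    def test_non_rotation_rejected(self):
        with pytest.raises(ValueError):
            matrix_to_euler(np.diag([1.0, 1.0, -1.0]))

    def test_export_consistency_normal_from_euler(self, rng):
        """euler_to_matrix(angles) third column equals the stored normal."""
        for _ in range(50):
            n = rng.normal(size=3); n /= np.linalg.norm(n)
            v = rng.normal(size=3)
            if abs(abs(v / np.linalg.norm(v) @ n) - 1) < 1e-3:
                continue
            R = orientation_matrix(n, v)
            back = euler_to_matrix(*matrix_to_euler(R))
            np.testing.assert_allclose(back[:, 2], n, atol=1e-6)


class TestProjectionBasis:
    def test_z_degenerate_rule(self):
        e1, e2 = projection_basis([0, 0, 1.0])
        np.testing.assert_allclose(e1, [1, 0, 0])
        np.testing.assert_allclose(e2, [0, 1, 0])

    def test_x_axis_case(self):
        e1, e2 = projection_basis([1.0, 0, 0])
        np.testing.assert_allclose(e1, [0, -1, 0], atol=1e-12)
        np.testing.assert_allclose(e2, [0, 0, -1], atol=1e-12)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(d=unit_vectors)
    def test_orthonormal_right_handed(self, d):
        e1, e2 = projection_basis(d)
        assert abs(e1 @ e2) < 1e-9
        assert np.linalg.norm(e1) == pytest.approx(1, abs=1e-9)
        np.testing.assert_allclose(np.cross(e1, e2), d, atol=1e-9)


class TestProjection:
    def test_constant_volume(self):
        vol = VoxelVolume(np.full((40, 40, 40), 2.0, np.float32))
        img, ok = project_particle(vol, [20, 20, 20], [0, 0, 1.0],
                                   ProjectionSpec(box=11, depth=7))
        assert ok
        np.testing.assert_allclose(img, 14.0, atol=1e-6)

    def test_axis_aligned_equals_crop_sum(self, rng):
        data = rng.normal(size=(40, 40, 40)).astype(np.float32)
        vol = VoxelVolume(data)
        img, _ = project_particle(vol, [20, 20, 20], [0, 0, 1.0],
                                  ProjectionSpec(box=9, depth=7))
        crop = data[16:25, 16:25, 17:24].sum(axis=2)
        np.testing.assert_allclose(img, crop, atol=1e-5)

    def test_oblique_matches_analytic_oracle(self):
        """Projection of a gridded smooth Gaussian along an oblique direction
        vs brute-force evaluation of the analytic function at the exact sample
        locations (no interpolation in the oracle)."""
        n, sig, c3 = 48, 7.0, 23.5
        ax = np.arange(n)
        data = np.exp(-(((ax[:, None, None] - c3)**2 + (ax[None, :, None] - c3)**2
                         + (ax[None, None, :] - c3)**2) / (2 * sig**2))).astype(np.float32)
        vol = VoxelVolume(data)
        d = np.array([0.3, 0.2, 0.95]); d /= np.linalg.norm(d)
        spec = ProjectionSpec(box=9, depth=5)
        img, _ = project_particle(vol, [c3, c3, c3], d, spec)
        e1, e2 = projection_basis(d)
        c = (spec.box - 1) / 2
        ts = np.arange(spec.depth) - (spec.depth - 1) / 2
        oracle = np.zeros((spec.box, spec.box))
        for i in range(spec.box):
            for j in range(spec.box):
                pos = (np.full(3, c3) + (i - c) * e1 + (j - c) * e2 + ts[:, None] * d)
                oracle[i, j] = np.exp(-((pos - c3)**2).sum(1) / (2 * sig**2)).sum()
        assert np.abs(img - oracle).max() < 1e-2 * img.max()

    def test_even_depth_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ProjectionSpec(box=16, depth=6)

    def test_outside_center_rejected(self):
        vol = VoxelVolume(np.zeros((10, 10, 10), np.float32))
        with pytest.raises(ValueError, match="outside"):
            project_particle(vol, [50, 5, 5], [0, 0, 1.0], ProjectionSpec(box=5, depth=3))


class TestWedgeCTF:
    def test_single_tilt_slab_only(self):
        w = build_3dctf(33, [0.0])
        qz = np.abs(np.arange(33) - 16)
        outside = np.broadcast_to(qz[None, None, :] > 1, (33, 33, 33))
        assert w.ctf3d[outside].max() == 0.0
        assert w.ctf3d[16, 16, 16] == pytest.approx(1.0)

    def test_hermitian_symmetry_exact(self):
        w = build_3dctf(33, np.arange(-60, 61, 2.0))
        np.testing.assert_array_equal(w.ctf3d, w.ctf3d[::-1, ::-1, ::-1])

    def test_missing_wedge_volume_matches_analytic_count(self):
        """Zero-weight voxels agree with the analytic double-wedge criterion
        (half-angle 30 deg about qz for a +-60 deg series) within 2%, counted
        inside the in-plane Nyquist disc with a 1-voxel guard band."""
        size = 33
        w = build_3dctf(size, np.arange(-60, 61, 2.0))
        c = size // 2
        q = np.arange(size) - c
        QX, QY, QZ = np.meshgrid(q, q, q, indexing="ij")
        rho = np.sqrt(QX**2 + QZ**2)
        ang = np.radians(np.degrees(np.arctan2(np.abs(QX), np.abs(QZ))))
        disc = (rho <= c) & (rho > 3)
        # inside the wedge, the closest measured section is the +-60 deg one;
        # the slab kernel of half-width 1 voxel leaves zeros only where
        # rho * sin(30 deg - ang) exceeds 1 (the guard band)
        gap = rho * np.sin(np.maximum(np.radians(30) - ang, 0.0))
        analytic_zero = disc & (gap > 1.0)
        measured_zero = disc & (w.ctf3d == 0)
        frac_analytic = analytic_zero.sum() / disc.sum()
        frac_measured = measured_zero.sum() / disc.sum()
        assert frac_measured == pytest.approx(frac_analytic, abs=0.02)
        assert np.all(w.ctf3d[disc & (gap > 1.5)] == 0)

    def test_ctf_modulation_bounded(self):
        w = build_3dctf(33, np.arange(-60, 61, 2.0),
                        ctf_params={"defocus_A": 3e4}, voxel_size=7.26)
        assert np.abs(w.ctf3d).max() <= 1.0 + 1e-9


class TestExtract2DCTF:
    def test_z_projection_has_no_missing_wedge(self):
        w = build_3dctf(33, np.arange(-60, 61, 2.0))
        ctf = extract_2dctf(w, [0, 0, 1.0])
        assert ctf.min() > 0.0

    def test_x_projection_zero_sectors(self):
        """Perpendicular to both tilt axis and beam: the 2DCTF shows zero
        sectors around the image axis mapped from z (30 deg half-angle and
        beyond, outside a guard band)."""
        size = 33
        w = build_3dctf(size, np.arange(-60, 61, 2.0))
        ctf = extract_2dctf(w, [1.0, 0, 0])
        e1, e2 = projection_basis([1.0, 0, 0])
        i = np.arange(size) - (size - 1) / 2
        I, J = np.meshgrid(i, i, indexing="ij")
        q = I[..., None] * e1 + J[..., None] * e2
        ang = np.degrees(np.arctan2(np.abs(q[..., 1]), np.abs(q[..., 2])))
        rad = np.sqrt(I**2 + J**2)
        sector = (ang < 30) & (rad >= 5) & (rad <= size // 2)
        assert ctf[sector].max() == 0.0
        on_axis = (np.abs(q[..., 2]) < 0.5) & (rad < size // 2)
        assert ctf[on_axis].min() > 0.5

    def test_matches_rotation_oracle(self):
        """Slice extraction equals rotating the whole 3DCTF cube and reading
        its central plane."""
        size = 33
        w = build_3dctf(size, np.arange(-60, 61, 2.0))
        d = np.array([0.6, 0.3, 0.74]); d /= np.linalg.norm(d)
        ctf = extract_2dctf(w, d)
        e1, e2 = projection_basis(d)
        R = np.column_stack([e1, e2, d])
        i = np.arange(size) - (size - 1) / 2
        coords = np.stack(np.meshgrid(i, i, [0.0], indexing="ij"), -1).reshape(-1, 3)
        pts = coords @ R.T + size // 2
        oracle = ndimage.map_coordinates(w.ctf3d, pts.T, order=1,
                                         cval=0.0).reshape(size, size)
        assert np.abs(ctf - oracle).max() < 1e-3


class TestClass2DImport:
    def _picks(self, n=1):
        return pd.DataFrame({"u": np.zeros(n), "v": np.zeros(n), "w": np.zeros(n),
                             "X": np.zeros(n), "Y": np.zeros(n), "Z": np.zeros(n),
                             "nx": np.zeros(n), "ny": np.zeros(n), "nz": np.ones(n),
                             "score": np.ones(n)})

    def test_zero_angle_identity(self):
        asg = pd.DataFrame({"class_id": [1], "psi": [0.0], "du": [0.0], "dv": [0.0]})
        out = inplane_from_class2d(self._picks(), asg)
        np.testing.assert_allclose(out[["dx", "dy", "dz"]].to_numpy()[0], [1, 0, 0],
                                   atol=1e-12)
        np.testing.assert_allclose(
            euler_to_matrix(out["rot"][0], out["tilt"][0], out["psi"][0]), np.eye(3),
            atol=1e-9)

    def test_ninety_degrees_about_z(self):
        asg = pd.DataFrame({"class_id": [1], "psi": [90.0], "du": [0.0], "dv": [0.0]})
        out = inplane_from_class2d(self._picks(), asg)
        np.testing.assert_allclose(out[["dx", "dy", "dz"]].to_numpy()[0], [0, 1, 0],
                                   atol=1e-12)
        R = euler_to_matrix(out["rot"][0], out["tilt"][0], out["psi"][0])
        np.testing.assert_allclose(
            R, Rotation.from_euler("Z", 90, degrees=True).as_matrix(), atol=1e-9)

    def test_class_offset_composes(self, rng):
        """rotation(psi) followed by the class offset equals rotation(psi+dpsi)."""
        for _ in range(20):
            psi, dpsi = rng.uniform(0, 360, 2)
            asg1 = pd.DataFrame({"class_id": [1], "psi": [psi], "du": [0.0], "dv": [0.0]})
            asg2 = pd.DataFrame({"class_id": [1], "psi": [psi + dpsi],
                                 "du": [0.0], "dv": [0.0]})
            out1 = inplane_from_class2d(self._picks(), asg1, {1: (dpsi, 0, 0)})
            out2 = inplane_from_class2d(self._picks(), asg2)
            R1 = euler_to_matrix(out1["rot"][0], out1["tilt"][0], out1["psi"][0])
            R2 = euler_to_matrix(out2["rot"][0], out2["tilt"][0], out2["psi"][0])
            np.testing.assert_allclose(R1, R2, atol=1e-9)

    def test_shift_converted_to_raw_frame(self):
        asg = pd.DataFrame({"class_id": [1], "psi": [0.0], "du": [2.0], "dv": [3.0]})
        out = inplane_from_class2d(self._picks(), asg)
        np.testing.assert_allclose(
            out[["shift_x", "shift_y", "shift_z"]].to_numpy()[0], [2, 3, 0], atol=1e-12)

    def test_unknown_class_dropped(self):
        asg = pd.DataFrame({"class_id": [1, 7], "psi": [0.0, 0.0],
                            "du": [0.0, 0.0], "dv": [0.0, 0.0]})
        with pytest.warns(UserWarning, match="unknown class"):
            out = inplane_from_class2d(self._picks(2), asg, {1: (0.0, 0.0, 0.0)})
        assert len(out) == 1


class TestTemplateMatching:
    def test_known_rotation_recovered(self):
        """An asymmetric template rotated by a known angle is matched to it."""
        t = np.zeros((25, 25))
        t[12, 12:20] = 1.0
        t[10:15, 12] = 0.5
        for true_ang in (0.0, 40.0, 160.0, 250.0):
            img = ndimage.rotate(t, true_ang, reshape=False, order=1)
            ang, cc = match_template_rotation(img, t, step_deg=1.0)
            err = (ang - true_ang + 180) % 360 - 180
            assert abs(err) <= 2.0
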