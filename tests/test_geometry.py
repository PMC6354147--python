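"""Section-plane construction, perturbation, and extraction geometry."""

import numpy as np
import pytest

from sectmorph import (
    PhaseVolume,
    SectionPlane,
    VoxelVolume,
    axis_aligned_plane,
    extract_phase_slice,
    extract_slice,
    offset_plane,
    perturb_plane,
    rotate_plane,
)

PITCH = 19.75


def random_volume(seed, shape=(12, 12, 12), spacing=PITCH):
    rng = np.random.default_rng(seed)
    return VoxelVolume(values=rng.normal(size=shape), spacing=spacing)


class TestPlaneConstruction:
    def test_frame_must_be_orthonormal(self):
        with pytest.raises(ValueError):
            SectionPlane(np.zeros(3), np.array([0, 0, 1.0]), np.array([1.0, 0, 0]),
                         np.array([1.0, 0, 0]), PITCH, (4, 4))
        with pytest.raises(ValueError):  # left-handed frame
            SectionPlane(np.zeros(3), np.array([0, 0, -1.0]), np.array([1.0, 0, 0]),
                         np.array([0, 1.0, 0]), PITCH, (4, 4))

    def test_axis_aligned_z_plane_geometry(self):
        vol = random_volume(0)
        k = 5
        plane = axis_aligned_plane(vol, "z", k)
        assert np.allclose(plane.normal, [0, 0, 1])
        assert plane.origin[2] == vol.origin[2] + k * vol.spacing

    def test_parallel_indices_are_spaced_by_voxels(self):
        vol = random_volume(1)
        p1 = axis_aligned_plane(vol, "z", 3)
        p2 = axis_aligned_plane(vol, "z", 7)
        assert np.linalg.norm(p2.origin - p1.origin) == pytest.approx(4 * vol.spacing)

    def test_index_out_of_range(self):
        vol = random_volume(2)
        with pytest.raises(IndexError):
            axis_aligned_plane(vol, "z", 12)


class TestPerturbations:
    def test_offset_zero_is_identity(self):
        vol = random_volume(3)
        plane = axis_aligned_plane(vol, "z", 4)
        assert offset_plane(plane, 0) is plane

    def test_offset_displacement_is_pitch_times_k(self):
        vol = random_volume(3)
        plane = axis_aligned_plane(vol, "z", 4)
        moved = offset_plane(plane, 4)
        assert np.linalg.norm(moved.origin - plane.origin) == pytest.approx(4 * PITCH)

    def test_offset_round_trip(self):
        vol = random_volume(3)
        plane = axis_aligned_plane(vol, "z", 4)
        back = offset_plane(offset_plane(plane, 4), -4)
        assert np.abs(back.origin - plane.origin).max() < 1e-9

    def test_rotation_zero_is_identity(self):
        vol = random_volume(4)
        plane = axis_aligned_plane(vol, "z", 4)
        assert rotate_plane(plane, 0.0) is plane

    def test_rotation_round_trip(self):
        vol = random_volume(4)
        plane = axis_aligned_plane(vol, "z", 4)
        back = rotate_plane(rotate_plane(plane, 10.0), -10.0)
        for attr in ("normal", "u_axis", "v_axis", "origin"):
            assert np.abs(getattr(back, attr) - getattr(plane, attr)).max() < 1e-9

    def test_rotation_angle_via_normal_dot_product(self):
        vol = random_volume(4)
        plane = axis_aligned_plane(vol, "z", 4)
        rot = rotate_plane(plane, 10.0)
        assert abs(rot.normal @ plane.normal - np.cos(np.deg2rad(10))) < 1e-12
        assert np.array_equal(rot.v_axis, plane.v_axis)  # pivot axis unchanged

    def test_frame_stays_orthonormal_under_100_compositions(self):
        rng = np.random.default_rng(7)
        vol = random_volume(5)
        plane = axis_aligned_plane(vol, "z", 4)
        for _ in range(100):
            if rng.random() < 0.5:
                plane = rotate_plane(plane, rng.uniform(-15, 15))
            else:
                plane = offset_plane(plane, int(rng.integers(-4, 5)))
        n, u, v = plane.normal, plane.u_axis, plane.v_axis
        assert abs(np.linalg.norm(n) - 1) < 1e-9
        assert abs(np.linalg.norm(u) - 1) < 1e-9
        assert abs(u @ v) < 1e-9 and abs(u @ n) < 1e-9 and abs(v @ n) < 1e-9
        assert np.abs(np.cross(u, v) - n).max() < 1e-9

    def test_rotate_then_offset_differs_from_offset_then_rotate(self):
        vol = random_volume(6)
        plane = axis_aligned_plane(vol, "z", 4)
        a = offset_plane(rotate_plane(plane, 10), 4)
        b = rotate_plane(offset_plane(plane, 4), 10)
        assert not np.allclose(a.origin, b.origin)

    def test_perturb_plane_pure_offset_matches_pixel_offset(self):
        vol = random_volume(6)
        plane = axis_aligned_plane(vol, "z", 4)
        a = perturb_plane(plane, offset_um=4 * PITCH)
        b = offset_plane(plane, 4)
        assert np.abs(a.origin - b.origin).max() < 1e-9


class TestExtraction:
    @pytest.mark.parametrize("axis,index", [("z", 3), ("x", 7), ("y", 0)])
    def test_identity_slice_nearest(self, axis, index):
        vol = random_volume(10)
        plane = axis_aligned_plane(vol, axis, index)
        sl = extract_slice(vol, plane, interpolation="nearest")
        expected = {"z": vol.values[index],
                    "x": vol.values[:, :, index],
                    "y": vol.values[:, index, :]}[axis]
        assert sl.valid_mask.all()
        assert np.array_equal(sl.values, expected)

    def test_trilinear_exact_at_voxel_centers(self):
        vol = random_volume(11)
        plane = axis_aligned_plane(vol, "z", 6)
        sl = extract_slice(vol, plane, interpolation="trilinear")
        assert np.abs(sl.values - vol.values[6]).max() < 1e-12

    def test_constant_volume_oblique_plane(self):
        vol = VoxelVolume(values=np.full((16, 16, 16), 7.5), spacing=PITCH)
        plane = rotate_plane(axis_aligned_plane(vol, "z", 8, extent=(8, 8)), 9.0)
        sl = extract_slice(vol, plane)
        assert np.abs(sl.values[sl.valid_mask] - 7.5).max() < 1e-12

    def test_out_of_volume_samples_are_masked(self):
        vol = random_volume(12, shape=(8, 8, 8))
        plane = axis_aligned_plane(vol, "z", 4, extent=(16, 16))
        sl = extract_slice(vol, plane)
        assert not sl.valid_mask.all()
        assert np.isnan(sl.values[~sl.valid_mask]).all()
        assert np.isfinite(sl.values[sl.valid_mask]).all()

    def test_trilinear_extraction_is_linear_in_the_volume(self):
        v1, v2 = random_volume(13), random_volume(14)
        plane = rotate_plane(axis_aligned_plane(v1, "z", 6, extent=(6, 6)), 7.0)
        combo = VoxelVolume(values=2.0 * v1.values + 3.0 * v2.values, spacing=PITCH)
        s = extract_slice(combo, plane).values
        s12 = 2.0 * extract_slice(v1, plane).values + 3.0 * extract_slice(v2, plane).values
        ok = np.isfinite(s) & np.isfinite(s12)
        assert ok.any()
        assert np.abs(s[ok] - s12[ok]).max() < 1e-9

    def test_phase_identity_slice(self, small_phase):
        plane = axis_aligned_plane(small_phase, "z", 20)
        pm = extract_phase_slice(small_phase, plane)
        assert np.array_equal(pm.labels, small_phase.labels[20])

    def test_all_bone_volume_gives_all_bone_map(self):
        vol = PhaseVolume(labels=np.ones((10, 10, 10), dtype=np.uint8), spacing=PITCH)
        plane = rotate_plane(axis_aligned_plane(vol, "z", 5, extent=(6, 6)), 10.0)
        pm = extract_phase_slice(vol, plane)
        assert np.all(pm.labels[pm.valid_mask] == 1)

    def test_rotated_phase_slice_matches_brute_force_nearest_lookup(self, small_phase):
        plane = rotate_plane(axis_aligned_plane(small_phase, "z", 32), 10.0)
        pm = extract_phase_slice(small_phase, plane)
        # oracle: per-pixel nearest-voxel lookup, written out longhand
        pts = plane.grid_points()
        idx = np.round((pts - small_phase.origin) / small_phase.spacing).astype(int)
        nz, ny, nx = small_phase.shape
        counts = np.zeros(3, dtype=int)
        valid = 0
        for r in range(pts.shape[0]):
            for c in range(pts.shape[1]):
                ix, iy, iz = idx[r, c]
                fx, fy, fz = (pts[r, c] - small_phase.origin) / small_phase.spacing
                if -1e-7 <= fx <= nx - 1 + 1e-7 and -1e-7 <= fy <= ny - 1 + 1e-7 \
                        and -1e-7 <= fz <= nz - 1 + 1e-7:
                    counts[small_phase.labels[iz, iy, ix]] += 1
                    valid += 1
        got = np.bincount(pm.labels[pm.valid_mask], minlength=3)
        assert valid == pm.valid_mask.sum()
        assert np.array_equal(got, counts)
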