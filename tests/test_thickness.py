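"""The thickness protocol: circle fit, angular frames, per-site read-outs."""

import numpy as np
import pytest

import kneemorph as km
from kneemorph.thickness import (
    MEDIAL_ZERO_OFFSET_DEG,
    REGION_CENTERS,
    select_fpc_slice,
)


def circle_points(center, radius, angles_deg):
    a = np.deg2rad(np.asarray(angles_deg, float))
    return np.column_stack(
        [center[0] + radius * np.sin(a), center[1] - radius * np.cos(a)]
    )


def annulus_slice(center, r_in, r_out, spacing=0.2, extent=80.0):
    """Sagittal (y, z) slice of a full annulus, plus a bone disc inside."""
    n = int(extent / spacing)
    coords = np.arange(n) * spacing
    Y, Z = np.meshgrid(coords, coords, indexing="ij", sparse=True)
    r = np.hypot(Y - center[0], Z - center[1])
    cart = (r >= r_in) & (r < r_out)
    bone = r < r_in
    return cart, bone, np.full(2, spacing), np.zeros(2)


class TestCircleFit:
    def test_exact_circle_recovered(self):
        pts = circle_points((0.0, 0.0), 30.0, np.linspace(-60, 75, 40))
        center, radius, resid = km.fit_condyle_circle(pts)
        assert np.allclose(center, 0, atol=1e-9)
        assert radius == pytest.approx(30.0, abs=1e-9)
        assert resid == pytest.approx(0.0, abs=1e-9)

    def test_noisy_arc_parameters_and_residual(self):
        rng = np.random.default_rng(0)
        sigma = 0.2
        resids = []
        for _ in range(50):
            pts = circle_points((5.0, -3.0), 30.0, np.linspace(-90, 90, 240))
            pts = pts + rng.normal(0, sigma, pts.shape)
            center, radius, resid = km.fit_condyle_circle(pts)
            assert np.allclose(center, (5.0, -3.0), atol=0.2)
            assert radius == pytest.approx(30.0, abs=0.2)
            resids.append(resid)
        se = np.std(resids, ddof=1) / np.sqrt(len(resids))
        # RMS radial residual concentrates near sigma (3 dof absorbed)
        assert abs(np.mean(resids) - sigma) < 3 * se + 0.01

    def test_objective_beats_grid_search(self):
        rng = np.random.default_rng(1)
        pts = circle_points((0.0, 0.0), 30.0, np.linspace(-50, 70, 25))
        pts = pts + rng.normal(0, 0.3, pts.shape)

        def objective(cy, cz, r):
            return np.mean((np.hypot(pts[:, 0] - cy, pts[:, 1] - cz) - r) ** 2)

        center, radius, _ = km.fit_condyle_circle(pts)
        best_fit = objective(center[0], center[1], radius)
        grid = np.arange(-0.5, 0.51, 0.1)
        brute = min(
            objective(cy, cz, 30.0 + dr)
            for cy in grid for cz in grid for dr in grid
        )
        assert best_fit <= brute + 1e-12

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="collinear"):
            km.fit_condyle_circle(pts)


class TestCondyleFrame:
    def test_lc_zero_points_at_inferior_point(self):
        frame = km.condyle_frame((0.0, 0.0), "LC", (0.0, -30.0))
        assert np.allclose(frame.zero_dir, (0.0, -1.0))
        assert frame.zero_angle == pytest.approx(0.0)

    def test_mc_offset_is_exactly_20_degrees(self):
        lc = km.condyle_frame((0.0, 0.0), "LC", (0.0, -30.0))
        mc = km.condyle_frame((0.0, 0.0), "MC", (0.0, -30.0))
        angle = np.rad2deg(
            np.arccos(np.clip(np.dot(lc.zero_dir, mc.zero_dir), -1, 1))
        )
        assert angle == pytest.approx(MEDIAL_ZERO_OFFSET_DEG)
        assert mc.zero_dir[0] > 0  # rotated toward anterior (+y)

    def test_equivariance_under_rotation(self):
        a = np.deg2rad(25)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        inferior = np.array([3.0, -29.0])
        f1 = km.condyle_frame((0.0, 0.0), "LC", inferior)
        f2 = km.condyle_frame((0.0, 0.0), "LC", rot @ inferior)
        assert np.allclose(rot @ f1.zero_dir, f2.zero_dir, atol=1e-12)


class TestRadialThickness:
    def test_uniform_annulus_reads_3mm_everywhere(self):
        center = (40.0, 40.0)
        cart, _, spacing, origin = annulus_slice(center, 30.0, 33.0)
        frame = km.condyle_frame(center, "LC", (center[0], center[1] - 30.0))
        for angle in (-15.0, 15.0, 45.0, 80.0, -60.0):
            t = km.radial_thickness(frame, cart, spacing, origin, angle)
            assert t == pytest.approx(3.0, abs=0.15)

    def test_sinusoidal_shell_profile(self):
        spacing = 0.2
        center = (40.0, 40.0)
        n = 400
        coords = np.arange(n) * spacing
        Y, Z = np.meshgrid(coords, coords, indexing="ij", sparse=True)
        r = np.hypot(Y - center[0], Z - center[1])
        theta = np.arctan2(-(Y - center[0]), -(Z - center[1]))
        cart = (r >= 30.0) & (r < 30.0 + 2.0 + np.sin(theta))
        frame = km.condyle_frame(center, "LC", (center[0], center[1] - 30.0))
        t90 = km.radial_thickness(frame, cart, np.full(2, spacing), np.zeros(2), 90.0)
        assert t90 == pytest.approx(3.0, abs=spacing / 2 + 1e-6)

    def test_angle_outside_arc_errors(self):
        center = (40.0, 40.0)
        n = 400
        coords = np.arange(n) * 0.2
        Y, Z = np.meshgrid(coords, coords, indexing="ij", sparse=True)
        r = np.hypot(Y - center[0], Z - center[1])
        theta = np.rad2deg(np.arctan2(-(Y - center[0]), -(Z - center[1])))
        cart = (r >= 30.0) & (r < 33.0) & (theta > -60) & (theta < 75)
        frame = km.condyle_frame(center, "LC", (center[0], center[1] - 30.0))
        with pytest.raises(ValueError, match="no cartilage"):
            km.radial_thickness(frame, cart, np.full(2, 0.2), np.zeros(2), 170.0)


class TestFemoralAct:
    def test_uniform_shell_averages_to_thickness(self):
        center = (40.0, 40.0)
        cart, bone, spacing, origin = annulus_slice(center, 30.0, 33.0)
        meas, avg = km.femoral_act(cart, bone, spacing, origin, "LC")
        assert len(meas) == 3
        assert {m.point for m in meas} == set(REGION_CENTERS)
        assert avg == pytest.approx(3.0, abs=0.15)
        assert avg == pytest.approx(np.mean([m.thickness_mm for m in meas]))

    def test_empty_cartilage_errors(self):
        cart = np.zeros((10, 10), bool)
        bone = np.ones((10, 10), bool)
        with pytest.raises(ValueError, match="absent"):
            km.femoral_act(cart, bone, np.ones(2), np.zeros(2), "LC")


class TestTibialAct:
    def _slab(self, thickness_fn, spacing=0.2, y0=10.0, y1=50.0):
        n = 300
        coords = np.arange(n) * spacing
        Y, Z = np.meshgrid(coords, coords, indexing="ij", sparse=True)
        t = thickness_fn(Y)
        cart = (Y >= y0) & (Y <= y1) & (Z >= 20.0) & (Z < 20.0 + t)
        return cart, np.full(2, spacing), np.zeros(2)

    def test_uniform_slab(self):
        cart, spacing, origin = self._slab(lambda y: 2.4)
        meas, avg = km.tibial_act(cart, spacing, origin, "MC")
        assert [m.thickness_mm for m in meas] == pytest.approx([2.4] * 3, abs=0.15)
        assert avg == pytest.approx(2.4, abs=0.15)

    def test_linear_taper_reads_sixth_points(self):
        # 2 mm at the posterior end rising to 4 mm at the anterior end
        cart, spacing, origin = self._slab(lambda y: 2.0 + 2.0 * (y - 10.0) / 40.0)
        meas, _ = km.tibial_act(cart, spacing, origin, "LC")
        by_point = {m.point: m.thickness_mm for m in meas}
        assert by_point["posterior"] == pytest.approx(2.0 + 2.0 / 6.0, abs=0.15)
        assert by_point["middle"] == pytest.approx(3.0, abs=0.15)
        assert by_point["anterior"] == pytest.approx(2.0 + 10.0 / 6.0, abs=0.15)

    def test_too_short_cartilage_errors(self):
        cart = np.zeros((10, 10), bool)
        cart[4, 2:5] = True  # single AP column
        with pytest.raises(ValueError, match="3 voxels"):
            km.tibial_act(cart, np.ones(2), np.zeros(2), "MC")


class TestFpcSliceSelection:
    def _stack(self, tro_profile, pat_profile, spacing=0.5):
        nz = len(tro_profile)
        tro = np.zeros((40, 40, nz), bool)
        pat = np.zeros((40, 40, nz), bool)
        for k, (t_t, t_p) in enumerate(zip(tro_profile, pat_profile)):
            tro[5:35, 10 : 10 + int(round(t_t / spacing)), k] = True
            pat[5:35, 25 : 25 + int(round(t_p / spacing)), k] = True
        return tro, pat, np.full(3, spacing)

    def test_known_thickest_slice(self):
        tro, pat, spacing = self._stack([1, 2, 3, 2, 1], [1, 1, 3, 1, 1])
        assert select_fpc_slice(tro, pat, spacing) == 2

    def test_single_slice_cartilage(self):
        tro, pat, spacing = self._stack([0, 2, 0], [0, 2, 0])
        assert select_fpc_slice(tro, pat, spacing) == 1

    def test_tie_breaks_to_lowest_index(self):
        tro, pat, spacing = self._stack([1, 3, 3, 1], [1, 2, 2, 1])
        assert select_fpc_slice(tro, pat, spacing) == 1

    def test_empty_mask_errors(self):
        tro, pat, spacing = self._stack([1], [1])
        with pytest.raises(ValueError, match="non-empty"):
            select_fpc_slice(np.zeros_like(tro), pat, spacing)


class TestFpcAct:
    def _axial(self, pat_t=(2.0, 2.0, 2.0), tro_t=(2.0, 3.0), spacing=0.2):
        n = 300
        coords = np.arange(n) * spacing
        X, Y = np.meshgrid(coords, coords, indexing="ij", sparse=True)
        x0, x1 = 10.0, 50.0
        mid = (x0 + x1) / 2
        # patella: three x-bands at the half/quarter points
        thirds = np.select(
            [X < x0 + (x1 - x0) / 3, X < x0 + 2 * (x1 - x0) / 3], [pat_t[0], pat_t[1]], pat_t[2]
        )
        pat = (X >= x0) & (X <= x1) & (Y >= 40.0) & (Y < 40.0 + thirds)
        halves = np.where(X < mid, tro_t[0], tro_t[1])
        tro = (X >= x0) & (X <= x1) & (Y >= 20.0) & (Y < 20.0 + halves)
        return pat, tro, np.full(2, spacing), np.zeros(2)

    def test_uniform_patella(self):
        pat, _, spacing, origin = self._axial()
        meas, avg = km.patellar_act(pat, spacing, origin)
        assert [m.point for m in meas] == ["medial", "center", "lateral"]
        assert avg == pytest.approx(2.0, abs=0.15)

    def test_asymmetric_trochlea_average(self):
        _, tro, spacing, origin = self._axial(tro_t=(2.0, 3.0))
        meas, avg = km.trochlear_act(tro, spacing, origin)
        by_point = {m.point: m.thickness_mm for m in meas}
        assert by_point["medial"] == pytest.approx(2.0, abs=0.15)
        assert by_point["lateral"] == pytest.approx(3.0, abs=0.15)
        assert avg == pytest.approx(2.5, abs=0.15)

    def test_asymmetric_patella_per_point(self):
        pat, _, spacing, origin = self._axial(pat_t=(1.6, 2.4, 3.2))
        meas, _ = km.patellar_act(pat, spacing, origin)
        by_point = {m.point: m.thickness_mm for m in meas}
        assert by_point["medial"] == pytest.approx(1.6, abs=0.15)
        assert by_point["center"] == pytest.approx(2.4, abs=0.15)
        assert by_point["lateral"] == pytest.approx(3.2, abs=0.15)

    def test_absent_cartilage_errors(self):
        with pytest.raises(ValueError, match="absent"):
            km.patellar_act(np.zeros((5, 5), bool), np.ones(2), np.zeros(2))


class TestPhantomProtocol:
    def test_all_sites_within_half_voxel(self, default_phantom):
        masks = {n: m.selection for n, m in default_phantom.truth_masks_mri.items()}
        measured = km.measure_all_sites(
            masks, default_phantom.mri.spacing, default_phantom.mri.origin
        )
        assert set(measured) == set(default_phantom.truth_thickness)
        for site, truth in default_phantom.truth_thickness.items():
            assert measured[site] == pytest.approx(truth, abs=0.3), site

    def test_error_shrinks_at_finer_spacing(self, default_phantom):
        fine = km.generate_phantom(km.PhantomConfig(voxel_spacing=(0.3, 0.3, 0.3)))

        def max_err(ph):
            measured = km.measure_all_sites(
                {n: m.selection for n, m in ph.truth_masks_mri.items()},
                ph.mri.spacing, ph.mri.origin,
            )
            return max(abs(measured[k] - ph.truth_thickness[k]) for k in measured)

        assert max_err(fine) < max_err(default_phantom)

    def test_invariant_under_in_plane_translation(self):
        base = km.PhantomConfig(misalignment=(0, 0, 0, 0, 0, 0))
        shifted = km.PhantomConfig(misalignment=(0, 0, 0, 1.7, -2.3, 0.9))
        m0 = km.generate_phantom(base)
        m1 = km.generate_phantom(shifted)
        t0 = km.measure_all_sites(
            {n: m.selection for n, m in m0.truth_masks_mri.items()},
            m0.mri.spacing, m0.mri.origin,
        )
        t1 = km.measure_all_sites(
            {n: m.selection for n, m in m1.truth_masks_mri.items()},
            m1.mri.spacing, m1.mri.origin,
        )
        for site in t0:
            assert abs(t0[site] - t1[site]) <= 0.6, site
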