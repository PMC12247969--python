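"""Line scans, averaging, and dual-Gaussian thickness fitting."""

import numpy as np
import pytest

import memthick as mt
from memthick.profiling import (LineScan, _dual_gaussian, scan_offsets,
                                fit_dual_gaussian)


def model_scan(mu1=-1.8, mu2=1.8, sigma=0.8, amp=1.0, baseline=0.0,
               lo=-10, hi=10, step=0.25):
    x = scan_offsets(lo, hi, step)
    y = _dual_gaussian(x, mu1, mu2, sigma, sigma, amp, amp, baseline)
    return LineScan(offsets=x, values=y, valid=np.ones_like(x, dtype=bool))


class TestScanNormal:
    def test_default_grid_has_81_samples(self):
        x = scan_offsets(-10, 10, 0.25)
        assert len(x) == 81 and x[0] == -10 and x[-1] == 10

    def test_constant_field(self):
        vol = mt.DensityVolume(np.full((30, 30, 30), 3.0), voxel_size=1.0)
        s = mt.scan_normal(vol, [15, 15, 15], [1, 0, 0])
        assert np.allclose(s.values[s.valid], 3.0)

    def test_linear_ramp_exact(self):
        nz = ny = nx = 30
        x = np.arange(nx, dtype=float)
        vol = mt.DensityVolume(np.broadcast_to(2.5 * x, (nz, ny, nx)).copy(),
                               voxel_size=1.0)
        s = mt.scan_normal(vol, [15.0, 10.0, 10.0], [1, 0, 0], -5, 5, 0.25)
        assert np.allclose(s.values, 2.5 * (15.0 + s.offsets))

    def test_bilayer_peaks_at_half_separation(self):
        """Axis-aligned bilayer in the plane x = center: maxima at ±t/2.

        The raw argmax can only land on a trilinear knot (a voxel center),
        so it locates each head-group peak to within one voxel; sub-voxel
        precision is the fit's job, not the scan's.
        """
        res = mt.rasterize_bilayer(mt.PhantomSpec(
            geometry="plane", phg_separation=3.6, normal=(1.0, 0.0, 0.0)))
        c = res.volume.center()
        s = mt.scan_normal(res.volume, c, [1, 0, 0])
        vx = res.volume.voxel_size
        pos = s.values[s.offsets > 0]
        neg = s.values[s.offsets < 0]
        assert abs(s.offsets[s.offsets > 0][np.argmax(pos)] - 1.8) <= vx
        assert abs(s.offsets[s.offsets < 0][np.argmax(neg)] + 1.8) <= vx

    def test_truncation_marked_invalid(self):
        vol = mt.DensityVolume(np.ones((20, 20, 20)), voxel_size=1.0)
        s = mt.scan_normal(vol, [2.0, 10.0, 10.0], [1, 0, 0])  # runs off -x
        assert not s.valid.all() and s.valid.any()

    def test_fully_outside_raises(self):
        vol = mt.DensityVolume(np.ones((20, 20, 20)), voxel_size=1.0)
        with pytest.raises(ValueError, match="outside"):
            mt.scan_normal(vol, [500.0, 500.0, 500.0], [1, 0, 0])

    def test_non_unit_normal_rejected(self):
        vol = mt.DensityVolume(np.ones((20, 20, 20)), voxel_size=1.0)
        with pytest.raises(ValueError, match="unit"):
            mt.scan_normal(vol, [10, 10, 10], [2, 0, 0])


class TestAverageScans:
    def test_single_scan_identity(self):
        s = model_scan()
        out = mt.average_scans([s], [1.0])
        assert np.allclose(out.values, s.values)

    def test_cancellation(self):
        s = model_scan()
        neg = LineScan(s.offsets, -s.values, s.valid)
        out = mt.average_scans([s, neg], [1.0, 1.0])
        assert np.allclose(out.values, 0.0)

    def test_weighted_mean_value(self):
        x = scan_offsets(-1, 1, 0.1)
        a = LineScan(x, np.full_like(x, 3.0), np.ones_like(x, bool))
        b = LineScan(x, np.zeros_like(x), np.ones_like(x, bool))
        out = mt.average_scans([a, b], [2.0, 1.0])
        assert np.allclose(out.values, 2.0)  # (2*3 + 1*0) / 3

    def test_weights_renormalized_over_valid(self):
        x = scan_offsets(-1, 1, 0.5)
        va = np.ones_like(x, bool)
        vb = va.copy()
        vb[0] = False
        a = LineScan(x, np.full_like(x, 4.0), va)
        b = LineScan(x, np.zeros_like(x), vb)
        out = mt.average_scans([a, b], [1.0, 1.0])
        assert out.values[0] == pytest.approx(4.0)  # only a valid there
        assert out.values[1] == pytest.approx(2.0)
        assert out.valid.all()

    def test_mismatched_grids_rejected(self):
        a = model_scan(step=0.25)
        b = model_scan(step=0.5)
        with pytest.raises(ValueError, match="mismatch"):
            mt.average_scans([a, b], [1, 1])


class TestNeighborhoodWeight:
    @pytest.mark.parametrize("d,expected", [(0.0, 1.0), (1.0, 0.5),
                                            (11.0, 1 / 12)])
    def test_inverse_one_plus_distance(self, d, expected):
        assert mt.neighborhood_weight(d) == pytest.approx(expected)

    def test_strictly_decreasing(self):
        d = np.linspace(0, 20, 50)
        w = mt.neighborhood_weight(d)
        assert (np.diff(w) < 0).all()

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            mt.neighborhood_weight(-0.1)


class TestLocalAveragedScan:
    def test_radius_zero_equals_single_scan(self, plane_phantom, plane_graph):
        mesh, vol = plane_phantom.mesh, plane_phantom.volume
        f = int(np.argmin(np.linalg.norm(mesh.face_centers - vol.center(), axis=1)))
        single = mt.scan_normal(vol, mesh.face_centers[f], mesh.face_normals[f])
        avg = mt.local_averaged_scan(vol, mesh, plane_graph, f, radius=0.0)
        assert np.allclose(avg.values[avg.valid], single.values[single.valid])

    def test_noiseless_plane_averaging_is_noop(self):
        """Identical normals and an x-only density field: every neighbor scan
        equals the central one, so averaging changes nothing."""
        res = mt.rasterize_bilayer(mt.PhantomSpec(
            geometry="plane", phg_separation=3.6, normal=(1.0, 0.0, 0.0)))
        mesh, vol = res.mesh, res.volume
        graph = mt.build_face_graph(mesh)
        f = int(np.argmin(np.linalg.norm(mesh.face_centers - vol.center(), axis=1)))
        single = mt.scan_normal(vol, mesh.face_centers[f], mesh.face_normals[f])
        avg = mt.local_averaged_scan(vol, mesh, graph, f, radius=12.0)
        ok = avg.valid & single.valid
        assert np.allclose(avg.values[ok], single.values[ok], atol=1e-9)

    def test_averaging_reduces_noise_variance(self, noisy_plane_phantom):
        mesh, vol = noisy_plane_phantom.mesh, noisy_plane_phantom.volume
        graph = mt.build_face_graph(mesh)
        excl = mt.edge_exclusion_mask(mesh, graph, 8.0)
        faces = np.flatnonzero(~excl)[:100]
        resid_single, resid_avg = [], []
        for f in faces:
            s = mt.scan_normal(vol, mesh.face_centers[f], mesh.face_normals[f])
            a = mt.local_averaged_scan(vol, mesh, graph, f, radius=12.0)
            resid_single.append(s.values[s.valid])
            resid_avg.append(a.values[a.valid])
        var_single = np.var(np.stack(resid_single), axis=0).mean()
        var_avg = np.var(np.stack(resid_avg), axis=0).mean()
        assert var_avg < var_single


class TestDualGaussianFit:
    def test_recovers_own_model(self):
        fit = fit_dual_gaussian(model_scan())
        assert fit.converged
        assert fit.mu1 == pytest.approx(-1.8, abs=1e-3)
        assert fit.mu2 == pytest.approx(1.8, abs=1e-3)
        assert fit.thickness == pytest.approx(3.6, abs=1e-3)

    def test_noisy_monte_carlo_within_tolerance(self):
        """95% of noisy fits land within 0.1 nm of the true 3.6 nm."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            s = model_scan()
            noisy = LineScan(s.offsets, s.values + rng.normal(0, 0.05, s.values.shape),
                             s.valid)
            fit = fit_dual_gaussian(noisy)
            if fit.converged and abs(fit.thickness - 3.6) < 0.1:
                hits += 1
        assert hits >= 95

    def test_single_gaussian_not_converged(self):
        x = scan_offsets(-10, 10, 0.25)
        y = np.exp(-0.5 * (x / 0.8) ** 2)
        fit = fit_dual_gaussian(LineScan(x, y, np.ones_like(x, bool)))
        assert not fit.converged

    def test_too_few_valid_samples(self):
        x = scan_offsets(-10, 10, 0.25)
        valid = np.zeros_like(x, bool)
        valid[:10] = True
        fit = fit_dual_gaussian(LineScan(x, np.ones_like(x), valid))
        assert not fit.converged and "valid samples" in fit.message

    def test_invariant_under_baseline_and_scale(self):
        base = fit_dual_gaussian(model_scan()).thickness
        s = model_scan()
        shifted = LineScan(s.offsets, 7.0 + 3.0 * s.values, s.valid)
        assert fit_dual_gaussian(shifted).thickness == pytest.approx(base, abs=1e-6)


class TestThicknessMeasurement:
    def test_global_thickness_volume_affine_invariance(self, plane_phantom,
                                                       plane_graph):
        vol, mesh = plane_phantom.volume, plane_phantom.mesh
        t0, _ = mt.measure_global_thickness(vol, mesh, plane_graph)
        vol2 = mt.DensityVolume(5.0 + 2.0 * vol.grid, vol.voxel_size,
                                vol.origin)
        t1, _ = mt.measure_global_thickness(vol2, mesh, plane_graph)
        assert t1 == pytest.approx(t0, abs=1e-6)

    def test_global_thickness_normal_flip_invariance(self, plane_phantom,
                                                     plane_graph):
        vol, mesh = plane_phantom.volume, plane_phantom.mesh
        t0, _ = mt.measure_global_thickness(vol, mesh, plane_graph)
        flipped = mesh.flipped()
        t1, _ = mt.measure_global_thickness(vol, flipped,
                                            mt.build_face_graph(flipped))
        assert t1 == pytest.approx(t0, abs=1e-6)

    def test_all_faces_masked_raises(self, plane_phantom, plane_graph):
        with pytest.raises(ValueError, match="no faces"):
            mt.measure_global_thickness(
                plane_phantom.volume, plane_phantom.mesh, plane_graph,
                mask=np.ones(plane_phantom.mesh.n_faces, bool))

    def test_local_noiseless_plane_uniform(self, plane_phantom, plane_graph):
        mesh, vol = plane_phantom.mesh, plane_phantom.volume
        excl = mt.edge_exclusion_mask(mesh, plane_graph, 8.0)
        tmap = mt.measure_local_thickness(vol, mesh, plane_graph, mask=excl)
        got = tmap.thickness[~excl]
        assert np.isfinite(got).all()
        assert np.abs(got - 3.6).max() < 0.05

    def test_two_slab_halves_differ_by_truth(self):
        """Per-half thickness medians reproduce the 0.6 nm built-in step,
        with the transition confined to the 12 nm kernel width."""
        spec = mt.PhantomSpec(geometry="two_slab", phg_separation=3.2,
                              phg_separation_2=3.8, normal=(1.0, 0.0, 0.0),
                              volume_shape=(64, 64, 40), mesh_step=2.5)
        res = mt.rasterize_bilayer(spec)
        mesh = res.mesh
        graph = mt.build_face_graph(mesh)
        excl = mt.edge_exclusion_mask(mesh, graph, 8.0)
        tmap = mt.measure_local_thickness(res.volume, mesh, graph, mask=excl)
        truth = res.truth["true_thickness_nm"].to_numpy()
        # the slab switches thickness at the in-plane u = 0 line (u = z here);
        # faces farther than the 12 nm kernel radius from the seam are pure
        u = mesh.face_centers[:, 2] - res.volume.center()[2]
        pure = np.abs(u) > 12.0
        thin = np.isclose(truth, 3.2) & ~excl & pure
        thick = np.isclose(truth, 3.8) & ~excl & pure
        assert thin.any() and thick.any()
        med_thin = np.nanmedian(tmap.thickness[thin])
        med_thick = np.nanmedian(tmap.thickness[thick])
        assert med_thick - med_thin == pytest.approx(0.6, abs=0.1)
        # inside the kernel width the measurement blends the two truths
        seam = (np.abs(u) <= 12.0) & ~excl
        blended = tmap.thickness[seam]
        assert np.nanmin(blended) > 3.1 and np.nanmax(blended) < 3.9

    def test_sub_step_precision(self, plane_phantom, plane_graph):
        """Gaussian fitting resolves far below the 0.25 nm sampling step."""
        excl = mt.edge_exclusion_mask(plane_phantom.mesh, plane_graph, 8.0)
        t, _ = mt.measure_global_thickness(plane_phantom.volume,
                                           plane_phantom.mesh, plane_graph,
                                           mask=excl)
        assert abs(t - 3.6) < 0.025  # an order below the step
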