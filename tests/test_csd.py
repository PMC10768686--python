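"""Constrained spherical deconvolution: response, convolution, recovery."""

import numpy as np
import pytest

from deepcsd import csd, sh, simulate
from deepcsd.errors import InvalidArgumentError
from deepcsd.simulate import DWIVolume
from deepcsd.sphere import angle_between, symmetric_sphere

Z = np.array([0.0, 0.0, 1.0])
X = np.array([1.0, 0.0, 0.0])
Y = np.array([0.0, 1.0, 0.0])


def _acc(u, v):
    u, v = u[1:], v[1:]
    return u @ v / (np.linalg.norm(u) * np.linalg.norm(v))


class TestEstimateResponse:
    def test_reconvolution_matches_single_fiber_signal(self, scheme96, response96):
        cfg = simulate.FiberConfig(Z[None], np.array([0.75]))
        truth = simulate.simulate_signal(cfg, scheme96)[1:]
        delta = sh.design_matrix(Z[None], 8)[0]  # band-limited delta at z
        signal_sh = csd.forward_convolve(delta, response96)
        recon = sh.sh_to_amplitudes(signal_sh, scheme96.directions)
        assert np.max(np.abs(recon - truth)) / truth.max() < 0.01

    def test_isotropic_voxels_give_zonal_zero_above_order0(self, scheme96):
        shape = (4, 4, 4)
        cfg = simulate.FiberConfig(np.zeros((0, 3)), np.zeros(0))
        sig = simulate.simulate_signal(cfg, scheme96)
        data = np.broadcast_to(sig, shape + (sig.size,)).copy()
        vol = DWIVolume(data, scheme96, s0=1.0)
        resp = csd.estimate_response(vol, np.ones(shape, dtype=bool))
        np.testing.assert_allclose(resp.zonal[1:], 0.0, atol=1e-6)

    def test_duplicated_voxels_do_not_change_response(self, noiseless_volume, phantom16):
        m = phantom16.single_fiber_mask
        r1 = csd.estimate_response(noiseless_volume, m)
        # duplicate the sample set by stacking the volume along x
        data2 = np.concatenate([noiseless_volume.data, noiseless_volume.data], axis=0)
        m2 = np.concatenate([m, m], axis=0)
        vol2 = DWIVolume(data2, noiseless_volume.scheme, s0=1.0)
        r2 = csd.estimate_response(vol2, m2)
        np.testing.assert_allclose(r1.zonal, r2.zonal, atol=1e-12)

    def test_empty_mask_rejected(self, noiseless_volume, phantom16):
        with pytest.raises(InvalidArgumentError):
            csd.estimate_response(noiseless_volume, np.zeros(phantom16.shape, dtype=bool))


class TestForwardConvolve:
    def test_identity_kernel_preserves_fodf(self, rng):
        k = sh.orders(8)
        identity = csd.ResponseFunction(np.sqrt((2 * np.arange(0, 9, 2) + 1) / (4 * np.pi)))
        f = rng.standard_normal(45)
        np.testing.assert_allclose(csd.forward_convolve(f, identity), f, atol=1e-12)

    def test_zero_fodf_maps_to_zero(self, response96):
        assert np.all(csd.forward_convolve(np.zeros(45), response96) == 0.0)

    def test_matches_dense_quadrature_convolution(self, rng, response96):
        """Spherical convolution theorem vs direct numerical convolution:
        S(g) = int fODF(u) R(g.u) dOmega on a Gauss-Legendre product grid,
        which is exact for the band-limited integrand."""
        f = rng.standard_normal(45)
        out = csd.forward_convolve(f, response96)
        nodes, gl_w = np.polynomial.legendre.leggauss(24)
        n_phi = 48
        phis = np.arange(n_phi) * 2 * np.pi / n_phi
        ct, ph_ = np.meshgrid(nodes, phis, indexing="ij")
        st = np.sqrt(1 - ct**2)
        grid = np.stack([st * np.cos(ph_), st * np.sin(ph_), ct], axis=-1).reshape(-1, 3)
        w = np.repeat(gl_w, n_phi) * (2 * np.pi / n_phi)
        fvals = sh.sh_to_amplitudes(f, grid)
        probe = symmetric_sphere(724)
        dots = np.clip(probe @ grid.T, -1, 1)
        # R(g.u): zonal profile evaluated via its Legendre series
        zon = response96.zonal
        legs = np.stack([np.polynomial.legendre.Legendre.basis(k)(dots) for k in range(0, 9, 2)])
        nk = np.sqrt((2 * np.arange(0, 9, 2) + 1) / (4 * np.pi))
        R = np.einsum("k,kpg->pg", zon * nk, legs)
        S = np.einsum("pg,g,g->p", R, fvals, w)
        S_theorem = sh.sh_to_amplitudes(out, probe)
        assert np.max(np.abs(S - S_theorem)) < 1e-3

    def test_order_mismatch_rejected(self, response96):
        with pytest.raises(InvalidArgumentError):
            csd.forward_convolve(np.zeros(sh.n_coeffs(10)), response96)


class TestCsdFit:
    def test_single_fiber_peak_within_2_degrees(self, scheme96, response96):
        cfg = simulate.FiberConfig(Z[None], np.array([0.75]))
        s = simulate.simulate_signal(cfg, scheme96)[1:]
        f = csd.csd_fit(s, scheme96, response96)
        peaks = csd.peak_directions(f)
        assert peaks.shape[0] == 1
        assert angle_between(peaks[0], Z) <= 2.0

    def test_isotropic_voxel_energy_in_zeroth_term(self, scheme96, response96):
        cfg = simulate.FiberConfig(np.zeros((0, 3)), np.zeros(0))
        s = simulate.simulate_signal(cfg, scheme96)[1:]
        f = csd.csd_fit(s, scheme96, response96)
        assert f[0] ** 2 / np.sum(f**2) >= 0.99

    def test_crossing_fibers_recovered(self, scheme96, response96):
        cfg = simulate.FiberConfig(np.stack([X, Y]), np.array([0.4, 0.4]))
        s = simulate.simulate_signal(cfg, scheme96)[1:]
        f = csd.csd_fit(s, scheme96, response96)
        peaks = csd.peak_directions(f)
        assert peaks.shape[0] == 2
        errs = angle_between(peaks, np.stack([X, Y])).min(axis=1)
        assert np.all(errs <= 5.0)
        amps = sh.sh_to_amplitudes(f, peaks)
        ratio = amps.max() / amps.min()
        assert 0.8 <= ratio <= 1.25

    def test_deconvolution_inverts_convolution_for_nonneg_fodf(self, scheme96, response96):
        """Band-limited strictly positive fODF -> signal -> CSD recovers it.

        When every amplitude clears the hard-threshold level the constraint
        never fires and the deconvolution inverts the convolution exactly.
        (An fODF with a near-zero floor is deliberately regularized toward
        zero in that region, so exact recovery is only promised here.)
        """
        cfg = simulate.FiberConfig(Z[None], np.array([0.3]))
        f_true = simulate.ground_truth_fodf(cfg, sharpness=20.0)
        amps = sh.sh_to_amplitudes(f_true, symmetric_sphere(724))
        assert amps.min() > 0.1 * amps.mean()  # strictly above the threshold
        s = sh.sh_to_amplitudes(csd.forward_convolve(f_true, response96), scheme96.directions)
        f_rec = csd.csd_fit(s, scheme96, response96)
        assert _acc(f_rec, f_true) >= 0.99

    def test_nonnegativity_on_constraint_sphere(self, scheme96, response96, phantom16,
                                                noiseless_volume):
        grid = symmetric_sphere(724)
        norm = noiseless_volume.normalized_dwi()
        for i, j, k in np.argwhere(phantom16.wm_mask)[::101]:
            f = csd.csd_fit(norm[i, j, k], scheme96, response96)
            amps = sh.sh_to_amplitudes(f, grid)
            assert amps.min() >= -0.01 * amps.max()


class TestFitVolume:
    def test_empty_mask_gives_zero_field(self, noiseless_volume, response96, phantom16):
        field = csd.fit_csd_volume(noiseless_volume, np.zeros(phantom16.shape, bool), response96)
        assert np.all(field.data == 0.0)

    def test_deterministic(self, noiseless_volume, response96, phantom16):
        m = phantom16.wm_mask.copy()
        m[:, :, :7] = False  # subset for speed
        a = csd.fit_csd_volume(noiseless_volume, m, response96)
        b = csd.fit_csd_volume(noiseless_volume, m, response96)
        np.testing.assert_array_equal(a.data, b.data)

    def test_noiseless_phantom_recovery(self, noiseless_volume, response96, phantom16):
        """Sanity floor for noiseless recovery.  The hard-threshold
        constraint smooths the deconvolved lobes relative to the sharp
        Watson ground truth, which bounds ACC below ~0.87 here."""
        field = csd.fit_csd_volume(noiseless_volume, phantom16.wm_mask, response96)
        gt = phantom16.gt_fodf.data[phantom16.wm_mask]
        est = field.data[phantom16.wm_mask]
        accs = np.einsum("ij,ij->i", gt[:, 1:], est[:, 1:]) / (
            np.linalg.norm(gt[:, 1:], axis=1) * np.linalg.norm(est[:, 1:], axis=1))
        assert accs.mean() >= 0.8
        # peak geometry is nearly exact even though lobe shape differs
        i, j, k = np.argwhere(phantom16.single_fiber_mask)[40]
        peaks = csd.peak_directions(field.data[i, j, k])
        true_dir = phantom16.fiber_dirs[i, j, k, 0]
        assert angle_between(peaks[0], true_dir) <= 2.0


class TestPeakDirections:
    def test_single_lobe_matches_dense_argmax(self, rng):
        cfg = simulate.FiberConfig(np.array([[0.6, 0.0, 0.8]]), np.array([0.8]))
        c = simulate.ground_truth_fodf(cfg)
        peaks = csd.peak_directions(c)
        dense = symmetric_sphere(20000)
        brute = dense[np.argmax(sh.sh_to_amplitudes(c, dense))]
        assert peaks.shape[0] == 1
        assert angle_between(peaks[0], brute) <= 1.0

    def test_two_orthogonal_lobes_give_two_peaks(self):
        cfg = simulate.FiberConfig(np.stack([X, Y]), np.array([0.4, 0.4]))
        peaks = csd.peak_directions(simulate.ground_truth_fodf(cfg))
        assert peaks.shape[0] == 2

    def test_isotropic_gives_no_peaks(self):
        c = np.zeros(45)
        c[0] = 1.0
        assert csd.peak_directions(c).shape[0] == 0
        assert csd.peak_directions(np.zeros(45)).shape[0] == 0


def test_direction_count_degrades_csd_quality(phantom16, scheme96, noiseless_volume,
                                              response96):
    """Fewer directions -> worse agreement with the full-direction fit."""
    full = csd.fit_csd_volume(noiseless_volume, phantom16.wm_mask, response96)
    scan, _ = simulate.make_scan_rescan(phantom16, scheme96, seed=77)
    m = phantom16.wm_mask.copy()
    m[:, :, :7] = False
    noisy_resp = csd.estimate_response(scan, phantom16.single_fiber_mask)
    means = []
    rng = np.random.default_rng(5)
    for n_keep in (96, 75, 60, 45):
        keep = np.sort(rng.choice(96, n_keep, replace=False))
        sub = DWIVolume(scan.data[..., np.concatenate([[0], keep + 1])],
                        scheme96.subset(keep), s0=1.0)
        field = csd.fit_csd_volume(sub, m, noisy_resp)
        gt = full.data[m]
        est = field.data[m]
        accs = np.einsum("ij,ij->i", gt[:, 1:], est[:, 1:]) / (
            np.linalg.norm(gt[:, 1:], axis=1) * np.linalg.norm(est[:, 1:], axis=1))
        means.append(accs.mean())
    assert means[0] > means[-1]
    assert all(means[i] >= means[i + 1] - 0.01 for i in range(3))
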