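"""Phantom construction, volume bookkeeping, and signal simulation."""

import numpy as np
import pytest

from tractgr.connectome import assign_edges
from tractgr.geometry import AcquisitionScheme, KernelParams
from tractgr.maps import MTsatInputs, compute_mtsat
from tractgr.phantom import (
    BundleSpec,
    PhantomOverfillError,
    PhantomSpec,
    build_phantom,
    calibration_phantom,
    default_scheme,
    orthogonal_crossing_spec,
    simulate_dwi,
    simulate_mtw,
    single_bundle_spec,
    two_bundle_spec,
)


def _one_streamline_spec(csa=0.1, g=0.7, grid=8, jitter=0.0):
    line = np.array([[1.0, 3.5, 3.5], [grid - 2.0, 3.5, 3.5]])
    return PhantomSpec(
        grid_shape=(grid, grid, grid),
        bundles=[BundleSpec.from_g(0, line, 1, csa, g)],
        n_spurious=0,
        jitter_sd=jitter,
        seed=0,
    )


class TestBundleSpec:
    def test_g_consistent_with_areas(self):
        b = BundleSpec.from_g(0, [[0, 0, 0], [1, 0, 0]], 1, 0.004, 0.6)
        assert b.g_true**2 == pytest.approx(
            b.axon_csa_true / (b.axon_csa_true + b.myelin_csa_true), abs=1e-12
        )

    def test_rejects_nonpositive_axon(self):
        with pytest.raises(ValueError):
            BundleSpec(0, [[0, 0, 0], [1, 0, 0]], 1, 0.0, 0.1)


class TestBuildPhantom:
    def test_axis_aligned_unit_traversal(self):
        # single straight streamline along +x, CSA 0.1 mm^2, 1 mm voxels:
        # fully-traversed voxels gain exactly 0.1 of axonal volume fraction
        _, truth, _, _ = build_phantom(_one_streamline_spec())
        interior = truth.avf[2:5, 4, 4]   # voxels crossed over their full 1 mm
        np.testing.assert_allclose(interior, 0.1, atol=1e-12)

    def test_crossing_voxel_mvf_is_sum_of_bundles(self):
        # direct bookkeeping oracle: deposit each bundle's myelin volume by
        # hand and compare in the voxel where both centerlines cross
        grid = 8
        line_x = np.array([[1.0, 3.5, 3.5], [6.0, 3.5, 3.5]])
        line_y = np.array([[3.5, 1.0, 3.5], [3.5, 6.0, 3.5]])
        b0 = BundleSpec.from_g(0, line_x, 1, 0.02, 0.6)
        b1 = BundleSpec.from_g(1, line_y, 1, 0.02, 0.8)
        spec = PhantomSpec(
            grid_shape=(grid, grid, grid), bundles=[b0, b1],
            n_spurious=0, jitter_sd=0.0, seed=0,
        )
        _, truth, _, _ = build_phantom(spec)
        expected = b0.myelin_csa_true * 1.0 + b1.myelin_csa_true * 1.0
        assert truth.mvf[4, 4, 4] == pytest.approx(expected, rel=1e-9)

    def test_total_axonal_volume_conserved(self):
        spec = two_bundle_spec()
        streamlines, truth, _, _ = build_phantom(spec)
        deposited = truth.avf.sum() * truth.voxel_volume
        expected = float((truth.axon_csa * streamlines.lengths()).sum())
        assert deposited == pytest.approx(expected, rel=1e-9)

    def test_voxel_volume_conservation(self):
        _, truth, _, _ = build_phantom(two_bundle_spec())
        # fractions: myelin + axonal + hindered + isotropic pools <= 1
        with np.errstate(divide="ignore", invalid="ignore"):
            eh = np.where(truth.icvf > 0, truth.avf * (1 / truth.icvf - 1), 0.0)
        total = (
            truth.mvf + truth.avf + eh
            + (truth.iso_volume + truth.gm_volume) / truth.voxel_volume
        )
        np.testing.assert_allclose(total, 1.0, atol=1e-9)
        assert truth.avf.min() >= 0 and truth.mvf.min() >= 0
        assert truth.icvf.max() <= 1 and truth.isovf.max() <= 1

    def test_gratio_model_identities_hold(self):
        _, truth, _, _ = build_phantom(two_bundle_spec())
        fiber = truth.avf > 0
        avf = (1 - truth.mvf) * (1 - truth.isovf) * truth.icvf
        np.testing.assert_allclose(avf[fiber], truth.avf[fiber], atol=1e-12)
        np.testing.assert_allclose(
            truth.g[fiber],
            np.sqrt(truth.avf[fiber] / (truth.avf[fiber] + truth.mvf[fiber])),
            atol=1e-12,
        )

    def test_bit_reproducible(self):
        s1, t1_, p1, r1 = build_phantom(two_bundle_spec(seed=7))
        s2, t2_, p2, r2 = build_phantom(two_bundle_spec(seed=7))
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(t1_.mvf, t2_.mvf)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(r1, r2)

    def test_endpoints_match_bundle_node_pairs(self):
        spec = orthogonal_crossing_spec(n_spurious=0)
        streamlines, truth, parc, _ = build_phantom(spec)
        pairs, assigned = assign_edges(streamlines, parc, truth.affine)
        assert assigned.all()
        for _, edge in truth.edges.iterrows():
            sel = truth.bundle_id == edge.bundle
            got = np.unique(pairs[sel], axis=0)
            assert got.shape == (1, 2)
            assert tuple(got[0]) == (edge.node_a, edge.node_b)

    def test_overfill_rejected_with_diagnostic(self):
        with pytest.raises(PhantomOverfillError, match="volume fraction"):
            build_phantom(_one_streamline_spec(csa=0.9, g=0.6))

    def test_calibration_roi_is_single_fiber_high_fa(self):
        _, truth, _, roi = build_phantom(two_bundle_spec())
        assert roi.sum() > 0
        assert (truth.bundle_count[roi] == 1).all()
        assert (truth.fa[roi] > 0.8).all()

    def test_spurious_streamlines_cross_bundle_orientations(self):
        spec = two_bundle_spec()
        streamlines, truth, _, _ = build_phantom(spec)
        bundle_dirs = []
        for b in spec.bundles:
            d = b.centerline[-1] - b.centerline[0]
            bundle_dirs.append(d / np.linalg.norm(d))
        for si in np.flatnonzero(truth.bundle_id == -1):
            line = np.asarray(streamlines[si])
            chord = line[-1] - line[0]
            chord = chord / np.linalg.norm(chord)
            for u in bundle_dirs:
                assert np.degrees(np.arccos(abs(chord @ u))) >= 30.0


class TestSimulateDwi:
    def test_b0_equals_nonmyelin_water_volume(self):
        spec = two_bundle_spec()
        streamlines, truth, _, _ = build_phantom(spec)
        scheme = AcquisitionScheme([0.0, 0.0], [[0, 0, 0], [0, 0, 0]])
        sig = simulate_dwi(truth, streamlines, scheme)
        np.testing.assert_allclose(
            sig[..., 0], (1 - truth.mvf) * truth.voxel_volume, atol=1e-12
        )
        np.testing.assert_array_equal(sig[..., 0], sig[..., 1])

    def test_parallel_stick_attenuation(self):
        # gradient along the fiber at b=1000, D_par=1.7e-3 -> e^-1.7
        spec = _one_streamline_spec(csa=0.1)
        spec.isovf_background = 0.0
        streamlines, truth, _, _ = build_phantom(spec)
        truth.iso_volume[:] = 0.0   # isolate the fiber compartments
        truth.gm_volume[:] = 0.0
        truth.extra_csa[:] = 0.0
        scheme = AcquisitionScheme([0, 1000.0], [[0, 0, 0], [1, 0, 0]])
        sig = simulate_dwi(truth, streamlines, scheme)
        v = (3, 4, 4)
        assert sig[v][1] / sig[v][0] == pytest.approx(np.exp(-1.7), rel=1e-9)

    def test_perpendicular_stick_unattenuated(self):
        spec = _one_streamline_spec(csa=0.1)
        streamlines, truth, _, _ = build_phantom(spec)
        truth.iso_volume[:] = 0.0
        truth.gm_volume[:] = 0.0
        truth.extra_csa[:] = 0.0
        scheme = AcquisitionScheme([0, 1000.0], [[0, 0, 0], [0, 0, 1]])
        sig = simulate_dwi(truth, streamlines, scheme)
        v = (3, 4, 4)
        assert sig[v][1] == pytest.approx(sig[v][0], rel=1e-12)

    def test_noiseless_simulation_reproducible(self):
        spec = single_bundle_spec(grid=8)
        streamlines, truth, _, _ = build_phantom(spec)
        scheme = default_scheme()
        s1 = simulate_dwi(truth, streamlines, scheme, seed=1)
        s2 = simulate_dwi(truth, streamlines, scheme, seed=2)
        np.testing.assert_array_equal(s1, s2)

    def test_rician_b0_bias_small_at_high_snr(self):
        # Monte-Carlo: at SNR > 20 the Rician mean bias on b=0 stays < 2%
        spec = single_bundle_spec(grid=8)
        streamlines, truth, _, _ = build_phantom(spec)
        n_b0 = 40
        scheme = AcquisitionScheme([0.0] * n_b0, [[0, 0, 0]] * n_b0)
        clean = simulate_dwi(truth, streamlines, scheme)
        sigma = clean[clean > 0].min() / 25.0
        noisy = simulate_dwi(
            truth, streamlines, scheme, noise_sigma=sigma, seed=123
        )
        sel = clean > 0   # > 10^4 voxel-measurement draws
        assert sel.sum() > 10_000
        bias = (noisy[sel] - clean[sel]).mean() / clean[sel].mean()
        assert abs(bias) < 0.02

    def test_gaussian_noise_unbiased(self):
        spec = single_bundle_spec(grid=8)
        streamlines, truth, _, _ = build_phantom(spec)
        scheme = AcquisitionScheme([0.0] * 40, [[0, 0, 0]] * 40)
        clean = simulate_dwi(truth, streamlines, scheme)
        noisy = simulate_dwi(
            truth, streamlines, scheme, noise_sigma=0.01, seed=5,
            noise_model="gaussian",
        )
        assert abs((noisy - clean).mean()) < 1e-3


class TestSimulateMtw:
    def test_zero_saturation_closed_form(self):
        s0, t1g, tr, a = 1000.0, 1000.0, 27.0, np.deg2rad(6.0)
        got = simulate_mtw(np.zeros((2, 2)), np.full((2, 2), s0),
                           np.full((2, 2), t1g), a, np.ones((2, 2)), tr)
        expected = s0 * a / (1 + a**2 * t1g / (2 * tr))
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_roundtrip_recovers_mtsat(self):
        rng = np.random.default_rng(0)
        mtsat = rng.uniform(0.001, 0.08, (4, 4, 4))
        s0 = rng.uniform(500, 1500, (4, 4, 4))
        t1g = rng.uniform(600, 2000, (4, 4, 4))
        b1 = rng.uniform(0.8, 1.2, (4, 4, 4))
        a = np.deg2rad(6.0)
        smtw = simulate_mtw(mtsat, s0, t1g, a, b1, 27.0)
        rec = compute_mtsat(MTsatInputs(smtw, s0, t1g, a, b1, 27.0))
        np.testing.assert_allclose(rec, mtsat, rtol=1e-10)

    def test_protocol_flip_angle_gives_finite_signal(self):
        # 6 degree excitation, TR 27 ms: positive finite signal across the
        # physiological MTsat range
        mtsat = np.linspace(0.0, 0.1, 11)
        sig = simulate_mtw(mtsat, np.full(11, 1000.0), np.full(11, 1000.0),
                           np.deg2rad(6.0), 1.0, 27.0)
        assert np.all(np.isfinite(sig)) and np.all(sig > 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_mtw([0.01], [0.0], [1000.0], 0.1, 1.0, 27.0)
        with pytest.raises(ValueError):
            simulate_mtw([0.01], [1000.0], [1000.0], 2.0, 1.0, 27.0)


class TestCalibrationPhantom:
    def test_uniform_maps_and_central_roi(self):
        maps, roi = calibration_phantom()
        assert roi.any() and not roi.all()
        assert np.unique(maps["mtsat"]).size == 1
        assert (maps["fa"][roi] > 0.8).all()
        assert (maps["fa"][~roi] < 0.8).all()
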