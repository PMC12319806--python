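"""NNLS solver correctness and the three streamline-weight solves."""

import warnings

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from tractgr.fit import (
    ZERO_WEIGHT_RTOL,
    fit_filtering,
    fit_myelin,
    fit_true_axonal,
    myelin_correct_signal,
    nnls,
)
from tractgr.geometry import AcquisitionScheme, KernelParams
from tractgr.phantom import (
    BundleSpec,
    PhantomSpec,
    build_phantom,
    default_scheme,
    simulate_dwi,
)

from conftest import enumerate_nnls


class TestNnls:
    def test_identity_system(self):
        x, conv = nnls(np.eye(3), np.array([1.0, 2.0, 3.0]))
        assert conv
        np.testing.assert_allclose(x, [1, 2, 3], atol=1e-10)

    def test_zero_data_gives_zero(self):
        x, conv = nnls(np.random.default_rng(0).standard_normal((5, 3)),
                       np.zeros(5))
        assert conv
        np.testing.assert_array_equal(x, 0.0)

    def test_noiseless_recovery_matches_grid_search(self):
        # brute-force oracle: exhaustive grid search at step 1e-3 over a
        # 2-column system with a known non-negative generator
        rng = np.random.default_rng(4)
        A = rng.standard_normal((6, 2))
        x_true = np.array([0.437, 1.212])
        y = A @ x_true
        grid = np.arange(0.0, 2.0, 1e-3)
        g0, g1 = np.meshgrid(grid, grid, indexing="ij")
        obj = ((A[:, 0][:, None, None] * g0 + A[:, 1][:, None, None] * g1
                - y[:, None, None]) ** 2).sum(axis=0)
        best = np.unravel_index(np.argmin(obj), obj.shape)
        x_grid = np.array([grid[best[0]], grid[best[1]]])
        x, _ = nnls(A, y)
        np.testing.assert_allclose(x, x_grid, atol=2e-3)
        np.testing.assert_allclose(x, x_true, atol=1e-8)

    def test_matches_enumeration_and_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            m = n + int(rng.integers(2, 8))
            A = rng.standard_normal((m, n))
            y = rng.standard_normal(m)
            x, conv = nnls(A, y)
            assert conv
            np.testing.assert_allclose(x, enumerate_nnls(A, y), atol=1e-8)
            np.testing.assert_allclose(x, scipy_nnls(A, y)[0], atol=1e-8)

    def test_active_constraints_respected(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        y = np.array([-1.0, -2.0])
        x, _ = nnls(A, y)
        np.testing.assert_array_equal(x, 0.0)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            nnls(np.eye(2), np.array([np.nan, 1.0]))


def _single_streamline_dataset(grid=8, csa=0.05, g=0.7):
    line = np.array([[1.0, 3.5, 3.5], [grid - 2.0, 3.5, 3.5]])
    spec = PhantomSpec(
        grid_shape=(grid, grid, grid),
        bundles=[BundleSpec.from_g(0, line, 1, csa, g)],
        n_spurious=0,
        jitter_sd=0.0,
        seed=0,
    )
    streamlines, truth, parc, roi = build_phantom(spec)
    scheme = default_scheme()
    dwi = simulate_dwi(truth, streamlines, scheme)
    mask = (truth.avf > 0) | (truth.mvf > 0)
    return spec, streamlines, truth, scheme, dwi, mask


class TestMyelinFit:
    def test_worked_single_voxel_case(self):
        # 1 mm chord through one voxel with MVF 0.2 -> myelin CSA 0.2 mm^2
        from tractgr.streamlines import StreamlineSet

        grid = (8, 8, 8)
        lines = StreamlineSet([np.array([[2.5, 3.0, 3.0], [3.5, 3.0, 3.0]])])
        mvf = np.zeros(grid)
        mvf[3, 3, 3] = 0.2
        mask = np.zeros(grid, dtype=bool)
        mask[3, 3, 3] = True
        w = fit_myelin(mvf, lines, mask, np.eye(4))
        assert w.kind == "myelin"
        assert w.csa[0] == pytest.approx(0.2, abs=1e-10)
        assert w.volume[0] == pytest.approx(0.2 * 1.0, abs=1e-10)

    def test_disjoint_streamlines_recovered_independently(self):
        from tractgr.streamlines import StreamlineSet

        grid = (8, 8, 8)
        lines = StreamlineSet(
            [
                np.array([[1.5, 2.0, 2.0], [4.5, 2.0, 2.0]]),
                np.array([[1.5, 5.0, 5.0], [4.5, 5.0, 5.0]]),
            ]
        )
        mvf = np.zeros(grid)
        mvf[2:5, 2, 2] = 0.10   # csa 0.10 deposited over 1 mm
        mvf[2:5, 5, 5] = 0.25
        mask = mvf > 0
        w = fit_myelin(mvf, lines, mask, np.eye(4))
        np.testing.assert_allclose(w.csa, [0.10, 0.25], atol=1e-9)

    def test_zero_mvf_gives_zero_csa(self):
        _, streamlines, truth, _, _, mask = _single_streamline_dataset()
        w = fit_myelin(np.zeros(truth.grid_shape), streamlines, mask, truth.affine)
        np.testing.assert_allclose(w.csa, 0.0, atol=1e-12)

    def test_phantom_bundle_recovery(self, corridor_result):
        res = corridor_result
        for _, row in res.comparison.iterrows():
            assert row.mv_fit == pytest.approx(row.mv_true, rel=0.01)


class TestMyelinCorrection:
    def test_zero_mvf_is_b0_normalization(self):
        _, streamlines, truth, scheme, dwi, mask = _single_streamline_dataset()
        corrected, _ = myelin_correct_signal(
            dwi, np.zeros(truth.grid_shape), scheme, mask
        )
        b0 = dwi[..., scheme.b0_mask].mean(axis=-1)
        np.testing.assert_allclose(
            corrected[mask], dwi[mask] / b0[mask][..., None], atol=1e-12
        )

    def test_half_mvf_halves_signal(self):
        scheme = AcquisitionScheme([0.0], [[0, 0, 0]])
        dwi = np.full((2, 2, 2, 1), 5.0)
        mvf = np.full((2, 2, 2), 0.5)
        corrected, _ = myelin_correct_signal(dwi, mvf, scheme)
        np.testing.assert_allclose(corrected, 0.5)   # normalized 1.0 * (1-MVF)

    def test_roundtrip_restores_volume_units(self):
        # simulated signal already carries the (1 - MVF) water scaling, so
        # correction must reproduce the water-compartment volumes exactly
        _, streamlines, truth, scheme, dwi, mask = _single_streamline_dataset()
        corrected, _ = myelin_correct_signal(dwi, truth.mvf, scheme, mask)
        b0_corr = corrected[..., scheme.b0_mask].mean(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            eh = np.where(truth.icvf > 0, truth.avf * (1 / truth.icvf - 1), 0.0)
        water = truth.avf + eh + truth.iso_volume + truth.gm_volume
        np.testing.assert_allclose(b0_corr[mask], water[mask], atol=1e-9)

    def test_rejects_mvf_of_one(self):
        scheme = AcquisitionScheme([0.0], [[0, 0, 0]])
        with pytest.raises(ValueError):
            myelin_correct_signal(np.ones((2, 2, 2, 1)), np.ones((2, 2, 2)),
                                  scheme)


class TestTrueAxonalFit:
    def test_isolated_streamline_exact_recovery(self):
        # noiseless one-streamline system is invertible: CSA to 1e-6 relative
        spec, streamlines, truth, scheme, dwi, mask = _single_streamline_dataset()
        corrected, cmask = myelin_correct_signal(dwi, truth.mvf, scheme, mask)
        w = fit_true_axonal(corrected, streamlines, scheme, KernelParams(),
                            cmask, truth.affine)
        assert w.kind == "intra_axonal_true"
        assert w.csa[0] == pytest.approx(truth.axon_csa[0], rel=1e-6)

    def test_zero_signal_gives_zero_weights(self):
        spec, streamlines, truth, scheme, dwi, mask = _single_streamline_dataset()
        w = fit_true_axonal(np.zeros_like(dwi), streamlines, scheme,
                            KernelParams(), mask, truth.affine)
        np.testing.assert_array_equal(w.csa, 0.0)

    def test_volume_is_csa_times_length(self, corridor_result):
        w = corridor_result.av_weights
        np.testing.assert_allclose(w.volume, w.csa * w.length, rtol=1e-9)

    def test_phantom_bundle_recovery(self, corridor_result):
        for _, row in corridor_result.comparison.iterrows():
            assert row.av_fit == pytest.approx(row.av_true, rel=0.01)


class TestFiltering:
    def test_spurious_removed_true_retained(self, orthogonal_result):
        res = orthogonal_result
        spurious = np.flatnonzero(res.truth.bundle_id == -1)
        true = np.flatnonzero(res.truth.bundle_id >= 0)
        removed = ~np.isin(spurious, res.filter_result.kept_indices)
        assert removed.sum() >= 9
        assert np.isin(true, res.filter_result.kept_indices).all()

    def test_icvf_zero_outside_streamlines(self, orthogonal_result):
        res = orthogonal_result
        icvf = res.filter_result.icvf
        assert (icvf[res.truth.avf == 0] == 0).all()
        assert icvf[res.truth.avf > 0].max() <= 1.0 + 1e-12

    def test_fitted_weights_nonnegative(self, corridor_result):
        assert (corridor_result.filter_result.weights >= 0).all()

    def test_degenerate_tractogram_rejected(self):
        spec, streamlines, truth, scheme, dwi, mask = _single_streamline_dataset()
        with pytest.raises(ValueError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_filtering(np.zeros_like(dwi), streamlines, scheme,
                              KernelParams(), mask, truth.affine)


class TestModelFitQuality:
    def test_noiseless_residual_small(self):
        # with the generating streamlines in the dictionary the fitted model
        # reproduces the noiseless corrected signal
        from tractgr.fit import _masked_y
        from tractgr.geometry import build_dwi_operator, build_segment_map

        spec, streamlines, truth, scheme, dwi, mask = _single_streamline_dataset()
        corrected, cmask = myelin_correct_signal(dwi, truth.mvf, scheme, mask)
        segmap = build_segment_map(streamlines, truth.affine, truth.grid_shape)
        system = build_dwi_operator(segmap, scheme, KernelParams(), cmask)
        y = _masked_y(corrected, system)
        x, _ = nnls(system.A, y)
        resid = np.linalg.norm(system.A @ x - y) / np.linalg.norm(y)
        assert resid <= 1e-6

    def test_edge_g_close_to_truth(self, corridor_result):
        for _, row in corridor_result.comparison.iterrows():
            assert abs(row.g_tract_specific - row.g_true) < 0.01
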