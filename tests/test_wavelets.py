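"""Filter banks, transform matrices, multilevel DWT and density windows."""

import numpy as np
import pytest

from icawave.wavelets import (
    assemble_H,
    assemble_H_from_density,
    build_L_matrix,
    daubechies_filters,
    density_basis,
    density_window,
    dwt,
    idwt,
    max_levels,
    strang_convert,
    wavelet_feature_basis,
    DensityWindow,
)


def conv_downsample_oracle(x, taps):
    """Independent periodic correlate-and-decimate, written long-hand."""
    m = len(x)
    out = np.zeros(m // 2)
    for i in range(m // 2):
        acc = 0.0
        for k, t in enumerate(taps):
            acc += t * x[(2 * i + k) % m]
        out[i] = acc
    return out


class TestDaubechiesFilters:
    def test_haar_closed_form(self):
        fp = daubechies_filters(1)
        np.testing.assert_allclose(fp.h, [1 / np.sqrt(2)] * 2, atol=1e-12)
        np.testing.assert_allclose(fp.g, [1 / np.sqrt(2), -1 / np.sqrt(2)], atol=1e-12)

    @pytest.mark.parametrize("i", range(1, 11))
    def test_filter_invariants(self, i):
        fp = daubechies_filters(i)
        assert len(fp.h) == 2 * i
        assert abs(fp.h.sum() - np.sqrt(2)) < 1e-10
        assert abs(np.linalg.norm(fp.h) - 1.0) < 1e-10
        mirror = [(-1) ** k * fp.h[len(fp.h) - 1 - k] for k in range(len(fp.h))]
        np.testing.assert_allclose(fp.g, mirror, atol=1e-12)

    @pytest.mark.parametrize("i", range(1, 11))
    def test_vanishing_moments(self, i):
        # sum_k k^m g_k = 0 for m < i
        fp = daubechies_filters(i)
        k = np.arange(len(fp.g), dtype=float)
        for m in range(i):
            moment = float(np.sum(k**m * fp.g))
            scale = float(np.sum(k**m * np.abs(fp.g))) or 1.0
            assert abs(moment) / scale < 1e-6, (i, m)

    @pytest.mark.parametrize("i", [0, 11, -3])
    def test_out_of_range(self, i):
        with pytest.raises(ValueError):
            daubechies_filters(i)


class TestTransformMatrix:
    def test_haar_constant_signal(self):
        L = build_L_matrix(daubechies_filters(1), 4, 1)
        out = L.matrix @ np.ones(4)
        np.testing.assert_allclose(out, [np.sqrt(2), np.sqrt(2), 0, 0], atol=1e-12)

    @pytest.mark.parametrize("i", range(1, 11))
    @pytest.mark.parametrize("d", [32, 64, 162])
    def test_orthogonality_all_filters_and_sizes(self, i, d):
        fp = daubechies_filters(i)
        if d < len(fp.h):
            pytest.skip("window shorter than filter")
        L = build_L_matrix(fp, d, 1)
        err = np.max(np.abs(L.matrix @ L.matrix.T - np.eye(d)))
        assert err < 1e-8

    def test_matches_convolution_oracle(self, rng):
        fp = daubechies_filters(2)
        x = rng.standard_normal(162)
        L = build_L_matrix(fp, 162, 1)
        out = L.matrix @ x
        np.testing.assert_allclose(out[:81], conv_downsample_oracle(x, fp.h), atol=1e-8)
        np.testing.assert_allclose(out[81:], conv_downsample_oracle(x, fp.g), atol=1e-8)

    def test_level_slices_partition_rows(self):
        L = build_L_matrix(daubechies_filters(3), 64, 3)
        sl = L.level_slices()
        covered = sorted(i for s in sl.values() for i in range(s.start, s.stop))
        assert covered == list(range(64))

    def test_depth_and_divisibility_errors(self):
        fp = daubechies_filters(6)
        with pytest.raises(ValueError):
            build_L_matrix(fp, 162, 2)  # 162 not divisible by 4
        with pytest.raises(ValueError):
            build_L_matrix(fp, 32, 3)  # 4 approximations < filter length
        with pytest.raises(ValueError):
            build_L_matrix(fp, 8, 1)  # d shorter than filter


class TestDWT:
    @pytest.mark.parametrize("i", [1, 4, 6])
    def test_constant_signal_has_zero_details(self, i):
        fp = daubechies_filters(i)
        J = max_levels(64, len(fp.h))
        c = dwt(np.full(64, 2.5), fp, J)
        assert np.max(np.abs(c[64 >> J :])) < 1e-10

    @pytest.mark.parametrize("d,J", [(32, 1), (64, 3), (162, 1)])
    def test_matrix_equivalence_reconstruction_parseval(self, rng, d, J):
        fp = daubechies_filters(6)
        x = rng.standard_normal(d)
        c = dwt(x, fp, J)
        L = build_L_matrix(fp, d, J)
        np.testing.assert_allclose(c, L.matrix @ x, atol=1e-8)
        np.testing.assert_allclose(idwt(c, fp, J), x, atol=1e-8)
        assert abs(np.linalg.norm(c) - np.linalg.norm(x)) < 1e-8

    def test_identity_at_zero_levels(self, rng):
        x = rng.standard_normal(32)
        np.testing.assert_array_equal(dwt(x, daubechies_filters(2), 0), x)

    def test_indivisible_length_rejected(self):
        with pytest.raises(ValueError):
            dwt(np.zeros(33), daubechies_filters(1), 1)


class TestStrangConvert:
    def test_matches_dwt_ordering(self, rng):
        fp = daubechies_filters(4)
        L = build_L_matrix(fp, 64, 2)
        x = rng.standard_normal(64)
        np.testing.assert_allclose(strang_convert(L, x), dwt(x, fp, 2), atol=1e-10)

    def test_zero_and_energy(self, rng):
        L = build_L_matrix(daubechies_filters(5), 64, 1)
        assert np.all(strang_convert(L, np.zeros(64)) == 0)
        x = rng.standard_normal(64)
        block = strang_convert(L, x)
        assert abs(np.sum(block**2) - np.sum(x**2)) < 1e-8

    def test_length_mismatch(self):
        L = build_L_matrix(daubechies_filters(1), 32, 1)
        with pytest.raises(ValueError):
            strang_convert(L, np.zeros(33))


class TestAssembleH:
    def test_identical_beats_identical_blocks(self):
        fp = daubechies_filters(2)
        beat = np.sin(np.linspace(0, 3, 32))
        H = assemble_H([beat] * 3, fp, 1)
        assert H.matrix.shape == (3, 32)
        np.testing.assert_array_equal(H.matrix[0], H.matrix[1])
        np.testing.assert_array_equal(H.matrix[0], H.matrix[2])
        assert H.per_beat_blocks == {0: (0, 1), 1: (1, 2), 2: (2, 3)}

    def test_permutation_equivariance(self, rng):
        fp = daubechies_filters(3)
        beats = [rng.standard_normal(64) for _ in range(5)]
        H = assemble_H(beats, fp, 1)
        Hp = assemble_H(beats[::-1], fp, 1)
        np.testing.assert_array_equal(H.matrix, Hp.matrix[::-1])

    def test_heterogeneous_lengths_rejected(self):
        with pytest.raises(ValueError):
            assemble_H([np.zeros(32), np.zeros(64)], daubechies_filters(1), 1)


class TestDensityWindows:
    def test_exponential_peak_value_is_inverse_lambda(self):
        win = density_window("F2", 162, 81, params={"lam": 12.0})
        assert win.values[81] == pytest.approx(1 / 12.0)

    def test_poisson_direct_evaluation(self):
        # 3^3/3! * e^-3 evaluated at t = 3
        win = density_window("F1", 20, 3, params={"lam": 3.0})
        assert win.values[3] == pytest.approx(27 / 6 * np.exp(-3), rel=1e-6)

    def test_normal_symmetry_about_mode(self):
        win = density_window("F4", 162, 81)
        for dx in (1, 5, 20):
            assert win.values[81 + dx] == pytest.approx(win.values[81 - dx])

    @pytest.mark.parametrize("fid", ["F1", "F2", "F3", "F4", "F5", "F6"])
    @pytest.mark.parametrize("tR", [40, 81, 120])
    def test_mode_alignment_and_nonnegativity(self, fid, tR):
        win = density_window(fid, 162, tR)
        assert np.all(win.values >= 0) and np.all(np.isfinite(win.values))
        assert abs(int(np.argmax(win.values)) - tR) <= 1

    def test_garbled_variants_run(self):
        density_window("F3", 162, 81, garbled=True, seed=0)
        density_window("F6", 162, 81, garbled=True)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            density_window("F4", 162, 81, params={"sigma": -1})
        with pytest.raises(ValueError):
            density_window("F9", 162, 81)
        with pytest.raises(ValueError):
            density_window("F1", 162, 200)


class TestAssembleHFromDensity:
    def test_zero_beats_zero_h(self):
        win = density_window("F4", 32, 16)
        H = assemble_H_from_density([np.zeros(32)] * 2, win)
        assert np.all(H.matrix == 0)

    def test_delta_window_sifts_downsampled_samples(self, rng):
        d, tR = 32, 5
        delta = np.zeros(d)
        delta[tR] = 1.0
        win = DensityWindow(function_id="F4", params={}, values=delta, t_R=tR)
        beat = rng.standard_normal(d)
        H = assemble_H_from_density([beat], win)
        expect = beat[(2 * np.arange(d // 2) + tR) % d]
        np.testing.assert_allclose(H.matrix[0, : d // 2], expect, atol=1e-12)

    def test_shape_contract_matches_wavelet_assembly(self, rng):
        beats = [rng.standard_normal(64) for _ in range(4)]
        win = density_window("F4", 64, 32)
        Hd = assemble_H_from_density(beats, win)
        Hw = assemble_H(beats, daubechies_filters(1), 1)
        assert Hd.matrix.shape == Hw.matrix.shape
        assert Hd.per_beat_blocks == Hw.per_beat_blocks


class TestFeatureBasis:
    def test_full_basis_is_orthogonal(self):
        B = wavelet_feature_basis("db6", 162, keep="all")
        np.testing.assert_allclose(B @ B.T, np.eye(162), atol=1e-8)

    def test_truncated_basis_has_orthonormal_rows(self):
        B = wavelet_feature_basis("db6", 162, keep="approx")
        assert B.shape == (81, 162)
        np.testing.assert_allclose(B @ B.T, np.eye(81), atol=1e-8)

    def test_density_basis_low_band_shape(self):
        win = density_window("F4", 64, 32)
        B = density_basis(win, 64)
        assert B.shape == (32, 64)
        assert np.max(np.abs(B)) <= 1.0 + 1e-12
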