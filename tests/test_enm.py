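import numpy as np
import pytest

from loopgraft import (
    ENMParams,
    Region,
    anm_modes,
    bfactors,
    build_hessian,
    build_kirchhoff,
    compute_modes,
    cross_correlations,
    flexibility_profile,
    gnm_modes,
    ideal_helix,
    make_homolog_pair,
    normalize_profile,
    region_cross_correlation,
    region_mean_flexibility,
    square_fluctuations,
    ToyArchitecture,
)


def seeded_toy(seed, sigma=0.0):
    return make_homolog_pair(
        ToyArchitecture(seed=seed, noise_sigma=sigma)
    ).scaffold.coords


class TestKirchhoff:
    def test_rows_sum_to_zero(self):
        K = build_kirchhoff(seeded_toy(0), cutoff=10.0)
        np.testing.assert_allclose(K.sum(axis=1), 0.0, atol=1e-12)

    def test_triangle_closed_form(self, triangle_coords):
        K = build_kirchhoff(triangle_coords, cutoff=10.0)
        np.testing.assert_allclose(
            K, [[2, -1, -1], [-1, 2, -1], [-1, -1, 2]]
        )

    def test_distant_points_unconnected(self):
        K = build_kirchhoff(np.array([[0.0, 0, 0], [100.0, 0, 0]]), 10.0)
        np.testing.assert_allclose(K, 0.0)


class TestHessian:
    def test_block_rows_sum_to_zero(self):
        H = build_hessian(seeded_toy(1), cutoff=15.0)
        n = H.shape[0] // 3
        blocks = H.reshape(n, 3, n, 3).sum(axis=2)
        np.testing.assert_allclose(blocks, 0.0, atol=1e-12)

    def test_two_particle_pair_along_x(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.0, 50.0, 0]])
        H = build_hessian(coords, cutoff=15.0)
        # only the xx components of the 0-1 interaction are nonzero
        assert H[0, 0] == pytest.approx(1.0)
        assert H[0, 3] == pytest.approx(-1.0)
        assert H[1, 1] == H[2, 2] == 0.0

    def test_folded_toy_has_six_zero_modes(self):
        H = build_hessian(seeded_toy(2)[:20], cutoff=15.0)
        spectrum = compute_modes(H, model="ANM", expected_zero=6)
        assert spectrum.n_zero == 6


class TestComputeModes:
    def test_triangle_spectrum(self, triangle_coords):
        K = build_kirchhoff(triangle_coords, 10.0)
        spectrum = compute_modes(K, model="GNM", expected_zero=1)
        assert spectrum.n_zero == 1
        np.testing.assert_allclose(spectrum.eigenvalues, [3.0, 3.0])

    def test_disconnected_graph_warns(self):
        coords = np.vstack([seeded_toy(3)[:10],
                            seeded_toy(3)[:10] + 500.0])
        K = build_kirchhoff(coords, 10.0)
        with pytest.warns(UserWarning, match="2 zero modes"):
            spectrum = compute_modes(K, model="GNM", expected_zero=1)
        assert spectrum.n_zero == 2

    def test_collinear_anm_warns(self):
        coords = np.outer(np.arange(10), [3.8, 0.0, 0.0])
        H = build_hessian(coords, cutoff=15.0)
        with pytest.warns(UserWarning):
            spectrum = compute_modes(H, model="ANM", expected_zero=6)
        assert spectrum.n_zero > 6

    def test_truncation_warns_when_too_few_modes(self, triangle_coords):
        K = build_kirchhoff(triangle_coords, 10.0)
        with pytest.warns(UserWarning, match="retaining all"):
            compute_modes(K, n_modes=10, model="GNM")


class TestFluctuations:
    def test_triangle_msf_closed_form(self, triangle_coords):
        spectrum = gnm_modes(triangle_coords)
        np.testing.assert_allclose(
            square_fluctuations(spectrum), 2.0 / 9.0, atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_gnm_mode_sum_equals_pseudoinverse_diagonal(self, seed):
        coords = seeded_toy(seed)
        K = build_kirchhoff(coords, 10.0)
        spectrum = compute_modes(K, model="GNM")
        msf = square_fluctuations(spectrum)
        oracle = np.diag(np.linalg.pinv(K, hermitian=True, rcond=1e-10))
        np.testing.assert_allclose(msf, oracle, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_anm_mode_sum_equals_pseudoinverse_blocks(self, seed):
        coords = seeded_toy(seed)[:30]
        H = build_hessian(coords, 15.0)
        spectrum = compute_modes(H, model="ANM")
        msf = square_fluctuations(spectrum)
        pinv = np.linalg.pinv(H, hermitian=True, rcond=1e-10)
        n = len(coords)
        oracle = np.array([np.trace(pinv[3 * k:3 * k + 3, 3 * k:3 * k + 3])
                           for k in range(n)])
        np.testing.assert_allclose(msf, oracle, atol=1e-8)

    def test_truncated_msf_monotone_in_mode_count(self):
        coords = seeded_toy(4)
        K = build_kirchhoff(coords, 10.0)
        prev = np.zeros(len(coords))
        for n_modes in (1, 3, 10, len(coords) - 1):
            msf = square_fluctuations(compute_modes(K, n_modes, model="GNM"))
            assert np.all(msf >= prev - 1e-12)
            prev = msf


class TestBfactors:
    def test_debye_waller_scaling(self):
        assert bfactors(np.array([0.0]))[0] == 0.0
        assert bfactors(np.array([2.0 / 9.0]))[0] == pytest.approx(
            8 * np.pi ** 2 / 3 * 2 / 9, abs=1e-3
        )
        assert bfactors(np.array([2.0 / 9.0]))[0] == pytest.approx(5.848, abs=1e-3)

    def test_order_preserved(self):
        msf = np.array([0.1, 0.5, 0.3])
        assert list(np.argsort(bfactors(msf))) == list(np.argsort(msf))


class TestCrossCorrelations:
    def test_unit_diagonal_symmetry_bounds(self):
        spectrum = gnm_modes(seeded_toy(6))
        C = cross_correlations(spectrum)
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-9)
        np.testing.assert_allclose(C, C.T, atol=1e-9)
        assert np.all(np.abs(C) <= 1 + 1e-9)

    def test_triangle_off_diagonal(self, triangle_coords):
        C = cross_correlations(gnm_modes(triangle_coords))
        assert C[0, 1] == pytest.approx(-0.5, abs=1e-9)

    def test_rigidly_linked_distant_residues_move_together(self):
        # hairpin: two helices packed into one rigid block, joined by a
        # long floppy coil that wanders away — residues far apart in
        # sequence but inside the same rigid block are strongly
        # positively coupled
        from loopgraft import random_coil

        h1 = ideal_helix(10, origin=(0, 0, 0), axis=(0, 0, 1))
        coil = random_coil(12, np.random.default_rng(1),
                           start=h1[-1] + [0, 12, 0], direction=(0, 1, 0))
        h2 = ideal_helix(10, origin=(5.0, 0, 13.5), axis=(0, 0, -1))
        coords = np.vstack([h1, coil, h2])
        C = cross_correlations(gnm_modes(coords))
        assert region_cross_correlation(C, Region(0, 9), Region(22, 31)) > 0.5
        assert C[5, 27] > 0.5


class TestProfileUtilities:
    def test_normalize_examples(self):
        np.testing.assert_allclose(
            normalize_profile(np.array([1.0, 2.0, 3.0])), [0, 0.5, 1]
        )
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_profile(np.full(4, 2.2))
        np.testing.assert_allclose(out, 0.0)

    def test_normalized_bounds(self):
        prof = flexibility_profile(seeded_toy(7))
        assert prof.normalized.min() == 0.0
        assert prof.normalized.max() == 1.0
        assert np.all(prof.msf >= 0)

    def test_region_mean(self):
        values = np.array([1.0, 3.0, 5.0])
        assert region_mean_flexibility(values, Region(0, 1)) == 2.0
        assert region_mean_flexibility(values, Region(2, 2)) == 5.0

    def test_region_cross_correlation_formula(self, triangle_coords):
        C = cross_correlations(gnm_modes(triangle_coords))
        assert region_cross_correlation(C, Region(0, 0), Region(1, 1)) == \
            pytest.approx(-0.5, abs=1e-9)
        # region vs itself includes the unit diagonal
        expected = (2 * 1.0 + 2 * C[0, 1]) / 4
        assert region_cross_correlation(C, Region(0, 1), Region(0, 1)) == \
            pytest.approx(expected)
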