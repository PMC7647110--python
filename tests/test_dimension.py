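"""Genome-count estimation: exact rank path and PCA marker pattern."""

import numpy as np
import pytest

from bscount import (
    MultiplicityModel,
    NoMarkerPattern,
    compute_bs,
    detect_marker_pattern,
    estimate_genome_count,
    generate_sample_set,
    incremental_rank,
    pca_residual_curve,
    sequential_basis,
)
from bscount.dimension import MarkerCurves
from bscount.exactrank import integer_rank
from bscount.simulate import iter_samples, make_fragment_set


@pytest.fixture(scope="module")
def genome_spectra(dict6):
    from bscount import generate_synthetic_genome

    rng = np.random.default_rng(5)
    genomes = [generate_synthetic_genome(8000, rng, id=f"g{i}") for i in range(8)]
    return np.array([compute_bs(g, dict6).counts for g in genomes])


class TestIncrementalRank:
    def test_distinct_genome_spectra_are_full_rank(self, genome_spectra):
        assert incremental_rank(genome_spectra) == len(genome_spectra)

    def test_hand_constructed_dependence(self, genome_spectra):
        b, c = genome_spectra[0].astype(float), genome_spectra[1].astype(float)
        assert incremental_rank(np.array([b, 2 * b, b + c])) == 2

    def test_all_zero_rows(self):
        assert incremental_rank(np.zeros((4, 10))) == 0

    def test_matches_exact_rational_rank_on_random_integer_matrices(self, rng):
        for _ in range(40):
            m, n = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            mat = rng.integers(0, 6, size=(m, n))
            if rng.random() < 0.5 and m >= 2:
                mat[-1] = mat[:-1].sum(axis=0)  # plant a dependence
            assert incremental_rank(mat) == integer_rank(mat.tolist())

    def test_matches_exact_rank_on_sample_matrix(self, genome_spectra, rng):
        # integer combinations of 8 genome spectra in the 4096-dim space
        coeff = rng.integers(0, 5, size=(20, len(genome_spectra)))
        samples = coeff @ genome_spectra
        assert incremental_rank(samples) == integer_rank(samples.tolist())


class TestSequentialBasis:
    def test_single_repeated_spectrum(self, genome_spectra):
        row = genome_spectra[0]
        stream = iter([row] * 50)
        state, est = sequential_basis(stream, stop_m=4)
        assert est.genome_count == 1
        assert state.samples_consumed == 1 + 4
        assert est.terminated

    def test_error_free_binary_stream_recovers_genome_count(self, dict6, small_genomes):
        fragsets = [
            make_fragment_set(g, 1.0, 1, letter_error_rate=0.0, rng=0, dictionary=dict6)
            for g in small_genomes
        ]
        model = MultiplicityModel.uniform_discrete((0, 1), len(small_genomes))
        rng = np.random.default_rng(8)
        state, est = sequential_basis(iter_samples(fragsets, model, rng), stop_m=6)
        assert est.genome_count == len(small_genomes)
        assert "0.98" in est.confidence_note or est.confidence_note

    def test_mean_consumed_close_to_n_over_p_plus_m(self, dict6, small_genomes):
        # Monte-Carlo check of the expected sampling length at p approx 0.5
        fragsets = [
            make_fragment_set(g, 1.0, 1, letter_error_rate=0.0, rng=0, dictionary=dict6)
            for g in small_genomes[:3]
        ]
        model = MultiplicityModel.uniform_discrete((0, 1), 3)
        rng = np.random.default_rng(9)
        consumed = []
        for _ in range(60):
            state, est = sequential_basis(iter_samples(fragsets, model, rng), stop_m=4)
            if est.genome_count == 3:
                consumed.append(state.samples_consumed - 4)
        mean = np.mean(consumed)
        # success probability is >= 0.5 and grows toward 1 in low codimension
        assert 3.0 <= mean <= 6.5

    def test_exhausted_stream_flagged(self, genome_spectra):
        stream = iter([genome_spectra[0], genome_spectra[1]])
        state, est = sequential_basis(stream, stop_m=4)
        assert not est.terminated
        assert est.genome_count == 2


class TestResidualCurves:
    def test_noise_free_low_rank_curve_hits_zero(self, genome_spectra, rng):
        r = 4
        coeff = rng.integers(0, 5, size=(12, r)).astype(float)
        samples = coeff @ genome_spectra[:r]
        curves = pca_residual_curve(samples)
        # centered rank is r, so the residual vanishes from n = r on
        assert curves.f[r - 1] <= 1e-9 * curves.f0
        assert curves.f[r - 2] > 1e-6 * curves.f0

    def test_f_non_increasing_on_noisy_data(self, rng):
        samples = rng.random((15, 60))
        curves = pca_residual_curve(samples)
        assert np.all(np.diff(curves.f) <= 1e-9)
        assert np.all(curves.f >= 0)
        assert np.all((curves.d1 >= -1e-12) & (curves.d1 <= 1 + 1e-12))

    def test_row_order_invariance(self, rng):
        samples = rng.random((12, 40))
        base = pca_residual_curve(samples)
        perm = pca_residual_curve(samples[rng.permutation(12)])
        assert np.allclose(base.f, perm.f)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_residual_curve(rng.random((2, 10)))


def _curves(f):
    f = np.asarray(f, dtype=float)
    d1 = (f[:-1] - f[1:]) / f[:-1]
    d2 = (d1[:-1] - d1[1:]) / d1[:-1]
    return MarkerCurves(f=f, d1=d1, d2=d2, n_max=len(f), f0=float(f[0] * 1.2))


class TestMarkerDetection:
    def test_unique_peak_maps_to_peak_plus_one(self):
        # geometric decay with one sharp drop between n=5 and n=6
        f = [100 * 0.9**i for i in range(5)] + [20 * 0.95**i for i in range(8)]
        est = detect_marker_pattern(_curves(f))
        assert est.peak_index == 5
        assert est.genome_count == 6
        assert not est.ambiguous

    def test_adjacent_tie_resolves_low_and_flags_ambiguous(self):
        f = np.array([100.0, 80, 64, 32, 16, 14, 12.6, 11.3, 10.2, 9.2])
        curves = _curves(f)
        # force an exact tie in d2 at two adjacent positions
        m = np.nanmax(curves.d2)
        tied = np.isclose(curves.d2, m)
        curves.d2[np.argmax(tied) + 1] = m
        est = detect_marker_pattern(curves)
        assert est.ambiguous
        assert est.peak_index == int(np.argmax(np.isclose(curves.d2, m))) + 1

    def test_flat_curve_raises_no_marker_pattern(self):
        f = [100 * 0.9**i for i in range(12)]  # perfectly geometric: d2 == 0
        with pytest.raises(NoMarkerPattern):
            detect_marker_pattern(_curves(f))

    def test_noise_free_rank_r_returns_r(self, genome_spectra, rng):
        r = 5
        coeff = rng.integers(0, 5, size=(14, r)).astype(float)
        samples = coeff @ genome_spectra[:r]
        est = detect_marker_pattern(pca_residual_curve(samples))
        assert est.genome_count == r
        assert "low-rank" in est.notes[0]


class TestEstimateGenomeCount:
    def test_error_free_exact_path(self, small_genomes):
        ss = generate_sample_set(
            small_genomes, MultiplicityModel.normal(5, 2), coverage=1.0,
            n_samples=14, rng_seed=2, n_fragments=1, letter_error_rate=0.0,
        )
        est = estimate_genome_count(ss)
        assert est.method == "exact_rank"
        assert est.genome_count == len(small_genomes)

    def test_noisy_pca_path_recovers_within_one(self):
        from bscount import generate_synthetic_genome

        rng = np.random.default_rng(21)
        genomes = [generate_synthetic_genome(50_000, rng, id=f"g{i}") for i in range(6)]
        ss = generate_sample_set(
            genomes, MultiplicityModel.normal(10, 3), coverage=0.75,
            n_samples=16, rng_seed=rng,
        )
        est = estimate_genome_count(ss)
        assert est.method == "pca_marker"
        assert abs(est.genome_count - 6) <= 1

    def test_single_sample_degenerates_with_warning(self, genome_spectra):
        with pytest.warns(UserWarning):
            est = estimate_genome_count(genome_spectra[:1])
        assert est.genome_count == 1

    def test_scale_invariance(self, rng):
        samples = rng.random((14, 50)) + rng.random(50)  # noisy full-rank cloud
        a = estimate_genome_count(samples, method="pca")
        b = estimate_genome_count(samples * 37.5, method="pca")
        assert a.genome_count == b.genome_count

    def test_too_few_samples_for_pca_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_genome_count(rng.random((4, 30)) + 1, method="pca")

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_genome_count(rng.random((5, 5)), method="magic")
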