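"""Sample simulation: genomes, mutation, fragment sets, multiplicities."""

import numpy as np
import pytest

from bscount import (
    GenomeRecord,
    MultiplicityModel,
    compute_bs,
    draw_multiplicities,
    generate_sample_set,
    generate_synthetic_genome,
    make_fragment_set,
    mutate_letters,
    synthesize_sample,
)


class TestSyntheticGenome:
    def test_exact_length_and_alphabet(self):
        g = generate_synthetic_genome(1000, 0)
        assert len(g.sequence) == 1000
        assert set(g.sequence) <= set("ACGT")

    def test_same_seed_is_deterministic(self):
        assert (
            generate_synthetic_genome(5000, 7).sequence
            == generate_synthetic_genome(5000, 7).sequence
        )

    def test_different_seeds_give_independent_spectra(self, dict6):
        a = generate_synthetic_genome(50_000, 1, id="a")
        b = generate_synthetic_genome(50_000, 2, id="b")
        mat = np.array(
            [compute_bs(a, dict6).counts, compute_bs(b, dict6).counts], dtype=float
        )
        assert np.linalg.matrix_rank(mat) == 2

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_genome(0, 0)

    def test_order0_uses_given_composition(self):
        g = generate_synthetic_genome(20_000, 0, markov_order=0)
        assert len(g.sequence) == 20_000


class TestMutateLetters:
    def test_rate_zero_is_identity(self, small_genomes):
        seq = small_genomes[0].sequence
        assert mutate_letters(seq, 0.0, 0) == seq

    @pytest.mark.parametrize("rate", [-0.1, 1.0, 1.5])
    def test_invalid_rate_rejected(self, rate):
        with pytest.raises(ValueError):
            mutate_letters("ACGT", rate, 0)

    def test_hamming_distance_matches_binomial(self, rng):
        n, rate = 1_000_000, 1e-3
        seq = generate_synthetic_genome(n, rng).sequence
        mut = mutate_letters(seq, rate, rng)
        dist = sum(a != b for a, b in zip(seq, mut))
        sd = np.sqrt(n * rate * (1 - rate))
        assert abs(dist - n * rate) < 4 * sd

    def test_replacement_always_changes_the_letter(self, rng):
        seq = generate_synthetic_genome(2000, rng).sequence
        mut = mutate_letters(seq, 0.5, rng)
        assert len(mut) == len(seq)
        # every position either kept or substituted by a different letter;
        # with rate 0.5 on 2000 letters some substitutions must occur
        assert any(a != b for a, b in zip(seq, mut))

    def test_ambiguous_letters_untouched(self):
        out = mutate_letters("ANNNA", 0.999, 0)
        assert out[1:4] == "NNN"


class TestFragmentSets:
    def test_random_window_count_and_mass(self, dict6, small_genomes):
        g = small_genomes[0]
        fs = make_fragment_set(g, 0.75, n_fragments=20, letter_error_rate=1e-3,
                               rng=0, dictionary=dict6)
        assert len(fs) == 20
        frag_len = round(0.75 * len(g.sequence))
        for spec in fs.fragment_spectra:
            # substitutions keep length, so the mass identity is exact
            assert spec.total == 2 * (frag_len - dict6.k + 1)

    def test_full_coverage_no_error_equals_genome_spectrum(self, dict6, small_genomes):
        g = small_genomes[1]
        full = compute_bs(g, dict6)
        fs = make_fragment_set(g, 1.0, n_fragments=3, letter_error_rate=0.0,
                               rng=0, dictionary=dict6)
        for spec in fs.fragment_spectra:
            assert np.array_equal(spec.counts, full.counts)

    def test_partition_exclusion_structure(self, dict6, small_genomes):
        g = small_genomes[2]
        fs = make_fragment_set(g, 0.9, n_fragments=10, scheme="partition_exclusion",
                               letter_error_rate=0.0, rng=0, dictionary=dict6)
        assert len(fs) == 10
        L = len(g.sequence)
        part_sizes = [len(p) for p in np.array_split(np.arange(L), 10)]
        for i, spec in enumerate(fs.fragment_spectra):
            # fragment i omits exactly one of the 10 parts (80% pairwise overlap)
            assert spec.total == 2 * (L - part_sizes[i] - dict6.k + 1)

    def test_partition_exclusion_requires_f09_and_10_fragments(self, dict6, small_genomes):
        with pytest.raises(ValueError):
            make_fragment_set(small_genomes[0], 0.75, n_fragments=10,
                              scheme="partition_exclusion", dictionary=dict6)

    def test_too_small_fragment_rejected(self, dict6):
        with pytest.raises(ValueError):
            make_fragment_set(GenomeRecord("t", "ACGTACGT"), 0.5, n_fragments=1,
                              dictionary=dict6)


class TestMultiplicities:
    def test_discrete_binary_is_bernoulli_half(self, rng):
        model = MultiplicityModel.uniform_discrete((0, 1), 8)
        draws = np.array([draw_multiplicities(model, 8, rng) for _ in range(2000)])
        assert set(np.unique(draws)) <= {0, 1}
        assert abs(draws.mean() - 0.5) < 0.02

    def test_normal_sigma_zero_is_constant(self, rng):
        vgm = draw_multiplicities(MultiplicityModel.normal(10, 0.0), 12, rng)
        assert np.array_equal(vgm, np.full(12, 10))

    def test_normal_draws_are_clipped_nonnegative(self, rng):
        vgm = draw_multiplicities(MultiplicityModel.normal(1, 5.0), 5000, rng)
        assert vgm.min() >= 0

    def test_mean_abs_deviation_matches_closed_form(self, rng):
        from bscount import rounded_normal_mean_abs_deviation

        model = MultiplicityModel.normal(10, 3.0)
        draws = np.concatenate(
            [draw_multiplicities(model, 1000, rng) for _ in range(100)]
        )
        observed = np.abs(draws - 10).mean()
        assert observed == pytest.approx(rounded_normal_mean_abs_deviation(3.0), abs=0.03)

    def test_draws_independent_across_genomes(self, rng):
        model = MultiplicityModel.normal(10, 3.0)
        draws = np.array([draw_multiplicities(model, 2, rng) for _ in range(20_000)])
        corr = np.corrcoef(draws.T)[0, 1]
        assert abs(corr) < 0.03

    def test_model_validation(self):
        with pytest.raises(ValueError):
            MultiplicityModel.normal(-1, 1)
        with pytest.raises(ValueError):
            MultiplicityModel.discrete([[]])
        with pytest.raises(ValueError):
            MultiplicityModel.discrete([[0, 1]], probs=[[0.9, 0.2]])


class TestSynthesizeSample:
    @pytest.fixture
    def fragsets(self, dict6, small_genomes):
        return [
            make_fragment_set(g, 1.0, n_fragments=1, letter_error_rate=0.0,
                              rng=0, dictionary=dict6)
            for g in small_genomes[:2]
        ]

    def test_all_zero_multiplicities_give_zero_spectrum(self, fragsets):
        spec = synthesize_sample(fragsets, np.array([0, 0]), 0)
        assert spec.total == 0

    def test_linearity_in_copies(self, dict6, small_genomes, fragsets):
        full = compute_bs(small_genomes[0], dict6)
        spec = synthesize_sample(fragsets, np.array([2, 0]), 0)
        assert np.array_equal(spec.counts, 2 * full.counts)

    def test_length_mismatch_rejected(self, fragsets):
        with pytest.raises(ValueError):
            synthesize_sample(fragsets, np.array([1, 1, 1]), 0)


class TestSampleSet:
    def test_error_free_rank_bounded_by_genome_count(self, small_genomes):
        ss = generate_sample_set(
            small_genomes, MultiplicityModel.normal(5, 2), coverage=1.0,
            n_samples=12, rng_seed=3, n_fragments=1, letter_error_rate=0.0,
        )
        assert np.linalg.matrix_rank(ss.matrix.astype(float)) <= len(small_genomes)

    def test_fixed_seed_reproducible(self, small_genomes):
        kw = dict(coverage=0.75, n_samples=4, n_fragments=3, letter_error_rate=1e-3)
        a = generate_sample_set(small_genomes[:2], MultiplicityModel.normal(5, 2),
                                rng_seed=11, **kw)
        b = generate_sample_set(small_genomes[:2], MultiplicityModel.normal(5, 2),
                                rng_seed=11, **kw)
        assert np.array_equal(a.matrix, b.matrix)
        assert a.provenance["coverage"] == 0.75

    def test_tsv_round_trip(self, tmp_path, small_genomes):
        ss = generate_sample_set(small_genomes[:2], MultiplicityModel.normal(5, 2),
                                 coverage=0.75, n_samples=3, rng_seed=1,
                                 n_fragments=2, letter_error_rate=0.0)
        path = tmp_path / "s.tsv"
        ss.to_tsv(path)
        from bscount import SampleSet

        back = SampleSet.from_tsv(path)
        assert np.array_equal(back.matrix, ss.matrix)
        assert back.dictionary.k == 6
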