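import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from centrodyad.conservation import (
    MIN_ENTROPY,
    Statistic,
    Weighting,
    blosum62_matrix,
    column_frequencies,
    conservation_profile,
    entropy_score,
    henikoff_weights,
    overall_frequencies,
    sum_of_pairs_score,
    variance_score,
)
from centrodyad.io_formats import AMINO_ACIDS

from conftest import make_msa
from centrodyad.synthetic_data import simulate_msa

AA = {a: i for i, a in enumerate(AMINO_ACIDS)}


def freqs_from(column_spec: dict[str, float]) -> np.ndarray:
    f = np.zeros(20)
    for aa, v in column_spec.items():
        f[AA[aa]] = v
    return f


class TestColumnFrequencies:
    def test_pure_column(self):
        msa = make_msa(["AC", "AC", "AC", "AC"])
        f = column_frequencies(msa, 0)
        assert f[AA["A"]] == 1.0 and f.sum() == pytest.approx(1.0)

    def test_even_split(self):
        msa = make_msa(["AD", "CD"])
        f = column_frequencies(msa, 0)
        assert f[AA["A"]] == f[AA["C"]] == 0.5

    def test_gap_excluded_from_denominator(self):
        msa = make_msa(["AD", "-D"])
        f = column_frequencies(msa, 0)
        assert f[AA["A"]] == 1.0

    def test_all_gap_column_raises(self):
        msa = make_msa(["-D", "-D"])
        with pytest.raises(ValueError, match="all-gap"):
            column_frequencies(msa, 0)

    def test_weights_shift_frequencies(self):
        msa = make_msa(["AD", "CD"])
        f = column_frequencies(msa, 0, weights=np.array([3.0, 1.0]))
        assert f[AA["A"]] == pytest.approx(0.75)


class TestEntropyScore:
    def test_pure_column_is_zero(self):
        assert entropy_score(freqs_from({"W": 1.0})) == 0.0

    def test_uniform_column_is_minus_log20(self):
        assert entropy_score(np.full(20, 0.05)) == pytest.approx(-math.log(20))

    def test_two_way_split(self):
        f = freqs_from({"A": 0.5, "C": 0.5})
        assert entropy_score(f) == pytest.approx(math.log(0.5))

    def test_bounds_on_random_frequency_vectors(self, rng):
        for _ in range(100):
            f = rng.dirichlet(np.ones(20) * rng.uniform(0.1, 5))
            assert MIN_ENTROPY - 1e-9 <= entropy_score(f) <= 0.0


class TestVarianceScore:
    def test_zero_at_background(self):
        b = np.full(20, 0.05)
        assert variance_score(b, b) == 0.0

    def test_pure_column_vs_uniform_closed_form(self):
        f = freqs_from({"A": 1.0})
        expected = math.sqrt((1 - 0.05) ** 2 + 19 * 0.05**2)
        assert variance_score(f, np.full(20, 0.05)) == pytest.approx(expected)

    def test_random_column_matches_direct_summation(self, rng):
        f = rng.dirichlet(np.ones(20))
        b = rng.dirichlet(np.ones(20))
        direct = math.sqrt(sum((f[i] - b[i]) ** 2 for i in range(20)))
        assert variance_score(f, b) == pytest.approx(direct)


class TestSumOfPairsScore:
    def test_pure_tryptophan_is_blosum_diagonal(self):
        assert sum_of_pairs_score(freqs_from({"W": 1.0})) == 11.0

    def test_two_residue_expansion(self):
        mat = blosum62_matrix()
        f = freqs_from({"A": 0.5, "V": 0.5})
        expected = 0.25 * (
            mat[AA["A"], AA["A"]] + 2 * mat[AA["A"], AA["V"]] + mat[AA["V"], AA["V"]]
        )
        assert sum_of_pairs_score(f) == pytest.approx(expected)

    def test_random_column_matches_double_loop(self, rng):
        mat = blosum62_matrix()
        f = rng.dirichlet(np.ones(20))
        direct = sum(
            f[i] * f[j] * mat[i, j] for i in range(20) for j in range(20)
        )
        assert sum_of_pairs_score(f, mat) == pytest.approx(direct)

    def test_asymmetric_matrix_rejected(self):
        mat = blosum62_matrix()
        mat[0, 1] += 1
        with pytest.raises(ValueError, match="symmetric"):
            sum_of_pairs_score(np.full(20, 0.05), mat)


class TestHenikoffWeights:
    def test_identical_sequences_equal_weights(self):
        msa = make_msa(["ACDE"] * 4)
        assert henikoff_weights(msa) == pytest.approx(np.ones(4))

    def test_two_distinct_sequences_equal_weights(self):
        msa = make_msa(["ACDE", "WYYH"])
        assert henikoff_weights(msa) == pytest.approx(np.ones(2))

    def test_three_sequence_toy_matches_hand_computation(self):
        # cols: "AAA" (r=1, s=3 each) and "AAC" (r=2; s_A=2, s_C=1)
        msa = make_msa(["AA", "AA", "AC"])
        w = henikoff_weights(msa)
        assert w == pytest.approx([7 / 8, 7 / 8, 10 / 8])

    def test_gap_positions_contribute_zero(self):
        msa = make_msa(["AA", "A-", "AC"])
        w = henikoff_weights(msa)
        # col1: r=2 over {A, C}; the gapped row collects only col0
        assert w[1] < w[0] == pytest.approx(w[2])


class TestConservationProfile:
    def test_fully_conserved_alignment_scores_zero_everywhere(self):
        msa = make_msa(["ACDEF"] * 5)
        prof = conservation_profile(msa)
        scores = prof.scores[(Statistic.ENTROPY, Weighting.UNWEIGHTED)]
        assert np.allclose(scores, 0.0)

    def test_gap_majority_columns_masked(self):
        msa = make_msa(["A-DE", "A-DE", "ACDE", "A-DE"])
        prof = conservation_profile(msa, gap_threshold=0.5)
        assert prof.masked[1]
        assert np.isnan(prof.scores[(Statistic.ENTROPY, Weighting.UNWEIGHTED)][1])
        assert prof.gap_fraction[1] == pytest.approx(0.75)

    def test_sequence_reordering_leaves_profile_unchanged(self, rng):
        msa, _ = simulate_msa(n_seqs=8, length=40, conserved_block=(20, 40),
                              divergent_block=(0, 15), seed=5)
        measures = [
            (Statistic.ENTROPY, Weighting.UNWEIGHTED),
            (Statistic.VARIANCE, Weighting.HENIKOFF),
            (Statistic.SUM_OF_PAIRS, Weighting.UNWEIGHTED),
        ]
        prof = conservation_profile(msa, measures=measures)
        order = rng.permutation(msa.n_sequences)
        shuffled = make_msa(
            [msa.records[i].sequence for i in order],
            ids=[msa.records[i].id for i in order],
        )
        prof2 = conservation_profile(shuffled, measures=measures)
        for m in measures:
            assert np.allclose(
                prof.scores[m], prof2.scores[m], equal_nan=True
            )

    def test_planted_blocks_separate_by_mean_entropy(self):
        msa, truth = simulate_msa(
            n_seqs=20, length=120, conserved_block=(70, 120),
            divergent_block=(0, 40), seed=11,
        )
        prof = conservation_profile(msa)
        scores = prof.scores[(Statistic.ENTROPY, Weighting.UNWEIGHTED)]
        assert np.nanmean(scores[70:120]) > np.nanmean(scores[0:40])

    def test_entropy_ranking_recovers_planted_rates(self):
        # 40 rows: per-column entropy from fewer draws is too noisy to
        # resolve a 100-level rate gradient rank-for-rank
        for seed in range(5):
            rates = np.linspace(0.01, 0.8, 100)
            msa, _ = simulate_msa(
                n_seqs=40, length=100, sub_rate_profile=rates, seed=seed
            )
            prof = conservation_profile(msa)
            scores = prof.scores[(Statistic.ENTROPY, Weighting.UNWEIGHTED)]
            rho = spearmanr(scores, -rates).statistic
            assert rho >= 0.9

    def test_normalize_z_scores_unmasked_columns(self):
        msa, _ = simulate_msa(n_seqs=10, length=60, conserved_block=(30, 60),
                              divergent_block=(0, 20), seed=3)
        prof = conservation_profile(msa, normalize=True)
        scores = prof.scores[(Statistic.ENTROPY, Weighting.UNWEIGHTED)]
        keep = ~prof.masked
        assert np.nanmean(scores[keep]) == pytest.approx(0.0, abs=1e-9)
        assert np.nanstd(scores[keep]) == pytest.approx(1.0, abs=1e-9)

    def test_all_columns_masked_is_an_error(self):
        msa = make_msa(["--", "--", "AC"])
        with pytest.raises(ValueError, match="gap-masked"):
            conservation_profile(msa, gap_threshold=0.3)

    def test_entropy_bounds_hold_on_simulated_alignment(self):
        msa, _ = simulate_msa(n_seqs=15, length=80, conserved_block=(50, 80),
                              divergent_block=(0, 30), seed=7)
        prof = conservation_profile(
            msa,
            measures=[(Statistic.ENTROPY, Weighting.UNWEIGHTED),
                      (Statistic.ENTROPY, Weighting.HENIKOFF)],
        )
        for arr in prof.scores.values():
            vals = arr[~np.isnan(arr)]
            assert np.all(vals <= 0.0) and np.all(vals >= MIN_ENTROPY - 1e-9)

    def test_overall_frequencies_sum_to_one(self):
        msa = make_msa(["AC-E", "ACD-"])
        f = overall_frequencies(msa)
        assert f.sum() == pytest.approx(1.0)
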