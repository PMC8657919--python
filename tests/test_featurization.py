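import numpy as np
import pytest

from prospr.featurization import (CH_APC, CH_COUPLINGS, CH_INDEX_I,
                                  CH_INDEX_J, CH_MASK, CH_ONEHOT_I,
                                  CH_ONEHOT_J, N_DCA_CHANNELS,
                                  N_INPUT_CHANNELS, apc_correct,
                                  assemble_input, compute_dca, featurize,
                                  profile_from_msa, sequence_weights,
                                  weighted_frequencies)
from prospr.synthetic_fixtures import make_potts_spec, potts_sample, random_msa

from conftest import make_alignment


class TestSequenceWeights:
    def test_identical_rows_share_weight(self):
        aln = make_alignment(["ACDF"] * 4)
        w = sequence_weights(aln, 0.8)
        np.testing.assert_allclose(w.weights, 0.25)
        assert w.neff == pytest.approx(1.0)

    def test_dissimilar_rows_keep_full_weight(self):
        aln = make_alignment(["AAAA", "WWWW", "CCCC"])
        w = sequence_weights(aln, 0.8)
        np.testing.assert_allclose(w.weights, 1.0)
        assert w.neff == pytest.approx(3.0)

    def test_mixed_redundancy(self):
        # brute force: the two AAAA rows see 2 neighbours each, WWWW sees 1
        aln = make_alignment(["AAAA", "AAAA", "WWWW"])
        w = sequence_weights(aln, 0.8)
        np.testing.assert_allclose(w.weights, [0.5, 0.5, 1.0])

    def test_threshold_validation(self):
        aln = make_alignment(["ACDF"])
        with pytest.raises(ValueError):
            sequence_weights(aln, 1.0)


class TestWeightedFrequencies:
    def test_single_row_indicator(self):
        aln = make_alignment(["AA"])
        w = sequence_weights(aln)
        site, pair = weighted_frequencies(aln, w, pseudocount=0.0)
        assert site[0, 0] == pytest.approx(1.0)  # 'A' is alphabet index 0
        assert site.sum(axis=1) == pytest.approx(1.0)

    def test_pair_marginalizes_to_site(self, small_msa):
        w = sequence_weights(small_msa)
        site, pair = weighted_frequencies(small_msa, w, pseudocount=0.0)
        np.testing.assert_allclose(pair.sum(axis=3)[:, 0, :], site, atol=1e-12)
        np.testing.assert_allclose(pair[3].sum(axis=(1, 2)),
                                   np.ones(small_msa.length), atol=1e-12)

    def test_equal_weight_split(self):
        aln = make_alignment(["A", "C"])
        w = sequence_weights(aln)
        site, _ = weighted_frequencies(aln, w, pseudocount=0.0)
        assert site[0, 0] == pytest.approx(0.5)
        assert site[0, 1] == pytest.approx(0.5)  # 'C' is index 1


class TestApcCorrect:
    def test_rank_one_structure_removed(self, rng):
        a = rng.random(8) + 0.5
        F = np.outer(a, a)
        np.fill_diagonal(F, 0.0)
        corrected = apc_correct(F)
        off = ~np.eye(8, dtype=bool)
        # product structure is background; APC should cancel it (n-1 vs n
        # finite-size effect leaves a small residual)
        assert np.abs(corrected[off]).max() < 0.1 * F[off].max()

    def test_zero_matrix(self):
        np.testing.assert_array_equal(apc_correct(np.zeros((5, 5))),
                                      np.zeros((5, 5)))

    def test_hand_computed_3x3(self):
        F = np.array([[0.0, 2.0, 4.0],
                      [2.0, 0.0, 6.0],
                      [4.0, 6.0, 0.0]])
        rowmean = np.array([3.0, 4.0, 5.0])
        grand = 4.0
        expected = F - np.outer(rowmean, rowmean) / grand
        np.testing.assert_allclose(apc_correct(F), expected)

    def test_requires_square(self):
        with pytest.raises(ValueError):
            apc_correct(np.zeros((3, 4)))


class TestComputeDca:
    def test_channel_count(self, small_msa):
        dca = compute_dca(small_msa)
        assert dca.couplings.shape[2] + 1 == N_DCA_CHANNELS == 442

    def test_constant_columns_give_zero_couplings(self):
        aln = make_alignment(["ACDEFG"] * 5)
        dca = compute_dca(aln)
        L = 6
        off = ~np.eye(L, dtype=bool)
        # zero covariance between sites: inverse is (block) diagonal
        coup = dca.couplings.reshape(L, L, 441)
        assert np.abs(coup[off]).max() < 1e-8
        np.testing.assert_allclose(dca.apc_score, 0.0, atol=1e-8)

    def test_planted_pair_recovery(self):
        spec = make_potts_spec(L=40, n_pairs=8, n_seq=2000, seed=1)
        aln = potts_sample(spec)
        dca = compute_dca(aln)
        iu = np.triu_indices(40, k=5)
        order = np.argsort(-dca.apc_score[iu])[:8]
        top = {(int(iu[0][k]), int(iu[1][k])) for k in order}
        planted = set(map(tuple, spec.planted_pairs))
        assert len(top & planted) >= 6

    def test_row_order_invariance(self, small_msa):
        from prospr.io_formats import Alignment

        perm = np.random.default_rng(7).permutation(small_msa.depth - 1) + 1
        rows = [small_msa.sequences[0]] + \
            [small_msa.sequences[k] for k in perm]
        shuffled = Alignment(query_id="q", sequences=rows)
        a = compute_dca(small_msa)
        b = compute_dca(shuffled)
        np.testing.assert_allclose(a.apc_score, b.apc_score, atol=1e-9)

    def test_apc_score_shrinks_with_regularization(self, small_msa):
        scores = [np.abs(compute_dca(small_msa, shrinkage=s).apc_score).sum()
                  for s in (0.1, 10.0, 1000.0)]
        assert scores[0] > scores[1] > scores[2]

    def test_symmetry_of_blocks(self, small_msa):
        dca = compute_dca(small_msa)
        L = small_msa.length
        blocks = dca.couplings.reshape(L, L, 21, 21)
        np.testing.assert_allclose(blocks[2, 5], blocks[5, 2].T, atol=1e-9)
        np.testing.assert_allclose(dca.apc_score, dca.apc_score.T, atol=1e-12)


class TestProfileFromMsa:
    def test_single_sequence_one_hot(self):
        aln = make_alignment(["ACD"])
        prof = profile_from_msa(aln)
        np.testing.assert_allclose(prof.values[0, :20],
                                   np.eye(20)[0])  # 'A'
        np.testing.assert_allclose(prof.values[2, :20],
                                   np.eye(20)[2])  # 'D'

    def test_emission_mass_excludes_gaps(self):
        aln = make_alignment(["ACD", "A-D", "ACD"])
        prof = profile_from_msa(aln)
        sums = prof.values[:, :20].sum(axis=1)
        assert np.all(sums <= 1.0 + 1e-12)
        assert sums[1] < 1.0  # the gapped column lost mass

    def test_even_split(self):
        aln = make_alignment(["A", "C"])
        prof = profile_from_msa(aln)
        assert prof.values[0, 0] == pytest.approx(0.5)
        assert prof.values[0, 1] == pytest.approx(0.5)


class TestAssembleInput:
    def test_channel_budget(self, small_msa):
        feats = featurize(small_msa)
        assert feats.tensor.shape == (16, 16, N_INPUT_CHANNELS)
        assert feats.tensor.shape[2] == 547

    def test_one_hot_symmetry(self, small_msa):
        x = featurize(small_msa).tensor
        np.testing.assert_array_equal(x[2, 5, CH_ONEHOT_I],
                                      x[5, 2, CH_ONEHOT_J])
        np.testing.assert_array_equal(x[2, 5, CH_ONEHOT_J],
                                      x[5, 2, CH_ONEHOT_I])

    def test_index_channels(self, small_msa):
        x = featurize(small_msa).tensor
        L = small_msa.length
        for i, j in [(0, 0), (3, 11), (15, 2)]:
            assert x[i, j, CH_INDEX_I] == i
            assert x[i, j, CH_INDEX_J] == j

    def test_mask_all_ones_unpadded(self, small_msa):
        x = featurize(small_msa).tensor
        np.testing.assert_array_equal(x[:, :, CH_MASK], 1.0)

    def test_length_mismatch_names_shapes(self, small_msa):
        from prospr.io_formats import HmmProfile

        prof = HmmProfile(values=np.zeros((5, 30)))
        from prospr.featurization import compute_dca

        dca = compute_dca(small_msa)
        with pytest.raises(ValueError, match="5"):
            assemble_input(small_msa, prof, dca)

    def test_subsample_preserves_shapes(self, small_msa):
        from prospr.training import subsample_msa

        sub = subsample_msa(small_msa, 0.5, rng=0)
        full = featurize(small_msa).tensor
        half = featurize(sub).tensor
        assert half.shape == full.shape
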