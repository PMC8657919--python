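import numpy as np
import pytest

from prospr.featurization import featurize
from prospr.labeling import IGNORE
from prospr.network import CropPrediction, DistogramNetwork, tiny_config
from prospr.training import (Checkpoint, CropLabels, CropSpec, LossWeights,
                             SCHEDULES, Schedule, TrainConfig, TrainingDomain,
                             combine_losses, crop_grid, extract_feature_crop,
                             extract_label_crop, lr_at, multicomponent_loss,
                             subsample_msa, train)
from prospr.synthetic_fixtures import random_msa


def coverage_count(crops, L):
    cover = np.zeros((L, L), dtype=int)
    for spec in crops:
        cover[spec.rows, spec.cols] += 1
    return cover


class TestCropGrid:
    def test_l128_c64_four_crops(self):
        crops = crop_grid(128, 64, (0, 0))
        assert len(crops) == 4
        assert {c.origin for c in crops} == {(0, 0), (0, 64), (64, 0), (64, 64)}
        assert all(c.pad == (0, 0, 0, 0) for c in crops)

    def test_identity_when_l_equals_c(self):
        crops = crop_grid(64, 64, (0, 0))
        assert len(crops) == 1
        assert crops[0].origin == (0, 0)

    def test_offset_grid_covers_once_with_padding(self):
        crops = crop_grid(100, 64, (10, 0))
        assert len(crops) == 4  # 2 x 2 grid
        assert any(c.pad != (0, 0, 0, 0) for c in crops)
        np.testing.assert_array_equal(coverage_count(crops, 100), 1)

    @pytest.mark.parametrize("L,c,offset", [
        (20, 7, (3, 5)), (64, 64, (0, 0)), (65, 64, (63, 1)), (10, 16, (0, 9)),
    ])
    def test_coverage_and_nonoverlap_property(self, L, c, offset):
        crops = crop_grid(L, c, offset)
        np.testing.assert_array_equal(coverage_count(crops, L), 1)

    def test_random_offset_reproducible(self):
        a = crop_grid(50, 16, rng=np.random.default_rng(3))
        b = crop_grid(50, 16, rng=np.random.default_rng(3))
        assert a == b

    def test_invalid_crop_size(self):
        with pytest.raises(ValueError):
            crop_grid(10, 0)


class TestCropExtraction:
    def test_padding_zeroes_features_and_mask(self, small_msa):
        feats = featurize(small_msa)
        spec = CropSpec(origin=(10, 0), size=16, pad=(0, 10, 0, 0))
        x = extract_feature_crop(feats, spec)
        assert x.shape == (16, 16, 547)
        assert np.all(x[6:] == 0.0)       # padded rows
        assert np.all(x[:6, :, -1] == 1)  # mask on real cells

    def test_label_padding_is_ignore(self, helix16_labels):
        spec = CropSpec(origin=(10, 10), size=16, pad=(0, 10, 0, 10))
        lbl = extract_label_crop(helix16_labels, spec)
        assert np.all(lbl.dist[6:, :] == IGNORE)
        assert np.all(lbl.aux_i["ss"][6:] == IGNORE)
        assert np.all(lbl.aux_i["ss"][:6] != IGNORE)


class TestSubsampleMsa:
    def test_depth_one_unchanged(self):
        aln = random_msa(8, 1, 0.1, seed=0)
        assert subsample_msa(aln, 0.5, rng=0) is aln

    def test_counting_rule(self):
        aln = random_msa(8, 101, 0.1, seed=0)
        sub = subsample_msa(aln, 0.5, rng=0)
        assert sub.depth == 51
        assert sub.sequences[0] == aln.sequences[0]  # query retained

    def test_same_seed_identical(self):
        aln = random_msa(8, 40, 0.1, seed=0)
        a = subsample_msa(aln, 0.5, rng=7)
        b = subsample_msa(aln, 0.5, rng=7)
        assert a.sequences == b.sequences

    def test_full_fraction_is_identity(self):
        aln = random_msa(8, 20, 0.1, seed=0)
        sub = subsample_msa(aln, 1.0, rng=0)
        assert sorted(sub.sequences) == sorted(aln.sequences)

    def test_invalid_fraction(self):
        aln = random_msa(8, 5, 0.1, seed=0)
        with pytest.raises(ValueError):
            subsample_msa(aln, 0.0)


class TestLoss:
    def test_printed_weights_sum(self):
        # unit cross-entropies weighted 15 + 0.5 + 0.25 + 0.25 + 0.5
        components = {k: 1.0 for k in ("dist", "ss", "phi", "psi", "asa")}
        assert combine_losses(components) == pytest.approx(16.5)

    def test_only_distance_component(self):
        assert combine_losses({"dist": 2.0}) == pytest.approx(30.0)

    def test_perfect_predictions_zero_loss(self):
        c = 4
        rng = np.random.default_rng(0)
        dist_labels = rng.integers(0, 10, (c, c))
        dist = np.eye(10)[dist_labels]
        aux_labels = {k: rng.integers(0, n) * np.ones(c, dtype=int)
                      for k, n in (("ss", 9), ("phi", 37), ("psi", 37),
                                   ("asa", 11))}
        aux = np.concatenate([np.eye(n)[aux_labels[k]]
                              for k, n in (("ss", 9), ("phi", 37),
                                           ("psi", 37), ("asa", 11))], axis=1)
        pred = CropPrediction(dist=dist, aux_i=aux, aux_j=aux)
        labels = CropLabels(dist=dist_labels, aux_i=aux_labels,
                            aux_j=aux_labels)
        assert multicomponent_loss(pred, labels) == pytest.approx(0.0, abs=1e-9)

    def test_all_ignored_component_contributes_zero(self):
        c = 4
        dist = np.full((c, c, 10), 0.1)
        aux = np.full((c, 94), 1 / 94)
        pred = CropPrediction(dist=dist, aux_i=aux, aux_j=aux)
        ig = {k: np.full(c, IGNORE) for k in ("ss", "phi", "psi", "asa")}
        labels = CropLabels(dist=np.zeros((c, c), dtype=int), aux_i=ig,
                            aux_j=ig)
        w = LossWeights()
        expected = w.dist * -np.log(0.1)
        assert multicomponent_loss(pred, labels, w) == pytest.approx(expected)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(dist=-1.0)


class TestLrSchedule:
    @pytest.mark.parametrize("model_id,epoch,expected", [
        ("A", 0, 1e-3), ("A", 4, 1e-3), ("A", 5, 5e-4), ("A", 14, 5e-4),
        ("A", 15, 1e-4), ("A", 100, 1e-4),
        ("B", 9, 1e-3), ("B", 10, 5e-4), ("B", 25, 1e-4),
        ("C", 7, 1e-3), ("C", 8, 5e-4), ("C", 20, 1e-4),
    ])
    def test_printed_decay_tables(self, model_id, epoch, expected):
        assert lr_at(epoch, SCHEDULES[model_id]) == pytest.approx(expected)

    def test_lr_non_increasing(self):
        for s in SCHEDULES.values():
            lrs = [lr_at(e, s) for e in range(40)]
            assert all(b <= a for a, b in zip(lrs, lrs[1:]))

    def test_increasing_schedule_rejected(self):
        with pytest.raises(ValueError):
            Schedule("bad", 1e-3, ((5, 2e-3),))


class TestTrainLoop:
    @pytest.fixture()
    def domain(self, small_msa, helix16_labels):
        return TrainingDomain(alignment=small_msa, labels=helix16_labels,
                              features=featurize(small_msa))

    def test_checkpoints_sorted_and_capped(self, domain):
        model = DistogramNetwork(tiny_config(seed=0))
        cfg = TrainConfig(epochs=4, seed=0, recompute_features=False)
        result = train(model, [domain], cfg)
        losses = [c.val_loss for c in result.checkpoints]
        assert losses == sorted(losses)
        assert len(result.checkpoints) == 3  # min(3, epochs)

    def test_single_epoch_yields_one_checkpoint(self, domain):
        model = DistogramNetwork(tiny_config(seed=0))
        result = train(model, [domain],
                       TrainConfig(epochs=1, seed=0, recompute_features=False))
        assert len(result.checkpoints) == 1

    def test_same_seed_same_first_step_loss(self, domain):
        losses = []
        for _ in range(2):
            model = DistogramNetwork(tiny_config(seed=0))
            result = train(model, [domain],
                           TrainConfig(epochs=1, seed=11,
                                       recompute_features=False))
            losses.append(result.step_losses[0])
        assert losses[0] == losses[1]

    def test_epoch_crops_cover_full_map(self, domain):
        # accumulate the random grids used across epochs: each must tile
        # the full L x L label map exactly once
        rng = np.random.default_rng(5)
        for _ in range(4):
            crops = crop_grid(domain.length, 16, rng=rng)
            np.testing.assert_array_equal(
                coverage_count(crops, domain.length), 1)
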