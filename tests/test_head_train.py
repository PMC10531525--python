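import math

import numpy as np
import pytest

from dtifusion.head_train import (ModelConfig, build_variant, ce_loss, collate,
                                  compute_metrics, evaluate, load_checkpoint,
                                  predict_scores, run_cv, save_checkpoint,
                                  train, FeaturePipeline)
from dtifusion.nn import TrainContext

from oracles import auc_pairwise, mlp_head_loops

CTX = TrainContext.eval()


class TestCeLoss:
    def test_half_probability_is_ln2(self):
        assert ce_loss(1, 0.5) == pytest.approx(math.log(2), abs=1e-12)
        assert ce_loss(0, 0.5) == pytest.approx(math.log(2), abs=1e-12)

    def test_confident_correct_small_loss(self):
        assert ce_loss(1, 0.9) == pytest.approx(-math.log(0.9), abs=1e-12)
        assert ce_loss(0, 1e-9) < 1e-6  # loss -> 0 in the limit

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            ce_loss(1, 1.2)

    def test_nonnegative(self, rng):
        for _ in range(50):
            assert ce_loss(int(rng.integers(0, 2)), float(rng.random())) >= 0.0


class TestComputeMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert (m.auc, m.precision, m.recall) == (1.0, 1.0, 1.0)

    def test_three_of_four_concordant(self):
        m = compute_metrics([0.8, 0.3, 0.5, 0.2], [1, 1, 0, 0])
        assert m.auc == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        m = compute_metrics([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert m.auc == pytest.approx(0.5)

    def test_single_class_fatal(self):
        with pytest.raises(ValueError):
            compute_metrics([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_auc_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        labels = rng.integers(0, 2, size=n)
        labels[0], labels[1] = 0, 1
        scores = np.round(rng.random(n), 2)  # rounding forces some ties
        m = compute_metrics(scores, labels)
        assert m.auc == pytest.approx(auc_pairwise(scores, labels), abs=1e-12)


class TestModelConfig:
    def test_unknown_variant_fatal(self):
        with pytest.raises(ValueError):
            ModelConfig(variant="wo_everything")

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig.from_dict({"learning_rate_typo": 1})

    def test_round_trip(self):
        cfg = ModelConfig(d_model=32, seed=9)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


@pytest.fixture(scope="module")
def fitted(small_dataset, tiny_config=None):
    records, _ = small_dataset
    cfg = ModelConfig(epochs=1, d_model=16, n_heads=2, n_bert_layers=1,
                      n_gat_layers=1, att_pool_layers=1, ntn_k=4, mlp_hidden=16,
                      batch_size=8, seed=11, dtype="float64", dropout=0.0)
    pipeline = FeaturePipeline(cfg).fit(records)
    return records, cfg, pipeline


class TestPredictHead:
    def _model_and_batch(self, fitted):
        records, cfg, pipeline = fitted
        model = build_variant(cfg, pipeline.drug_vocab, pipeline.protein_vocab,
                              np.random.default_rng(0))
        batch = collate(pipeline.transform(records[:4]), dtype=np.float64)
        return model, batch

    def test_zero_output_weights_give_half(self, fitted):
        model, batch = self._model_and_batch(fitted)
        model.head2.weight.data[:] = 0.0
        probs = model(batch, CTX).data
        np.testing.assert_array_equal(probs, 0.5)

    def test_probabilities_strictly_inside_unit_interval(self, fitted):
        model, batch = self._model_and_batch(fitted)
        probs = model(batch, CTX).data
        assert np.all(probs > 0.0) and np.all(probs < 1.0)

    def test_head_matches_loop_oracle(self, fitted):
        model, batch = self._model_and_batch(fitted)
        feats = model.interaction_features(batch, CTX).data
        probs = model(batch, CTX).data
        for i in range(feats.shape[0]):
            want = mlp_head_loops(feats[i], model.head1.weight.data,
                                  model.head2.weight.data)
            assert probs[i] == pytest.approx(want, abs=1e-9)


class TestVariants:
    def test_parameter_count_difference_full_vs_wo_ntn(self, fitted):
        records, cfg, pipeline = fitted
        full = build_variant(cfg, pipeline.drug_vocab, pipeline.protein_vocab,
                             np.random.default_rng(0))
        cfg_wo = ModelConfig.from_dict({**cfg.to_dict(), "variant": "wo_ntn"})
        wo = build_variant(cfg_wo, pipeline.drug_vocab, pipeline.protein_vocab,
                           np.random.default_rng(0))
        k, d = cfg.ntn_k, cfg.d_graph
        ntn_params = k * d * d + k * 2 * d + k
        head_diff = k * cfg.mlp_hidden  # head input shrinks by K columns
        assert full.n_parameters() - wo.n_parameters() == ntn_params + head_diff

    def test_wo_att_output_invariant_to_atom_permutation(self, fitted):
        records, cfg, pipeline = fitted
        cfg_wo = ModelConfig.from_dict({**cfg.to_dict(), "variant": "wo_att"})
        model = build_variant(cfg_wo, pipeline.drug_vocab, pipeline.protein_vocab,
                              np.random.default_rng(0))
        pair = pipeline.transform(records[:1])
        batch = collate(pair, dtype=np.float64)
        p0 = model(batch, CTX).data
        n = pair[0].graph.n_atom
        perm = np.random.default_rng(1).permutation(n)
        batch2 = {k: v.copy() for k, v in batch.items()}
        batch2["atom_ids"][0, :n] = batch["atom_ids"][0, :n][perm]
        batch2["adjacency"][0, :n, :n] = batch["adjacency"][0, :n, :n][np.ix_(perm, perm)]
        p1 = model(batch2, CTX).data
        np.testing.assert_allclose(p1, p0, atol=1e-8)

    @pytest.mark.parametrize("variant", ["full", "wo_ntn_itm", "wo_itm", "wo_ntn", "wo_att"])
    def test_every_variant_trains_one_epoch(self, small_dataset, variant):
        records, _ = small_dataset
        cfg = ModelConfig(epochs=1, d_model=16, n_heads=2, n_bert_layers=1,
                          n_gat_layers=1, att_pool_layers=1, ntn_k=4,
                          mlp_hidden=16, batch_size=16, seed=3, variant=variant)
        result = train(records[:32], cfg)
        assert len(result.history) == 1 and np.isfinite(result.history[0])


class TestTrainingProtocol:
    def test_same_seed_identical_histories_and_metrics(self, small_dataset):
        records, _ = small_dataset
        cfg = ModelConfig(epochs=2, d_model=16, n_heads=2, n_bert_layers=1,
                          n_gat_layers=1, att_pool_layers=1, ntn_k=4,
                          mlp_hidden=16, batch_size=16, seed=21)
        r1 = train(records, cfg)
        r2 = train(records, cfg)
        assert r1.history == r2.history
        m1 = evaluate(r1, records)
        m2 = evaluate(r2, records)
        assert m1 == m2

    def test_initial_loss_near_ln2(self, small_dataset):
        records, _ = small_dataset
        cfg = ModelConfig(epochs=1, d_model=16, n_heads=2, n_bert_layers=1,
                          n_gat_layers=1, att_pool_layers=1, ntn_k=4,
                          mlp_hidden=16, batch_size=64, seed=5)
        result = train(records, cfg)
        assert abs(result.history[0] - math.log(2)) < 0.15

    def test_run_cv_deterministic(self, small_dataset):
        records, _ = small_dataset
        cfg = ModelConfig(epochs=1, d_model=16, n_heads=2, n_bert_layers=1,
                          n_gat_layers=1, att_pool_layers=1, ntn_k=4,
                          mlp_hidden=16, batch_size=16, seed=13)
        a = run_cv(records, cfg, k=2)
        b = run_cv(records, cfg, k=2)
        assert a.mean == b.mean
        assert a.fold_metrics == b.fold_metrics


class TestCheckpoint:
    def test_round_trip_scores_identical(self, small_dataset, tmp_path):
        records, _ = small_dataset
        cfg = ModelConfig(epochs=1, d_model=16, n_heads=2, n_bert_layers=1,
                          n_gat_layers=1, att_pool_layers=1, ntn_k=4,
                          mlp_hidden=16, batch_size=16, seed=2)
        result = train(records[:24], cfg)
        before = predict_scores(result, records[24:32])
        path = tmp_path / "model.npz"
        save_checkpoint(result, path)
        loaded = load_checkpoint(path)
        after = predict_scores(loaded, records[24:32])
        np.testing.assert_array_equal(before, after)
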