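import itertools

import numpy as np
import pytest

from ktgel import (ELMConfig, GOAParams, LabeledFeatureSet, WeightMask,
                   apply_weight_mask, derive_pruning, hidden_output,
                   init_random_layer, masked_fitness, model_from_mask, predict,
                   predict_pruned, train_elm, train_ktgel)
from ktgel.elm import one_hot, solve_beta
from ktgel.pruning import _rle_decode, _rle_encode, load_pruned, save_pruned
from ktgel.wrapper import cv_accuracy


class TestApplyWeightMask:
    def test_identity(self, rng):
        W = rng.normal(size=(4, 5))
        assert np.array_equal(apply_weight_mask(W, np.ones((4, 5), dtype=np.uint8)), W)

    def test_zero(self, rng):
        W = rng.normal(size=(4, 5))
        out = apply_weight_mask(W, np.zeros((4, 5), dtype=np.uint8))
        assert not out.any()

    def test_single_bit_cleared(self, rng):
        W = rng.normal(size=(3, 3)) + 1.0
        bits = np.ones((3, 3), dtype=np.uint8)
        bits[1, 2] = 0
        out = apply_weight_mask(W, bits)
        assert np.sum(out != W) == 1 and out[1, 2] == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            apply_weight_mask(np.ones((2, 3)), np.ones((3, 2), dtype=np.uint8))


class TestDerivePruning:
    def test_dead_column(self):
        bits = np.ones((4, 5), dtype=np.uint8)
        bits[:, 2] = 0
        nodes, feats = derive_pruning(bits)
        assert nodes.tolist() == [0, 1, 3, 4]
        assert feats.tolist() == [0, 1, 2, 3]

    def test_dead_row_eliminates_feature(self):
        bits = np.ones((4, 5), dtype=np.uint8)
        bits[1, :] = 0
        nodes, feats = derive_pruning(bits)
        assert nodes.tolist() == [0, 1, 2, 3, 4]
        assert feats.tolist() == [0, 2, 3]

    def test_matches_brute_force_scan(self, rng):
        for _ in range(200):
            bits = (rng.random((6, 7)) < 0.3).astype(np.uint8)
            nodes, feats = derive_pruning(bits)
            brute_nodes = [j for j in range(7) if any(bits[i, j] for i in range(6))]
            brute_feats = [i for i in range(6) if any(bits[i, j] for j in range(7))]
            assert nodes.tolist() == brute_nodes
            assert feats.tolist() == brute_feats

    def test_conservation(self, rng):
        bits = (rng.random((5, 8)) < 0.5).astype(np.uint8)
        m = WeightMask(bits)
        assert m.n_kept + np.sum(bits == 0) == 40


class TestMaskedFitness:
    def test_all_ones_equals_plain_cv(self, three_class):
        cfg = ELMConfig(n_hidden=25, seed=8)
        W, b = init_random_layer(three_class.n_features, 25, 8)
        ones = np.ones((three_class.n_features, 25), dtype=np.uint8)
        assert masked_fitness(ones, three_class, W, b, cfg, 3) == \
            cv_accuracy(three_class, cfg, 3)

    def test_all_zero_scores_zero(self, three_class):
        W, b = init_random_layer(4, 10, 0)
        z = np.zeros((4, 10), dtype=np.uint8)
        assert masked_fitness(z, three_class, W, b, ELMConfig(10, 0), 3) == 0.0

    def test_masked_entries_do_not_matter(self, three_class, rng):
        cfg = ELMConfig(n_hidden=10, seed=1)
        W, b = init_random_layer(4, 10, 1)
        bits = (rng.random((4, 10)) < 0.5).astype(np.uint8)
        bits[0, 0] = 1   # keep at least one weight
        base = masked_fitness(bits, three_class, W, b, cfg, 3)
        W2 = W.copy()
        W2[bits == 0] = 1e6
        assert masked_fitness(bits, three_class, W2, b, cfg, 3) == base

    def test_agrees_with_reduced_architecture_rebuild(self, tiny_instance):
        """Every 2x3 mask scores like an ELM rebuilt on the reduced layer."""
        cfg = ELMConfig(n_hidden=3, seed=42)
        W, b = init_random_layer(2, 3, 42)
        from ktgel.evaluation import kfold_stratified
        fold = kfold_stratified(tiny_instance.y, 4, cfg.seed)
        for combo in itertools.product([0, 1], repeat=6):
            bits = np.array(combo, dtype=np.uint8).reshape(2, 3)
            got = masked_fitness(bits, tiny_instance, W, b, cfg, 4)
            if not bits.any():
                assert got == 0.0
                continue
            act = np.flatnonzero(bits.any(axis=0))
            Wm = (W * bits)[:, act]
            accs = []
            for f in np.unique(fold):
                val = fold == f
                H = hidden_output(tiny_instance.X, Wm, b[act])
                beta = solve_beta(H[~val], one_hot(tiny_instance.y, 2)[~val])
                pred = np.argmax(H[val] @ beta, axis=1) + 1
                accs.append(np.mean(pred == tiny_instance.y[val]))
            assert got == pytest.approx(np.mean(accs), abs=1e-12)


class TestTrainKtgel:
    def test_zero_iterations_returns_all_ones_model(self, three_class):
        cfg = ELMConfig(n_hidden=12, seed=6)
        goa = GOAParams(pop_size=2, max_iter=0, k=2, seed=6)
        model, result = train_ktgel(three_class, 12, goa, cfg, folds=3)
        if model.mask.bits.all():
            plain = train_elm(three_class, 12, seed=6)
            assert np.array_equal(predict_pruned(model, three_class.X),
                                  predict(plain, three_class.X))
            assert np.allclose(model.base.beta, plain.beta)
        else:   # a random agent beat the all-ones agent in the initial pool
            ones_fit = masked_fitness(np.ones((4, 12), dtype=np.uint8), three_class,
                                      *init_random_layer(4, 12, 6), cfg, 3)
            assert model.fitness >= ones_fit

    def test_result_has_active_node(self, three_class):
        model, _ = train_ktgel(three_class, 6, GOAParams(5, 3, seed=1),
                               ELMConfig(6, 1), folds=3)
        assert model.n_active_nodes >= 1
        assert model.base.n_hidden == model.n_active_nodes

    def test_benchmark_close_to_unpruned(self, rng):
        cents = rng.uniform(-1, 1, (3, 6))
        y = np.repeat([1, 2, 3], 40)
        X = cents[y - 1] + rng.normal(0, 0.35, (120, 6))
        Xt = cents[y - 1] + rng.normal(0, 0.35, (120, 6))
        data = LabeledFeatureSet(X, y)
        plain = train_elm(data, 30, seed=2)
        acc_plain = np.mean(predict(plain, Xt) == y)
        model, _ = train_ktgel(data, 30, GOAParams(10, 12, k=3, seed=2),
                               ELMConfig(30, 2), folds=3)
        acc_pruned = np.mean(predict_pruned(model, Xt) == y)
        assert acc_pruned >= acc_plain - 0.05

    def test_history_monotone(self, three_class):
        _, result = train_ktgel(three_class, 8, GOAParams(6, 10, seed=3),
                                ELMConfig(8, 3), folds=3)
        assert np.all(np.diff(result.history) >= 0)


class TestPredictPruned:
    def test_compact_equals_masked_full(self, three_class, rng):
        cfg = ELMConfig(n_hidden=9, seed=13)
        W, b = init_random_layer(4, 9, 13)
        bits = (rng.random((4, 9)) < 0.6).astype(np.uint8)
        bits[0, 0] = 1
        model = model_from_mask(three_class, W, b, WeightMask(bits), cfg)
        # non-compacted masked model with identical beta rows
        Wm = W * bits
        H_full = hidden_output(three_class.X, Wm, b)
        beta_full = np.zeros((9, 3))
        beta_full[model.active_nodes] = model.base.beta
        # dead nodes contribute a constant g(b_j) column; beta row is zero there
        X_new = rng.normal(size=(1000, 4))
        compact = predict_pruned(model, X_new)
        H_new = hidden_output(X_new, Wm[:, model.active_nodes], b[model.active_nodes])
        full = np.argmax(H_new @ model.base.beta, axis=1) + 1
        assert np.array_equal(compact, full)

    def test_eliminated_feature_content_irrelevant(self, three_class, rng):
        cfg = ELMConfig(n_hidden=5, seed=3)
        W, b = init_random_layer(4, 5, 3)
        bits = np.ones((4, 5), dtype=np.uint8)
        bits[2, :] = 0   # eliminate feature 3
        model = model_from_mask(three_class, W, b, WeightMask(bits), cfg)
        X = rng.normal(size=(50, 4))
        base = predict_pruned(model, X)
        X2 = X.copy()
        X2[:, 2] = rng.normal(size=50) * 100
        assert np.array_equal(predict_pruned(model, X2), base)

    def test_all_ones_matches_plain_elm(self, three_class):
        cfg = ELMConfig(n_hidden=7, seed=21)
        W, b = init_random_layer(4, 7, 21)
        model = model_from_mask(three_class, W, b,
                                WeightMask(np.ones((4, 7), dtype=np.uint8)), cfg)
        plain = train_elm(three_class, 7, seed=21)
        assert np.array_equal(predict_pruned(model, three_class.X),
                              predict(plain, three_class.X))


class TestPrunedSerialization:
    def test_rle_roundtrip(self, rng):
        for _ in range(50):
            bits = (rng.random(rng.integers(1, 64)) < 0.5).astype(np.uint8)
            assert np.array_equal(_rle_decode(_rle_encode(bits), bits.size), bits)

    def test_save_load(self, three_class, tmp_path, rng):
        cfg = ELMConfig(n_hidden=6, seed=17)
        W, b = init_random_layer(4, 6, 17)
        bits = (rng.random((4, 6)) < 0.7).astype(np.uint8)
        bits[0, 0] = 1
        model = model_from_mask(three_class, W, b, WeightMask(bits), cfg, fitness=0.5)
        p = tmp_path / "pruned.json"
        save_pruned(model, p)
        loaded = load_pruned(p)
        assert np.array_equal(loaded.mask.bits, model.mask.bits)
        assert np.array_equal(loaded.active_nodes, model.active_nodes)
        X = rng.normal(size=(20, 4))
        assert np.array_equal(predict_pruned(loaded, X), predict_pruned(model, X))
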