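import numpy as np
import pytest

from tfinfluence.exceptions import ConfigError, ContractError, DomainError, LeakageError
from tfinfluence.model import (
    Dataset,
    ModelConfig,
    _backward,
    _bce_loss,
    _forward,
    build_model,
    evaluate_heldout,
    load_checkpoint,
    predict,
    predict_labels,
    save_checkpoint,
    tokenize,
    train,
)
from tfinfluence.preprocess import ModelInputTensor, ProteinLabelMatrix

N_GENES, N_PROTEINS = 12, 4
GENES = [f"g{i:02d}" for i in range(N_GENES)]
PROTS = [f"p{i}" for i in range(N_PROTEINS)]
TF_FLAG = np.array([1.0] * 3 + [0.0] * (N_GENES - 3))

TINY = ModelConfig(d_model=4, ffn_hidden=6, max_epochs=8, batch_size=4,
                   n_aug=6, early_stop_patience=4, seed=0)


def _tensor(n_samples, seed=0, prefix="s"):
    rng = np.random.default_rng(seed)
    return ModelInputTensor(
        GENES, [f"{prefix}{j}" for j in range(n_samples)],
        rng.random((N_GENES, n_samples)), TF_FLAG,
    )


def _labels(tensor, seed=0):
    rng = np.random.default_rng(seed + 100)
    vals = rng.random((N_PROTEINS, tensor.n_samples))
    return ProteinLabelMatrix(PROTS, list(tensor.sample_ids),
                              (vals >= 0.6).astype(float), 0.6, vals)


def _dataset(n_samples, seed=0, timepoint="estrus", prefix="s"):
    tensor = _tensor(n_samples, seed, prefix)
    return Dataset(tensor, _labels(tensor, seed), [timepoint] * n_samples)


class TestBuild:
    def test_same_seed_identical_parameters(self):
        a = build_model(TINY, GENES, PROTS, TF_FLAG)
        b = build_model(TINY, GENES, PROTS, TF_FLAG)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_head_emits_one_logit_per_protein(self):
        m = build_model(TINY, GENES, PROTS, TF_FLAG)
        logits, _ = _forward(m.params, m.config, np.zeros((2, N_GENES, 2)))
        assert logits.shape == (2, N_PROTEINS)

    def test_multi_head_override_warns_but_builds(self):
        cfg = ModelConfig(d_model=4, n_heads=2)
        with pytest.warns(UserWarning, match="single-head"):
            m = build_model(cfg, GENES, PROTS, TF_FLAG)
        assert m.params["Wq0"].shape == (4, 4)

    def test_too_small_width_rejected(self):
        with pytest.raises(ConfigError):
            build_model(ModelConfig(d_model=1), GENES, PROTS, TF_FLAG)


class TestGradients:
    @pytest.mark.parametrize("mlp_hidden,n_heads,n_layers",
                             [(0, 1, 1), (5, 1, 1), (0, 2, 2)])
    def test_backward_matches_finite_differences(self, mlp_hidden, n_heads, n_layers):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = ModelConfig(d_model=6, ffn_hidden=5, mlp_hidden=mlp_hidden,
                              n_heads=n_heads, n_layers=n_layers, seed=2)
            m = build_model(cfg, GENES[:7], PROTS[:3], TF_FLAG[:7])
        rng = np.random.default_rng(0)
        F = rng.random((3, 7, 2))
        y = rng.integers(0, 2, (3, 3)).astype(float)
        logits, cache = _forward(m.params, cfg, F)
        _, dlog = _bce_loss(logits, y)
        grads = _backward(m.params, cfg, cache, dlog)
        eps = 1e-6
        for key, p in m.params.items():
            flat_idx = rng.integers(0, p.size, size=min(3, p.size))
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape) if p.shape else ()
                orig = p[idx]
                p[idx] = orig + eps
                lp = _bce_loss(_forward(m.params, cfg, F, want_cache=False)[0], y)[0]
                p[idx] = orig - eps
                lm = _bce_loss(_forward(m.params, cfg, F, want_cache=False)[0], y)[0]
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[key][idx] == pytest.approx(num, abs=1e-6, rel=1e-4), key


class TestTokenize:
    def test_sequence_length_equals_gene_count(self):
        m = build_model(TINY, GENES, PROTS, TF_FLAG)
        toks = tokenize(m, _tensor(3))
        assert toks.shape == (3, N_GENES, TINY.d_model)

    def test_permuted_genes_restore_canonical_tokens(self):
        m = build_model(TINY, GENES, PROTS, TF_FLAG)
        tensor = _tensor(2, seed=5)
        perm = np.random.default_rng(1).permutation(N_GENES)
        shuffled = ModelInputTensor(
            [tensor.gene_ids[i] for i in perm], list(tensor.sample_ids),
            tensor.expression[perm], tensor.tf_flag[perm],
        )
        np.testing.assert_allclose(tokenize(m, tensor), tokenize(m, shuffled))

    def test_zero_expression_non_tf_token_is_identity_embedding(self):
        m = build_model(TINY, GENES, PROTS, TF_FLAG)
        tensor = ModelInputTensor(GENES, ["s0"], np.zeros((N_GENES, 1)), TF_FLAG)
        toks = tokenize(m, tensor)[0]
        # non-TF gene with zero expression projects (0, 0) -> only E remains
        non_tf = np.flatnonzero(TF_FLAG == 0)
        np.testing.assert_allclose(toks[non_tf], m.params["E"][non_tf])

    def test_gene_set_mismatch_is_contract_error(self):
        m = build_model(TINY, GENES, PROTS, TF_FLAG)
        bad = ModelInputTensor(["other"], ["s0"], np.zeros((1, 1)), np.zeros(1))
        with pytest.raises(ContractError):
            tokenize(m, bad)


class TestTrain:
    def test_seeded_training_is_reproducible(self):
        ds = _dataset(8, seed=3)
        metrics = []
        for _ in range(2):
            m = build_model(TINY, GENES, PROTS, TF_FLAG)
            m = train(m, ds)
            metrics.append(m.history)
        assert metrics[0] == metrics[1]

    def test_heldout_timepoint_in_training_fails_hard(self):
        tensor = _tensor(4)
        ds = Dataset(tensor, _labels(tensor),
                     ["estrus", "dpc0.5", "dpc2.5", "dpc1.5"])
        m = build_model(TINY, GENES, PROTS, TF_FLAG)
        with pytest.raises(LeakageError):
            train(m, ds)

    def test_single_sample_rejected(self):
        ds = _dataset(1)
        m = build_model(TINY, GENES, PROTS, TF_FLAG)
        with pytest.raises(DomainError):
            train(m, ds)

    def test_history_records_train_and_val_loss(self):
        m = train(build_model(TINY, GENES, PROTS, TF_FLAG), _dataset(8))
        assert m.history
        assert {"epoch", "train_loss", "val_loss"} <= set(m.history[0])


class TestPredict:
    def _trained(self):
        m = build_model(TINY, GENES, PROTS, TF_FLAG)
        return train(m, _dataset(8, seed=1))

    def test_probabilities_in_unit_interval(self):
        m = self._trained()
        probs = predict(m, _tensor(5, seed=9))
        assert probs.shape == (N_PROTEINS, 5)
        assert np.isfinite(probs).all()
        assert probs.min() >= 0 and probs.max() <= 1

    def test_label_is_probability_at_least_half(self):
        m = self._trained()
        tensor = _tensor(4, seed=2)
        np.testing.assert_array_equal(
            predict_labels(m, tensor), (predict(m, tensor) >= 0.5).astype(float)
        )

    def test_checkpoint_round_trip_identical_predictions(self, tmp_path):
        m = self._trained()
        path = tmp_path / "model.ckpt"
        save_checkpoint(m, path)
        back = load_checkpoint(path)
        tensor = _tensor(3, seed=4)
        np.testing.assert_array_equal(predict(m, tensor), predict(back, tensor))
        assert back.gene_ids == m.gene_ids
        assert back.trained_sample_ids == m.trained_sample_ids

    def test_mismatched_gene_set_rejected(self):
        m = self._trained()
        bad = ModelInputTensor(["x"], ["s0"], np.zeros((1, 1)), np.zeros(1))
        with pytest.raises(ContractError):
            predict(m, bad)


class TestEvaluateHeldout:
    def _trained(self):
        return train(build_model(TINY, GENES, PROTS, TF_FLAG), _dataset(8, seed=1))

    def test_confusion_counts_cover_every_pair(self):
        m = self._trained()
        ds = _dataset(5, seed=7, timepoint="dpc2.5", prefix="h")
        report = evaluate_heldout(m, ds)
        assert sum(report.confusion.values()) == N_PROTEINS * 5
        assert "dpc2.5" in report.split_description
        for agg in (report.micro, report.macro):
            for v in agg.values():
                assert 0.0 <= v <= 1.0

    def test_perfect_predictor_scores_one(self):
        m = self._trained()
        ds = _dataset(4, seed=8, timepoint="dpc2.5", prefix="h")
        # overwrite labels with the model's own predictions
        preds = predict_labels(m, ds.tensor)
        ds.labels.labels = preds
        report = evaluate_heldout(m, ds)
        assert report.micro["accuracy"] == 1.0
        assert report.micro["f1"] in (1.0, 0.0)  # 0.0 iff no positive predicted

    def test_wrong_timepoint_rejected(self):
        m = self._trained()
        with pytest.raises(DomainError):
            evaluate_heldout(m, _dataset(3, timepoint="dpc1.5", prefix="h"))

    def test_sample_overlap_with_training_is_leakage(self):
        m = self._trained()
        ds = _dataset(8, seed=1, timepoint="dpc2.5")  # same "s*" ids as training
        with pytest.raises(LeakageError):
            evaluate_heldout(m, ds)


class TestChannelIsolation:
    def test_tf_flag_shuffle_is_inert_for_flag_blind_model(self):
        """A model trained with the TF-indicator channel zeroed must give
        identical predictions when that channel is shuffled at input."""
        tensor = _tensor(8, seed=3)
        blind = ModelInputTensor(GENES, list(tensor.sample_ids),
                                 tensor.expression, np.zeros(N_GENES))
        ds = Dataset(blind, _labels(blind, 3), ["estrus"] * 8)
        m = train(build_model(TINY, GENES, PROTS, np.zeros(N_GENES)), ds)
        test = _tensor(4, seed=11, prefix="t")
        zeroed = ModelInputTensor(GENES, list(test.sample_ids),
                                  test.expression, np.zeros(N_GENES))
        shuffled = ModelInputTensor(GENES, list(test.sample_ids),
                                    test.expression, np.zeros(N_GENES))
        np.testing.assert_array_equal(predict(m, zeroed), predict(m, shuffled))
        # and the flag channel does matter for a model trained with real flags
        m2 = train(build_model(TINY, GENES, PROTS, TF_FLAG), _dataset(8, seed=3))
        flagged = ModelInputTensor(GENES, list(test.sample_ids), test.expression, TF_FLAG)
        assert not np.array_equal(predict(m2, zeroed), predict(m2, flagged))
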