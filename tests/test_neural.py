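import math

import numpy as np
import pytest

from genelm import (
    Corpus,
    GeneRecord,
    NeuralLMConfig,
    SelectionRule,
    TrainingHistory,
    build_model,
    config_grid,
    corpus_perplexity,
    count_parameters,
    entropy_rate,
    fit_ngram,
    generate_corpus,
    neural_perplexity,
    next_token_prob,
    random_sim_spec,
    restore_checkpoint,
    select_checkpoint,
    split_corpus,
    train,
)
from genelm.data_io import SplitSpec
from genelm.neural import VOCAB, _embedding_param_count, encode
from genelm._autograd import Tensor, masked_nll
from conftest import make_corpus


def tiny_cfg(arch, **kw):
    base = dict(
        architecture=arch,
        embedding_dim=8,
        num_layers=1,
        hidden_dim=12,
        ff_dim=16,
        num_heads=2,
        context_length=40,
        epochs=1,
        seed=0,
    )
    base.update(kw)
    return NeuralLMConfig(**base)


class TestBuildModel:
    @pytest.mark.parametrize("arch", ["lstm", "transformer"])
    def test_forward_distributions_normalize(self, arch):
        model = build_model(tiny_cfg(arch))
        ids = np.array([encode("ACGT"), encode("TTAA")])
        logits = model.forward(ids).data
        probs = np.exp(logits - logits.max(-1, keepdims=True))
        probs /= probs.sum(-1, keepdims=True)
        np.testing.assert_allclose(probs.sum(-1), 1.0, atol=1e-12)

    def test_transformer_causality(self):
        """Perturbing a future token never changes earlier predictions."""
        model = build_model(tiny_cfg("transformer", seed=3))
        rng = np.random.default_rng(0)
        for k, p in model.params.items():  # non-trivial weights everywhere
            if k.startswith(("head", "b0.b", "lnf.b", "b0.ln")) is False:
                p.data = rng.normal(0, 0.3, p.data.shape)
        ids = np.array([encode("ACGTACGT")])
        base = model.forward(ids).data.copy()
        for t in range(1, ids.shape[1]):
            perturbed = ids.copy()
            perturbed[0, t] = (perturbed[0, t] % 6) + 1
            out = model.forward(perturbed).data
            np.testing.assert_array_equal(out[0, : t], base[0, : t])

    @pytest.mark.parametrize("arch", ["lstm", "transformer"])
    def test_seeded_initialization_reproducible(self, arch):
        a = build_model(tiny_cfg(arch, seed=11))
        b = build_model(tiny_cfg(arch, seed=11))
        c = build_model(tiny_cfg(arch, seed=12))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k].data, b.params[k].data)
        assert any(not np.array_equal(a.params[k].data, c.params[k].data) for k in a.params)

    def test_heads_must_divide_embedding_dim(self):
        with pytest.raises(ValueError, match="heads"):
            tiny_cfg("transformer", embedding_dim=10, num_heads=3)


class TestParameterCount:
    def test_embedding_layer_closed_form(self):
        # token embedding 7x8 plus positional embedding 16x8
        assert _embedding_param_count(7, 8, 16) == 184

    @pytest.mark.parametrize("arch", ["lstm", "transformer"])
    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_equals_instantiated_model(self, arch, seed):
        rng = np.random.default_rng(seed)
        heads = int(rng.choice([1, 2, 4]))
        cfg = tiny_cfg(
            arch,
            embedding_dim=int(rng.integers(1, 6)) * heads * 2,
            num_layers=int(rng.integers(1, 4)),
            hidden_dim=int(rng.integers(4, 40)),
            ff_dim=int(rng.integers(4, 64)),
            num_heads=heads,
            context_length=int(rng.integers(8, 64)),
        )
        assert count_parameters(cfg) == build_model(cfg).num_params()

    def test_count_strictly_increases_with_width(self):
        small = tiny_cfg("lstm", hidden_dim=16)
        big = tiny_cfg("lstm", hidden_dim=32)
        assert count_parameters(big) > count_parameters(small)


class TestTraining:
    def test_one_epoch_returns_one_history_entry(self):
        corpus = make_corpus(["ACGT"] * 10)
        cfg = tiny_cfg("lstm", epochs=1)
        history = train(build_model(cfg), corpus, corpus, cfg)
        assert len(history.epochs) == 1
        assert len(history.checkpoints) == 1

    def test_sequence_longer_than_context_errors(self):
        corpus = make_corpus(["A" * 50])
        cfg = tiny_cfg("lstm", context_length=40)
        with pytest.raises(ValueError, match="context_length"):
            train(build_model(cfg), corpus, corpus, cfg)

    def test_training_is_reproducible(self):
        corpus = make_corpus(["ACGTAC", "GGTTAA", "CAGTCA", "TTTTCC"] * 3)
        cfg = tiny_cfg("lstm", epochs=2, learning_rate=5e-3)
        h1 = train(build_model(cfg), corpus, corpus, cfg, keep_checkpoints=False)
        h2 = train(build_model(cfg), corpus, corpus, cfg, keep_checkpoints=False)
        assert h1.epochs == h2.epochs

    @pytest.mark.parametrize("arch,epochs,lr", [("lstm", 300, 1e-2), ("transformer", 300, 3e-3)])
    def test_overfitting_one_record_drives_perplexity_to_one(self, arch, epochs, lr):
        corpus = make_corpus(["ACGTACGTACGTACGGGTACAT"])
        cfg = tiny_cfg(
            arch, embedding_dim=16, hidden_dim=32, ff_dim=32, context_length=32,
            epochs=epochs, learning_rate=lr, batch_size=1,
        )
        history = train(build_model(cfg), corpus, corpus, cfg, keep_checkpoints=False)
        assert history.epochs[-1][0] < 1.2

    def test_restored_checkpoint_reproduces_recorded_perplexity(self):
        corpus = make_corpus(["ACGTAC", "GGTTAA", "CAGTCA"])
        cfg = tiny_cfg("lstm", epochs=3, learning_rate=5e-3)
        model = build_model(cfg)
        history = train(model, corpus, corpus, cfg)
        restore_checkpoint(model, history, 1)
        assert neural_perplexity(model, corpus) == pytest.approx(history.epochs[1][0])


class TestSelectCheckpoint:
    def test_only_qualifying_epoch_wins(self):
        h = TrainingHistory(epochs=[(3.30, 3.50), (3.40, 3.41)])
        assert select_checkpoint(h, SelectionRule(0.02)) == 1

    def test_best_validation_among_qualifying(self):
        h = TrainingHistory(epochs=[(3.30, 3.31), (3.27, 3.28), (3.10, 3.50)])
        assert select_checkpoint(h, SelectionRule(0.02)) == 1

    def test_fallback_to_closest_gap(self, caplog):
        h = TrainingHistory(epochs=[(3.0, 3.5), (3.0, 3.2)])
        with caplog.at_level("WARNING"):
            assert select_checkpoint(h, SelectionRule(0.02)) == 1
        assert "no epoch satisfies" in caplog.text


class TestPerplexity:
    @pytest.mark.parametrize("arch", ["lstm", "transformer"])
    def test_untrained_model_is_uniform_over_vocabulary(self, arch):
        corpus = make_corpus(["ACGT", "GGTTAACC", "T"])
        ppl = neural_perplexity(build_model(tiny_cfg(arch)), corpus)
        assert ppl == pytest.approx(len(VOCAB), rel=0.02)

    def test_identical_calls_identical_values(self):
        corpus = make_corpus(["ACGTA", "GGTT"])
        model = build_model(tiny_cfg("lstm"))
        assert neural_perplexity(model, corpus) == neural_perplexity(model, corpus)

    def test_matches_ngram_convention_when_emitting_ngram_conditionals(self):
        """A 'neural' model whose softmax equals a Laplace bigram's conditionals
        must report exactly the n-gram corpus perplexity."""
        corpus = make_corpus(["ACG", "GGTA", "CAT"])
        ngram = fit_ngram(corpus, N=2, smoothing="laplace")

        class NgramLogits:
            config = tiny_cfg("lstm", context_length=64)

            def forward(self, ids):
                B, T = ids.shape
                logits = np.full((B, T, len(VOCAB)), -1e30)
                for b in range(B):
                    for t in range(T):
                        prev = VOCAB[ids[b, t]]
                        if prev == "_":
                            logits[b, t, :] = 0.0
                            continue
                        ctx = (prev,)
                        for v, tok in enumerate(VOCAB):
                            if tok in ngram.predictive_vocab:
                                p = next_token_prob(ngram, ctx, tok)
                                logits[b, t, v] = math.log(p) if p > 0 else -1e30
                return Tensor(logits)

        assert neural_perplexity(NgramLogits(), corpus, batch_size=2) == pytest.approx(
            corpus_perplexity(ngram, corpus), rel=1e-6
        )


class TestLearningSignal:
    def test_both_architectures_approach_entropy_rate_bound(self):
        """On an order-2 Markov corpus both LMs beat the unigram and land
        within 5% of exp(entropy rate)."""
        spec = random_sim_spec(2, concentration=0.8, seed=11, end_prob=0.02, n_records=2000, max_len=100)
        corpus = generate_corpus(spec)
        bound = math.exp(entropy_rate(spec))
        tr, va, te = split_corpus(corpus, SplitSpec(seed=1))
        train_c = Corpus(tr.records + va.records)  # 80/20 train/validation
        val_c = te
        unigram_ppl = corpus_perplexity(fit_ngram(train_c, 1, "laplace"), val_c)
        configs = {
            "lstm": NeuralLMConfig(
                architecture="lstm", embedding_dim=24, hidden_dim=48, context_length=104,
                epochs=10, learning_rate=1e-2, lr_decay=0.2, batch_size=32, seed=4,
            ),
            "transformer": NeuralLMConfig(
                architecture="transformer", embedding_dim=16, num_layers=1, ff_dim=32,
                num_heads=2, context_length=104, epochs=45, learning_rate=3e-3,
                lr_decay=0.2, batch_size=32, seed=4,
            ),
        }
        for arch, cfg in configs.items():
            history = train(build_model(cfg), train_c, val_c, cfg, keep_checkpoints=False)
            best_val = min(v for _, v in history.epochs)
            assert best_val < unigram_ppl, arch
            assert best_val <= 1.05 * bound, (arch, best_val, bound)


def test_config_grid_is_cartesian():
    grid = config_grid("lstm", hidden_dim=[16, 32], learning_rate=[1e-3, 1e-2, 1e-1])
    assert len(grid) == 6
    assert {(c.hidden_dim, c.learning_rate) for c in grid} == {
        (h, lr) for h in (16, 32) for lr in (1e-3, 1e-2, 1e-1)
    }
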