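import math
from collections import Counter

import edlib
import numpy as np
import pytest
from scipy import stats

from genelm import (
    MutationConfig,
    MutationOp,
    MutationPair,
    apply_mutation,
    build_mutation_dataset,
    corpus_perplexity,
    discriminate,
    evaluate_accuracy,
    fit_ngram,
    generate_corpus,
    load_real_pairs,
    mutate_sequence,
    random_sim_spec,
    sample_num_changes,
    split_corpus,
    write_pairs,
)
from genelm.data_io import GeneRecord, SplitSpec
from conftest import make_corpus


def levenshtein(a, b):
    return edlib.align(a, b, task="distance")["editDistance"]


class TestSampleNumChanges:
    def test_max_one_is_always_one(self):
        rng = np.random.default_rng(0)
        assert all(sample_num_changes(1, rng) == 1 for _ in range(100))

    def test_uniform_over_range(self):
        rng = np.random.default_rng(1)
        draws = Counter(sample_num_changes(5, rng) for _ in range(50_000))
        assert sorted(draws) == [1, 2, 3, 4, 5]
        # three standard errors around 0.2
        se = math.sqrt(0.2 * 0.8 / 50_000)
        for k in range(1, 6):
            assert abs(draws[k] / 50_000 - 0.2) < 3 * se

    def test_reproducible_for_fixed_seed(self):
        a = [sample_num_changes(7, np.random.default_rng(2)) for _ in range(10)]
        b = [sample_num_changes(7, np.random.default_rng(2)) for _ in range(10)]
        assert a == b


class TestApplyMutation:
    @pytest.mark.parametrize(
        "op,expected",
        [
            (MutationOp("substitute", 1, "G"), "AGGT"),
            (MutationOp("delete", 0), "CGT"),
            (MutationOp("insert", 4, "T"), "ACGTT"),
            (MutationOp("insert", 0, "C"), "CACGT"),
        ],
    )
    def test_hand_examples(self, op, expected):
        assert apply_mutation("ACGT", op) == expected

    def test_identity_substitution_rejected(self):
        with pytest.raises(ValueError):
            apply_mutation("ACGT", MutationOp("substitute", 1, "C"))

    def test_delete_on_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            apply_mutation("", MutationOp("delete", 0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_mutation("AC", MutationOp("insert", 5, "A"))


class TestMutateSequence:
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_edit_distance_bounded_by_num_changes(self, k):
        rng = np.random.default_rng(10 + k)
        for _ in range(200):
            L = int(rng.integers(2, 25))
            seq = "".join(rng.choice(list("ACGT"), size=L))
            mutated, ops = mutate_sequence(seq, k, rng)
            assert len(ops) == k
            assert levenshtein(seq, mutated) <= k
            assert abs(len(mutated) - len(seq)) <= k

    def test_operation_kinds_equiprobable(self):
        rng = np.random.default_rng(20)
        kinds = Counter()
        for _ in range(5000):
            _, ops = mutate_sequence("ACGTACGTACGT", 3, rng)
            kinds.update(op.kind for op in ops)
        counts = [kinds[k] for k in ("insert", "delete", "substitute")]
        assert stats.chisquare(counts).pvalue > 0.001

    def test_fixed_seed_reproducible(self):
        a = mutate_sequence("ACGTACGT", 4, np.random.default_rng(3))
        b = mutate_sequence("ACGTACGT", 4, np.random.default_rng(3))
        assert a == b

    def test_survives_deleting_down_to_empty(self):
        # enough deletes to exhaust the sequence: engine must redraw kinds
        rng = np.random.default_rng(4)
        mutated, ops = mutate_sequence("AC", 30, rng)
        assert len(ops) == 30


class TestBuildDataset:
    def test_real_members_distinct_while_corpus_lasts(self):
        corpus = make_corpus(["ACGTAC"] * 10)
        pairs = build_mutation_dataset(corpus, MutationConfig(n_pairs=3, max_changes=2, seed=0))
        assert len({p.real.gene_id for p in pairs}) == 3
        assert all(len(p.ops) >= 1 for p in pairs)

    def test_oversampling_wraps_with_replacement(self):
        corpus = make_corpus(["ACGTAC"] * 4)
        pairs = build_mutation_dataset(corpus, MutationConfig(n_pairs=10, max_changes=1, seed=0))
        assert len(pairs) == 10

    def test_different_seeds_differ(self):
        corpus = make_corpus(["ACGTACGTAGCA"] * 20)
        a = build_mutation_dataset(corpus, MutationConfig(n_pairs=5, max_changes=5, seed=419432))
        b = build_mutation_dataset(corpus, MutationConfig(n_pairs=5, max_changes=5, seed=623598))
        assert [p.mutated for p in a] != [p.mutated for p in b]

    def test_deterministic_for_fixed_config(self):
        corpus = make_corpus(["ACGTACGTAGCA"] * 20)
        cfg = MutationConfig(n_pairs=5, max_changes=5, seed=1)
        a = build_mutation_dataset(corpus, cfg)
        b = build_mutation_dataset(corpus, cfg)
        assert [(p.real.gene_id, p.mutated, p.ops) for p in a] == [
            (p.real.gene_id, p.mutated, p.ops) for p in b
        ]

    def test_empty_corpus_rejected(self):
        from genelm import Corpus

        with pytest.raises(ValueError):
            build_mutation_dataset(Corpus([]), MutationConfig(n_pairs=1, max_changes=1, seed=0))


class TestDiscriminate:
    def _pair(self):
        return MutationPair(real=GeneRecord("r", "ACGT"), mutated="ACTT")

    def test_lower_real_perplexity_is_correct(self):
        scores = {"ACGT": 1.0, "ACTT": 2.0}
        assert discriminate(lambda rec: scores[rec.sequence], self._pair())

    def test_lower_mutated_perplexity_is_incorrect(self):
        scores = {"ACGT": 2.0, "ACTT": 1.0}
        assert not discriminate(lambda rec: scores[rec.sequence], self._pair())

    def test_ties_count_as_incorrect(self):
        assert not discriminate(lambda rec: 1.5, self._pair())
        assert not discriminate(lambda rec: math.inf, self._pair())


class TestEvaluateAccuracy:
    def test_memorizing_mle_model_is_perfect_when_mutations_create_unseen_ngrams(self):
        rng = np.random.default_rng(30)
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(20)]
        corpus = make_corpus(seqs)
        model = fit_ngram(corpus, N=8, smoothing="mle")
        pairs = build_mutation_dataset(corpus, MutationConfig(n_pairs=20, max_changes=1, seed=7))
        # single edits on random 40-mers create unseen 8-grams: mutated scores inf
        assert all(math.isinf(model.score(GeneRecord("m", p.mutated))) for p in pairs)
        assert evaluate_accuracy(model.score, pairs) == 1.0

    def test_random_scorer_sits_at_chance(self):
        corpus = make_corpus(["ACGTACGTACGTACGTACGT"] * 50)
        pairs = build_mutation_dataset(corpus, MutationConfig(n_pairs=10_000, max_changes=3, seed=8))
        rng = np.random.default_rng(9)
        acc = evaluate_accuracy(lambda rec: rng.random(), pairs)
        assert 0.45 <= acc <= 0.55

    def test_accuracy_non_decreasing_in_max_changes(self):
        """More edits make the discrimination easier for a competent scorer."""
        spec = random_sim_spec(2, concentration=0.5, seed=40, end_prob=0.01, n_records=400, max_len=400)
        corpus = generate_corpus(spec)
        tr, va, te = split_corpus(corpus, SplitSpec(seed=0))
        model = fit_ngram(tr, N=4, smoothing="laplace")
        means = []
        for mc in (1, 5, 10):
            accs = [
                evaluate_accuracy(
                    model.score,
                    build_mutation_dataset(te, MutationConfig(n_pairs=150, max_changes=mc, seed=s)),
                )
                for s in (419432, 623598, 638453)
            ]
            means.append(sum(accs) / len(accs))
        assert means[1] >= means[0] - 0.02
        assert means[2] >= means[1] - 0.02


class TestPairCSV:
    def test_write_read_round_trip(self, tmp_path):
        corpus = make_corpus(["ACGTACGTA"] * 5)
        pairs = build_mutation_dataset(corpus, MutationConfig(n_pairs=5, max_changes=3, seed=2))
        path = tmp_path / "pairs.csv"
        write_pairs(pairs, path)
        back = load_real_pairs(path)
        assert [p.real.sequence for p in back] == [p.real.sequence for p in pairs]
        assert [p.mutated for p in back] == [p.mutated for p in pairs]
        assert [p.ops for p in back] == [p.ops for p in pairs]

    def test_ten_row_file_gives_ten_pairs(self, tmp_path):
        path = tmp_path / "real.csv"
        rows = "\n".join(f"p{i},ACGTACGT,ACGTACGA,1 Substitution" for i in range(10))
        path.write_text("pair_id,real_sequence,mutated_sequence,mutation_info\n" + rows + "\n")
        assert len(load_real_pairs(path)) == 10

    def test_malformed_rows_are_skipped(self, tmp_path):
        path = tmp_path / "mixed.csv"
        path.write_text(
            "pair_id,real_sequence,mutated_sequence\np1,ACGT,ACGA\np2,,ACGT\np3,ACXT,ACGT\n"
        )
        assert len(load_real_pairs(path)) == 1

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("pair_id,real_sequence,mutated_sequence\n")
        with pytest.raises(ValueError):
            load_real_pairs(path)
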