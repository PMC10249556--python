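"""Contracts of the masked-prediction backends (n-gram focus).

The n-gram backend is exactly testable: its training is counting, so an
independent brute-force counter serves as the oracle for both the fitted
cross-entropy and the top-k rankings.
"""

from collections import Counter

import numpy as np
import pytest

import mlmga as M
from mlmga.predictor import NGramPredictor, TrainReport
from mlmga.tokenizer import TokenSequence


def brute_force_tables(sequences, bos=-1, eos=-2):
    """Independent (left, right) -> centre counter, plus unigrams."""
    ctx: dict[tuple[int, int], Counter] = {}
    uni: Counter = Counter()
    for seq in sequences:
        ids = seq.ids
        for i, t in enumerate(ids):
            left = ids[i - 1] if i > 0 else bos
            right = ids[i + 1] if i < len(ids) - 1 else eos
            ctx.setdefault((left, right), Counter())[t] += 1
            uni[t] += 1
    return ctx, uni


def brute_force_ranking(vocab, table, k):
    """Add-one-smoothed ranking over predictable tokens, ties by ID."""
    predictable = [i for i in range(len(vocab)) if i not in vocab.special_ids]
    scored = sorted(predictable, key=lambda t: (-table.get(t, 0), t))
    return scored[:k]


class TestNGramTraining:
    def test_end_loss_matches_brute_force_cross_entropy(self, small_vocab, small_sequences):
        model = NGramPredictor(small_vocab, seed=0)
        report = model.pretrain(small_sequences, epochs=1)

        ctx, uni = brute_force_tables(small_sequences)
        predictable = [i for i in range(len(small_vocab)) if i not in small_vocab.special_ids]
        total, n = 0.0, 0
        for seq in small_sequences:
            ids = seq.ids
            for i, t in enumerate(ids):
                left = ids[i - 1] if i > 0 else -1
                right = ids[i + 1] if i < len(ids) - 1 else -2
                table = ctx.get((left, right), uni)
                denom = sum(table.get(j, 0) for j in predictable) + len(predictable)
                total += -np.log((table.get(t, 0) + 1.0) / denom)
                n += 1
        assert report.mean_masked_loss_end == pytest.approx(total / n, rel=1e-12)

    def test_zero_epochs_is_identity(self, small_vocab, small_sequences):
        model = NGramPredictor(small_vocab, seed=0)
        report = model.pretrain(small_sequences, epochs=0)
        assert report.mean_masked_loss_start == report.mean_masked_loss_end
        assert not model.context_counts

    def test_training_reduces_loss(self, small_vocab, small_sequences):
        model = NGramPredictor(small_vocab, seed=0)
        report = model.pretrain(small_sequences, epochs=1)
        assert report.mean_masked_loss_end < report.mean_masked_loss_start

    def test_empty_corpus_raises(self, small_vocab):
        with pytest.raises(ValueError):
            NGramPredictor(small_vocab).pretrain([], epochs=1)

    def test_single_sequence_adapt_is_valid(self, small_vocab, small_sequences):
        model = NGramPredictor(small_vocab, seed=0)
        report = model.adapt(small_sequences[:1])
        assert report.epochs == 1 and report.n_sequences == 1

    def test_repeated_adaptation_moves_toward_population(self, small_vocab):
        # adapting twice on a fixed population: the second pass starts from
        # counts already fitted to it, so its end loss can only improve on
        # the first pass's starting loss (majority over seeds)
        wins = 0
        for seed in range(5):
            pop = [
                M.encode(small_vocab, s)
                for s in M.make_gdb9_like(30, seed=100 + seed)
            ]
            model = NGramPredictor(small_vocab, seed=seed)
            first = model.adapt(pop)
            second = model.adapt(pop)
            if second.mean_masked_loss_end <= first.mean_masked_loss_start:
                wins += 1
        assert wins >= 3

    def test_train_report_validates(self):
        with pytest.raises(ValueError):
            TrainReport(1, -0.5, 0.1, 10)
        with pytest.raises(ValueError):
            TrainReport(1, 0.5, 0.1, 0)


class TestTopK:
    def test_matches_count_oracle_on_forced_context(self):
        # character-level vocab (no repeated pairs -> no merges); the
        # context C _ O is always filled by C in the training data
        vocab = M.build_vocabulary(["CON"], target_size=16)
        seqs = [M.encode(vocab, "CCO")] * 5
        model = NGramPredictor(vocab, seed=0)
        model.pretrain(seqs, epochs=1)
        masked = TokenSequence(
            (vocab.id_of["C"], vocab.mask_id, vocab.id_of["O"])
        )
        small_vocab = vocab
        ranked = model.predict_topk(masked, k=1)
        assert ranked[0][0][0] == small_vocab.id_of["C"]

    def test_k1_returns_one_candidate_per_mask(self, ngram_model, small_vocab):
        masked = TokenSequence((small_vocab.mask_id, small_vocab.id_of["C"]))
        ranked = ngram_model.predict_topk(masked, k=1)
        assert len(ranked) == 1 and len(ranked[0]) == 1

    def test_two_masks_give_two_ranked_lists(self, ngram_model, small_vocab):
        masked = TokenSequence(
            (small_vocab.mask_id, small_vocab.id_of["C"], small_vocab.mask_id)
        )
        ranked = ngram_model.predict_topk(masked, k=3)
        assert len(ranked) == 2
        assert all(len(r) == 3 for r in ranked)

    def test_scores_non_increasing_and_special_free(self, ngram_model, small_vocab):
        masked = TokenSequence((small_vocab.id_of["C"], small_vocab.mask_id))
        ranked = ngram_model.predict_topk(masked, k=10)
        scores = [s for _, s in ranked[0]]
        ids = [t for t, _ in ranked[0]]
        assert scores == sorted(scores, reverse=True)
        assert not set(ids) & set(small_vocab.special_ids)
        assert sum(scores) <= 1.0 + 1e-9

    def test_no_mask_raises(self, ngram_model, small_vocab):
        with pytest.raises(ValueError):
            ngram_model.predict_topk(TokenSequence((small_vocab.id_of["C"],)), k=1)

    def test_k_beyond_predictable_raises(self, ngram_model, small_vocab):
        masked = TokenSequence((small_vocab.mask_id,))
        with pytest.raises(ValueError):
            ngram_model.predict_topk(masked, k=small_vocab.n_predictable + 1)

    def test_deterministic_given_state(self, ngram_model, small_vocab):
        masked = TokenSequence((small_vocab.id_of["C"], small_vocab.mask_id))
        assert ngram_model.predict_topk(masked, 5) == ngram_model.predict_topk(masked, 5)


class TestSampling:
    def test_temperature_zero_limit_equals_rank_one(self, ngram_model, small_vocab):
        masked = TokenSequence((small_vocab.id_of["C"], small_vocab.mask_id))
        top = ngram_model.predict_topk(masked, k=1)[0][0][0]
        rng = np.random.default_rng(0)
        draws = {ngram_model.predict_sample(masked, 1e-9, rng)[0] for _ in range(20)}
        assert draws == {top}

    def test_fixed_seed_reproducible(self, ngram_model, small_vocab):
        masked = TokenSequence((small_vocab.mask_id, small_vocab.id_of["C"]))
        a = ngram_model.predict_sample(masked, 1.0, np.random.default_rng(42))
        b = ngram_model.predict_sample(masked, 1.0, np.random.default_rng(42))
        assert a == b

    def test_nonpositive_temperature_raises(self, ngram_model, small_vocab):
        masked = TokenSequence((small_vocab.mask_id,))
        with pytest.raises(ValueError):
            ngram_model.predict_sample(masked, 0.0)

    def test_empirical_frequencies_match_distribution(self):
        # two-token vocabulary with a 3:1 context distribution; draws at
        # temperature 1 must reproduce it within binomial 3 sigma
        vocab = M.build_vocabulary(["CCC", "CCO"], target_size=8)
        seqs = [M.encode(vocab, "CCC")] * 73 + [M.encode(vocab, "CCO")] * 23
        model = NGramPredictor(vocab, seed=0)
        model.pretrain(seqs, epochs=1)
        masked = TokenSequence(
            (vocab.id_of["C"], vocab.id_of["C"], vocab.mask_id)
        )
        # smoothed probability of C in context (C, EOS): (73+1)/(96+2)
        p_c = model._distribution(vocab.id_of["C"], NGramPredictor.EOS)[vocab.id_of["C"]]
        n = 10_000
        rng = np.random.default_rng(1)
        hits = sum(
            model.predict_sample(masked, 1.0, rng)[0] == vocab.id_of["C"]
            for _ in range(n)
        )
        sigma = np.sqrt(n * p_c * (1 - p_c))
        assert abs(hits - n * p_c) < 3 * sigma


class TestPersistence:
    def test_ngram_save_load_identical_predictions(self, ngram_model, small_vocab, tmp_path):
        ngram_model.save(tmp_path / "ckpt")
        loaded = M.load_predictor(tmp_path / "ckpt")
        masked = TokenSequence((small_vocab.id_of["C"], small_vocab.mask_id))
        assert loaded.predict_topk(masked, 5) == ngram_model.predict_topk(masked, 5)

    def test_unknown_backend_raises(self, tmp_path):
        d = tmp_path / "ckpt"
        d.mkdir()
        (d / "config.json").write_text('{"backend": "nonsense"}')
        with pytest.raises(ValueError):
            M.load_predictor(d)
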