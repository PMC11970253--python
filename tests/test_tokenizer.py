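import datetime as dt

import numpy as np
import pytest

from glucodyn.tokenizer import (
    MaskPlan,
    TokenSequence,
    TokenVocabulary,
    apply_masking,
    detokenize,
    tfidf_token_weights,
    tokenize_day,
)
from glucodyn.types import DayProfile

DATE = dt.date(2024, 1, 1)


def day_from(values):
    return DayProfile.from_values("s", DATE, np.asarray(values, dtype=float))


@pytest.fixture()
def full_day():
    rng = np.random.default_rng(1)
    return day_from(rng.uniform(60, 250, 288).round())


class TestVocabulary:
    def test_cardinality_and_disjoint_specials(self, vocab):
        assert vocab.n_glucose == 260
        assert vocab.size == 263
        assert len({vocab.pad_id, vocab.cls_id, vocab.mask_id}) == 3
        assert all(s >= vocab.n_glucose for s in vocab.special_ids)

    def test_exhaustive_bin_mapping(self, vocab):
        # all 261 clipped integer values map into 260 bins; 300 shares the top
        mapping = {g: vocab.id_of(g) for g in range(40, 301)}
        assert mapping[40] == 0
        assert mapping[299] == 259
        assert mapping[300] == 259
        assert sorted(set(mapping.values())) == list(range(260))
        for g in range(40, 300):
            assert mapping[g] == g - 40

    def test_id_level_round_trip(self, vocab):
        for tid in range(260):
            assert vocab.id_of(vocab.level_of(tid)) == tid

    def test_level_of_rejects_special(self, vocab):
        with pytest.raises(ValueError):
            vocab.level_of(vocab.pad_id)


class TestTokenizeDay:
    def test_full_day_289_tokens(self, vocab, full_day):
        seq = tokenize_day(full_day, vocab)
        assert len(seq) == 289
        assert seq.token_ids[0] == vocab.cls_id
        assert (seq.token_ids[1:] < vocab.n_glucose).all()

    def test_fully_missing_day(self, vocab):
        day = DayProfile("s", DATE, np.full(288, np.nan), np.zeros(288, bool))
        seq = tokenize_day(day, vocab)
        assert seq.token_ids[0] == vocab.cls_id
        assert (seq.token_ids[1:] == vocab.pad_id).all()

    def test_boundary_values(self, vocab):
        day = day_from([40.0] * 144 + [300.0] * 144)
        seq = tokenize_day(day, vocab)
        assert seq.token_ids[1] == 0
        assert seq.token_ids[288] == 259


class TestDetokenize:
    def test_round_trip_integer_day(self, vocab):
        rng = np.random.default_rng(2)
        day = day_from(rng.integers(40, 300, 288).astype(float))
        back = detokenize(tokenize_day(day, vocab), vocab)
        np.testing.assert_array_equal(back.values, day.values)

    def test_all_pad_round_trip(self, vocab):
        day = DayProfile("s", DATE, np.full(288, np.nan), np.zeros(288, bool))
        back = detokenize(tokenize_day(day, vocab), vocab)
        assert not back.present_mask.any()

    def test_top_bin_maps_300_to_299(self, vocab):
        day = day_from([300.0] * 288)
        back = detokenize(tokenize_day(day, vocab), vocab)
        assert (back.values == 299.0).all()

    def test_unknown_id_rejected(self, vocab):
        ids = np.full(289, 0, dtype=np.int64)
        ids[0] = vocab.cls_id
        ids[5] = vocab.mask_id
        with pytest.raises(ValueError, match="position 5"):
            detokenize(TokenSequence(ids), vocab)


class TestTfidf:
    def test_ubiquitous_token_has_minimal_idf(self, vocab):
        days = [day_from(np.full(288, 100.0 + i)) for i in range(4)]
        days.append(day_from(np.full(288, 100.0)))  # token 60 in every day? no:
        # token for 100 mg/dL appears in day 0 and day 4 only
        corpus = [tokenize_day(d, vocab) for d in days]
        w = tfidf_token_weights(corpus, vocab)
        n = len(corpus)
        tid_100 = vocab.id_of(100.0)
        df = 2  # days 0 and 4
        assert w.idf[tid_100] == pytest.approx(np.log((1 + n) / (1 + df)) + 1)
        # CLS appears in every day -> minimal idf = 1 under the smoothing
        assert w.idf[vocab.cls_id] == pytest.approx(1.0)

    def test_counting_oracle(self, vocab):
        rng = np.random.default_rng(3)
        corpus = [tokenize_day(day_from(rng.integers(60, 200, 288).astype(float)), vocab)
                  for _ in range(6)]
        w = tfidf_token_weights(corpus, vocab)
        # brute-force recomputation
        n = len(corpus)
        for tid in (0, vocab.id_of(100), vocab.id_of(199)):
            df = sum(tid in seq.token_ids for seq in corpus)
            assert w.idf[tid] == pytest.approx(np.log((1 + n) / (1 + df)) + 1)
        seq = corpus[0]
        pw = w.position_weights(seq)
        for pos in (1, 57, 288):
            tid = seq.token_ids[pos]
            tf = int((seq.token_ids == tid).sum())
            boost = 2.0 if (vocab.level_of(tid) > 180 or vocab.level_of(tid) < 70) else 1.0
            assert pw[pos] == pytest.approx(tf * w.idf[tid] * boost)

    def test_abnormal_boost_factor(self, vocab):
        day = day_from([100.0] * 287 + [200.0])
        corpus = [tokenize_day(day, vocab)]
        boosted = tfidf_token_weights(corpus, vocab, abnormal_boost=2.0)
        plain = tfidf_token_weights(corpus, vocab, abnormal_boost=1.0)
        pos_200 = 288
        assert boosted.position_weights(corpus[0])[pos_200] == pytest.approx(
            2.0 * plain.position_weights(corpus[0])[pos_200]
        )

    def test_uniform_day_symmetric_weights(self, vocab):
        day = day_from(np.full(288, 120.0))
        corpus = [tokenize_day(day, vocab)]
        w = tfidf_token_weights(corpus, vocab)
        pw = w.position_weights(corpus[0])
        assert pw[0] == 0.0
        assert len(set(pw[1:])) == 1

    def test_empty_corpus_rejected(self, vocab):
        with pytest.raises(ValueError):
            tfidf_token_weights([], vocab)


class TestApplyMasking:
    def test_zero_fraction_no_masking(self, vocab, full_day):
        seq = tokenize_day(full_day, vocab)
        w = tfidf_token_weights([seq], vocab)
        masked, plan = apply_masking(seq, w, np.random.default_rng(0), (0.0, 0.0))
        assert plan.mask_fraction == 0.0
        np.testing.assert_array_equal(masked.token_ids, seq.token_ids)

    def test_default_fraction_mean_within_range(self, vocab, full_day):
        seq = tokenize_day(full_day, vocab)
        w = tfidf_token_weights([seq], vocab)
        rng = np.random.default_rng(42)
        fracs = [apply_masking(seq, w, rng)[1].mask_fraction for _ in range(1000)]
        assert 0.45 <= np.mean(fracs) <= 0.60

    def test_never_masks_cls_or_pad(self, vocab):
        values = np.full(288, np.nan)
        values[:100] = 120.0
        day = DayProfile("s", DATE, values, np.isfinite(values))
        seq = tokenize_day(day, vocab)
        w = tfidf_token_weights([seq], vocab)
        rng = np.random.default_rng(1)
        for _ in range(50):
            masked, plan = apply_masking(seq, w, rng)
            assert 0 not in plan.masked_positions
            assert (masked.token_ids[101:] == vocab.pad_id).all()

    def test_boost_doubles_abnormal_masking_rate_monte_carlo(self, vocab):
        # low target fraction so without-replacement saturation is negligible;
        # independent Monte-Carlo oracle = inclusion frequency under the same
        # weight vector using a separately coded Gumbel top-k sampler
        values = np.concatenate([np.full(144, 100.0), np.full(144, 200.0)])
        seq = tokenize_day(day_from(values), vocab)
        weights = np.ones(289)
        weights[1:145] = 1.0
        weights[145:] = 2.0
        rng = np.random.default_rng(5)
        hits_eu = hits_hyper = 0
        n_draws, frac = 4000, (0.10, 0.10)
        for _ in range(n_draws):
            _, plan = apply_masking(seq, weights, rng, frac, vocab=vocab)
            hits_eu += np.sum(plan.masked_positions <= 144)
            hits_hyper += np.sum(plan.masked_positions > 144)
        ratio = hits_hyper / hits_eu
        # Monte-Carlo oracle with an independent sampler
        oracle_rng = np.random.default_rng(99)
        o_eu = o_hyper = 0
        w = weights[1:]
        for _ in range(n_draws):
            keys = np.log(oracle_rng.random(288)) / w
            chosen = np.argsort(-keys)[: int(round(0.10 * 288))]
            o_hyper += np.sum(chosen >= 144)
            o_eu += np.sum(chosen < 144)
        oracle_ratio = o_hyper / o_eu
        assert ratio == pytest.approx(oracle_ratio, rel=0.10)
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_uniform_weights_reduce_to_uniform_sampling(self, vocab, full_day):
        from scipy.stats import chisquare

        seq = tokenize_day(full_day, vocab)
        weights = np.ones(289)
        rng = np.random.default_rng(11)
        counts = np.zeros(289)
        for _ in range(2000):
            _, plan = apply_masking(seq, weights, rng, (0.5, 0.5), vocab=vocab)
            counts[plan.masked_positions] += 1
        observed = counts[1:]
        stat, p = chisquare(observed)
        assert p > 0.01

    def test_invalid_fraction_range(self, vocab, full_day):
        seq = tokenize_day(full_day, vocab)
        with pytest.raises(ValueError):
            apply_masking(seq, np.ones(289), np.random.default_rng(0), (0.2, 1.5),
                          vocab=vocab)

    def test_all_pad_rejected(self, vocab):
        day = DayProfile("s", DATE, np.full(288, np.nan), np.zeros(288, bool))
        seq = tokenize_day(day, vocab)
        with pytest.raises(ValueError, match="maskable"):
            apply_masking(seq, np.ones(289), np.random.default_rng(0), vocab=vocab)

    def test_plan_records_truth(self, vocab, full_day):
        seq = tokenize_day(full_day, vocab)
        w = tfidf_token_weights([seq], vocab)
        masked, plan = apply_masking(seq, w, np.random.default_rng(2))
        np.testing.assert_array_equal(
            seq.token_ids[plan.masked_positions], plan.target_ids
        )
        assert (masked.token_ids[plan.masked_positions] == vocab.mask_id).all()
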