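import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cutscan.cnn_predictor import (
    ConvSiteClassifier,
    ModelConfig,
    RankedPrediction,
    build_training_set,
    decode_site,
    encode_batch,
    encode_site,
    predict_rank,
    recall_at_rank,
    train,
)
from cutscan.genome_scan import CandidateSite, GuideTarget, count_mismatches

from conftest import mutate_protospacer, random_seq

dna23 = st.text(alphabet="ACGT", min_size=23, max_size=23)


@pytest.fixture(scope="module")
def bench_guide():
    rng = np.random.default_rng(99)
    return GuideTarget(
        protospacer=random_seq(rng, 20),
        pam_pattern="NNN",
        chrom="chr1",
        protospacer_start=100,
    )


def make_positives(guide, n, rng, max_mm=3):
    out = []
    for _ in range(n):
        proto = mutate_protospacer(guide.protospacer, int(rng.integers(0, max_mm + 1)), rng)
        out.append(proto + random_seq(rng, 3))
    return out


class TestEncoding:
    def test_a_is_first_channel(self):
        mat = encode_site("A" * 23)
        assert tuple(mat[0]) == (1, 0, 0, 0)

    def test_g_is_last_channel(self):
        mat = encode_site("G" + "A" * 22)
        assert tuple(mat[0]) == (0, 0, 0, 1)

    def test_channel_order_atcg(self):
        mat = encode_site("ATCG" * 5 + "ATC")
        assert tuple(mat[0]) == (1, 0, 0, 0)
        assert tuple(mat[1]) == (0, 1, 0, 0)
        assert tuple(mat[2]) == (0, 0, 1, 0)
        assert tuple(mat[3]) == (0, 0, 0, 1)

    @given(dna23)
    def test_roundtrip(self, seq):
        assert decode_site(encode_site(seq)) == seq

    @given(dna23)
    def test_rows_one_hot(self, seq):
        mat = encode_site(seq)
        assert (mat.sum(axis=1) == 1).all()

    def test_bad_length_error(self):
        with pytest.raises(ValueError):
            encode_site("ACGT")

    def test_non_acgt_error(self):
        with pytest.raises(ValueError):
            encode_site("N" * 23)


class TestBuildTrainingSet:
    def test_negatives_have_at_least_11_mismatches(self, bench_guide):
        pos = ["A" * 20 + "AGG"]
        X, y, seqs = build_training_set(pos * 10, bench_guide, 5.0, seed=3)
        for seq, label in zip(seqs, y):
            if label == 0:
                assert (
                    count_mismatches(seq[:20], bench_guide.protospacer) >= 11
                )

    def test_positive_count_preserved(self, bench_guide, rng):
        pos = make_positives(bench_guide, 17, rng)
        X, y, _ = build_training_set(pos, bench_guide, 2.0, seed=1)
        assert int(y.sum()) == 17
        assert len(y) == 17 + 34

    def test_same_seed_identical(self, bench_guide, rng):
        pos = make_positives(bench_guide, 10, rng)
        a = build_training_set(pos, bench_guide, 1.0, seed=5)
        b = build_training_set(pos, bench_guide, 1.0, seed=5)
        assert a[2] == b[2]
        assert np.array_equal(a[1], b[1])

    def test_bad_ratio_error(self, bench_guide):
        with pytest.raises(ValueError):
            build_training_set(["A" * 23], bench_guide, 0.0)

    def test_empty_positives_error(self, bench_guide):
        with pytest.raises(ValueError):
            build_training_set([], bench_guide, 1.0)


class TestTrain:
    def test_zero_epochs_untrained_empty_history(self):
        X = encode_batch(["A" * 23, "C" * 23])
        model, history = train(ModelConfig(epochs=0), X, np.array([1.0, 0.0]))
        assert history == []
        assert isinstance(model, ConvSiteClassifier)

    def test_single_class_error(self):
        X = encode_batch(["A" * 23, "C" * 23])
        with pytest.raises(ValueError):
            train(ModelConfig(epochs=1), X, np.array([1.0, 1.0]))

    def test_history_length_equals_epochs(self, bench_guide, rng):
        pos = make_positives(bench_guide, 20, rng)
        X, y, _ = build_training_set(pos, bench_guide, 1.0, seed=2)
        _, history = train(ModelConfig(epochs=3, seed=2), X, y)
        assert len(history) == 3
        assert [h["epoch"] for h in history] == [1, 2, 3]

    def test_training_deterministic_from_seed(self, bench_guide, rng):
        pos = make_positives(bench_guide, 20, rng)
        X, y, _ = build_training_set(pos, bench_guide, 1.0, seed=2)
        m1, h1 = train(ModelConfig(epochs=2, seed=8), X, y)
        m2, h2 = train(ModelConfig(epochs=2, seed=8), X, y)
        assert h1 == h2
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_dense_units_fixed(self):
        with pytest.raises(ValueError):
            ModelConfig(dense_units=(64, 32))

    def test_separable_task_accuracy(self, bench_guide):
        rng = np.random.default_rng(12)
        pos = make_positives(bench_guide, 250, rng)
        X, y, _ = build_training_set(pos, bench_guide, 1.0, seed=12)
        model, history = train(ModelConfig(epochs=15, seed=12), X, y)
        assert history[-1]["accuracy"] >= 0.95
        assert history[-1]["loss"] < history[0]["loss"]


@pytest.fixture(scope="module")
def trained(bench_guide):
    rng = np.random.default_rng(7)
    pos = make_positives(bench_guide, 200, rng)
    X, y, _ = build_training_set(pos, bench_guide, 1.0, seed=7)
    model, _ = train(ModelConfig(epochs=15, seed=7), X, y)
    return model


class TestPredictRank:
    def _sites(self, seqs, bench_guide, chrom="chr1"):
        return [
            CandidateSite(
                chrom=chrom,
                start=i * 30,
                end=i * 30 + 23,
                strand="+",
                sequence_23=s,
                mismatch_count=count_mismatches(s[:20], bench_guide.protospacer),
                pam=s[20:],
            )
            for i, s in enumerate(seqs)
        ]

    def test_empty_candidates(self, trained):
        assert predict_rank(trained, []) == []

    def test_single_candidate_rank_one(self, trained, bench_guide):
        sites = self._sites([random_seq(np.random.default_rng(0), 23)], bench_guide)
        ranked = predict_rank(trained, sites)
        assert ranked[0].rank == 1

    def test_ranks_are_permutation_scores_nonincreasing(self, trained, bench_guide, rng):
        sites = self._sites([random_seq(rng, 23) for _ in range(50)], bench_guide)
        ranked = predict_rank(trained, sites)
        assert sorted(r.rank for r in ranked) == list(range(1, 51))
        scores = [r.score for r in ranked]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_input_order_invariant(self, trained, bench_guide, rng):
        sites = self._sites([random_seq(rng, 23) for _ in range(30)], bench_guide)
        fwd = predict_rank(trained, sites)
        rev = predict_rank(trained, sites[::-1])
        assert [r.site.key() for r in fwd] == [r.site.key() for r in rev]


class TestRecallAtRank:
    def _ranked(self, keys):
        return [
            RankedPrediction(
                site=CandidateSite(
                    chrom=c, start=s, end=s + 23, strand=st_, sequence_23="A" * 23,
                    mismatch_count=0, pam="AAA",
                ),
                score=1.0 - i * 1e-3,
                rank=i + 1,
            )
            for i, (c, s, st_) in enumerate(keys)
        ]

    def test_all_truths_first(self):
        keys = [("chr1", i * 30, "+") for i in range(10)]
        truth = set(keys[:3])
        curve, missing = recall_at_rank(self._ranked(keys), truth)
        assert curve[2] == 3
        assert curve[-1] == 3
        assert missing == []

    def test_truths_last(self):
        keys = [("chr1", i * 30, "+") for i in range(10)]
        truth = set(keys[-2:])
        curve, _ = recall_at_rank(self._ranked(keys), truth)
        assert (curve[:8] == 0).all()
        assert curve[-1] == 2

    def test_monotone_and_bounded(self, rng):
        keys = [("chr1", int(i) * 30, "+") for i in range(100)]
        truth = {keys[int(i)] for i in rng.choice(100, 20, replace=False)}
        curve, _ = recall_at_rank(self._ranked(keys), truth)
        assert (np.diff(curve) >= 0).all()
        for k in range(1, 101):
            assert curve[k - 1] <= min(k, len(truth))

    def test_missing_truths_flagged(self):
        keys = [("chr1", i * 30, "+") for i in range(5)]
        truth = {("chrX", 0, "+")}
        curve, missing = recall_at_rank(self._ranked(keys), truth)
        assert curve[-1] == 0
        assert missing == [("chrX", 0, "+")]

    def test_random_ranking_expectation(self, rng):
        # E[truths in top k] = k * |truth| / n under random permutation
        n, t, reps = 60, 12, 400
        keys = [("chr1", i * 30, "+") for i in range(n)]
        k = 15
        acc = 0
        for _ in range(reps):
            perm = rng.permutation(n)
            truth = set(keys[i] for i in perm[:t])
            curve, _ = recall_at_rank(self._ranked(keys), truth)
            acc += curve[k - 1]
        expected = k * t / n
        se = np.sqrt(reps * t * (k / n) * (1 - k / n)) / reps  # loose bound
        assert abs(acc / reps - expected) < 6 * max(se, 0.05)
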