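import numpy as np
import pytest

from saltc import (
    JUNK,
    Category,
    LabeledRecord,
    MappedRecord,
    NoiseSpec,
    generate_corpus,
    map_corpus,
    score_mapping,
    vectorize,
)


def test_spec_validation():
    with pytest.raises(ValueError):
        NoiseSpec(n_records=0)
    with pytest.raises(ValueError):
        NoiseSpec(typo_rate=1.5)
    with pytest.raises(ValueError):
        NoiseSpec(category_mix={Category.URINE_COLOR: 0.0})
    with pytest.raises(ValueError):
        NoiseSpec(typo_ops=("telegraph",))


def test_same_seed_reproduces_corpus_exactly(registry):
    spec = NoiseSpec(n_records=200, seed=7, typo_rate=0.3, case_noise_rate=0.2,
                     prefix_rate=0.3, junk_rate=0.05)
    assert generate_corpus(spec, registry) == generate_corpus(spec, registry)
    other = NoiseSpec(n_records=200, seed=8, typo_rate=0.3, case_noise_rate=0.2,
                      prefix_rate=0.3, junk_rate=0.05)
    assert generate_corpus(other, registry) != generate_corpus(spec, registry)


def test_noise_free_corpus_recovers_perfectly(registry):
    spec = NoiseSpec(n_records=400, seed=3)
    corpus = generate_corpus(spec, registry)
    result = map_corpus(corpus, registry, "hybrid")
    report = score_mapping(corpus, result.records)
    assert report.value_level == 1.0
    assert report.data_level == 1.0
    assert report.n_review_records == 0


def test_junk_vectorizes_to_zero_and_is_labeled(registry):
    spec = NoiseSpec(n_records=500, seed=11, junk_rate=0.5)
    corpus = generate_corpus(spec, registry)
    junk = [r for r in corpus if r.true_label == JUNK]
    assert junk, "junk_rate=0.5 must produce junk records"
    assert all(not vectorize(r.raw_value).any() for r in junk)


def test_swap_typos_produce_printed_style_variants(registry):
    spec = NoiseSpec(n_records=4000, seed=5, typo_rate=0.5, typo_ops=("swap_adjacent",))
    corpus = generate_corpus(spec, registry)
    raws = {r.raw_value for r in corpus if r.true_label == "straw"}
    # single adjacent swaps of "straw" include the observed variant "starw"
    assert raws & {"starw", "tsraw", "srtaw", "strwa"}


def test_labels_belong_to_registry(registry):
    spec = NoiseSpec(n_records=300, seed=2, typo_rate=0.2, junk_rate=0.1)
    for rec in generate_corpus(spec, registry):
        if rec.true_label != JUNK:
            assert registry.get(rec.true_category, rec.true_label) is not None


def test_accuracy_degrades_with_typo_rate_on_average(registry):
    def mean_acc(rate):
        accs = []
        for seed in range(20):
            spec = NoiseSpec(n_records=300, seed=seed, typo_rate=rate)
            corpus = generate_corpus(spec, registry)
            res = map_corpus(corpus, registry, "hybrid")
            accs.append(score_mapping(corpus, res.records).data_level)
        return float(np.mean(accs))

    assert mean_acc(0.45) <= mean_acc(0.05)


class TestScoreMapping:
    @staticmethod
    def pred(test_id, raw, label, unmapped=False):
        return MappedRecord(test_id, raw, raw, Category.PRESENCE_FINDING, label,
                            None, None, None, "hybrid", unmapped,
                            "tie" if unmapped else None)

    @staticmethod
    def truth(test_id, raw, label):
        return LabeledRecord(test_id, raw, Category.PRESENCE_FINDING, label)

    def test_perfect_predictions(self):
        truth = [self.truth("t", f"v{i}", "positive") for i in range(10)]
        preds = [self.pred("t", f"v{i}", "positive") for i in range(10)]
        report = score_mapping(truth, preds)
        assert report.value_level == 1.0 and report.data_level == 1.0

    def test_one_wrong_singleton(self):
        truth = [self.truth("t", f"v{i}", "positive") for i in range(10)]
        preds = [self.pred("t", f"v{i}", "positive") for i in range(9)]
        preds.append(self.pred("t", "v9", "negative"))
        report = score_mapping(truth, preds)
        assert report.value_level == pytest.approx(0.9)
        assert report.data_level == pytest.approx(0.9)

    def test_frequent_value_weighs_data_level_only(self):
        truth = [self.truth("t", "big", "positive")] * 1000
        truth += [self.truth("t", f"v{i}", "positive") for i in range(9)]
        preds = [self.pred("t", "big", "negative")] * 1000
        preds += [self.pred("t", f"v{i}", "positive") for i in range(9)]
        report = score_mapping(truth, preds)
        assert report.value_level == pytest.approx(0.9)
        assert report.data_level == pytest.approx(9 / 1009)

    def test_junk_correct_only_when_unmapped(self):
        truth = [self.truth("t", "****", JUNK), self.truth("t", "??", JUNK)]
        preds = [self.pred("t", "****", None, unmapped=True),
                 self.pred("t", "??", "positive")]
        report = score_mapping(truth, preds)
        assert report.data_level == pytest.approx(0.5)
        assert report.n_review_records == 0

    def test_abstentions_are_reported_not_scored(self):
        truth = [self.truth("t", "v0", "positive"), self.truth("t", "v1", "positive")]
        preds = [self.pred("t", "v0", "positive"),
                 self.pred("t", "v1", None, unmapped=True)]
        report = score_mapping(truth, preds)
        assert report.value_level == 1.0
        assert report.n_review_values == 1
        assert report.n_review_records == 1

    def test_mismatched_keys_rejected(self):
        truth = [self.truth("t", "a", "positive")]
        preds = [self.pred("t", "b", "positive")]
        with pytest.raises(ValueError, match="mismatch"):
            score_mapping(truth, preds)
        with pytest.raises(ValueError, match="records"):
            score_mapping(truth, [])
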