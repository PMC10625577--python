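import numpy as np
import pytest

from occucode.coder import (
    CodeSuggestion,
    DatasetSplit,
    HyperParams,
    augment_with_index,
    filter_viable,
    load_coder,
    predict_suggestions,
    predict_topk,
    save_coder,
    select_input_classes,
    split_dataset,
    train_coder,
)
from occucode.errors import (
    ConfigurationError,
    DataError,
    DegenerateModelError,
    DegenerateSplitError,
    InvalidCodeError,
)
from occucode.evaluation import per_level_metrics
from occucode.schemes import Code, parse_code
from occucode.synthdata import CorpusSpec, generate_corpus, generate_scheme
from occucode.textprep import HashedBagOfStems, InputRecord


def _records(scheme, raws, with_ids=None):
    out = []
    for i, raw in enumerate(raws):
        gold = parse_code(scheme, raw) if raw is not None else None
        out.append(InputRecord(str(with_ids[i] if with_ids else i), {"a": f"t{i}"}, gold=gold))
    return out


class TestFilterViable:
    def test_paper_defaults(self):
        assert HyperParams() == HyperParams(
            eta=0.6, max_delta_step=1, max_depth=20, gamma=1.5, lambda_=1e-4,
            min_child_weight=0, subsample=0.75, colsample_by_tree=1,
            colsample_by_level=1, early_stopping_rounds=1, max_rounds=500,
        )

    def test_incomplete_rejected(self, isco68):
        raws = ["1-21.10", "1-21", "2-11.05", "3-00.00", "1-21.10"]
        viable, rejected = filter_viable(_records(isco68, raws))
        assert len(viable) == 4
        assert [(r.entry_id, reason) for r, reason in rejected] == [("1", "incomplete")]

    def test_all_complete(self, isco88):
        viable, rejected = filter_viable(_records(isco88, ["2221", "3111"]))
        assert len(viable) == 2 and rejected == []

    def test_uncoded_reason(self, isco88):
        viable, rejected = filter_viable(_records(isco88, ["2221", None]))
        assert len(viable) == 1
        assert rejected[0][1] == "uncoded"

    def test_ten_record_fixture(self, isco68):
        # 3 placeholder codes by construction -> 7 viable
        raws = ["1-21.10", "1-21", "2-11", "3-11.20", "4-00.00",
                "5-10.10", "6-21", "7-11.11", "8-12.13", "9-99.99"]
        viable, rejected = filter_viable(_records(isco68, raws))
        assert len(viable) == 7 and len(rejected) == 3


class TestSplitDataset:
    def test_sizes_100(self, isco88):
        records = _records(isco88, ["2221"] * 100)
        split = split_dataset(records, seed=0)
        assert (len(split.train), len(split.test), len(split.validation)) == (60, 30, 10)

    def test_exhaustive_and_disjoint(self, isco88):
        records = _records(isco88, ["2221"] * 103)
        split = split_dataset(records, seed=3)
        ids = [r.entry_id for part in (split.train, split.test, split.validation) for r in part]
        assert sorted(ids) == sorted(r.entry_id for r in records)
        assert len(set(ids)) == len(ids)

    def test_same_seed_identical(self, isco88):
        records = _records(isco88, ["2221"] * 50)
        a = split_dataset(records, seed=7)
        b = split_dataset(records, seed=7)
        assert [r.entry_id for r in a.train] == [r.entry_id for r in b.train]
        assert [r.entry_id for r in a.validation] == [r.entry_id for r in b.validation]

    def test_different_seeds_differ(self, isco88):
        records = _records(isco88, ["2221"] * 1000)
        a = split_dataset(records, seed=1)
        b = split_dataset(records, seed=2)
        assert [r.entry_id for r in a.train] != [r.entry_id for r in b.train]

    def test_largest_remainder(self, isco88):
        split = split_dataset(_records(isco88, ["2221"] * 7), fractions=(0.6, 0.3, 0.1), seed=0)
        sizes = (len(split.train), len(split.test), len(split.validation))
        assert sum(sizes) == 7 and sizes == (4, 2, 1)

    def test_too_few_records(self, isco88):
        with pytest.raises(DegenerateSplitError):
            split_dataset(_records(isco88, ["2221"] * 2), seed=0)

    def test_bad_fractions(self, isco88):
        records = _records(isco88, ["2221"] * 10)
        with pytest.raises(DataError):
            split_dataset(records, fractions=(0.5, 0.3, 0.1), seed=0)
        with pytest.raises(DataError):
            split_dataset(records, fractions=(0.8, 0.3, -0.1), seed=0)


class TestAugmentWithIndex:
    def test_concatenates_and_flags(self, isco88):
        train = _records(isco88, ["2221"] * 3)
        index = [InputRecord("i0", {"a": "medical doctor"}, gold=parse_code(isco88, "2221"))]
        out = augment_with_index(train, index)
        assert len(out) == 4
        assert out[-1].origin == "index"

    def test_empty_index(self, isco88):
        train = _records(isco88, ["2221"] * 3)
        assert augment_with_index(train, []) == train

    def test_dedup_by_code_and_text(self, isco88):
        train = []
        gold = parse_code(isco88, "2221")
        index = [
            InputRecord("i0", {"a": "doctor"}, gold=gold),
            InputRecord("i1", {"a": "doctor"}, gold=gold),  # duplicate
            InputRecord("i2", {"a": "physician"}, gold=gold),
        ]
        assert len(augment_with_index(train, index)) == 2

    def test_incomplete_index_code_rejected(self, isco68):
        bad = [InputRecord("i0", {"a": "x"}, gold=parse_code(isco68, "1-21"))]
        with pytest.raises(InvalidCodeError):
            augment_with_index([], bad)

    def test_index_only_codes_become_trainable(self, isco88, benchmark):
        del benchmark  # unrelated; keeps fixture warm for later tests
        rng = np.random.default_rng(0)
        raws = ["1111", "2222", "3333"]
        train = [
            InputRecord(f"t{i}", {"a": f"tok{raws[i % 3]} blah{rng.integers(5)}"},
                        gold=parse_code(isco88, raws[i % 3]))
            for i in range(30)
        ]
        index = [
            InputRecord(f"i{raw}", {"a": f"tok{raw}"}, gold=parse_code(isco88, raw))
            for raw in raws + ["4444", "5555"]
        ]
        split = DatasetSplit(train=augment_with_index(train, index),
                             test=train[:3], validation=train[:5])
        coder = train_coder(split, HyperParams(), HashedBagOfStems(dim=64, language="none"),
                            ("a",), seed=0)
        assert coder.n_classes == 5
        assert set(coder.label_table) == {"1111", "2222", "3333", "4444", "5555"}


class TestTrainAndPredict:
    def test_separable_corpus_accuracy(self, benchmark):
        correct = sum(
            1
            for gold, sugg in zip(benchmark.gold, benchmark.suggestions)
            if sugg[0].code.canonical == gold.canonical
        )
        assert correct / len(benchmark.gold) >= 0.99

    def test_training_deterministic(self, benchmark):
        coder2 = train_coder(
            benchmark.split, HyperParams(), benchmark.embedder,
            ("occupation", "sector"), seed=1,
        )
        again = predict_suggestions(coder2, benchmark.split.test, k=5)
        for a, b in zip(benchmark.suggestions, again):
            assert [(s.code.canonical, s.confidence, s.rank) for s in a] == [
                (s.code.canonical, s.confidence, s.rank) for s in b
            ]

    def test_label_table_covers_training_codes(self, benchmark):
        expected = {r.gold.canonical for r in benchmark.split.train}
        assert set(benchmark.coder.label_table) == expected

    def test_topk_on_training_example(self, benchmark):
        rec = benchmark.split.train[0]
        top = predict_topk(benchmark.coder, rec, k=1)
        assert len(top) == 1
        assert top[0].code.canonical == rec.gold.canonical

    def test_full_k_sums_to_one(self, benchmark):
        n = benchmark.coder.n_classes
        sugg = predict_topk(benchmark.coder, benchmark.split.test[0], k=n)
        assert len(sugg) == n
        assert sum(s.confidence for s in sugg) == pytest.approx(1.0, abs=1e-6)

    def test_k_larger_than_classes_returns_all(self, benchmark):
        sugg = predict_topk(benchmark.coder, benchmark.split.test[0], k=10_000)
        assert len(sugg) == benchmark.coder.n_classes

    def test_confidences_non_increasing(self, benchmark):
        for sugg in benchmark.suggestions:
            confs = [s.confidence for s in sugg]
            assert confs == sorted(confs, reverse=True)
            assert [s.rank for s in sugg] == list(range(1, len(sugg) + 1))

    def test_identical_records_identical_suggestions(self, benchmark):
        rec = benchmark.split.test[0]
        twin = InputRecord("copy", dict(rec.texts), gold=rec.gold)
        a = predict_topk(benchmark.coder, rec, k=3)
        b = predict_topk(benchmark.coder, twin, k=3)
        assert [(s.code.canonical, s.confidence) for s in a] == [
            (s.code.canonical, s.confidence) for s in b
        ]

    def test_single_class_raises(self, isco88):
        records = _records(isco88, ["2221"] * 10)
        split = DatasetSplit(train=records[:6], test=records[6:9], validation=records[9:])
        with pytest.raises(DegenerateModelError):
            train_coder(split, HyperParams(), HashedBagOfStems(dim=16), ("a",), seed=0)

    def test_top_bin_accuracy_at_least_overall(self, benchmark):
        from occucode.decision_support import bin_by_confidence

        bins = bin_by_confidence(benchmark.suggestions, benchmark.gold)
        top = bins[-1]
        overall = 100.0 * sum(
            1
            for g, s in zip(benchmark.gold, benchmark.suggestions)
            if s[0].code.canonical == g.canonical
        ) / len(benchmark.gold)
        assert top.count > 0
        assert top.accuracy >= overall

    def test_per_level_accuracy_non_increasing(self, benchmark):
        pred = [s[0].code for s in benchmark.suggestions]
        metrics = per_level_metrics(pred, benchmark.gold, benchmark.scheme)
        accs = [m.accuracy for m in metrics]
        assert all(a >= b for a, b in zip(accs, accs[1:]))

    def test_save_load_round_trip(self, benchmark, tmp_path):
        path = tmp_path / "model.bin"
        save_coder(benchmark.coder, str(path))
        reloaded = load_coder(str(path))
        again = predict_suggestions(reloaded, benchmark.split.test, k=5)
        for a, b in zip(benchmark.suggestions, again):
            assert [(s.code.canonical, s.confidence) for s in a] == [
                (s.code.canonical, s.confidence) for s in b
            ]

    def test_unmapped_hyperparams_recorded(self, benchmark):
        assert "subsample" in benchmark.coder.metadata["unmapped_hyperparams"]


class TestSelectInputClasses:
    @staticmethod
    def _noisy_corpus(seed=0):
        scheme, codes = generate_scheme([3, 6], seed=seed)
        spec = CorpusSpec(
            scheme=scheme, codes=codes, n_entries=240, vocab_per_code=1,
            target_median_words=2, input_classes=("info",), seed=seed,
        )
        records, _ = generate_corpus(spec)
        rng = np.random.default_rng(seed)
        out = []
        for rec in records:
            texts = dict(rec.texts)
            texts["junk"] = " ".join(
                f"noise{rng.integers(30)}" for _ in range(2)
            )
            out.append(InputRecord(rec.entry_id, texts, gold=rec.gold))
        return out

    def test_informative_beats_noise(self):
        records = self._noisy_corpus()
        best, table = select_input_classes(
            records, ["info", "junk"], HyperParams(),
            HashedBagOfStems(dim=128, language="none"), seed=0,
        )
        assert "info" in best  # never the noise class alone
        assert len(table) == 3
        scores = {row["input_classes"]: row["test_accuracy"] for row in table}
        assert scores[("info",)] > scores[("junk",)]

    def test_single_candidate(self):
        records = self._noisy_corpus()
        best, table = select_input_classes(
            records, ["info"], HyperParams(),
            HashedBagOfStems(dim=128, language="none"), seed=0,
        )
        assert best == ("info",)
        assert len(table) == 1

    def test_too_many_candidates(self):
        with pytest.raises(ConfigurationError):
            select_input_classes([], list("abcdefg"), HyperParams(), HashedBagOfStems(dim=8))
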