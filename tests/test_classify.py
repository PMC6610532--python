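import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from eplff.classify import (
    ConcentrationModel,
    NONE_OF_THE_ABOVE,
    TemplateStore,
    classify,
    estimate_concentration,
    evaluate,
    fit_concentration_model,
    hamming_distance,
    mean_absolute_error,
    overlap,
)
from eplff.datasets import SensorSample
from eplff.network import GCBinaryVector

bits = arrays(np.int8, 32, elements=st.integers(0, 1))


class TestMetrics:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=bits, b=bits)
    def test_hamming_axioms(self, a, b):
        if not (a.any() or b.any()):
            return
        d_ab = hamming_distance(a, b)
        d_ba = hamming_distance(b, a)
        assert d_ab == d_ba
        assert 0.0 <= d_ab <= 1.0
        assert hamming_distance(a, a) == (0.0 if a.any() else 1.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=bits, b=bits)
    def test_overlap_axioms(self, a, b):
        if not (a.any() and b.any()):
            return
        s = overlap(a, b)
        assert s == overlap(b, a)
        assert 0.0 <= s <= 1.0
        assert overlap(a, a) == pytest.approx(1.0)

    def test_union_normalization_value(self):
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 0, 1, 0])
        assert hamming_distance(a, b) == pytest.approx(2 / 3)
        assert hamming_distance(a, b, normalization="length") == pytest.approx(0.5)

    def test_all_zero_conventions(self):
        z = np.zeros(4, dtype=int)
        with pytest.warns(UserWarning):
            assert hamming_distance(z, z) == 1.0
        with pytest.warns(UserWarning):
            assert overlap(z, np.array([1, 0, 0, 0])) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming_distance(np.zeros(3), np.zeros(4))

    def test_unknown_normalization(self):
        with pytest.raises(ValueError):
            hamming_distance(np.ones(3), np.ones(3), normalization="cosine")


def _store(codes: dict[str, list[int]]) -> TemplateStore:
    store = TemplateStore()
    for label, c in codes.items():
        store.add(label, GCBinaryVector(np.array(c)))
    return store


class TestClassify:
    def test_empty_store_is_nota(self):
        res = classify(np.array([1, 0]), TemplateStore())
        assert res.is_nota and res.best_template is None

    def test_nearest_template_wins(self):
        store = _store({"a": [1, 1, 0, 0], "b": [0, 0, 1, 1]})
        assert classify(np.array([1, 1, 1, 0]), store).predicted == "a"

    def test_distance_above_threshold_rejects(self):
        store = _store({"a": [1, 1, 0, 0]})
        res = classify(np.array([0, 0, 1, 1]), store, threshold=0.5)
        assert res.predicted == NONE_OF_THE_ABOVE

    def test_tie_goes_to_earliest_trained(self):
        store = _store({"a": [1, 0, 0, 0], "b": [0, 1, 0, 0]})
        res = classify(np.array([1, 1, 0, 0]), store)
        assert res.predicted == "a"

    def test_overlap_metric_rejects_below_threshold(self):
        store = _store({"a": [1, 1, 0, 0]})
        res = classify(np.array([0, 0, 1, 1]), store, metric="overlap", threshold=0.5)
        assert res.is_nota

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            classify(np.array([1]), _store({"a": [1]}), metric="euclid")


class TestTemplateStore:
    def test_labels_in_training_order(self):
        store = _store({"b": [1, 0], "a": [0, 1]})
        store.add("b", GCBinaryVector(np.array([1, 1])))
        assert store.labels() == ["b", "a"]
        assert store.entries[-1][2] == 1  # second shot of "b"

    def test_csv_roundtrip(self, tmp_path):
        store = _store({"a": [1, 0, 1], "b": [0, 1, 1]})
        store.save_csv(tmp_path / "t.csv")
        back = TemplateStore.load_csv(tmp_path / "t.csv")
        assert len(back) == 2
        for (l1, c1, s1), (l2, c2, s2) in zip(store.entries, back.entries):
            assert (l1, s1) == (l2, s2)
            np.testing.assert_array_equal(c1.bits, c2.bits)

    def test_clear(self):
        store = _store({"a": [1]})
        store.clear()
        assert len(store) == 0 and store.labels() == []


def test_evaluate_bookkeeping(small_online, small_split, small_scale):
    net, res = small_online
    summary = evaluate(small_split.test, net, small_scale, res.store)
    assert 0.0 <= summary.overall_accuracy <= 1.0
    assert summary.n_trained_samples == len(small_split.test)
    assert summary.nota_rate_untrained is None  # every test label was trained
    assert sum(summary.confusion.values()) == len(small_split.test)
    for lab, acc in summary.per_class_accuracy.items():
        assert 0.0 <= acc <= 1.0


class TestConcentrationModel:
    def test_exact_quadratic_recovery(self):
        model = ConcentrationModel()
        scale = np.array([1.0, 1.0])
        samples = [
            SensorSample(features=np.array([x / 2, x / 2]), concentration=3.0 * x**2 + 7.0)
            for x in (1.0, 2.0, 5.0)
        ]
        fit_concentration_model("a", samples, scale, model)
        a, b = model.coefficients["a"]
        assert a == pytest.approx(3.0) and b == pytest.approx(7.0)
        pred = model.predict("a", 4.0)
        assert pred == pytest.approx(3.0 * 16 + 7.0)

    def test_too_few_distinct_points_unavailable(self):
        model = ConcentrationModel()
        samples = [
            SensorSample(features=np.array([1.0, 1.0]), concentration=10.0),
            SensorSample(features=np.array([1.0, 1.0]), concentration=12.0),
        ]
        with pytest.warns(UserWarning, match="unavailable"):
            fit_concentration_model("a", samples, np.ones(2), model)
        assert not model.available("a")

    def test_negative_prediction_floored(self):
        model = ConcentrationModel(coefficients={"a": (1.0, -100.0)})
        with pytest.warns(UserWarning, match="floored"):
            assert model.predict("a", 1.0) == 0.0

    def test_estimate_returns_none_for_nota(self):
        model = ConcentrationModel(coefficients={"a": (1.0, 0.0)})
        s = SensorSample(features=np.ones(2), concentration=5.0)
        assert estimate_concentration(s, NONE_OF_THE_ABOVE, model, np.ones(2)) is None
        assert estimate_concentration(s, "unknown_label", model, np.ones(2)) is None
        assert estimate_concentration(s, "a", model, np.ones(2)) == pytest.approx(4.0)


class TestMeanAbsoluteError:
    def test_skips_unavailable(self):
        assert mean_absolute_error([1.0, None, 3.0], [2.0, 9.0, 3.0]) == pytest.approx(0.5)

    def test_misaligned(self):
        with pytest.raises(ValueError):
            mean_absolute_error([1.0], [1.0, 2.0])

    def test_all_missing(self):
        with pytest.raises(ValueError):
            mean_absolute_error([None], [1.0])
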