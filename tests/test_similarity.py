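"""Tests for FI-series similarity metrics and the range-based IOU."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freezeindex import (
    FISeries,
    MetricSet,
    SimilarityReport,
    leave_one_out_iou,
    pairwise_metrics,
    range_iou,
    resample_linear,
    similarity_matrix,
    standardize,
)


def make_series(values, label="m", step=0.1, t0=0.0):
    values = np.asarray(values, dtype=float)
    return FISeries(
        times=t0 + np.arange(values.size) * step,
        values=values,
        method=label,
        config={},
    )


class TestResample:
    def test_identity_on_matching_uniform_grid(self, rng):
        series = make_series(rng.standard_normal(50))
        out = resample_linear(series, 50)
        np.testing.assert_allclose(out.times, series.times, atol=1e-12)
        np.testing.assert_allclose(out.values, series.values, atol=1e-12)

    def test_exact_on_linear_trends(self):
        series = make_series(2.0 + 0.3 * np.arange(40))
        out = resample_linear(series, 17)
        expected = 2.0 + 0.3 * (out.times / 0.1)
        np.testing.assert_allclose(out.values, expected, atol=1e-10)
        assert out.values[0] == pytest.approx(series.values[0])
        assert out.values[-1] == pytest.approx(series.values[-1])

    def test_nan_values_dropped_before_interpolation(self):
        values = np.array([0.0, np.nan, 2.0, 3.0])
        out = resample_linear(make_series(values), 4)
        assert np.all(np.isfinite(out.values))
        np.testing.assert_allclose(out.values, [0.0, 1.0, 2.0, 3.0], atol=1e-12)

    def test_insufficient_support_rejected(self):
        values = np.array([1.0, np.nan, np.nan, np.nan])
        with pytest.raises(ValueError):
            resample_linear(make_series(values), 10)


class TestStandardize:
    def test_three_point_example(self):
        out = standardize(make_series([1.0, 2.0, 3.0]))
        # population std of [1,2,3] is sqrt(2/3)
        np.testing.assert_allclose(out.values, np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0))

    def test_contracts_and_idempotence(self, rng):
        out = standardize(make_series(rng.standard_normal(100) * 5 + 3))
        assert abs(out.values.mean()) < 1e-10
        assert np.std(out.values) == pytest.approx(1.0, abs=1e-10)
        twice = standardize(out)
        np.testing.assert_allclose(twice.values, out.values, atol=1e-10)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            standardize(make_series(np.full(10, 4.2)))


class TestPairwiseMetrics:
    def test_self_comparison(self, rng):
        a = standardize(make_series(rng.standard_normal(60)))
        scores = pairwise_metrics(a, a)
        assert scores.mad == pytest.approx(0.0, abs=1e-12)
        assert scores.rho == pytest.approx(1.0, abs=1e-12)
        assert scores.r2 == pytest.approx(1.0, abs=1e-12)

    def test_negated_standardized_series(self, rng):
        a = standardize(make_series(rng.standard_normal(60)))
        b = make_series(-a.values)
        scores = pairwise_metrics(a, b)
        assert scores.rho == pytest.approx(-1.0, abs=1e-10)
        assert scores.mad == pytest.approx(np.mean(np.abs(2 * a.values)), abs=1e-10)
        assert scores.r2 == pytest.approx(-3.0, abs=1e-8)

    def test_matches_textbook_formulas(self, rng):
        va = rng.standard_normal(100)
        vb = rng.standard_normal(100)
        scores = pairwise_metrics(make_series(va), make_series(vb))
        mad = np.sum(np.abs(va - vb)) / 100
        rho = np.sum((va - va.mean()) * (vb - vb.mean())) / (
            np.sqrt(np.sum((va - va.mean()) ** 2)) * np.sqrt(np.sum((vb - vb.mean()) ** 2))
        )
        r2 = 1.0 - np.sum((va - vb) ** 2) / np.sum((va - va.mean()) ** 2)
        assert scores.mad == pytest.approx(mad, abs=1e-10)
        assert scores.rho == pytest.approx(rho, abs=1e-10)
        assert scores.r2 == pytest.approx(r2, abs=1e-10)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pairwise_metrics(make_series(rng.standard_normal(10)), make_series(rng.standard_normal(11)))


@pytest.fixture(scope="module")
def five_series():
    rng = np.random.default_rng(101)
    base = np.cumsum(rng.standard_normal(400)) * 0.1
    out = []
    for i in range(5):
        noisy = base + 0.3 * rng.standard_normal(400) + i
        out.append(make_series(noisy, label=f"m{i}", step=0.1 * (1 + 0.1 * i)))
    return out


class TestSimilarityMatrix:
    def test_five_methods_give_ten_pairs(self, five_series):
        report = similarity_matrix(five_series)
        assert len(report.pairs) == 10
        assert set(report.labels) == {f"m{i}" for i in range(5)}

    def test_matrix_diagonal_is_self_score(self, five_series):
        report = similarity_matrix(five_series)
        assert np.allclose(np.diag(report.metric_matrix("mad")), 0.0)
        assert np.allclose(np.diag(report.metric_matrix("rho")), 1.0)
        assert np.allclose(np.diag(report.metric_matrix("r2")), 1.0)

    def test_permutation_invariance_up_to_relabeling(self, five_series):
        report = similarity_matrix(five_series)
        shuffled = similarity_matrix(five_series[::-1])
        for (i, j), scores in report.pairs.items():
            assert shuffled.pair(i, j).mad == pytest.approx(scores.mad, abs=1e-12)
            assert shuffled.pair(i, j).rho == pytest.approx(scores.rho, abs=1e-12)

    def test_duplicated_series_scores_perfectly(self, five_series):
        twin = make_series(five_series[0].values, label="twin", step=five_series[0].step)
        report = similarity_matrix([five_series[0], twin, five_series[1], five_series[2]])
        scores = report.pair("m0", "twin")
        assert scores.mad == pytest.approx(0.0, abs=1e-9)
        assert scores.rho == pytest.approx(1.0, abs=1e-9)
        assert scores.r2 == pytest.approx(1.0, abs=1e-9)

    def test_fewer_than_three_series_rejected(self, five_series):
        with pytest.raises(ValueError):
            similarity_matrix(five_series[:2])

    def test_json_round_trip_structure(self, five_series, tmp_path):
        import json

        report = similarity_matrix(five_series)
        path = tmp_path / "report.json"
        report.to_json(path)
        payload = json.loads(path.read_text())
        assert len(payload["pairs"]) == 10
        assert set(payload["leave_one_out_iou"]) == set(report.labels)


class TestRangeIou:
    @pytest.mark.parametrize(
        ("a", "b", "expected"),
        [
            ([0.1, 0.4, 0.9], [0.1, 0.4, 0.9], 1.0),   # identical -> perfect overlap
            ([0.0, 1.0], [2.0, 3.0], 0.0),              # disjoint ranges
            ([0.0, 1.0], [0.5, 2.0], 0.25),             # (1-0.5)/(2-0)
        ],
    )
    def test_analytic_cases(self, a, b, expected):
        assert range_iou(a, b) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_union_defined_as_one(self):
        assert range_iou([2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_small_sets_rejected(self):
        with pytest.raises(ValueError):
            range_iou([1.0], [1.0, 2.0])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=8),
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=8),
    )
    def test_bounds_symmetry_and_bruteforce(self, a, b):
        iou = range_iou(a, b)
        assert 0.0 <= iou <= 1.0
        assert iou == pytest.approx(range_iou(b, a), abs=1e-15)
        # brute force: interval overlap of the two hulls over their union hull
        lo_a, hi_a, lo_b, hi_b = min(a), max(a), min(b), max(b)
        union = max(hi_a, hi_b) - min(lo_a, lo_b)
        inter = max(0.0, min(hi_a, hi_b) - max(lo_a, lo_b))
        expected = 1.0 if union == 0 else inter / union
        assert iou == pytest.approx(expected, rel=1e-12, abs=1e-15)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=6),
        st.lists(st.floats(-100, 100), min_size=2, max_size=6),
        st.floats(0.1, 10.0),
        st.floats(-50.0, 50.0),
    )
    def test_affine_invariance(self, a, b, scale, shift):
        mapped_a = [scale * v + shift for v in a]
        mapped_b = [scale * v + shift for v in b]
        assert range_iou(mapped_a, mapped_b) == pytest.approx(range_iou(a, b), rel=1e-6, abs=1e-9)


class TestLeaveOneOut:
    def _toy_report(self):
        labels = ("a", "b", "c", "d")
        pair_values = {
            ("a", "b"): 0.1, ("a", "c"): 0.2, ("a", "d"): 0.3,
            ("b", "c"): 0.25, ("b", "d"): 0.5, ("c", "d"): 0.6,
        }
        pairs = {k: MetricSet(mad=v, rho=v, r2=v) for k, v in pair_values.items()}
        return SimilarityReport(labels=labels, pairs=pairs, n_common=10)

    def test_group_sizes_for_five_labels(self):
        rng = np.random.default_rng(7)
        series = [make_series(np.cumsum(rng.standard_normal(200)) + 0.1 * rng.standard_normal(200),
                              label=f"m{i}") for i in range(5)]
        report = similarity_matrix(series)
        a_scores = [m for pair, m in report.pairs.items() if "m0" in pair]
        b_scores = [m for pair, m in report.pairs.items() if "m0" not in pair]
        assert (len(a_scores), len(b_scores)) == (4, 6)
        ious = leave_one_out_iou(report, "m0")
        assert set(ious) == {"mad", "rho", "r2"}
        assert all(0.0 <= v <= 1.0 for v in ious.values())

    def test_hand_evaluated_toy(self):
        report = self._toy_report()
        # A = scores with "a": {0.1, 0.2, 0.3}; B = rest: {0.25, 0.5, 0.6}
        # intersection [0.25, 0.3], union [0.1, 0.6] -> 0.05 / 0.5 = 0.1
        ious = leave_one_out_iou(report, "a")
        for metric in ("mad", "rho", "r2"):
            assert ious[metric] == pytest.approx(0.1, abs=1e-12)

    def test_too_few_labels_rejected(self):
        pairs = {
            ("a", "b"): MetricSet(0.1, 0.9, 0.8),
            ("a", "c"): MetricSet(0.2, 0.8, 0.7),
            ("b", "c"): MetricSet(0.3, 0.7, 0.6),
        }
        report = SimilarityReport(labels=("a", "b", "c"), pairs=pairs, n_common=5)
        with pytest.raises(ValueError):
            leave_one_out_iou(report, "a")

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            leave_one_out_iou(self._toy_report(), "zz")
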