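"""IoU/SC/GC metrics, aggregation and the analytic IoU ceiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camval import (aggregate, area_ratio_analysis, compute_metrics,
                    is_consistent, max_achievable_iou)
from camval.consistency import make_record
from camval.errors import AlignmentError, ConfigurationError


def _mask(shape, n_true, seed=0):
    rng = np.random.default_rng(seed)
    flat = np.zeros(np.prod(shape), dtype=bool)
    flat[rng.choice(flat.size, size=n_true, replace=False)] = True
    return flat.reshape(shape)


def _nested_pair(n_small, n_large, shape=(40, 40)):
    big = np.zeros(shape, dtype=bool)
    big.ravel()[:n_large] = True
    small = np.zeros(shape, dtype=bool)
    small.ravel()[:n_small] = True
    return small, big


class TestComputeMetrics:
    def test_identical_masks(self):
        m = _mask((16, 16), 40)
        t = compute_metrics(m, m)
        assert (t.iou, t.sc, t.gc) == (1.0, 1.0, 1.0)

    def test_disjoint_masks(self):
        s = np.zeros((8, 8), bool)
        g = np.zeros((8, 8), bool)
        s[:2] = True
        g[6:] = True
        t = compute_metrics(s, g)
        assert (t.iou, t.sc, t.gc) == (0.0, 0.0, 0.0)

    def test_nested_300_100(self):
        g, s = _nested_pair(100, 300)
        t = compute_metrics(s, g)
        assert t.iou == pytest.approx(1 / 3)
        assert t.sc == pytest.approx(1 / 3)
        assert t.gc == 1.0

    def test_both_empty_is_perfect_agreement(self):
        z = np.zeros((8, 8), bool)
        t = compute_metrics(z, z)
        assert t.iou == 1.0 and t.sc is None and t.gc is None

    def test_one_empty_is_zero_iou_with_undefined_cover(self):
        z = np.zeros((8, 8), bool)
        m = _mask((8, 8), 10)
        t = compute_metrics(z, m)
        assert t.iou == 0.0 and t.sc is None and t.gc == 0.0
        t = compute_metrics(m, z)
        assert t.iou == 0.0 and t.sc == 0.0 and t.gc is None

    def test_dimension_mismatch(self):
        with pytest.raises(AlignmentError):
            compute_metrics(np.zeros((4, 4), bool), np.zeros((5, 5), bool))

    def test_matches_per_pixel_double_loop(self):
        # brute-force oracle over every pixel
        s = _mask((16, 16), 60, seed=1)
        g = _mask((16, 16), 45, seed=2)
        inter = union = 0
        for r in range(16):
            for c in range(16):
                if s[r, c] and g[r, c]:
                    inter += 1
                if s[r, c] or g[r, c]:
                    union += 1
        t = compute_metrics(s, g)
        assert t.iou == pytest.approx(inter / union)
        assert t.sc == pytest.approx(inter / s.sum())
        assert t.gc == pytest.approx(inter / g.sum())


@settings(max_examples=60, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_iou_identity_from_covers(seed):
    # iou = sc*gc / (sc + gc - sc*gc) wherever all are defined and positive
    rng = np.random.default_rng(seed)
    s = rng.random((12, 12)) < rng.uniform(0.1, 0.6)
    g = rng.random((12, 12)) < rng.uniform(0.1, 0.6)
    t = compute_metrics(s, g)
    if t.sc is None or t.gc is None or t.sc * t.gc == 0:
        return
    assert abs(t.iou - t.sc * t.gc / (t.sc + t.gc - t.sc * t.gc)) < 1e-12
    assert t.iou <= min(t.sc, t.gc) + 1e-12


def test_growing_intersection_increases_all_metrics():
    shape = (20, 20)
    s = np.zeros(shape, bool)
    g = np.zeros(shape, bool)
    s.ravel()[:100] = True
    g.ravel()[80:180] = True  # overlap 20
    t1 = compute_metrics(s, g)
    g2 = np.zeros(shape, bool)
    g2.ravel()[40:140] = True  # overlap 60, same |S|, |G|
    t2 = compute_metrics(s, g2)
    assert t2.iou > t1.iou and t2.sc > t1.sc and t2.gc > t1.gc


class TestIsConsistent:
    @pytest.mark.parametrize("iou,expected", [(0.51, True), (0.49, False),
                                              (0.50, True)])
    def test_threshold_boundary_inclusive(self, iou, expected):
        assert is_consistent(iou) is expected

    def test_undefined_rejected(self):
        with pytest.raises(ConfigurationError):
            is_consistent(None)


class TestAggregate:
    def _records(self, values, annotators=("A1",), model="m", variant="S_o"):
        recs = []
        for i, v in enumerate(values):
            n = int(200 * v)
            s, g = _nested_pair(n, 200)
            recs.append(make_record(f"img{i}", annotators[i % len(annotators)],
                                    model, variant, s, g))
        return recs

    def test_constant_records(self):
        recs = self._records([0.4] * 6)
        summ = aggregate(recs)
        row = summ.table[summ.table["metric"] == "iou"].iloc[0]
        assert row["overall_median"] == pytest.approx(0.4)
        assert row["A1_q1"] == pytest.approx(0.4)
        assert row["A1_q3"] == pytest.approx(0.4)

    def test_pooled_median_across_annotators(self):
        recs = self._records([0.2, 0.4, 0.6], annotators=("A1", "A2", "A3"))
        summ = aggregate(recs)
        row = summ.table[summ.table["metric"] == "iou"].iloc[0]
        assert row["overall_median"] == pytest.approx(0.4)

    def test_medians_match_sort_oracle(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0.05, 0.95, size=300).round(3)
        recs = self._records(vals, annotators=("A1", "A2"))
        summ = aggregate(recs)
        row = summ.table[summ.table["metric"] == "iou"].iloc[0]
        ious = np.array([r.iou for r in recs])
        srt = np.sort(ious)
        n = len(srt)
        med = (srt[n // 2 - 1] + srt[n // 2]) / 2 if n % 2 == 0 else srt[n // 2]
        assert row["overall_median"] == pytest.approx(med, abs=1e-12)

    def test_undefined_records_excluded_and_counted(self):
        z = np.zeros((10, 10), bool)
        m = _mask((10, 10), 20)
        recs = [make_record("a", "A1", "m", "S_o", z, m),
                make_record("b", "A1", "m", "S_o", m, m)]
        summ = aggregate(recs)
        sc_row = summ.table[summ.table["metric"] == "sc"].iloc[0]
        assert sc_row["overall_median"] == pytest.approx(1.0)  # only defined one
        excl = summ.excluded
        assert excl.loc[excl["metric"] == "sc", "n_undefined"].item() == 1


class TestAreaRatio:
    def test_equal_masks_ratio_one(self):
        m = _mask((16, 16), 50)
        recs = [make_record("i", "A1", "m", "S_o", m, m)]
        df = area_ratio_analysis(recs)
        assert (df["median_ratio"] == 1.0).all()

    def test_constructed_ratio(self):
        g, s = _nested_pair(100, 292)
        recs = [make_record("i", "A1", "m", "S_o", s, g)]
        df = area_ratio_analysis(recs)
        assert df["median_ratio"].iloc[0] == pytest.approx(2.92)


class TestMaxAchievableIoU:
    def test_ratio_one_is_perfect(self):
        assert max_achievable_iou(1.0) == 1.0

    def test_paper_like_ratios(self):
        assert max_achievable_iou(0.82) == pytest.approx(0.82)
        assert max_achievable_iou(2.92) == pytest.approx(100 / 292, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(r=st.floats(0.01, 100, allow_nan=False))
    def test_symmetry(self, r):
        assert max_achievable_iou(r) == pytest.approx(max_achievable_iou(1 / r),
                                                      rel=1e-9)

    def test_bound_is_tight_for_nested_masks(self):
        for n_g, n_s in [(100, 292), (100, 82), (50, 400)]:
            small, big = (n_s, n_g) if n_s < n_g else (n_g, n_s)
            inner, outer = _nested_pair(small, big)
            s, g = (inner, outer) if n_s < n_g else (outer, inner)
            t = compute_metrics(s, g)
            assert t.iou == pytest.approx(max_achievable_iou(n_s / n_g))

    def test_domain_error(self):
        with pytest.raises(ConfigurationError):
            max_achievable_iou(0.0)
        with pytest.raises(ConfigurationError):
            max_achievable_iou(-2.0)
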