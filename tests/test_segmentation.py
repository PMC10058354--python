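import numpy as np
import pytest

from armuse.segmentation import (Block, HotellingSegmenter,
                                 SegmentationConfig, calibrate_threshold,
                                 hotelling_t2, scan_statistics,
                                 segment_fixed, segment_variable)


def literal_t2(a, b):
    """Element-by-element transcription of the two-sample T² definition."""
    m, n, p = len(a), len(b), a.shape[1]
    xa = [sum(a[i][j] for i in range(m)) / m for j in range(p)]
    xb = [sum(b[i][j] for i in range(n)) / n for j in range(p)]
    d = [xa[j] - xb[j] for j in range(p)]
    s = [[0.0] * p for _ in range(p)]
    for j in range(p):
        for k in range(p):
            sa = sum((a[i][j] - xa[j]) * (a[i][k] - xa[k]) for i in range(m))
            sb = sum((b[i][j] - xb[j]) * (b[i][k] - xb[k]) for i in range(n))
            s[j][k] = (sa + sb) / (m + n - 2)
    inv = np.linalg.inv(np.array(s))
    d = np.array(d)
    return (m * n) / (m + n) * float(d @ inv @ d)


class TestHotellingT2:
    def test_identical_windows_give_zero(self, rng):
        w = rng.normal(size=(30, 6))
        assert hotelling_t2(w, w) == 0.0

    def test_one_channel_equals_squared_pooled_t(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(loc=0.7, size=35)
        m, n = len(a), len(b)
        sp2 = (((m - 1) * a.var(ddof=1) + (n - 1) * b.var(ddof=1))
               / (m + n - 2))
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / m + 1 / n))
        assert hotelling_t2(a, b, ridge_eps=0.0) == pytest.approx(t ** 2,
                                                                  rel=1e-10)

    def test_matches_literal_formula(self, rng):
        for _ in range(10):
            a = rng.normal(size=(25, 6))
            b = rng.normal(loc=0.3, size=(30, 6))
            assert hotelling_t2(a, b, ridge_eps=0.0) == pytest.approx(
                literal_t2(a, b), abs=1e-8, rel=1e-8)

    def test_invariant_under_common_affine_map(self, rng):
        a = rng.normal(size=(100, 6))
        b = rng.normal(loc=0.5, size=(100, 6))
        mat = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        shiftv = rng.normal(size=6)
        t_raw = hotelling_t2(a, b, ridge_eps=0.0)
        t_mapped = hotelling_t2(a @ mat + shiftv, b @ mat + shiftv,
                                ridge_eps=0.0)
        assert t_mapped == pytest.approx(t_raw, rel=1e-8)

    def test_monotone_in_mean_shift(self, rng):
        base_a = rng.normal(size=(200, 6))
        base_b = rng.normal(size=(200, 6))
        stats = [hotelling_t2(base_a, base_b + delta, ridge_eps=0.0)
                 for delta in np.linspace(0.2, 3.0, 10)]
        assert all(x < y for x, y in zip(stats, stats[1:]))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            hotelling_t2(np.zeros((1, 6)), np.zeros((10, 6)))

    def test_non_finite_rejected(self, rng):
        a = rng.normal(size=(10, 6))
        a[3, 2] = np.nan
        with pytest.raises(ValueError):
            hotelling_t2(a, rng.normal(size=(10, 6)))


class TestSegmentFixed:
    def test_exact_division(self, rng):
        blocks = segment_fixed(rng.normal(size=(2400, 6)), 800)
        assert [(b.start, b.end) for b in blocks] == [(0, 800), (800, 1600),
                                                      (1600, 2400)]

    def test_remainder_discarded(self, rng):
        blocks = segment_fixed(rng.normal(size=(2000, 6)), 800)
        assert len(blocks) == 2
        assert blocks[-1].end == 1600

    def test_block_spans_four_seconds_at_200hz(self, rng):
        blocks = segment_fixed(rng.normal(size=(800, 6)), 800)
        assert blocks[0].size / 200.0 == 4.0

    def test_short_series_warns_and_returns_empty(self, rng):
        with pytest.warns(UserWarning):
            assert segment_fixed(rng.normal(size=(100, 6)), 800) == []


def _shifted_series(rng, n=7000, change=3000, delta=4.0):
    x = rng.normal(size=(n, 6))
    x[change:] += delta
    return x


class TestSegmentVariable:
    def test_blocks_partition_series(self, rng):
        x = _shifted_series(rng)
        cfg = SegmentationConfig(t2_threshold=50.0)
        blocks = segment_variable(x, cfg)
        assert blocks[0].start == 0 and blocks[-1].end == len(x)
        for prev, cur in zip(blocks, blocks[1:]):
            assert prev.end == cur.start

    def test_first_or_second_comparison_block_lengths(self, rng):
        # change at 3000: the first probe comparison (boundary 2000) sees a
        # partially contaminated window, the second (boundary 2600) a more
        # contaminated one, so their statistics bracket usable thresholds.
        x = _shifted_series(rng, change=3000, delta=1.0)
        cfg = SegmentationConfig()
        stats = scan_statistics(x, cfg)
        low = stats[0] * 0.5          # below the first statistic -> split at 2000
        mid = (stats[0] + stats[1]) / 2   # between first and second -> 2600
        assert stats[1] > stats[0]
        first = segment_variable(x, SegmentationConfig(t2_threshold=low))[0]
        assert first.size == 2000
        second = segment_variable(x, SegmentationConfig(t2_threshold=mid))[0]
        assert second.size == 2600

    def test_boundary_recovered_within_shift(self, rng):
        x = _shifted_series(rng, change=3000, delta=4.0)
        cfg = SegmentationConfig()
        stats = scan_statistics(x, cfg)
        # exhaustive scan confirms the statistic peaks at the true change
        peak_boundary = 2000 + 600 * int(np.argmax(stats))
        assert abs(peak_boundary - 3000) <= 600
        blocks = segment_variable(
            x, SegmentationConfig(t2_threshold=float(np.median(stats) * 3)))
        bounds = [b.end for b in blocks[:-1]]
        assert any(abs(b - 3000) <= 600 for b in bounds)

    def test_homogeneous_series_single_block(self, rng):
        x = rng.normal(size=(9000, 6))
        stats = scan_statistics(x, SegmentationConfig())
        cfg = SegmentationConfig(t2_threshold=float(stats.max() + 1))
        assert len(segment_variable(x, cfg)) == 1

    def test_short_series_single_block_with_warning(self, rng):
        cfg = SegmentationConfig(t2_threshold=10.0)
        with pytest.warns(UserWarning):
            blocks = segment_variable(rng.normal(size=(3000, 6)), cfg)
        assert [(b.start, b.end) for b in blocks] == [(0, 3000)]

    def test_requires_threshold(self, rng):
        with pytest.raises(ValueError):
            segment_variable(rng.normal(size=(5000, 6)), SegmentationConfig())


class TestCalibrateThreshold:
    def test_separable_regimes_reach_full_tpr(self, rng):
        series, transitions = [], []
        for _ in range(2):
            x = rng.normal(size=(12000, 6))
            x[4200:] += 5.0
            x[8400:] += 5.0
            series.append(x)
            transitions.append([4200, 8400])
        cfg = SegmentationConfig()
        thr = calibrate_threshold(series, transitions, cfg)
        seg = HotellingSegmenter(threshold=thr).fit(series, transitions)
        assert seg.score(series, transitions) >= 0.80

    def test_degenerate_target_disables_detection(self, rng):
        x = _shifted_series(rng)
        cfg = SegmentationConfig(target_tpr=0.0)
        thr = calibrate_threshold([x], [[3000]], cfg)
        assert thr > scan_statistics(x, SegmentationConfig()).max()

    def test_unreachable_target_warns(self, rng):
        x = rng.normal(size=(8000, 6))  # homogeneous: no detectable change
        with pytest.warns(UserWarning):
            calibrate_threshold([x], [[100]], SegmentationConfig())


class TestHotellingSegmenter:
    def test_fit_predict_roundtrip(self, rng):
        x = _shifted_series(rng)
        seg = HotellingSegmenter().fit([x], [[3000]])
        blocks = seg.predict(x)
        assert blocks[0].start == 0 and blocks[-1].end == len(x)

    def test_sklearn_params_clone(self):
        seg = HotellingSegmenter(shift=300)
        assert seg.get_params()["shift"] == 300
        seg.set_params(target_tpr=0.7)
        assert seg.target_tpr == 0.7

    def test_unfitted_predict_rejected(self, rng):
        with pytest.raises(ValueError):
            HotellingSegmenter().predict(rng.normal(size=(5000, 6)))


class TestBlockInvariants:
    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            Block(5, 5)

    def test_fixed_blocks_cover_prefix(self, rng):
        n = 4100
        blocks = segment_fixed(rng.normal(size=(n, 6)), 800)
        assert blocks[0].start == 0
        assert all(b.size == 800 for b in blocks)
        assert blocks[-1].end <= n
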