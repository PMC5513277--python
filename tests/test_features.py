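import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songdiff import features
from songdiff.features import (
    FEATURE_NAMES,
    InsufficientDataError,
    cvm_counts,
    extract_features,
    frequency_shifts,
    internote_intervals,
    ks_compare_shifts,
    shifts_table,
)

from conftest import make_song


class TestIntervals:
    def test_positive_gap(self):
        s = make_song([(0.5, 1.0, 2000, 3000), (1.05, 1.4, 2000, 3000)])
        assert internote_intervals(s) == pytest.approx([0.05])

    def test_overlap_is_negative(self):
        s = make_song([(0.5, 1.0, 2000, 3000), (0.99, 1.4, 2000, 3000)])
        assert internote_intervals(s) == pytest.approx([-0.01])

    def test_single_note_song_empty(self):
        s = make_song([(0.0, 0.2, 2000, 3000)])
        assert internote_intervals(s).size == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.005, 0.5), min_size=2, max_size=12),
           st.lists(st.floats(-0.05, 0.4), min_size=11, max_size=11))
    def test_matches_bruteforce(self, durs, gaps):
        spans, t = [], 0.0
        for d, g in zip(durs, gaps):
            spans.append((t, t + d, 2000, 3000))
            t += d + g
        spans.sort(key=lambda x: x[0])
        s = make_song(spans)
        expected = [spans_i1[0] - spans_i[1]
                    for spans_i, spans_i1 in zip(spans, spans[1:])]
        assert internote_intervals(s) == pytest.approx(expected)


class TestCvmCounts:
    def test_all_slow_intervals_zero(self):
        s = make_song([(0, 0.2, 2000, 3000), (0.3, 0.5, 2000, 3000),
                       (0.8, 1.0, 2000, 3000)])
        assert cvm_counts(s) == (0, 0)

    def test_hand_enumeration(self):
        # intervals: 0.001 (short), -0.003 (overlap), 0.5 (neither)
        s = make_song([
            (0.0, 0.2, 2000, 3000),
            (0.201, 0.4, 2000, 3000),
            (0.397, 0.6, 2000, 3000),
            (1.1, 1.3, 2000, 3000),
        ])
        assert cvm_counts(s) == (1, 1)

    def test_boundary_exactly_2ms_not_short(self):
        s = make_song([(0.0, 0.2, 2000, 3000), (0.202, 0.4, 2000, 3000)])
        assert cvm_counts(s) == (0, 0)

    def test_invariant_under_translation_and_transposition(self):
        spans = [(0.0, 0.2, 2000, 3000), (0.2005, 0.4, 2500, 3500),
                 (0.39, 0.6, 2200, 3100)]
        s = make_song(spans)
        shifted = make_song([(a + 10, b + 10, lo + 700, hi + 700)
                             for a, b, lo, hi in spans])
        assert cvm_counts(s) == cvm_counts(shifted)
        f1, f2 = extract_features(s), extract_features(shifted)
        assert f1.cvm_short_interval_rate == f2.cvm_short_interval_rate
        assert f1.cvm_overlap_rate == f2.cvm_overlap_rate


class TestExtractFeatures:
    def test_single_note_song(self):
        f = extract_features(make_song([(1.0, 1.2, 2000, 4000)]))
        assert f.mean_note_length == pytest.approx(0.2)
        assert f.song_bandwidth == pytest.approx(2000)
        assert f.sd_note_length == f.sd_high_freq == 0.0
        assert f.cvm_short_interval_rate == f.cvm_overlap_rate == 0.0
        assert f.n_notes == 1

    def test_two_identical_notes(self):
        f = extract_features(make_song([(0, 0.2, 2000, 3000), (0.5, 0.7, 2000, 3000)]))
        assert f.sd_note_length == pytest.approx(0.0, abs=1e-12)
        assert f.sd_note_bandwidth == pytest.approx(0.0, abs=1e-12)
        assert f.delivery_rate == pytest.approx(2 / 0.7)

    def test_feature_arity_is_14(self):
        assert len(FEATURE_NAMES) == 14
        f = extract_features(make_song([(0, 0.2, 2000, 3000)]))
        numeric = {k: v for k, v in f.as_dict().items()
                   if not k.endswith("_id")}
        assert set(numeric) == set(FEATURE_NAMES)

    def test_recomputation_oracle_on_random_song(self):
        """Every field equals a straightforward independent recomputation."""
        rng = np.random.default_rng(42)
        spans, t = [], 0.0
        for _ in range(20):
            d = rng.uniform(0.05, 0.3)
            lo = rng.uniform(1500, 3000)
            spans.append((t, t + d, lo, lo + rng.uniform(300, 2500)))
            t += d + rng.uniform(-0.005, 0.2)
        spans.sort(key=lambda x: x[0])
        s = make_song(spans)
        f = extract_features(s)
        durs = np.array([b - a for a, b, _, _ in spans])
        highs = np.array([h for *_, h in spans])
        lows = np.array([lo for _, _, lo, _ in spans])
        dur_song = max(b for _, b, *_ in spans) - spans[0][0]
        assert f.mean_note_length == pytest.approx(durs.mean())
        assert f.sd_note_length == pytest.approx(durs.std(ddof=1))
        assert f.mean_high_freq == pytest.approx(highs.mean())
        assert f.sd_low_freq == pytest.approx(lows.std(ddof=1))
        assert f.mean_note_bandwidth == pytest.approx((highs - lows).mean())
        assert f.song_bandwidth == pytest.approx(highs.max() - lows.min())
        assert f.song_bandwidth >= (highs - lows).max()
        assert f.song_duration == pytest.approx(dur_song)
        assert f.delivery_rate == pytest.approx(20 / dur_song)
        iv = np.array([spans[i + 1][0] - spans[i][1] for i in range(19)])
        assert f.cvm_short_interval_rate == pytest.approx(
            np.sum((iv >= 0) & (iv < 0.002)) / 20)
        assert f.cvm_overlap_rate == pytest.approx(np.sum(iv < 0) / 20)

    def test_row_order_invariance(self):
        """Features are invariant to input note order (resorted on assembly)."""
        from songdiff.annotations import assemble_songs
        rng = np.random.default_rng(3)
        spans = [(i * 0.3, i * 0.3 + 0.2, 2000 + 10 * i, 3000 + 10 * i)
                 for i in range(8)]
        s1 = make_song(spans)
        notes = list(s1.notes)
        rng.shuffle(notes)
        (s2,) = assemble_songs(notes)
        assert extract_features(s1) == extract_features(s2)


class TestFrequencyShifts:
    def test_shift_definition(self):
        s = make_song([(0, 0.2, 2000, 3000), (0.3, 0.5, 2500, 4000)])
        t = frequency_shifts(s)
        assert t["shift"].tolist() == pytest.approx([4000 - 2000])

    def test_identical_notes_shift_equals_bandwidth(self):
        s = make_song([(0, 0.2, 2000, 3000), (0.3, 0.5, 2000, 3000),
                       (0.6, 0.8, 2000, 3000)])
        assert frequency_shifts(s)["shift"].tolist() == pytest.approx([1000, 1000])

    def test_class_agrees_with_cvm_interval(self):
        s = make_song([(0.0, 0.2, 2000, 3000), (0.2005, 0.4, 2000, 3000),
                       (0.9, 1.1, 2000, 3000)])
        t = frequency_shifts(s)
        assert t["interval_class"].tolist() == ["below_2ms", "at_or_above_2ms"]


class TestKSCompare:
    @staticmethod
    def _brute_force_D(x, y):
        pts = np.concatenate([x, y])
        d = 0.0
        for p in pts:
            d = max(d, abs(np.mean(x <= p) - np.mean(y <= p)))
        return d

    def _table(self, below, above):
        return pd.DataFrame({
            "shift": np.concatenate([below, above]),
            "interval_class": ["below_2ms"] * len(below)
            + ["at_or_above_2ms"] * len(above),
        })

    def test_identical_samples_D_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        assert ks_compare_shifts(self._table(v, v)).statistic == pytest.approx(0)

    def test_disjoint_supports_D_one(self):
        r = ks_compare_shifts(self._table(np.array([1, 2, 3.]), np.array([4, 5, 6.])))
        assert r.statistic == pytest.approx(1.0)

    def test_matches_exhaustive_ecdf_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            x = rng.normal(size=rng.integers(3, 15))
            y = rng.normal(0.5, 1.2, size=rng.integers(3, 15))
            r = ks_compare_shifts(self._table(x, y))
            assert r.statistic == pytest.approx(self._brute_force_D(x, y), abs=1e-12)

    def test_one_empty_class_raises(self):
        with pytest.raises(InsufficientDataError):
            ks_compare_shifts(self._table(np.array([]), np.array([1.0])))

    def test_adding_identical_observations_keeps_D(self):
        x = np.array([1.0, 2.0, 5.0])
        y = np.array([2.5, 3.0, 6.0])
        d1 = ks_compare_shifts(self._table(x, y)).statistic
        # duplicate every observation in both samples
        d2 = ks_compare_shifts(
            self._table(np.repeat(x, 2), np.repeat(y, 2))).statistic
        assert d1 == pytest.approx(d2)
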