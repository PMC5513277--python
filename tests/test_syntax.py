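import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songdiff import syntax
from songdiff.syntax import (
    bootstrap_ci,
    bootstrap_summary,
    build_library,
    classify_bout,
    classify_signatures,
    select_bout,
    song_signature,
    svi_spectral_correlation,
)

from conftest import make_song

# Three clearly separated note shapes (duration s, bandwidth Hz):
# quantization bins at 20% tolerance cannot merge them.
A = (0.10, 1000)
B = (0.20, 2000)
C = (0.40, 500)
D = (0.06, 3000)


def song_from_shapes(shapes, song_id="s", base=2000.0, start=0.0):
    spans, t = [], start
    for dur, bw in shapes:
        spans.append((t, t + dur, base, base + bw))
        t += dur + 0.1
    return make_song(spans, song_id=song_id)


class TestSignature:
    def test_trill_elongation_same_type(self):
        s1 = song_from_shapes([A, B, C, C, C])
        s2 = song_from_shapes([A, B, C, C])
        assert song_signature(s1) == song_signature(s2)

    def test_note_addition_new_type(self):
        s1 = song_from_shapes([A, B, C])
        s2 = song_from_shapes([A, B, C, D])
        assert song_signature(s1) != song_signature(s2)

    def test_transposition_invariant(self):
        s1 = song_from_shapes([A, B, C], base=2000)
        s2 = song_from_shapes([A, B, C], base=2700)
        assert song_signature(s1) == song_signature(s2)

    def test_single_note_vs_trill_distinct(self):
        s1 = song_from_shapes([A, C])
        s2 = song_from_shapes([A, C, C])
        assert song_signature(s1) != song_signature(s2)


class TestSelectBout:
    def _songs(self, k):
        return [song_from_shapes([A, B], song_id=f"s{i}", start=5.0 * i)
                for i in range(k)]

    def test_first_start_identity(self):
        songs = self._songs(11)
        assert [s.song_id for s in select_bout(songs, 11)] == [
            s.song_id for s in songs]

    def test_too_few_songs_rejected(self):
        with pytest.raises(ValueError):
            select_bout(self._songs(10), 11)

    def test_random_start_reproducible_and_consecutive(self):
        songs = self._songs(30)
        b1 = select_bout(songs, 11, "random", np.random.default_rng(9))
        b2 = select_bout(songs, 11, "random", np.random.default_rng(9))
        assert [s.song_id for s in b1] == [s.song_id for s in b2]
        ids = [int(s.song_id[1:]) for s in b1]
        assert ids == list(range(ids[0], ids[0] + 11))


class TestClassifyBout:
    def test_all_distinct_bout(self):
        sigs = [(((i, i), False),) for i in range(11)]
        cats, svi = classify_signatures(sigs)
        assert svi == 1.0 and cats == ["new"] * 11

    def test_all_same_bout(self):
        sig = (((1, 1), False), ((2, 2), False))
        cats, svi = classify_signatures([sig] * 11)
        assert svi == pytest.approx(1 / 11)
        assert cats == ["new"] + ["same"] * 10

    def test_manual_enumeration_new_old_mod_same(self):
        a, b, c, d = (1, 1), (2, 2), (3, 3), (4, 4)
        A_ = ((a, False), (c, False))
        B_ = ((b, False), (d, False))
        AB = ((a, False), (c, False), (b, False))  # shares block (a,c) with A_
        bout = [A_, B_, A_, AB, B_, B_]
        cats, svi = classify_signatures(bout)
        assert cats == ["new", "new", "old", "mod", "old", "same"]
        assert svi == pytest.approx(3 / 6)

    def test_classify_bout_on_songs(self):
        songs = [
            song_from_shapes([A, C], song_id="s0", start=0),
            song_from_shapes([B, D], song_id="s1", start=10),
            song_from_shapes([A, C], song_id="s2", start=20),
        ]
        bc = classify_bout(songs)
        assert bc.categories == ["new", "new", "old"]
        assert bc.svi == pytest.approx(2 / 3)
        props = bc.category_proportions()
        assert sum(props.values()) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=2, max_size=15))
    def test_svi_equals_bruteforce_distinct_count(self, codes):
        sigs = [(((c, c), False),) for c in codes]
        cats, svi = classify_signatures(sigs)
        assert svi == pytest.approx(len(set(codes)) / len(codes))
        assert len(cats) == len(codes) and cats[0] == "new"


class TestLibrary:
    def _bout(self, ind, shapes_list):
        songs = [song_from_shapes(sh, song_id=f"{ind}_s{i}", start=10.0 * i)
                 for i, sh in enumerate(shapes_list)]
        songs = [make_song([(n.start_time, n.end_time, n.low_freq, n.high_freq)
                            for n in s.notes],
                           song_id=s.song_id, individual_id=ind)
                 for s in songs]
        return classify_bout(songs)

    def test_planted_shared_type_detected(self):
        b1 = self._bout("i1", [[A, B], [A, C]])
        b2 = self._bout("i2", [[A, B], [B, D]])
        lib, share = build_library([b1, b2])
        assert share.loc["i1", "i2"] == 1  # exactly the planted [A, B]
        assert lib.n_types == 3

    def test_disjoint_repertoires_no_sharing(self):
        b1 = self._bout("i1", [[A, B], [A, C]])
        b2 = self._bout("i2", [[B, C], [C, D]])
        _, share = build_library([b1, b2])
        off = share.to_numpy().copy()
        np.fill_diagonal(off, 0)
        assert off.sum() == 0

    def test_library_size_matches_bruteforce(self, study_dataset):
        from songdiff import annotations
        songs = annotations.assemble_songs(
            annotations.frame_to_notes(study_dataset.notes))
        by_ind = {}
        for s in songs:
            by_ind.setdefault(s.individual_id, []).append(s)
        bouts = [classify_bout(select_bout(ss, 11)) for ss in by_ind.values()]
        lib, _ = build_library(bouts)
        brute = len({sig for b in bouts for sig in b.signatures})
        assert lib.n_types == brute

    def test_library_monotone_in_individuals(self):
        b1 = self._bout("i1", [[A, B], [A, C]])
        b2 = self._bout("i2", [[B, C], [C, D]])
        lib1, _ = build_library([b1])
        lib2, _ = build_library([b1, b2])
        assert lib2.n_types >= lib1.n_types


class TestBootstrap:
    def _bouts(self, values):
        out = []
        for i, v in enumerate(values):
            out.append(syntax.BoutClassification(
                individual_id=f"i{i}", population_id="P", song_ids=[],
                signatures=[], categories=["new"] * 11, svi=v))
        return out

    def test_identical_values_degenerate_ci(self):
        s = bootstrap_summary(self._bouts([0.6] * 5), rng=np.random.default_rng(0))
        svi = s[s.metric == "svi"].iloc[0]
        assert svi.ci_low == svi.ci_high == pytest.approx(0.6)

    def test_seeded_reproducibility(self):
        bouts = self._bouts([0.4, 0.5, 0.7, 0.9])
        s1 = bootstrap_summary(bouts, rng=np.random.default_rng(5))
        s2 = bootstrap_summary(bouts, rng=np.random.default_rng(5))
        pd.testing.assert_frame_equal(s1, s2)

    def test_single_individual_flagged(self):
        s = bootstrap_summary(self._bouts([0.5]), rng=np.random.default_rng(0))
        assert not s[s.metric == "svi"].iloc[0].ci_available

    def test_ci_bounds_ordered(self):
        rng = np.random.default_rng(2)
        lo, hi = bootstrap_ci(rng.random(10), rng=rng)
        assert lo <= hi


class TestCorrelation:
    def test_perfect_correlation(self):
        df = pd.DataFrame({
            "svi": [0.2, 0.4, 0.6, 0.8],
            "song_bandwidth": [200.0, 400, 600, 800],
            "delivery_rate": [1.0, 2, 3, 4],
        })
        out = svi_spectral_correlation(df)
        assert out["r"].tolist() == pytest.approx([1.0, 1.0])
        assert out["df"].tolist() == [2, 2]

    def test_df_is_n_minus_2(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "svi": rng.random(38),
            "song_bandwidth": rng.random(38),
            "delivery_rate": rng.random(38),
        })
        out = svi_spectral_correlation(df)
        assert out["df"].tolist() == [36, 36]

    def test_null_correlation_small(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "svi": rng.random(4000),
            "song_bandwidth": rng.random(4000),
            "delivery_rate": rng.random(4000),
        })
        out = svi_spectral_correlation(df)
        assert np.all(np.abs(out["r"]) < 0.05)

    def test_zero_variance_raises(self):
        df = pd.DataFrame({
            "svi": [0.5, 0.5, 0.5],
            "song_bandwidth": [1.0, 2, 3],
            "delivery_rate": [1.0, 2, 3],
        })
        with pytest.raises(syntax.UndefinedCorrelationError):
            svi_spectral_correlation(df)
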