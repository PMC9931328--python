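"""Feature engineering against brute-force oracles and rule-forced cases."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lmscreen.features import (
    FeatureTable,
    NgramToken,
    assemble_features,
    cohort_alphabet,
    compute_features,
    detect_syllabic_clusters,
    lm_pair_durations,
    ngram_counts,
    ngram_mean_duration,
    ngram_rate,
    ratio_features,
    speech_rate,
    strength_features,
    tokenize,
)
from lmscreen.synthetic_data import GeneratorConfig, generate_dataset, generate_stream

from conftest import make_stream, random_stream


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_ngram_counts(labels, n):
    counts = {}
    for i in range(len(labels)):
        if i + n <= len(labels):
            key = "".join(labels[i : i + n])
            counts[key] = counts.get(key, 0) + 1
    return counts


def brute_strength_means(stream, n):
    """Per-type n-gram mean strength via explicit loops."""
    by_type = {}
    ev = stream.events
    for i in range(len(ev) - n + 1):
        window = ev[i : i + n]
        name = "".join(e.label.text for e in window)
        by_type.setdefault(name, []).append(
            sum(e.strength for e in window) / n
        )
    return {k: sum(v) / len(v) for k, v in by_type.items()}


class TestTokenize:
    def test_order_preserved(self):
        s = make_stream([(0.1, "+g", 50), (0.3, "-g", 50)])
        assert tokenize(s) == ["+g", "-g"]

    def test_empty(self):
        assert tokenize(make_stream([])) == []

    def test_token_name_parses_back(self):
        token = NgramToken.parse("+b-b+b")
        assert token.name == "+b-b+b"
        assert [lbl.text for lbl in token.labels] == ["+b", "-b", "+b"]


class TestNgramCounts:
    def test_definition_forced_bigrams(self):
        s = make_stream([(0.0, "+g", 1), (0.1, "-g", 1), (0.2, "+b", 1)])
        assert ngram_counts(s, 2) == {"+g-g": 1, "-g+b": 1}

    def test_unigram_conservation(self):
        rng = np.random.default_rng(0)
        s = random_stream(rng, 30)
        assert sum(ngram_counts(s, 1).values()) == 30

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_matches_brute_force_on_random_streams(self, n):
        rng = np.random.default_rng(42)
        for _ in range(30):
            s = random_stream(rng, int(rng.integers(0, 50)))
            assert ngram_counts(s, n) == brute_ngram_counts(tokenize(s), n)

    def test_exhaustive_short_streams(self):
        """All streams of length <= 8 over a 3-letter sub-alphabet."""
        alphabet = ("+g", "-g", "+b")
        for length in range(0, 9):
            # sample the full product space deterministically when too big
            space = list(itertools.product(alphabet, repeat=length))
            for labels in space[:: max(1, len(space) // 81)]:
                rows = [(0.1 * i, lbl, 50.0) for i, lbl in enumerate(labels)]
                s = make_stream(rows)
                for n in (1, 2, 3):
                    assert ngram_counts(s, n) == brute_ngram_counts(list(labels), n)

    @given(st.integers(min_value=-2, max_value=8))
    def test_invalid_order_rejected(self, n):
        s = make_stream([(0.0, "+g", 1)])
        if n in (1, 2, 3):
            ngram_counts(s, n)
        else:
            with pytest.raises(ValueError):
                ngram_counts(s, n)

    def test_conservation_sum_equals_window_count(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            L = int(rng.integers(0, 40))
            s = random_stream(rng, L)
            for n in (1, 2, 3):
                assert sum(ngram_counts(s, n).values()) == max(L - n + 1, 0)


class TestDurations:
    def test_mean_bigram_duration_arithmetic(self):
        s = make_stream([(0.0, "+g", 1), (0.1, "-g", 1), (0.3, "+b", 1)])
        assert ngram_mean_duration(s, 2) == pytest.approx(0.15)

    def test_too_few_events_undefined(self):
        s = make_stream([(0.0, "+g", 1), (0.1, "-g", 1)])
        assert math.isnan(ngram_mean_duration(s, 3))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = random_stream(rng, int(rng.integers(3, 40)))
            for n in (2, 3):
                ev = s.events
                expected = np.mean(
                    [ev[i + n - 1].time - ev[i].time for i in range(len(ev) - n + 1)]
                )
                assert ngram_mean_duration(s, n) == pytest.approx(expected)


class TestPairDurations:
    def test_single_pair(self):
        s = make_stream([(0.1, "+g", 1), (0.4, "-g", 1)])
        assert lm_pair_durations(s)["g"] == pytest.approx(0.3)

    def test_nearest_onset_rule(self):
        s = make_stream([(0.0, "+g", 1), (0.2, "+g", 1), (0.5, "-g", 1)])
        # the -g closes the *second* +g; the first stays unmatched
        assert lm_pair_durations(s)["g"] == pytest.approx(0.3)

    def test_no_pair_is_nan(self):
        s = make_stream([(0.0, "+g", 1)])
        d = lm_pair_durations(s)
        assert math.isnan(d["g"]) and math.isnan(d["b"])

    def test_generated_streams_every_onset_matched(self):
        cfg = GeneratorConfig(seed=2)
        for i in range(50):
            s = generate_stream("normal", cfg, seed=i)
            onsets = {k: 0 for k in "gbsfv"}
            offsets = {k: 0 for k in "gbsfv"}
            for e in s.events:
                (onsets if e.label.sign == "+" else offsets)[e.label.kind] += 1
            assert onsets == offsets
            d = lm_pair_durations(s)
            for kind, n in onsets.items():
                if n:
                    assert d[kind] > 0


class TestRates:
    def test_unigram_rate(self):
        rows = [(0.25 * i, "+g" if i % 2 == 0 else "-g", 1) for i in range(5)]
        s = make_stream(rows)  # 5 events over 1.0 s
        assert ngram_rate(s, 1) == pytest.approx(5.0)
        assert ngram_rate(s, 2) == pytest.approx(4.0)

    def test_single_event_undefined(self):
        assert math.isnan(ngram_rate(make_stream([(0.0, "+g", 1)]), 1))


class TestSyllabicClusters:
    @pytest.mark.parametrize(
        "spans,expected",
        [([0.020], 0), ([0.050], 1), ([0.040, 0.010, 0.100], 2)],
    )
    def test_thirty_ms_rule(self, spans, expected):
        rows, t = [], 0.0
        for span in spans:
            t += 0.1
            rows.append((t, "+g", 50.0))
            rows.append((t + span, "-g", 50.0))
            t += span
        s = make_stream(rows)
        assert len(detect_syllabic_clusters(s)) == expected

    def test_leading_unvoiced_events_attach_to_cluster(self):
        s = make_stream(
            [(0.00, "+b", 1), (0.02, "-b", 1), (0.10, "+g", 1), (0.20, "-g", 1)]
        )
        clusters = detect_syllabic_clusters(s)
        assert len(clusters) == 1
        assert [e.label.text for e in clusters[0].events] == ["+b", "-b", "+g", "-g"]
        assert clusters[0].voiced_span == pytest.approx(0.1)

    def test_monotone_in_threshold(self):
        cfg = GeneratorConfig(seed=4)
        for i in range(30):
            s = generate_stream("normal", cfg, seed=i)
            counts = [
                len(detect_syllabic_clusters(s, min_voiced_s=th))
                for th in (0.060, 0.030, 0.010, 0.0)
            ]
            assert counts == sorted(counts)

    def test_speech_rate_consistent_with_clusters(self):
        cfg = GeneratorConfig(seed=6)
        for i in range(20):
            s = generate_stream("normal", cfg, seed=i)
            if s.duration > 0:
                expected = len(detect_syllabic_clusters(s)) / s.duration
                assert speech_rate(s) == pytest.approx(expected)

    def test_zero_clusters_rate_zero(self):
        s = make_stream([(0.0, "+b", 1), (1.0, "-b", 1)])
        assert speech_rate(s) == 0.0


class TestStrengthFeatures:
    def test_strength_change_arithmetic(self):
        s = make_stream([(0.0, "+g", 10), (0.1, "-g", 20), (0.2, "+b", 15)])
        assert strength_features(s)["strchange:all"] == pytest.approx(7.5)

    def test_single_event_change_undefined(self):
        out = strength_features(make_stream([(0.0, "+g", 10)]))
        assert "strchange:all" not in out

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            s = random_stream(rng, int(rng.integers(2, 40)))
            out = strength_features(s)
            for n, cat in ((1, "str1"), (2, "str2"), (3, "str3")):
                for name, expected in brute_strength_means(s, n).items():
                    assert out[f"{cat}:{name}"] == pytest.approx(expected)
            # grand means over all instances
            for n, cat in ((2, "strmean2"), (3, "strmean3")):
                ev = s.events
                insts = [
                    np.mean([e.strength for e in ev[i : i + n]])
                    for i in range(len(ev) - n + 1)
                ]
                if insts:
                    assert out[f"{cat}:all"] == pytest.approx(np.mean(insts))


class TestRatioFeatures:
    def test_basic_ratio(self):
        out = ratio_features({"+g": 4}, {"-g-b": 2}, {})
        assert out["ratio21:-g-b/+g"] == pytest.approx(0.5)

    def test_zero_denominator_undefined(self):
        out = ratio_features({"+g": 0, "-g": 2}, {"-g-b": 2}, {})
        assert math.isnan(out["ratio21:-g-b/+g"])
        assert out["ratio21:-g-b/-g"] == pytest.approx(1.0)

    def test_self_ratio_identity(self):
        out = ratio_features({"+g": 7}, {}, {})
        assert out["ratio11:+g/+g"] == 1.0


class TestAssemble:
    def test_absent_token_not_in_table(self, null_cohort):
        streams, manifest = null_cohort
        table = assemble_features(streams, manifest)
        observed = set(cohort_alphabet(streams)[1])
        for name in table.feature_names:
            if name.startswith("count1:"):
                assert name.split(":")[1] in observed

    def test_missing_denominator_prunes_ratios(self):
        # one sample lacks +b entirely -> all */+b ratios pruned
        a = make_stream([(0.0, "+b", 50), (0.05, "-b", 50),
                         (0.1, "+g", 50), (0.2, "-g", 50)], "a")
        b = make_stream([(0.1, "+g", 50), (0.2, "-g", 50)], "b")
        table = assemble_features([a, b])
        assert not any(n.endswith("/+b") for n in table.feature_names)
        assert any(n.endswith("/+g") for n in table.feature_names)

    def test_matrix_complete_and_typed(self, null_cohort):
        streams, manifest = null_cohort
        table = assemble_features(streams, manifest)
        values = table.values
        assert np.isfinite(values.to_numpy(dtype=float)).all()
        mask = table.integer_mask()
        counts = values.to_numpy(dtype=float)[:, mask]
        assert np.allclose(counts, np.round(counts)) and (counts >= 0).all()
        for name in table.feature_names:
            cat = table.categories[name]
            col = values[name]
            if cat.startswith(("rate", "dur", "pairdur")) or cat == "speech_rate":
                assert (col >= 0).all()
            if cat.startswith("str"):
                assert ((col >= 0) & (col <= 100)).all()
            if cat.startswith("ratio"):
                assert (col >= 0).all()
        # no constant-zero column survives pruning
        assert (values != 0).any(axis=0).all()

    def test_values_match_per_sample_recomputation(self, null_cohort):
        streams, manifest = null_cohort
        table = assemble_features(streams, manifest)
        alphabet = cohort_alphabet(streams)
        for s in streams[::7]:
            raw = compute_features(s, alphabet)
            row = table.values.loc[s.sample_id]
            for name in table.feature_names:
                assert row[name] == pytest.approx(raw[name]), name

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            assemble_features([])

    def test_csv_round_trip(self, tmp_path, null_cohort):
        streams, manifest = null_cohort
        table = assemble_features(streams[:10])
        path = tmp_path / "features.csv"
        table.to_csv(path)
        back = FeatureTable.from_csv(path)
        assert back.feature_names == table.feature_names
        assert np.allclose(back.values.to_numpy(), table.values.to_numpy())
        assert back.categories == table.categories
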