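"""Note-onset accuracy, pitch correlation, shuffle baseline, chance levels."""

import itertools

import numpy as np
import pandas as pd
import pytest

from melodecode.evaluation import (aggregate_scores, note_onset_accuracy,
                                   onset_accuracy_from_grids,
                                   permutation_chance, pitch_correlation,
                                   pitch_shuffle_baseline, quantize_window,
                                   score_records, timing_partition,
                                   timing_signature)
from melodecode.melody import Melody, NoteEvent


def melody_from_beats(beats_pitches, melody_id="m", n_bars=2):
    notes = [NoteEvent(b * 0.6, 0.6, p) for b, p in beats_pitches]
    return Melody(id=melody_id, notes=notes, n_bars=n_bars)


class TestOnsetAccuracy:
    def test_identical_is_one(self):
        ons = [0.0, 1.2, 2.4]
        assert note_onset_accuracy(ons, ons, 4.8) == 1.0

    def test_counts_positions_exhaustively(self):
        """Predicted {0,2,4}, actual {0,2,6} on 8 positions: 6/8 agree
        (positions 4 and 6 disagree) — oracle counted by hand."""
        pred = [0 * 0.6, 2 * 0.6, 4 * 0.6]
        act = [0 * 0.6, 2 * 0.6, 6 * 0.6]
        assert note_onset_accuracy(pred, act, 4.8) == pytest.approx(0.75)

    def test_complementary_patterns_score_zero(self):
        pred = [i * 0.6 for i in (0, 2, 4, 6)]
        act = [i * 0.6 for i in (1, 3, 5, 7)]
        assert note_onset_accuracy(pred, act, 4.8) == 0.0

    def test_symmetry(self, rng):
        for _ in range(20):
            a = list(rng.choice(8, size=4, replace=False) * 0.6)
            b = list(rng.choice(8, size=3, replace=False) * 0.6)
            assert note_onset_accuracy(a, b, 4.8) == note_onset_accuracy(b, a, 4.8)

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            note_onset_accuracy([0.0], [0.0], 2.4, grid=0.0)


def quantized(beats_pitches, n_bars=1):
    m = melody_from_beats(beats_pitches, n_bars=n_bars)
    return quantize_window(m, 0, n_bars)


class TestPitchCorrelation:
    def test_identical_pitches_rho_one(self):
        p, v = quantized([(0, 60), (1, 62), (2, 64), (3, 65)])
        rho, n = pitch_correlation(p, v, p, v)
        assert rho == 1.0 and n == 4

    def test_reversed_pitches_rho_minus_one(self):
        p1, v1 = quantized([(0, 60), (1, 62), (2, 64), (3, 65)])
        p2, v2 = quantized([(0, 65), (1, 64), (2, 62), (3, 60)])
        rho, _ = pitch_correlation(p2, v2, p1, v1)
        assert rho == -1.0

    def test_closed_form_spearman(self):
        """Ranks (1,2,3,4) vs (1,3,2,4): ρ = 1 − 6·2/(4·15) = 0.8."""
        p1, v1 = quantized([(0, 60), (1, 62), (2, 64), (3, 65)])
        p2, v2 = quantized([(0, 60), (1, 64), (2, 62), (3, 65)])
        rho, _ = pitch_correlation(p2, v2, p1, v1)
        assert rho == pytest.approx(0.8)

    def test_too_few_matches_undefined(self):
        p1, v1 = quantized([(0, 60), (2, 64)])
        rho, n = pitch_correlation(p1, v1, p1, v1)
        assert np.isnan(rho) and n == 2

    def test_constant_pitch_undefined(self):
        p, v = quantized([(0, 60), (1, 60), (2, 60), (3, 60)])
        rho, _ = pitch_correlation(p, v, p, v)
        assert np.isnan(rho)

    def test_monotone_transform_invariance(self, rng):
        p1, v1 = quantized([(0, 60), (1, 67), (2, 62), (3, 71)])
        v2 = np.where(np.isfinite(v1), 2 * v1 + 12, np.nan)  # strictly monotone
        rho_a, _ = pitch_correlation(p1, v1, p1, v1)
        rho_b, _ = pitch_correlation(p1, v2, p1, v1)
        assert rho_a == rho_b == 1.0


class TestTimingPartition:
    def test_partition_matches_brute_force_pairwise(self, rng):
        melodies = {}
        ids = []
        for i in range(20):
            beats = sorted(rng.choice(4, size=int(rng.integers(1, 5)),
                                      replace=False))
            mel = melody_from_beats(
                [(b, 60 + int(rng.integers(0, 12))) for b in beats],
                melody_id=f"m{i}", n_bars=1,
            )
            melodies[mel.id] = mel
            ids.append((mel.id, 0))
        classes = timing_partition(ids, melodies, 1)
        # brute force: same class iff identical signature
        for a in ids:
            for b in ids:
                same = any(a in c and b in c for c in classes.values())
                sig_a = timing_signature(melodies[a[0]], 0, 1)
                sig_b = timing_signature(melodies[b[0]], 0, 1)
                assert same == (sig_a == sig_b)


def records_df(rows):
    return pd.DataFrame(
        rows,
        columns=["subject", "condition", "bars", "trial", "start_bar",
                 "true_melody", "true_start_bar", "pred_melody",
                 "pred_start_bar", "score", "tie"],
    )


def four_note_melodies():
    a = melody_from_beats([(0, 60), (1, 62), (2, 64), (3, 65)], "a", 1)
    b = melody_from_beats([(0, 65), (1, 64), (2, 62), (3, 60)], "b", 1)
    c = melody_from_beats([(0, 60), (2, 64), (3, 67)], "c", 1)
    return {"a": a, "b": b, "c": c}


class TestShuffleBaseline:
    def test_unique_timings_give_identity_baseline(self, rng):
        melodies = four_note_melodies()
        # only 'a' and 'b' share timing; restrict references to 'a' and 'c'
        recs = records_df([
            ("s", "listening", 1, 0, 0, "a", 0, "a", 0, 0.9, False),
            ("s", "listening", 1, 1, 0, "c", 0, "c", 0, 0.8, False),
        ])
        base = pitch_shuffle_baseline(recs, [("a", 0), ("c", 0)], melodies, 1,
                                      rng, n_shuffles=20)
        scored = score_records(recs, melodies)
        assert base == pytest.approx(aggregate_scores(scored)["pitch_rho"])

    def test_shared_timing_shuffling_degrades_pitch_score(self, rng):
        """Perfect decoding of pitch-distinct, timing-identical melodies
        drops to the timing-only level under the shuffle."""
        melodies = four_note_melodies()
        recs = records_df([
            ("s", "listening", 1, i, 0, m, 0, m, 0, 1.0, False)
            for i, m in enumerate(["a", "b"] * 5)
        ])
        base = pitch_shuffle_baseline(recs, [("a", 0), ("b", 0)], melodies, 1,
                                      rng, n_shuffles=50)
        scored = aggregate_scores(score_records(recs, melodies))
        assert scored["pitch_rho"] == 1.0
        assert base < 0.5  # half the shuffles swap a and b (rho = -1)


class TestPermutationChance:
    def test_separation_by_construction(self, rng):
        # four timing-distinct melodies, perfectly decoded
        melodies = {
            "a": melody_from_beats([(0, 60), (1, 62), (2, 64), (3, 65)], "a", 1),
            "b": melody_from_beats([(0, 65), (2, 62)], "b", 1),
            "c": melody_from_beats([(0, 60), (3, 67)], "c", 1),
            "d": melody_from_beats([(0, 62), (1, 60), (3, 64)], "d", 1),
        }
        recs = records_df([
            ("s", "listening", 1, i, 0, m, 0, m, 0, 1.0, False)
            for i, m in enumerate(["a", "b", "c", "d"] * 2)
        ])
        out = permutation_chance(recs, melodies, rng, n_shuffles=100)
        assert out["observed"]["onset_accuracy"] == 1.0
        assert out["significant_onset"]

    def test_null_preserves_prediction_multiset(self, rng):
        """Shuffling permutes predicted identities, so every null draw uses
        the same multiset of predictions — its mean onset accuracy can never
        exceed the diagonal-free maximum of the assignment."""
        melodies = four_note_melodies()
        recs = records_df([
            ("s", "listening", 1, i, 0, m, 0, p, 0, 0.5, False)
            for i, (m, p) in enumerate([("a", "b"), ("b", "a"), ("c", "c")])
        ])
        out = permutation_chance(recs, melodies, rng, n_shuffles=50)
        assert len(out["null_onset"]) == 50
        assert np.all(out["null_onset"] <= 1.0)

    def test_small_case_matches_exhaustive_enumeration(self, rng):
        """3 segments: the Monte-Carlo 95th percentile is within 0.05 of the
        percentile of the exhaustive 3!-permutation null."""
        melodies = four_note_melodies()
        trues = ["a", "b", "c"]
        preds = ["a", "b", "c"]
        recs = records_df([
            ("s", "listening", 1, i, 0, t, 0, p, 0, 0.5, False)
            for i, (t, p) in enumerate(zip(trues, preds))
        ])
        out = permutation_chance(recs, melodies, rng, n_shuffles=100)
        exact = []
        for perm in itertools.permutations(range(3)):
            accs = [
                note_onset_accuracy(
                    [n.onset for n in melodies[preds[j]].notes],
                    [n.onset for n in melodies[trues[i]].notes],
                    2.4,
                )
                for i, j in enumerate(perm)
            ]
            exact.append(np.mean(accs))
        assert abs(out["chance_onset"] - np.percentile(exact, 95)) <= 0.05

    def test_few_shuffles_warns(self, rng):
        melodies = four_note_melodies()
        recs = records_df([
            ("s", "listening", 1, 0, 0, "a", 0, "a", 0, 1.0, False),
            ("s", "listening", 1, 1, 0, "b", 0, "b", 0, 1.0, False),
        ])
        with pytest.warns(UserWarning, match="shuffles"):
            permutation_chance(recs, melodies, rng, n_shuffles=5)


class TestAggregation:
    def test_undefined_rhos_excluded_not_zero_filled(self):
        melodies = four_note_melodies()
        # 'd' has notes on beats {0, 2} only; predicting 'a' for true 'd'
        # matches just 2 positions -> undefined rho
        melodies["d"] = melody_from_beats([(0, 62), (2, 60)], "d", 1)
        recs = records_df([
            ("s", "listening", 1, 0, 0, "a", 0, "a", 0, 1.0, False),
            ("s", "listening", 1, 1, 0, "d", 0, "a", 0, 0.2, False),
        ])
        agg = aggregate_scores(score_records(recs, melodies))
        assert agg["n_undefined"] == 1
        assert agg["pitch_rho"] == 1.0
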