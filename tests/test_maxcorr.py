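"""Segment construction and maximum-correlation classification."""

import numpy as np
import pytest
from scipy import stats

from melodecode.containers import EEGTrial
from melodecode.maxcorr import (Segment, build_segments, classify_segment,
                                maxcorr_loo_decode, resample_reference,
                                weighted_segment_correlation, window_samples)


def trial(data, melody="m", rep=0, idx_rate=64.0):
    return EEGTrial(np.asarray(data, float), idx_rate, "s", "listening", melody, rep)


def seg(data, melody="m", start=0, trial_index=0, n_bars=1):
    return Segment("s", "listening", trial_index, melody, 0, start, n_bars,
                   np.asarray(data, float))


class TestBuildSegments:
    def test_window8_step1_on_14_bars(self, rng):
        t = trial(rng.standard_normal((round(14 * 2.4 * 64), 3)))
        assert len(build_segments([t], 8, 1)) == 7

    def test_window4_step4_on_14_bars(self, rng):
        t = trial(rng.standard_normal((round(14 * 2.4 * 64), 3)))
        assert len(build_segments([t], 4, 4)) == 3  # bars 12-13 unused

    def test_step1_window1_partitions_trial_exactly(self, rng):
        t = trial(rng.standard_normal((round(14 * 2.4 * 64), 3)))
        segs = build_segments([t], 1, 1)
        assert len(segs) == 14
        assert np.array_equal(np.vstack([s.data for s in segs]), t.data)

    def test_short_trial_warns_and_yields_nothing(self, rng):
        t = trial(rng.standard_normal((100, 2)))
        with pytest.warns(UserWarning, match="shorter"):
            assert build_segments([t], 8, 1) == []


class TestResampleReference:
    def test_at_size_identity(self, rng):
        refs = [seg(rng.standard_normal((10, 2))) for _ in range(96)]
        assert resample_reference(refs, 96, rng) == refs

    def test_subsample_is_distinct_subset(self, rng):
        refs = [seg(rng.standard_normal((10, 2))) for _ in range(200)]
        out = resample_reference(refs, 96, rng)
        assert len(out) == 96
        assert len({id(s) for s in out}) == 96
        assert all(any(s is r for r in refs) for s in out)

    def test_inclusion_frequency_is_uniform(self, rng):
        """Hypergeometric check: each of 200 segments appears ~96/200 of the
        time over 1000 seeded draws, within 3σ."""
        refs = [seg(np.zeros((2, 1)), start=i) for i in range(200)]
        counts = np.zeros(200)
        for _ in range(1000):
            for s in resample_reference(refs, 96, rng):
                counts[s.start_bar] += 1
        p = 96 / 200
        sigma = np.sqrt(1000 * p * (1 - p))
        assert np.all(np.abs(counts - 1000 * p) < 3.5 * sigma)

    def test_bad_size_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            resample_reference([], 0, rng)


class TestWeightedCorrelation:
    def test_self_correlation_is_one(self, rng):
        a = seg(rng.standard_normal((50, 3)))
        w = np.array([0.5, 0.3, 0.2])
        assert weighted_segment_correlation(a, a, w) == pytest.approx(1.0)

    def test_negated_segment_scores_minus_one(self, rng):
        a = seg(rng.standard_normal((50, 3)))
        b = seg(-a.data)
        w = np.array([0.5, 0.3, 0.2])
        assert weighted_segment_correlation(a, b, w) == pytest.approx(-1.0)

    def test_weighted_mean_arithmetic(self, rng):
        """Per-component correlations (0.5, -0.5) with weights (0.75, 0.25)
        combine to 0.25 — verified by construction."""
        n = 4000
        x = rng.standard_normal(n)
        y1 = x.copy()
        y2 = rng.standard_normal(n)
        # build series with exact sample correlations 0.5 and -0.5
        def with_corr(x, r):
            z = rng.standard_normal(n)
            z = z - z.mean()
            x0 = x - x.mean()
            z -= x0 * np.dot(z, x0) / np.dot(x0, x0)
            out = r * x0 / np.linalg.norm(x0) + np.sqrt(1 - r**2) * z / np.linalg.norm(z)
            return out
        a = seg(np.column_stack([x, y2]))
        b = seg(np.column_stack([with_corr(x, 0.5), with_corr(y2, -0.5)]))
        w = np.array([0.75, 0.25])
        assert weighted_segment_correlation(a, b, w) == pytest.approx(0.25, abs=1e-9)

    def test_zero_variance_component_contributes_zero(self, rng):
        a = seg(np.column_stack([rng.standard_normal(30), np.zeros(30)]))
        b = seg(rng.standard_normal((30, 2)))
        w = np.array([0.0, 1.0])
        assert weighted_segment_correlation(a, b, w) == 0.0

    def test_length_mismatch_rejected(self, rng):
        a = seg(rng.standard_normal((30, 2)))
        b = seg(rng.standard_normal((40, 2)))
        with pytest.raises(ValueError, match="length mismatch"):
            weighted_segment_correlation(a, b, np.array([0.5, 0.5]))

    def test_symmetry_and_bounds(self, rng):
        w = np.full(3, 1 / 3)
        for _ in range(20):
            a = seg(rng.standard_normal((40, 3)))
            b = seg(rng.standard_normal((40, 3)))
            s1 = weighted_segment_correlation(a, b, w)
            s2 = weighted_segment_correlation(b, a, w)
            assert s1 == pytest.approx(s2, abs=1e-12)
            assert -1 - 1e-12 <= s1 <= 1 + 1e-12


class TestClassifySegment:
    def test_duplicate_wins(self, rng):
        test = seg(rng.standard_normal((40, 2)))
        refs = [seg(rng.standard_normal((40, 2)), melody="a", start=i) for i in range(3)]
        refs.append(seg(test.data.copy(), melody="b", start=5, trial_index=1))
        mel, start, score, tie = classify_segment(test, refs, np.array([0.5, 0.5]))
        assert (mel, start) == ("b", 5)
        assert score == pytest.approx(1.0)
        assert not tie

    def test_exact_ties_break_lexicographically(self):
        test = seg(np.zeros((40, 2)))  # zero variance -> all scores 0
        refs = [
            seg(np.random.default_rng(i).standard_normal((40, 2)), melody=m, start=s)
            for i, (m, s) in enumerate([("b", 0), ("a", 3), ("a", 1)])
        ]
        mel, start, score, tie = classify_segment(test, refs, np.array([0.5, 0.5]))
        assert (mel, start) == ("a", 1)
        assert tie

    def test_empty_reference_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            classify_segment(seg(rng.standard_normal((10, 1))), [], np.ones(1))

    def test_planted_monte_carlo_matches_brute_force(self, rng):
        """Correct identity recovered ≥95/100 with a 0.2 score margin at
        noise σ=0.1, and argmax always equals an exhaustive-loop oracle."""
        hits = 0
        w = np.array([0.6, 0.4])
        for _ in range(100):
            target = rng.standard_normal((60, 2))
            test = seg(target + 0.1 * rng.standard_normal((60, 2)))
            refs = [seg(target + 0.1 * rng.standard_normal((60, 2)), melody="true")]
            for i in range(3):
                decoy = 0.77 * target + rng.standard_normal((60, 2))
                refs.append(seg(decoy, melody=f"decoy{i}", trial_index=i + 1))
            mel, start, score, _ = classify_segment(test, refs, w)
            brute = max(
                range(len(refs)),
                key=lambda i: weighted_segment_correlation(test, refs[i], w),
            )
            assert score == pytest.approx(
                weighted_segment_correlation(test, refs[brute], w)
            )
            hits += mel == "true"
        assert hits >= 95

    def test_affine_rescaling_invariance(self, rng):
        test = seg(rng.standard_normal((40, 3)))
        refs = [seg(rng.standard_normal((40, 3)), start=i) for i in range(5)]
        w = np.array([0.2, 0.5, 0.3])
        base = classify_segment(test, refs, w)
        scale = np.array([2.0, 0.5, 7.0])
        shift = np.array([1.0, -3.0, 0.2])
        test2 = seg(test.data * scale + shift)
        refs2 = [
            seg(r.data * scale + shift, melody=r.melody_id, start=r.start_bar)
            for r in refs
        ]
        assert classify_segment(test2, refs2, w)[:2] == base[:2]


def component_trials(rng, n_melodies=2, n_reps=3, n_bars=6, M=3, noise=0.0):
    """Trials whose component data repeats exactly per melody + noise."""
    L = int(round(n_bars * 2.4 * 64))
    patterns = {f"m{j}": rng.standard_normal((L, M)) for j in range(n_melodies)}
    trials = []
    for mel, pat in patterns.items():
        for rep in range(n_reps):
            d = pat + noise * rng.standard_normal((L, M))
            trials.append(trial(d, melody=mel, rep=rep))
    return trials


class TestLooDecode:
    def test_noiseless_decoding_is_perfect(self, rng):
        trials = component_trials(rng)
        w = np.full(3, 1 / 3)
        for bars in (1, 2):
            rec = maxcorr_loo_decode(trials, bars, w, rng=np.random.default_rng(0))
            assert (rec.pred_melody == rec.true_melody).all()
            assert (rec.pred_start_bar == rec.true_start_bar).all()

    def test_leakage_guard_changes_noisy_results(self, rng):
        """Without the guard, same-trial step-1 segments — which share
        slowly varying trial noise with the test segment — steal matches."""
        base = component_trials(rng, noise=0.5)
        kern = np.ones(300) / np.sqrt(300)
        trials = []
        for t in base:
            slow = np.apply_along_axis(
                lambda x: np.convolve(x, kern, mode="same"), 0,
                rng.standard_normal(t.data.shape),
            )
            trials.append(t.copy_with(t.data + 5.0 * slow))
        w = np.full(3, 1 / 3)
        guarded = maxcorr_loo_decode(trials, 2, w, rng=np.random.default_rng(1),
                                     leakage_guard=True)
        open_ = maxcorr_loo_decode(trials, 2, w, rng=np.random.default_rng(1),
                                   leakage_guard=False)
        # same-trial raw-sample overlap redirects matches: the guard must
        # change the predictions on noisy data
        assert not open_.equals(guarded)
        same_trial_hits = (
            open_.pred_start_bar.isin([1, 3]).mean()
        )
        assert same_trial_hits > 0  # overlapping neighbours do win sometimes

    def test_reference_resampling_caps_pool(self, rng):
        trials = component_trials(rng, n_melodies=2, n_reps=4, n_bars=8)
        w = np.full(3, 1 / 3)
        rec = maxcorr_loo_decode(trials, 1, w, reference_size=10,
                                 rng=np.random.default_rng(2))
        assert len(rec) == 8 * 8  # one prediction per test segment

    def test_decode_is_seed_deterministic(self, rng):
        trials = component_trials(rng, noise=2.0)
        w = np.full(3, 1 / 3)
        r1 = maxcorr_loo_decode(trials, 1, w, reference_size=20,
                                rng=np.random.default_rng(3))
        r2 = maxcorr_loo_decode(trials, 1, w, reference_size=20,
                                rng=np.random.default_rng(3))
        assert r1.equals(r2)
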