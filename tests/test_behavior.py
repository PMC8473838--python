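import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duetsync import behavior as bhv
from duetsync.melody import MelodyEvent, MelodySpec
from duetsync.simulate import TimingSimConfig, inject_pitch_errors, simulate_duet_timing

from conftest import trial_from_onsets

from fractions import Fraction


class TestPitchErrorClassification:
    def test_exact_performance_is_clean(self, melody, isochronous_trial):
        cls = bhv.classify_pitch_errors(isochronous_trial, melody)
        assert cls.status == "clean"
        assert np.array_equal(cls.matched_event_index, np.arange(32))

    def test_deleted_tone_is_excluded(self, melody):
        onsets = [float(p) * 500 for p in melody.beat_positions()]
        trial = trial_from_onsets(onsets, melody)
        trial = trial.with_events(trial.events.drop(index=10).reset_index(drop=True))
        cls = bhv.classify_pitch_errors(trial, melody)
        assert cls.status == "excluded"
        assert cls.n_deletions == 1

    def test_substituted_pitch_is_retained_with_correct_matching(self, melody):
        onsets = [float(p) * 500 for p in melody.beat_positions()]
        pitches = list(melody.pitches)
        pitches[4] = 71  # a pitch outside the template at event 5
        trial = trial_from_onsets(onsets, melody, pitches=pitches)
        cls = bhv.classify_pitch_errors(trial, melody)
        assert cls.status == "substitution_only"
        assert cls.n_substitutions == 1
        assert np.array_equal(cls.matched_event_index, np.arange(32))

    def test_empty_trial_excluded_with_reason(self, melody, isochronous_trial):
        empty = isochronous_trial.with_events(isochronous_trial.events.iloc[0:0])
        cls = bhv.classify_pitch_errors(empty, melody)
        assert cls.status == "excluded"
        assert cls.reason == "empty"

    def test_follower_count_in_repetition_aligns_to_truncated_template(self, melody):
        onsets = [float(p) * 500 for p in melody.beat_positions()][8:]
        trial = trial_from_onsets(onsets, melody, nominal_indices=list(range(8, 32)))
        cls = bhv.classify_pitch_errors(trial, melody)
        assert cls.status == "clean"
        assert np.array_equal(cls.matched_event_index, np.arange(8, 32))

    def test_filter_matches_injected_ground_truth(self, melody):
        cfg = TimingSimConfig(n_repetitions=24, seed=7)
        lt, _ = simulate_duet_timing(melody, cfg)
        corrupted = inject_pitch_errors(lt, 0.3, seed=8)
        for trial in corrupted:
            cls = bhv.classify_pitch_errors(trial, melody)
            if trial.injected_error is None:
                assert cls.retained
            else:
                assert cls.status == "excluded"

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.data())
    def test_random_substitutions_retained_random_indels_excluded(self, melody, data):
        onsets = [float(p) * 500 for p in melody.beat_positions()]
        pitches = list(melody.pitches)
        kind = data.draw(st.sampled_from(["sub", "del", "ins"]))
        k = data.draw(st.integers(0, 31))
        if kind == "sub":
            pitches[k] = data.draw(st.sampled_from([50, 58, 71, 72]))
            trial = trial_from_onsets(onsets, melody, pitches=pitches)
            assert bhv.classify_pitch_errors(trial, melody).retained
        elif kind == "del":
            trial = trial_from_onsets(onsets, melody)
            trial = trial.with_events(trial.events.drop(index=k).reset_index(drop=True))
            assert bhv.classify_pitch_errors(trial, melody).status == "excluded"
        else:
            trial = trial_from_onsets(onsets, melody)
            ev = trial.events
            row = ev.iloc[k].copy()
            row["onset_ms"] = row["onset_ms"] + 1.0  # just after event k
            ev = pd.concat([ev.iloc[: k + 1], row.to_frame().T, ev.iloc[k + 1 :]],
                           ignore_index=True)
            ev["event_index"] = np.arange(len(ev))
            trial = trial.with_events(ev)
            assert bhv.classify_pitch_errors(trial, melody).status == "excluded"


def toy_melody():
    """12-event test melody: 8 quarters, 1 half, an eighth pair, 1 quarter."""
    q, h, e = Fraction(1), Fraction(2), Fraction(1, 2)
    values = [q] * 8 + [h, e, e, q]
    events, acc = [], Fraction(0)
    for v in values:
        events.append(MelodyEvent(pitch=60, beat_value=v, is_on_beat=acc.denominator == 1))
        acc += v
    return MelodySpec(events=tuple(events))


class TestQuarterLevelIOIs:
    def test_isochronous_performance(self, melody, isochronous_trial):
        ioi = bhv.quarter_level_iois(isochronous_trial, melody)
        assert np.allclose(ioi.values, 500.0)
        assert ioi.rate_hz == pytest.approx(2.0)

    def test_half_note_splits_into_two_equal_iois(self):
        toy = toy_melody()
        onsets = [float(p) * 480 for p in toy.beat_positions()]
        trial = trial_from_onsets(onsets, toy)
        ioi = bhv.quarter_level_iois(trial, toy)
        # 8 quarter IOIs, the half split at its midpoint into 2, eighth-pair
        # beat to final quarter: 11 intervals of 480 ms
        assert len(ioi.values) == 11
        assert np.allclose(ioi.values, 480.0)
        assert ioi.mean_ioi_ms == pytest.approx(480.0)

    def test_off_beat_eighths_do_not_contribute(self):
        toy = toy_melody()
        onsets = np.array([float(p) * 480 for p in toy.beat_positions()])
        onsets[10] += 60.0  # displace the off-beat eighth only
        trial = trial_from_onsets(list(onsets), toy)
        ioi = bhv.quarter_level_iois(trial, toy)
        assert np.allclose(ioi.values, 480.0)

    def test_too_short_raises(self, melody):
        trial = trial_from_onsets([0.0], melody, nominal_indices=[0])
        with pytest.raises(ValueError, match="too short"):
            bhv.quarter_level_iois(trial, melody)

    def test_hz_round_trip(self, melody, isochronous_trial):
        ioi = bhv.quarter_level_iois(isochronous_trial, melody)
        assert 1000.0 / ioi.rate_hz == pytest.approx(ioi.mean_ioi_ms, rel=1e-12)


class TestDuetAsynchronies:
    def test_identical_streams_are_synchronous(self, melody, isochronous_trial):
        res = bhv.duet_asynchronies(isochronous_trial, isochronous_trial, melody)
        assert res.signed_mean == 0.0
        assert res.absolute_mean == 0.0

    def test_constant_follower_lag(self, melody):
        onsets = [float(p) * 500 for p in melody.beat_positions()]
        leader = trial_from_onsets(onsets, melody)
        follower = trial_from_onsets([o + 10.0 for o in onsets], melody, performer_id="F")
        res = bhv.duet_asynchronies(leader, follower, melody)
        assert res.signed_mean == pytest.approx(-0.02, abs=1e-12)
        assert res.absolute_mean == pytest.approx(0.02, abs=1e-12)

    def test_antisymmetry_under_role_swap(self, melody):
        rng = np.random.default_rng(0)
        base = np.array([float(p) * 500 for p in melody.beat_positions()])
        a = trial_from_onsets(base + rng.normal(0, 5, 32).cumsum() * 0, melody)
        b = trial_from_onsets(base + rng.normal(0, 8, 32), melody, performer_id="F")
        fwd = bhv.duet_asynchronies(a, b, melody)
        rev = bhv.duet_asynchronies(b, a, melody)
        assert fwd.signed_mean == pytest.approx(-rev.signed_mean, rel=1e-9)
        assert fwd.absolute_mean == pytest.approx(rev.absolute_mean, rel=1e-9)

    def test_scale_invariance_of_normalized_asynchrony(self, melody):
        rng = np.random.default_rng(1)
        base = np.array([float(p) * 500 for p in melody.beat_positions()])
        jitter = rng.normal(0, 6, 32)
        c = 1.7
        l1 = trial_from_onsets(base, melody)
        f1 = trial_from_onsets(base + jitter, melody, performer_id="F")
        l2 = trial_from_onsets(base * c, melody)
        f2 = trial_from_onsets((base + jitter) * c, melody, performer_id="F")
        r1 = bhv.duet_asynchronies(l1, f1, melody)
        r2 = bhv.duet_asynchronies(l2, f2, melody)
        assert r1.signed_mean == pytest.approx(r2.signed_mean, rel=1e-9)
        assert r1.absolute_mean == pytest.approx(r2.absolute_mean, rel=1e-9)
        ioi1 = bhv.quarter_level_iois(l1, melody)
        ioi2 = bhv.quarter_level_iois(l2, melody)
        assert ioi2.rate_hz == pytest.approx(ioi1.rate_hz / c, rel=1e-9)

    def test_absolute_bounds_signed(self, melody):
        rng = np.random.default_rng(2)
        base = np.array([float(p) * 500 for p in melody.beat_positions()])
        l = trial_from_onsets(base, melody)
        f = trial_from_onsets(base + rng.normal(0, 12, 32), melody, performer_id="F")
        res = bhv.duet_asynchronies(l, f, melody)
        assert res.absolute_mean >= abs(res.signed_mean)

    def test_no_common_events_raises(self, melody):
        l = trial_from_onsets([0, 500, 1000], melody, nominal_indices=[0, 1, 2])
        f = trial_from_onsets([0, 500, 1000], melody, nominal_indices=[4, 5, 6],
                              matched=[4, 5, 6])
        with pytest.raises(ValueError, match="co-performed"):
            bhv.duet_asynchronies(l, f, melody)


class TestCohortStatistics:
    def _summary(self, detuning, asym):
        n = len(detuning)
        return pd.DataFrame({
            "condition": ["First-Leader"] * n,
            "leader_solo_ioi_ms": 500.0 + np.asarray(detuning),
            "follower_solo_ioi_ms": [500.0] * n,
            "signed_asynchrony": asym,
        })

    def test_monotone_relation_gives_perfect_rank_correlation(self):
        d = np.array([-30.0, -10.0, 5.0, 20.0, 40.0])
        out = bhv.detuning_vs_asynchrony(self._summary(d, d / 250.0))
        assert out["First-Leader"]["rho"] == pytest.approx(1.0)
        out = bhv.detuning_vs_asynchrony(self._summary(d, -d / 250.0))
        assert out["First-Leader"]["rho"] == pytest.approx(-1.0)

    def test_constant_input_raises(self):
        d = np.array([-30.0, -10.0, 5.0, 20.0])
        with pytest.raises(ValueError, match="constant"):
            bhv.detuning_vs_asynchrony(self._summary(d, np.zeros(4)))

    def test_regression_duet_rate_equals_leader_rate(self):
        rng = np.random.default_rng(3)
        leader = rng.uniform(1.6, 3.2, 12)
        follower = rng.uniform(1.6, 3.2, 12)
        reg = bhv.duet_rate_regression(leader, follower, leader)
        assert reg.beta_leader == pytest.approx(1.0, abs=1e-9)
        assert reg.beta_follower == pytest.approx(0.0, abs=1e-9)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_regression_symmetric_mean(self):
        rng = np.random.default_rng(4)
        leader = rng.uniform(1.6, 3.2, 12)
        follower = rng.permutation(leader)  # same spread, shuffled pairing
        reg = bhv.duet_rate_regression(leader, follower, (leader + follower) / 2)
        assert reg.beta_leader == pytest.approx(reg.beta_follower, abs=1e-6)

    def test_regression_rejects_collinear_predictors(self):
        x = np.linspace(1.5, 3.0, 8)
        with pytest.raises(ValueError):
            bhv.duet_rate_regression(x, 2 * x, x)
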