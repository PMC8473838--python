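import numpy as np
import pandas as pd
import pytest
from scipy import stats

from duetsync import envelope as envm
from duetsync.data import EEGRecording
from duetsync.melody import make_melody_spec


@pytest.fixture(scope="module")
def melody():
    return make_melody_spec()


def tone_recording(f0=2.0, fs=500.0, beat_ms=500.0, n_reps=2, amplitude=None,
                   n_channels=1, pad=10.0):
    """Single-channel recording of a (possibly AM) tone with rep anchors.

    A generous lead-in keeps the narrowband filter's edge transient (its
    time constant is seconds at a 0.366 Hz bandwidth) away from the epochs.
    """
    melody = make_melody_spec()
    rep_s = 32 * beat_ms / 1000.0
    dur = pad * 2 + n_reps * rep_s
    n = int(dur * fs)
    t = np.arange(n) / fs
    amp = amplitude(t) if callable(amplitude) else np.ones(n)
    data = (amp * np.cos(2 * np.pi * f0 * t))[None, :].repeat(n_channels, axis=0)
    anchors, windows = [], []
    for r in range(n_reps):
        start_ms = pad * 1000 + r * rep_s * 1000
        windows.append(dict(trial_index=0, repetition_index=r,
                            start_sample=int(start_ms / 1000 * fs),
                            stop_sample=int((start_ms + rep_s * 1000) / 1000 * fs)))
        for i, p in enumerate(melody.beat_positions()):
            anchors.append(dict(trial_index=0, repetition_index=r, event_index=i,
                                nominal_event_index=i,
                                sample=int((start_ms + float(p) * beat_ms) / 1000 * fs)))
    return EEGRecording(data=data, fs=fs, ch_names=[f"c{i}" for i in range(n_channels)],
                        anchors=pd.DataFrame(anchors), rep_windows=pd.DataFrame(windows))


def series(values, m, rep=0, start_event=0):
    return envm.EnvelopeSeries(samples=np.asarray(values, float), m=m,
                               trial_index=0, repetition_index=rep,
                               start_event=start_event)


class TestExtractEnvelope:
    def test_pure_tone_envelope_is_flat_unit(self, melody):
        rec = tone_recording()
        envs = envm.extract_envelope(rec, np.array([1.0]), 2.0, melody)
        assert len(envs) == 2
        for e in envs:
            assert np.max(np.abs(e.samples - 1.0)) < 0.02

    def test_am_tone_envelope_tracks_modulator(self, melody):
        rec = tone_recording(amplitude=lambda t: 1.0 + 0.4 * np.sin(2 * np.pi * 0.08 * t))
        envs = envm.extract_envelope(rec, np.array([1.0]), 2.0, melody)
        for e in envs:
            win = rec.rep_windows[rec.rep_windows.repetition_index == e.repetition_index].iloc[0]
            t = (np.arange(len(e.samples)) / e.fs) + win.start_sample / rec.fs
            target = 1.0 + 0.4 * np.sin(2 * np.pi * 0.08 * t)
            rmse = np.sqrt(np.mean((e.samples - target) ** 2)) / np.sqrt(np.mean(target ** 2))
            assert rmse < 0.05

    def test_zero_signal_gives_zero_envelope(self, melody):
        rec = tone_recording()
        rec.data[:] = 0.0
        envs = envm.extract_envelope(rec, np.array([1.0]), 2.0, melody)
        for e in envs:
            assert np.allclose(e.samples, 0.0)

    def test_rate_out_of_range_rejected(self, melody):
        rec = tone_recording()
        with pytest.raises(ValueError, match="1-4 Hz"):
            envm.extract_envelope(rec, np.array([1.0]), 5.0, melody)

    def test_projection_and_filtering_commute(self, melody):
        """Project-then-filter equals filter-then-project (linearity)."""
        from scipy.signal import butter, sosfiltfilt

        rng = np.random.default_rng(0)
        rec = tone_recording(n_channels=3)
        rec.data += 0.1 * rng.standard_normal(rec.data.shape)
        w = np.array([0.5, -0.3, 0.8])
        proj_then = sosfiltfilt(
            butter(2, [1.817, 2.183], btype="band", fs=500.0, output="sos"),
            w @ rec.data,
        )
        filt_then = w @ sosfiltfilt(
            butter(2, [1.817, 2.183], btype="band", fs=500.0, output="sos"),
            rec.data, axis=-1,
        )
        assert np.allclose(proj_then, filt_then, atol=1e-10)


class TestEventResample:
    def _raw(self, samples, onset_idx, units, rep=0, start_event=0):
        return envm.RawEnvelope(samples=np.asarray(samples, float),
                                onset_idx=np.asarray(onset_idx, float),
                                eighth_units=np.asarray(units, float),
                                trial_index=0, repetition_index=rep,
                                start_event=start_event)

    def test_constant_envelope_resamples_to_constant_of_grid_length(self, melody):
        rec = tone_recording()
        envs = envm.extract_envelope(rec, np.array([1.0]), 2.0, melody)
        m = envm.min_grid_density(envs)
        out = envm.event_resample(envs[0], melody, m)
        assert out.grid_length == 64 * m
        assert np.max(np.abs(out.samples - 1.0)) < 0.02

    def test_linear_envelope_stays_linear_per_segment_with_exact_endpoints(self, melody):
        n = 1000
        raw = self._raw(np.linspace(0, 1, n), [0, 250, 500, 750], [2, 2, 2, 2])
        out = envm.event_resample(raw, melody, m=10)
        assert out.grid_length == 80
        # endpoints of each segment reproduce the original values exactly
        for k, idx in enumerate([0, 250, 500, 750]):
            assert out.samples[k * 20] == pytest.approx(idx / (n - 1), abs=1e-12)
        # linear data stay linear in each warped segment
        seg = out.samples[:20]
        assert np.allclose(np.diff(seg, 2), 0.0, atol=1e-9)

    def test_resampling_idempotence_on_conformal_series(self, melody):
        rng = np.random.default_rng(1)
        m = 10
        smooth = np.cumsum(rng.standard_normal(64 * m))
        onset_idx = np.arange(0, 640, 20.0)  # 32 events, 2 eighth-units each
        raw = self._raw(smooth, onset_idx, np.full(32, 2.0))
        out = envm.event_resample(raw, melody, m=m)
        assert out.grid_length == 64 * m
        assert np.max(np.abs(out.samples - smooth)) < 1e-9

    def test_two_tempi_same_shape_correlate_after_warping(self, melody):
        """Resampling makes performances at different tempi comparable."""
        def env_at_tempo(beat_ms):
            rep_s = 32 * beat_ms / 1000
            rec = tone_recording(beat_ms=beat_ms, n_reps=1,
                                 amplitude=lambda t: 1 + 0.5 * np.sin(
                                     2 * np.pi * (t - 10.0) / rep_s))
            return envm.extract_envelope(rec, np.array([1.0]), 2.0, melody)[0]
        e1, e2 = env_at_tempo(450.0), env_at_tempo(550.0)
        m = min(envm.min_grid_density([e1]), envm.min_grid_density([e2]))
        s1 = envm.event_resample(e1, melody, m)
        s2 = envm.event_resample(e2, melody, m)
        r = stats.pearsonr(s1.samples, s2.samples)[0]
        assert r > 0.99

    def test_grid_too_coarse_raises(self):
        raw = self._raw(np.ones(10), [0, 3, 6], [2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="too coarse"):
            envm.min_grid_density([raw])


class TestAEC:
    def test_identical_envelopes_correlate_perfectly(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(320).cumsum()
        r = envm.aec(series(x, 5), series(x, 5))
        assert r == pytest.approx(1.0)
        assert np.isfinite(envm.fisher_z(r))

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 320))
        r1 = envm.aec(series(x, 5), series(y, 5))
        r2 = envm.aec(series(3.7 * x, 5), series(0.2 * y, 5))
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_first_repetition_skips_count_in(self):
        m = 5
        rng = np.random.default_rng(4)
        shared = rng.standard_normal(48 * m)
        leader = series(np.concatenate([rng.standard_normal(16 * m), shared]), m)
        follower = series(shared, m, start_event=8)
        assert envm.aec(leader, follower) == pytest.approx(1.0)

    def test_fisher_mean_closed_form(self):
        rs = np.array([0.5, 0.5, 0.5])
        assert np.mean(envm.fisher_z(rs)) == pytest.approx(np.arctanh(0.5), rel=1e-9)
        assert envm.fisher_z_mean(rs) == pytest.approx(0.5, rel=1e-9)
        # identical per-repetition r: fisher averaging equals naive averaging
        assert envm.fisher_z_mean(np.full(5, 0.3)) == pytest.approx(0.3, rel=1e-12)

    def test_independent_envelopes_average_near_zero(self):
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(200):
            x, y = rng.standard_normal((2, 512))
            rs.append(envm.aec(series(x, 8), series(y, 8)))
        assert abs(envm.fisher_z_mean(np.array(rs))) < 0.02

    def test_zero_variance_envelope_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            envm.aec(series(np.ones(320), 5), series(np.arange(320.0), 5))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            envm.aec(series(np.arange(64.0), 1), series(np.arange(128.0), 2))


class TestSurrogates:
    def _cohort(self, n_pairs, rho_within, melody, seed=0, n_reps=6, n=400):
        """Raw envelopes per pair with within-pair sharing only."""
        rng = np.random.default_rng(seed)
        onset_idx = np.linspace(0, n, 33)[:-1]
        units = np.full(32, 2.0)
        cohort = {}
        for pid in range(n_pairs):
            cohort[pid] = {"Leader": [], "Follower": []}
            for rep in range(n_reps):
                shared = rng.standard_normal(n + 1)
                for role in ("Leader", "Follower"):
                    private = rng.standard_normal(n + 1)
                    z = np.sqrt(rho_within) * shared + np.sqrt(1 - rho_within) * private
                    z = np.convolve(z, np.ones(25) / 25, mode="same") + 2.5
                    cohort[pid][role].append(envm.RawEnvelope(
                        samples=z, onset_idx=onset_idx, eighth_units=units,
                        trial_index=0, repetition_index=rep, start_event=0,
                    ))
        return cohort

    def test_identical_envelopes_make_surrogates_equal_observed(self, melody):
        cohort = self._cohort(4, 1.0, melody, seed=6)
        base = cohort[0]["Leader"]
        for pid in cohort:
            cohort[pid] = {"Leader": base, "Follower": base}
        sur = envm.surrogate_aecs(cohort, melody)
        m = envm.min_grid_density(base)
        resampled = [envm.event_resample(e, melody, m) for e in base]
        observed = envm.condition_aec(resampled, resampled)["r_mean"]
        for pid, r_sur in sur.items():
            assert r_sur == pytest.approx(observed, abs=1e-9)

    def test_within_pair_sharing_beats_surrogates(self, melody):
        cohort = self._cohort(5, 0.8, melody, seed=7)
        sur = envm.surrogate_aecs(cohort, melody)
        wins = 0
        for pid, envs in cohort.items():
            m = envm.min_grid_density(envs["Leader"] + envs["Follower"])
            ls = [envm.event_resample(e, melody, m) for e in envs["Leader"]]
            fs_ = [envm.event_resample(e, melody, m) for e in envs["Follower"]]
            obs = envm.condition_aec(ls, fs_)["r_mean"]
            wins += obs > sur[pid]
        assert wins == 5

    def test_surrogate_count_is_n_minus_one(self, melody):
        cohort = self._cohort(4, 0.5, melody, seed=8)
        import unittest.mock as mock

        calls = []
        original = envm.condition_aec

        def counting(ls, fs_):
            calls.append(1)
            return original(ls, fs_)

        with mock.patch.object(envm, "condition_aec", counting):
            envm.surrogate_aecs(cohort, melody)
        assert len(calls) == 4 * 3  # each leader re-paired with n-1 followers

    def test_too_few_pairs_rejected(self, melody):
        cohort = self._cohort(2, 0.5, melody, seed=9)
        with pytest.raises(ValueError, match="3 pairs"):
            envm.surrogate_aecs(cohort, melody)


class TestBinomialComparison:
    def test_fifteen_of_twenty_matches_exact_tail(self):
        obs = np.arange(20, dtype=float)
        sur = obs - 1.0
        sur[:5] = obs[:5] + 1.0  # 15 wins
        res = envm.binomial_comparison(obs, sur)
        assert res["k"] == 15 and res["n"] == 20
        assert res["p"] == pytest.approx(21700 / 1048576, rel=1e-12)
        assert round(res["p"], 2) == 0.02

    def test_all_wins_gives_two_to_minus_n(self):
        obs = np.ones(12)
        res = envm.binomial_comparison(obs, np.zeros(12))
        assert res["p"] == pytest.approx(2.0 ** -12, rel=1e-12)

    def test_half_wins(self):
        obs = np.concatenate([np.ones(10), np.zeros(10)])
        res = envm.binomial_comparison(obs, np.full(20, 0.5))
        assert res["k"] == 10
        assert res["p"] == pytest.approx(0.588, abs=5e-4)

    def test_ties_count_as_failures(self):
        obs = np.ones(5)
        res = envm.binomial_comparison(obs, np.ones(5))
        assert res["k"] == 0 and res["p"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            envm.binomial_comparison(np.array([]), np.array([]))
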