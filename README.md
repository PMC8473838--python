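# duetsync

Behavioral and neural synchrony analysis for duet-performance
hyperscanning — plus a coupled-oscillator synthetic data generator so the
whole pipeline is testable by parameter recovery.

## The problem

When two musicians perform a melody together, how well they synchronize
is shaped by the mismatch between their *spontaneous rates* — the tempi
they adopt when playing alone, treated as natural frequencies of coupled
oscillators — and their coordination is expected to leave a trace in both
behavior and brain activity: tone-onset asynchronies on the one hand, and
EEG oscillations at the shared performance rate on the other. `duetsync`
implements the full analysis chain for dual-EEG + keystroke recordings of
leader/follower duets of a fixed 32-tone melody, for researchers studying
joint action, sensorimotor synchronization, and inter-brain coupling.

The stages:

* **behavior** — repetitions with added/deleted tones are excluded by
  global pitch-sequence alignment (substitutions retained); quarter-note
  IOIs (half notes midpoint-split, off-beat eighths dropped) give
  performance rates (Hz = 1000 / mean IOI in ms); signed and absolute
  leader−follower asynchronies are normalized by the mean duet IOI.
  Cohort statistics relate solo-rate detuning `T_L − T_F` to signed
  asynchrony (Spearman) and duet rate to both solo rates (standardized
  OLS).
* **spectral** — 9 s Hanning-windowed epochs, single-segment Welch PSD on
  an 8192-point FFT (0.061 Hz bins), log transform, noise normalization
  (each bin minus the mean of its ±1..3 neighbors), 49-bin spectra
  aligned on each pair's duet rate, fronto-central ROI (FC1, FC2, Cz,
  Fz), and a Wilcoxon signed-rank peak test of the duet-rate bin against
  its ±8-bin neighborhood.
* **ssd** — spatio-spectral decomposition: generalized eigenfilters
  `S·w = λ·N·w` maximizing 1.5–3.5 Hz band power against flanking bands,
  fitted on solo EEG, applied to duet EEG, with automated fronto-central
  component selection.
* **envelope** — the SSD component is filtered at the duet rate
  ±0.183 Hz, Hilbert-transformed to an amplitude envelope, resampled to
  the melodic event grid (m samples per eighth note, 2m per quarter, 4m
  per half), and correlated between brains per repetition (Fisher-z
  averaged). Chance level comes from surrogate re-pairings of each leader
  with every non-partner follower; observed-vs-surrogate is an exact
  one-sided binomial test.
* **simulate** — coupled-timekeeper duet timing
  (`A(k+1) = (1−α−β)A(k) + (T_L−T_F)`, steady state `(T_L−T_F)/(α+β)`),
  pitch-error injection, and dual-brain EEG whose duet-rate source
  envelopes share a controllable correlation `ρ` inside a 1/f + white
  noise background.

See `docs/methods.md` for the models, parameter defaults, and numerical
conventions.

## Worked example

The behavioral law, with the noise switched off — a leader 20 ms per beat
slower than the follower, coupled at α = 0.5:

```python
from duetsync import behavior as bhv
from duetsync.melody import make_melody_spec
from duetsync.simulate import TimingSimConfig, simulate_duet_timing

melody = make_melody_spec()
cfg = TimingSimConfig(t_leader_ms=520, t_follower_ms=500, alpha=0.5,
                      sigma_timekeeper_ms=0, sigma_motor_ms=0, n_repetitions=4)
leader, follower = simulate_duet_timing(melody, cfg)
lt, _ = bhv.apply_error_filter(leader, melody)
ft, _ = bhv.apply_error_filter(follower, melody)
res = bhv.duet_asynchronies(lt[-1], ft[-1], melody)
print(f"steady-state signed asynchrony: {res.signed_mean_ms:+.1f} ms "
      f"({res.signed_mean:+.4f} of the duet IOI)")
```

```
steady-state signed asynchrony: +40.0 ms (+0.0769 of the duet IOI)
```

— exactly the fixed point (520 − 500)/0.5 = +40 ms: the slower leader
lags by a constant fraction of the beat.

The full pipeline on a small simulated cohort (4 pairs, both leader-order
conditions, EEG with ground-truth envelope correlation ρ = 0.5):

```python
from duetsync.pipeline import RunConfig, run_pipeline
from duetsync.simulate import CohortConfig, EEGSimConfig

cfg = RunConfig(seed=7, out_dir="demo_out",
                cohort=CohortConfig(n_pairs=4, n_duet_repetitions=4,
                                    n_solo_repetitions=4, p_pitch_error=0.04,
                                    eeg=EEGSimConfig(rho_envelope=0.5, snr_db=15.0)))
stats = run_pipeline(cfg)
```

prints to `demo_out/stats.json` (and CSV tables alongside), containing
for this seed:

```
excluded: 2 of 96 repetitions (2.08%)
detuning ~ asynchrony Spearman rho: First-Leader 1.0, Second-Leader 1.0
duet-rate regression (First-Leader): beta_L=0.99  beta_F=0.01  R2=1.00
duet-rate spectral peak (First-Leader): W=36, p=3.9e-03
observed mean AEC r=0.45 vs surrogate r=-0.01; observed higher in 4/4 pairs
```

Reading: the error filter caught the injected pitch errors; signed
asynchronies track solo-rate detuning perfectly at this noise level; the
leader's solo rate (not the follower's) sets the duet tempo; every
participant shows a spectral peak at the duet rate; and the partners'
duet-rate amplitude envelopes correlate far above the re-paired surrogate
baseline.

A thin CLI wraps the same stages:

```sh
duetsync simulate --config sim.yaml --seed 1 --out data/
duetsync behavior --seed 1 --out results/
duetsync all --seed 1 --out results/
```

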