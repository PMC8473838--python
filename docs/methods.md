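# Methods

`duetsync` analyses temporal coordination between two musicians performing
the same melody, on two levels: tone-onset timing (behavior) and EEG
oscillations at the performance rate (brain). Because suitable paired
recordings are rarely shareable, the package ships a generative model of
coupled duet timing and dual-brain EEG whose ground-truth parameters the
pipeline must recover; every stage is validated that way.

## The melody template

All analyses are anchored to a fixed 32-tone melody in 4/4 (20 quarter
notes, 4 half notes, 8 eighth notes; 32 quarter-note beats; compass G3–A4).
The first 8 tones are all quarter notes; in duets the leader plays them
alone as a count-in and the follower joins at the 9th tone. Off-beat eighth
notes sit at the temporal midpoint of their beat (isochronous subdivision
— the simplest model consistent with the notation).

## Coupled-timekeeper timing model

Each performer is an oscillator with a spontaneous quarter-note period
`T` (ms). Latent beat times follow a linear phase-correction recursion:

    b_L(k+1) = b_L(k) + T_L + η_L(k) − β·A(k)
    b_F(k+1) = b_F(k) + T_F + η_F(k) + α·A(k),      A(k) = b_L(k) − b_F(k)

with follower gain `α` (default 0.5), leader gain `β` (default 0, i.e.
pure leading), and timekeeper noise `η ~ N(0, σ_tk²)` (default σ_tk =
10 ms). Emitted onsets are read off the beat grid — off-beat eighths at
beat-interval midpoints, half notes spanning a silent beat — plus motor
noise (default 4 ms). During the count-in the follower's timekeeper
passively shadows the leader's beats; coupling starts at the joining beat.

The recursion gives `A(k+1) = (1−α−β)·A(k) + (T_L − T_F)`, contracting for
`0 < α+β < 2` to the fixed point

    A* = (T_L − T_F) / (α + β).

A slower leader (larger period) therefore lags by a constant signed offset
proportional to the detuning — the behavioral law the pipeline must
recover, and recovers exactly under zero noise because correction operates
at the beat level (an event-level recursion with mixed note values would
have no constant fixed point). Phase correction only is modelled; period
correction is deliberately left out to keep this closed form.

With `α = β = 0` and detuned periods the drift is unbounded; this is
legitimate (uncoupled performers) and is flagged with a warning rather
than an error.

Cohorts draw spontaneous periods uniformly from 380–580 ms, matching the
observed spread of self-paced piano tempi (pair averages ≈ 300–600 ms,
typical partner detuning of order 70 ms). Melody repetitions are corrupted
with probability `p = 0.04` per repetition by one inserted or deleted tone
(matching observed error-exclusion rates of 3–4%), with ground-truth
labels retained for filter validation.

## Error exclusion and behavioral measures

A repetition is excluded when its played pitches align to the template
with any insertion or deletion (added/deleted tones disrupt sequence
timing); substituted pitches alone are retained. Alignment is global
(Needleman–Wunsch) with match +1, mismatch −0.25, indel −1 — one
substitution is cheaper than an indel pair — and traceback ties resolve
toward substitution. The alignment's template indices also pair events
across performers, so a substitution does not desynchronize asynchrony
computation.

Quarter-note-level IOIs drop off-beat eighths (the on-beat eighth onset
serves as the beat onset) and split each half note at the temporal
midpoint of its interval ("linear interpolation" read literally; swap in a
tempo-curve interpolation if needed). Rates are `Hz = 1000 / mean IOI`.

Signed asynchrony is mean (Leader − Follower) onset difference over
co-performed tones; absolute asynchrony the mean absolute difference. Both
are normalized per repetition by that repetition's mean duet IOI (the
average of the two performers' mean IOIs), then averaged — normalizing at
the performance level before aggregating. Cohort statistics: Spearman
correlation of solo detuning with signed asynchrony; OLS on standardized
variables predicting duet rate from both partners' solo rates.

## Frequency-tagged spectra

Each melody repetition contributes one fixed 9 s epoch (4500 samples at
500 Hz), starting at the repetition's first sample and extending into the
next repetition when a performance is faster than 9 s; a final repetition
with insufficient data is dropped with a warning. A fixed window length
gives every participant identical frequency resolution. Epochs are
pre-filtered 0.1–20 Hz (zero-phase windowed-sinc FIR, order 1000).

The PSD of an epoch is a single Hanning-windowed segment zero-padded to an
8192-point FFT — Welch's method degenerates to one modified periodogram
when the segment spans the epoch — giving 500/8192 ≈ 0.061 Hz bins. The
8192 is inferred: it is the unique power of two producing that resolution
at 500 Hz, and it anchors all bin arithmetic. Log power is averaged over
epochs, then noise-normalized: each bin minus the mean of its six
neighbors at offsets ±1..±3 (±0.183 Hz). Whether frequency-tagging
"±3 neighboring bins" should skip immediate neighbors is convention-
dependent; the offset set is exposed in `SpectralConfig.noise_offsets`.
Edge bins use available neighbors and are flagged.

Spectra are compared across pairs in a 49-bin window (±24 bins ≈ 2.99 Hz)
centered on the bin nearest the pair's duet rate (midpoint ties go to the
lower bin, deterministically). The entrainment test is a paired Wilcoxon
signed-rank of the center bin against the mean of the 16 bins at offsets
±1..±8, across participants; the normal-approximation z is reported (the
field's convention) with an exact-distribution option used automatically
for n ≤ 25. The natural log is used throughout (any log base rescales
normalized values uniformly; tests are base-invariant).

## SSD spatial filtering

Spatio-spectral decomposition maximizes band power against flanking-band
power via the generalized eigenproblem `S·w = λ·N·w`, with `S` the
covariance of data band-passed in the target band (1.5–3.5 Hz, the range
of observed self-paced rates) and `N` the summed covariances of two
flanking bands. Flank geometry is not canonical: defaults are 1 Hz-wide
flanks separated from the band by 0.5 Hz gaps; the lower flank edge is
clipped to 0.1 Hz because a DC band edge is unrealizable. All band-passes
are zero-phase second-order-section Butterworth of order 2 — chosen for
stability at delta frequencies. A near-singular `N` triggers a fixed
shrinkage ridge (1e−6 · trace/dim) with a warning.

Filters are fitted on solo-task EEG and applied to duet EEG — independent
data from the same performer. Component choice replaces human visual
selection with a documented score: eigenvalue (band/flank power ratio)
times the fronto-central ROI (FC1, FC2, Cz, Fz) fraction of the absolute
forward pattern (`S·w`, column-normalized); an explicit index overrides
it. The returned filter is unit-norm, sign-fixed so the mean ROI pattern
loading is positive.

## Amplitude envelopes and inter-brain correlations

The selected component's time course is band-passed at the pair's duet
rate ±0.183 Hz (zero-phase Butterworth order 2 — zero-phase so no group
delay misaligns partners), epoched per repetition with 2.5 s pads,
antialias-downsampled to 100 Hz (polyphase FIR), and its amplitude
envelope taken as the Hilbert magnitude; the pads absorb Hilbert edge
artifacts and are trimmed. Projection before filtering is used (linearity
makes the order irrelevant; one channel is filtered instead of 24). Note
the narrowband filter's impulse response lasts seconds: recordings need a
few seconds of lead-in before the first repetition.

Envelopes from different performances are made comparable by event-grid
resampling: the minimum eighth-note-equivalent inter-onset sample count
across repetitions (within pair × condition) sets the grid density `m`;
eighths map to `m` samples, quarters to `2m`, halves to `4m` (64·m per
full repetition), with shape-preserving piecewise-cubic (PCHIP)
interpolation warping each inter-onset segment. Segment start values are
knots, so they are reproduced exactly, and resampling an already
grid-conformal series is the identity.

AECs are Pearson correlations per repetition; for a trial's first
repetition only samples from the 9th tone's grid anchor onward enter (both
partners playing; the anchor sample itself is included). Per-repetition
r's are Fisher-z averaged within condition, then across conditions, and
back-transformed. Perfect correlations are clipped at atanh(0.999999).
Envelope means are not detrended per repetition — Pearson centering makes
level offsets irrelevant.

The chance level re-pairs each leader with every non-partner follower
(n−1 surrogates per leader, within condition, then condition-averaged);
each surrogate pairing is re-resampled to the two members' common grid
(their minimum `m`) before correlating corresponding repetitions in the
trial structure. The observed-vs-surrogate comparison is an exact
one-sided binomial test (success = observed above the pair's surrogate
mean, ties counted as failures, null p = 0.5); the direction is fixed a
priori.

## The EEG generator

Each brain's recording is

    X(t) = a · topo ⊗ [A(t)·cos(2π f t + φ)] + 1/f background + white noise

with `topo` a unit-norm fronto-central pattern over a 24-channel 10–20
montage and `f` the pair's duet beat rate (derived from the timing
simulation, so behavior and EEG agree). The amplitude envelope is
`A = softplus(1 + 0.6·z)` where `z = √ρ·z_shared + √(1−ρ)·z_private` and
the `z` processes are unit-variance Gaussian with a 0.15 Hz bandwidth
(synthesized spectrally — a time-domain IIR pass at so low a normalized
cutoff leaves edge transients that distort the scale). The softplus keeps
envelopes positive and smooth (Hilbert-friendly), and around 1.0 it is
nearly linear, so the correlation of the two brains' envelopes stays
within a few percent of `ρ` — `rho_envelope` is the recoverable ground
truth. The gain `a` is calibrated empirically so the source-to-background
power ratio within the duet-rate narrowband equals `snr_db` (default
10 dB; recovery experiments at 25 dB). The modulation depth 0.6 makes
envelope fluctuations resolvable above the narrowband noise floor at
these SNRs (depth × √SNR ≳ 3), and a ~16 s repetition contains several
fluctuation cycles at 0.15 Hz. An optional 10 Hz occipital distractor
source exercises component selection. With background and sensor noise
both zero the SNR calibration is ignored and the source has unit gain.

What the generator does not emulate: artifacts (blinks, EMG, motion),
volume-conduction mixing of multiple correlated sources, non-stationary
tempo drift (rubato), keystroke velocity. Passing tests therefore show
the pipeline's statistical machinery is correct and recovers known
coupling; they do not certify performance on artifact-laden recordings,
which are assumed cleaned before entry.

## Problem sizes and numerical choices

Validation cohorts are desk-scale by design: 4–8 pairs, 8 duet
repetitions per condition (the study design has 24), 6 solo repetitions,
both leader-order conditions where the measure averages across them.
Recovery experiments reuse the same per-pair seeds across ground-truth
levels, pairing the comparison so level effects are isolated from
pair-level simulation variance. The per-repetition AEC is intrinsically
noisy (a ~16 s window of a 0.15 Hz-bandwidth process has few effective
degrees of freedom); conclusions always rest on Fisher-z means over
repetitions and pairs.

All times are float milliseconds; EEG positions are 0-based integer
sample indices; epochs are half-open `[start, stop)`. All randomness
descends from one root seed through named `SeedSequence` spawns, so any
pair or batch is independently reproducible. Degenerate inputs fail
loudly: empty trials, zero-variance envelopes, non-finite power before a
log, constant inputs to correlations, duet rates outside 1–4 Hz.

## Known limitations

* The phase-correction recursion is a stand-in generative model; the
  underlying study asserts no specific duet timing mechanism.
* Automated SSD component selection approximates, but is not, expert
  visual selection; override by index when it errs.
* Event tables round-trip losslessly; EEG round-trips at float32
  precision. Only the native flat-binary + JSON sidecar format is
  supported for EEG I/O.
* The binomial comparison summarizes each pair's surrogate distribution
  by its mean; the full surrogate distributions are available from
  `surrogate_aecs` if a rank-based comparison is preferred.
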