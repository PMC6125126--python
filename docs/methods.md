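# Methods

`fearlfp` analyzes dual-region local field potentials (LFPs) recorded
from the dorsomedial prefrontal cortex (dmPFC) and basolateral amygdala
(BLA) of rats during auditory fear conditioning and extinction, and
ships a synthetic generator so that every estimator can be validated by
parameter recovery without animal data. This note documents the models,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic validation does and does not establish.

## Recording and session model

Signals are two composite LFP channels (one per region, microvolts)
sampled at 1 kHz and band-limited to 1–500 Hz. A session is a sequence
of 30 s conditioned-stimulus (CS) tones, each a train of 30 pips
(100 ms, 1 Hz), separated by inter-trial intervals drawn uniformly from
80–160 s (mean 120 s). Tone habituation presents 5 tones; the fear
recall/extinction and extinction recall sessions present 15; the number
of CS–US pairings during conditioning is configurable with no default
(it must be stated by the user). Timestamps are in seconds from
recording start and all windows are half-open `[start, end)`.

The three behavioral timepoints and their scoring conventions:

| timepoint | session | trials scored |
|---|---|---|
| before conditioning | tone habituation | last two |
| fear recall | fear recall/extinction | first two |
| extinction recall | extinction recall | first two |

## Analysis stages

**Auditory evoked potential (AEP).** All pips of the scored trials are
epoched at −100…+400 ms around pip onset (2 × 30 = 60 segments), each
segment baseline-corrected by its own pre-onset mean, and averaged
pointwise. The amplitude is the first post-onset local maximum minus the
first following local minimum, searched in 0–250 ms with a prominence
floor of twice the pre-onset SD (both config-exposed; the floor guards
against noise ripples, and the upper bound matches the theta-power
window). A waveform with no qualifying pair raises `NoDeflection` rather
than scoring 0. Amplitudes are reported per animal as percent of the
before-conditioning value.

**Evoked theta power.** The pip-averaged waveform (−200…+400 ms epoch)
is decomposed with complex Morlet wavelets in the bandwidth/center
convention, ψ(t) = (π·fb)^(−1/2)·exp(−t²/fb)·exp(j2π·fc·t) with fb = 2,
fc = 1 Hz, over 2–100 Hz in 0.1 Hz steps (scale = fc·fs/f; the package
pipeline evaluates only the 2–12.1 Hz rows when only the theta summary
is needed — rows are independent under the normalization, so the values
are identical). Power is 10·log10(|CWT|²) with a floor of 1e−12 before
the log; each frequency row is z-scored across the full epoch and the
mean over the −200…0 ms baseline is subtracted. Evoked theta power is
the mean of the normalized map over 0–250 ms × 2–12 Hz. Epochs are
reflection-padded by one wavelet support (4σ at the lowest frequency)
before the transform; the cone of influence is not masked. Because the
z-scoring span ("across the time series") is ambiguous in the field, the
full −200…+400 ms epoch is used.

Normalized theta power (percent of the before-conditioning value) is
only defined when the baseline value is positive; otherwise the output
carries the raw difference and a flag instead.

**Theta coherence.** Welch magnitude-squared coherence with 500 ms
Hamming windows, 50% overlap (unstated in the field convention;
chosen as the standard default) and 1024-point FFTs, computed over the
30 s CS windows of the two scored trials and summarized as the mean over
2–12 Hz.

**Envelope lead/lag.** Each CS-window signal is bandpassed to 2–12 Hz
with a 4th-order zero-phase (forward–backward) Butterworth filter — so
the filter itself delays neither channel — and the modulus of the
analytic (Hilbert) signal, minus its mean, is the instantaneous theta
amplitude. The two envelopes are Pearson-correlated at every integer
sample lag in ±0.1 s, normalizing over the overlapping samples only;
positive lag means the dmPFC leads. Significance uses a shift-surrogate
null: the BLA envelope is circularly shifted by u ~ Uniform(2, 5) s with
random sign, 100 times, the correlation peak recorded each time, and the
observed peak must exceed 95% of the surrogate peaks. Circular shifting
preserves envelope autocorrelation and segment length. The summary
lead/lag of a timepoint is the center of the maximal 5 ms bin of the
per-segment peak-lag histogram (ties resolve toward the smallest
absolute center, then the positive one).

**Freezing.** Freezing bouts arrive as intervals; a window score is
100 × |union ∩ window|/|window| with overlaps merged and bouts clipped
to the window. The pretone score uses the 30 s ending at the first tone
onset (one value per session); extinction-session trials are averaged in
consecutive two-trial blocks, a trailing 15th trial being excluded and
logged.

**Group statistics.** Values are screened once per group and measure for
|x − mean| > 2·SD (sample SD on all values). One-way repeated-measures
ANOVA (F = MS_condition / MS_condition×subject) with Tukey HSD post hocs
on the RM error term serves the within-group contrasts; a mixed
group × level ANOVA (subjects-within-group and level × subjects-within-
group error terms) with Holm–Šídák-adjusted post hocs serves the
group comparisons. Sphericity corrections are deliberately not applied;
the reported df are the uncorrected (k−1), (k−1)(n−1) pairs. The
lead/lag chance test is an unpaired Student's t between actual and
chance-derived lags (the convention this analysis battery follows), with
a documented one-sample-against-zero alternative (`mode="one-sample"`),
since testing a location against a constant with a two-sample test is
statistically unusual. The ANOVA engines delegate to pingouin; tests
verify them against brute-force sums-of-squares oracles to 1e−10.

## Synthetic generator

Each channel is a sum of four components:

* **Ongoing theta** — band-limited Gaussian noise (4–10 Hz source band,
  inside the 2–12 Hz analysis band) with SD `theta_sd` = 30 µV. A noise
  source rather than a sinusoid is essential: a pure tone has a constant
  envelope, making envelope cross-correlation degenerate. The dmPFC
  carries the shared source s(t); the BLA carries
  √coupling·s(t − lag) + √(1 − coupling)·private theta, so `coupling` is
  the shared fraction of BLA theta variance and `lag` > 0 means the
  dmPFC leads.
* **AEP template** at every pip onset — two raised-cosine lobes (peak
  +40 µV at 15 ms, trough −35 µV at 30 ms at the default amplitude,
  zero at both ends), rescaled per trial so its peak-trough amplitude
  equals the injected `aep_amplitude` exactly. The biphasic shape is a
  minimal smooth parameterization of a primary evoked deflection.
* **Evoked theta burst** at every pip onset — a Gaussian-windowed 8 Hz
  transient (center 120 ms, SD 50 ms, peak 15 µV at gain 1, per-pip
  lognormal amplitude jitter of 0.2). The per-region, per-trial
  `region_theta_gain` scales this burst only: the burst is the
  pip-locked component the evoked theta-power analysis actually
  measures, whereas scaling the ongoing theta together with it would
  cancel out of the z-scored measure (both the numerator and the
  averaged-noise floor would scale) and would also entangle the
  coherence conditions with the theta-power conditions.
* **Pink background** — 1/f noise (exponent 1.0; background spectra are
  otherwise uncharacterized in this preparation), band-limited to
  1–500 Hz, SD `noise_sd` = 15 µV.

Amplitude choices: ongoing theta SD 30 µV against a 75 µV peak-trough
AEP matches the roughly 1:1 ratio of theta to evoked deflection seen in
rodent LFP; the 15 µV burst with condition gains of ~2.5 at recall
timepoints puts normalized evoked theta power at recall in the
150–300% range reported for this preparation. The dB→z-score
normalization saturates near z ≈ 1.5 (the z value of a two-level row
depends on the burst duty fraction, not the contrast, once the burst
dominates), so very large bursts compress condition differences; the
defaults sit below that regime.

Freezing is generated as interval sets (frame-level video scoring is out
of scope): deterministic mode emits one bout of exactly fraction × 30 s;
stochastic mode freezes each 1 s slot independently with probability =
fraction, making the expected percent score exactly 100 × fraction.

All randomness in a session flows from one `numpy` generator seeded by
`SimulationParams.seed`; a cohort spawns per-animal, per-session seeds
via `SeedSequence([master, group-key, animal, session])`, so runs are
bit-reproducible and extensible animal by animal. Ground truth (lag,
coupling, per-trial gains and amplitudes, freezing fractions, seed) is
serialized as a JSON manifest next to the signals (HDF5 channels, CSV
event/trial tables).

## Scenarios

The built-in cohort scenarios encode the two qualitative group patterns
the pipeline is designed to resolve (7 control + 8 stressed animals):

* **control** — theta gain and AEP amplitude rise at fear recall in both
  regions and return to baseline at extinction recall; coupling rises
  from 0.3 to 0.9 at both recalls with a +20 ms dmPFC lead; freezing
  0.05 → 0.7 → 0.2.
* **CIS** (chronic immobilization stress) — BLA theta gain and BLA AEP
  stay elevated through extinction recall; dmPFC theta rises at fear
  recall and reverses; dmPFC AEP never changes; coupling is 0 at every
  timepoint (no coherence change, no reliable lead); freezing as in
  control.

## Validation studies and their problem sizes

Recall sessions in the validation cohort are simulated with the two
analyzed trials only (the scoring conventions never touch later trials),
and the lag-recovery/calibration studies use two-trial sessions and 30 s
channel pairs; habituation keeps its five tones. Study sizes: lag
recovery 5 lags × 20 sessions at coupling 0.9; surrogate calibration
1000 uncoupled 30 s pairs; coherence floor oracle 200 Monte-Carlo pairs;
theta-gain monotonicity 20 gain levels (0.5–3.0) at a low-noise
condition (background amplitudes at one fifth of the defaults, where the
per-session measurement noise does not mask adjacent gain levels); AEP
recovery at zero noise and at noise SD = 0.2 × template peak; ANOVA
equivalence on 1000 randomized toy designs.

Two calibration facts a user should know:

* The shift-surrogate significance rule is measurably anti-conservative:
  on uncoupled pairs it fires at ~0.06 rather than the nominal
  5/101 ≈ 0.05. The 100 surrogate peaks come from circular shifts
  confined to ±(2–5) s while the theta-envelope decorrelation time is
  ~0.2–0.3 s, so only ~30 of them are effectively independent, and
  beating 96 of 100 correlated peaks is easier than beating 96
  independent ones. This is a property of the procedure itself (shift
  range and surrogate count are fixed by convention), not of this
  implementation.
* The z-scored theta measure saturates (see above), so evoked theta
  power is monotone in the injected gain but not proportional to it.

## What passing the synthetic checks does not show

The generator emulates the statistical structure the analyses assume —
stationary band-limited noise, deterministic pip-locked components with
amplitude jitter, linear mixing with a pure delay. Real LFPs add
non-stationary state changes (movement, sleep-like epochs), volume
conduction, electrode drift and artifacts, frequency-dependent delays,
and spiking contamination; recovery results here bound estimator
behavior only under the modeled conditions. Freezing intervals are
generated directly, so behavioral scoring is validated as arithmetic,
not as video analysis.

## Known limitations

* One composite channel per region; how a multi-wire bundle is reduced
  to one trace is the caller's responsibility.
* Edge effects at the lowest wavelet frequencies are large relative to
  the 600 ms epoch even with reflection padding; the cone of influence
  is reported nowhere and not masked (config-exposed padding only).
* The surrogate significance rule's mild anti-conservatism (above).
* `import_source_data` requires an explicit column→level mapping and
  refuses to guess; published workbooks must be mapped by the caller.
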