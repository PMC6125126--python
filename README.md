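# fearlfp

Analysis pipeline for dual-region local field potentials (LFPs) recorded
during auditory fear conditioning and extinction, plus a synthetic
generator that makes every stage verifiable by parameter recovery.

## The problem

In rodent fear conditioning, a 30 s tone (a train of 30 pips at 1 Hz)
predicts a foot shock; freezing quantifies learned fear, and LFPs from
the dorsomedial prefrontal cortex (dmPFC) and basolateral amygdala (BLA)
track how the circuit reorganizes across tone habituation, fear recall,
and extinction recall. The measures this package computes, per animal
and timepoint:

* **AEP amplitude** — pips are epoched and averaged (60 per timepoint);
  the auditory evoked potential amplitude is the first post-onset peak
  minus the first following trough, normalized per animal as percent of
  the pre-conditioning baseline.
* **Evoked theta power** — the averaged evoked response is decomposed
  with complex Morlet wavelets (bandwidth 2, center 1 Hz; 2–100 Hz in
  0.1 Hz steps), power in dB is z-scored per frequency and
  baseline-subtracted, and theta power is the mean over
  0–250 ms × 2–12 Hz.
* **Theta coherence** — Welch magnitude-squared coherence (500 ms
  Hamming windows, 1024-point FFT) between dmPFC and BLA over the CS
  windows, averaged over 2–12 Hz.
* **Lead/lag** — instantaneous theta amplitudes (zero-phase 2–12 Hz
  bandpass → Hilbert envelope, demeaned) are cross-correlated over
  ±0.1 s (positive = dmPFC leads); significance compares the observed
  peak with 100 circular 2–5 s shift surrogates (beat 95% of them), and
  the summary lag is the modal 5 ms bin of the per-segment peak lags.
* **Freezing** — percent of each 30 s tone (and the 30 s pretone window)
  covered by freezing bouts, averaged over two-trial blocks.
* **Group statistics** — 2·SD outlier screen, one-way repeated-measures
  ANOVA with Tukey post hocs, mixed group × timepoint ANOVA with
  Holm–Šídák post hocs, and a chance-level test for the lead/lags.

The synthetic generator (`fearlfp.simulate`) produces sessions whose
ground truth is known exactly — a shared band-limited theta source with
configurable coupling and directional delay between regions, pip-locked
AEP templates and theta bursts with per-trial injected amplitudes, pink
background noise, and freezing intervals — so lag recovery, coherence
floors, gain monotonicity, amplitude recovery, and the surrogate test's
type-I rate can all be measured rather than assumed.

## Worked example

Simulate and analyze the built-in two-group cohort (7 control, 8
chronically stressed "CIS" animals; stress is modeled as persistent BLA
theta elevation with abolished inter-regional coupling):

```
python analysis/01_validate_estimators.py   # estimator recovery table
python analysis/02_run_cohort.py            # per-animal measures
python analysis/03_group_statistics.py      # ANOVAs over the cohort
```

`02_run_cohort.py` prints, for master seed 1:

```
control: median BLA theta % of baseline by timepoint:
before_conditioning    100.0
extinction_recall       57.5
fear_recall            129.0
control: fraction of animals with a significant dmPFC lead:
before_conditioning    1.0
extinction_recall      1.0
fear_recall            1.0
CIS: median BLA theta % of baseline by timepoint:
before_conditioning    100.0
extinction_recall      127.2
fear_recall            145.7
CIS: fraction of animals with a significant dmPFC lead:
before_conditioning    0.0
extinction_recall      0.0
fear_recall            0.0
```

Read: in control animals evoked BLA theta rises at fear recall (129% of
baseline) and reverses below baseline after extinction (57%), and the
dmPFC envelope reliably leads the BLA; in the stressed group the theta
elevation persists through extinction recall (127%) while the dmPFC
lead is absent at every timepoint — the injected decoupling is recovered
as non-significant surrogate tests. Per-animal tables land in
`results/cohort/` with a provenance manifest (config hash, seeds).

## Layout

```
src/fearlfp/        simulate, session_io, aep, spectral, connectivity,
                    behavior, stats, pipeline, validation
analysis/           numbered driver scripts (thin wrappers over src/)
tests/              pytest suite incl. acceptance checks
scripts/            acceptance.py
docs/methods.md     models, defaults, numerical decisions, limitations
```
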