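# Methods

`fatiscope` packages two things: (i) the analysis chain used to quantify
motor slowing of fast repetitive movements and its neurophysiological
correlates (EMG coactivation, paired-pulse TMS inhibition, surround
inhibition, alpha-band recovery), and (ii) a mechanistic simulator of the
phenomenon, used both as a scientific model and as the ground-truth engine
for synthetic cohorts on which the analysis chain is validated by
parameter recovery.

## The surround-inhibition fatigue model

Fast alternating movements (e.g. finger tapping at maximal rate) slow down
by roughly a fifth within 30 s and recover within a 25–30 s break.  The
model attributes this to fatigable inhibition in motor cortex.  Two
populations of output neurons prefer opposite movement phases (flexion at
phase 0, extension at phase π).  Each has a circular (von Mises) tuning
curve over movement phase with width

```
sigma(t) = sigma0 / g(t),        kappa = 1 / sigma^2
```

where `g ∈ [g_min, 1]` is an inhibition gain.  The overlap of the two
curves — the integral of their pointwise minimum, a number in [0, 1] — is
read out twice: as the predicted antagonist *coactivation*, and as a
proportional loss of movement speed

```
v(t) = v0 · (1 − beta · overlap(sigma(t), delta)).
```

The gain obeys first-order kinetics driven by how fast the subject is
actually moving relative to their maximum (`drive = v/v0`):

```
tapping:  dg/dt = −lambda_dec · drive^p_speed · (g − g_min)
rest:     dg/dt = +lambda_rec · (1 − g)
```

During paced tapping the produced speed is the pacing target clamped from
above by the momentary capability.  All of these equations are the
package's own concrete formulation: the mechanism they implement (breakdown
of surround inhibition broadening tuning curves and producing coactivation
and slowing) is qualitative in the literature, and the simplest first-order
forms were chosen deliberately.

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `v0` | 4.0 | cycles/s | ~40 cycles per 10 s, a typical maximal two-finger alternation rate |
| `sigma0` | 0.6 | rad | sharp baseline tuning; baseline overlap ≈ 0.06 |
| `delta` | π | rad | strict flexor/extensor antagonist pair |
| `lambda_dec` | 0.2 | 1/s | decay plateaus within ~30 s of maximal tapping |
| `lambda_rec` | 0.12 | 1/s | ~95 % gain recovery in 25 s, matching behavioural recovery saturation at 25–30 s breaks |
| `p_speed` | 1.0 | – | see below |
| `beta` | 1.0 | – | overlap converts one-to-one into fractional speed loss |
| `g_min` | 0.65 | – | sets the slowing plateau at ~20 % below initial speed |

The calibration targets ~20 % slowing over 30 s at maximal speed and is a
design choice, not a fit to any dataset.  With these values a maximal 30 s
trial slows 20.8 % (first to third 10 s bin), pacing at the end speed of
that trial produces 0.07 % slowing and pacing at 90 % of the end speed
produces exactly none — a strict ordering reproducing the speed dependence
of the phenomenon.

**Why `p_speed = 1`.**  Under the clamp rule, a paced trial's gain always
decays more slowly than a maximal trial's (drive is smaller), so the paced
capability can only cross below the pacing target if the drive exponent is
small.  For exponents ≳ 2 the crossing never happens within 30 s and paced
slowing is *exactly* zero regardless of pace, which would erase the strict
ordering between pacing levels.  With `p_speed = 1` the speed dependence is
preserved (slow movements barely fatigue the circuit thanks to the clamp
itself) and end-speed pacing retains a measurable, tiny slowing.

**Numerics.**  Fixed-step explicit Euler at `dt = 0.01 s`; halving the step
changes the speed series by < 5·10⁻⁴·v0 (tested).  The overlap-versus-gain
curve is precomputed on a 512-point grid and linearly interpolated inside
the integration loop; `tuning_overlap` itself is evaluated in closed form
from the von Mises CDF (the two equal-width curves cross at `delta/2` and
`delta/2 − π`, reducing the min-integral to tail masses).  A wrapped-
Gaussian tuning family is available as a configuration alternative and is
integrated numerically.

## Synthetic cohorts

A subject is a draw of model parameters: log-normal factors with CVs 0.08
(`v0`), 0.08 (`beta`) and 0.35 applied *jointly* to `lambda_dec` and
`lambda_rec`.  The joint factor encodes the empirical coupling that
subjects who slow faster also recover faster; it is what makes the
slowing-slope versus recovery-slope correlation positive across a cohort
(r ≈ 0.7 at n = 17), while the independent `beta` variation keeps that
correlation away from 1.

Modalities are rendered from the subject's simulated trajectory:

* **Taps** — a renewal process with gamma-distributed cycle durations, mean
  `1/v(t)`, CV 0.05; effectors fire in order at equal sub-intervals within
  the cycle.  A cycle begun before a segment ends is completed (the closing
  first-effector tap is emitted), so binned cycle counts carry no edge
  truncation.  A force trace (30 ms half-sine per tap + Gaussian noise,
  SD 0.05 of the pulse amplitude) feeds the detector tests.
* **EMG** — agonist (APB) bursts at phase 0 and antagonist (EPL) at phase
  π, band-limited noise carriers (20–450 Hz) under Gaussian phase
  envelopes; a copy of the agonist-phase envelope scaled by the momentary
  coactivation leaks into the antagonist channel, so the measured
  envelope-overlap index tracks the planted profile (recovered within
  ~0.03 by the analysis chain at default noise).
* **MEP sessions** — log-normal amplitudes (σ_log 0.3) around cell medians:
  `CS+TS = TS·(1 − inhibition)` for the paired-pulse protocol and
  `TMS_Move = TMS_Con·SI` for surround inhibition.  The MEP waveform is a
  triangular biphasic deflection with vertices on the sample grid: its
  peak-to-peak value is exact, and — unlike a smooth sine — additive
  background noise does not systematically inflate the peak-to-peak
  estimate, keeping the planted inhibition levels recoverable without
  bias.  Resting background is 0.005 mV RMS; a configurable fraction of
  trials (default 5 %) is contaminated with background RMS drawn uniformly
  from [0.12, 0.3] mV, unambiguously above the 0.1 mV screening cut.
* **EEG breaks** — 30 s, 200 Hz traces of a 10 Hz oscillation whose
  amplitude starts suppressed by 60 % and relaxes exponentially with
  τ = 12 s after slowing versus τ = 3 s after control, plus broadband
  noise (SD 0.1 of the oscillation amplitude).

Noise magnitudes are package defaults chosen for realism, not claims about
any particular dataset.  All randomness flows through one seeded generator;
identical (config, seed) pairs give byte-identical datasets (tested by
hashing the output tree).

Default planted inhibition profiles (slowing condition): SICI 0.45 at
Pre/Post, released to 0.20 / 0.35 / 0.45 across the three break bins;
surround inhibition 0.40 at Pre/Post with bin-1 release to 0.60.  The
control condition plants only a minor, quickly recovering release.

## Analysis conventions

* **Cycles and speed** — a cycle runs from one first-effector tap to the
  next; trailing incomplete cycles are dropped; bins are half-open
  `[start, end)` with trial time zero at the first tap, and cycles
  straddling an edge belong to the bin containing their start.  `bin_speed`
  offers count-based values (completed cycles per bin, rescaled to a 10 s
  basis) and rate-based values (mean of 1/cycle-time).  The pipeline
  estimates speed with the rate-based method: counting gives the first bin
  a ~half-cycle head start (the first tap anchors the bin edge), which
  inflates slowing estimates by ~1.5 percentage points, while per-cycle
  rates are edge-unbiased.  1 s bins should always use rates (counts are
  too coarse).
* **Normalisation** — slowing-condition bins are divided by the
  subject-level mean control speed (a scalar), matching the flat
  control reference near 1 in the group figures; per-bin division is a
  configuration alternative.
* **Coactivation** — "joint area" is the area under the pointwise minimum
  of the two envelopes (the standard cocontraction overlap), normalised by
  the agonist area; filters are 4th-order zero-phase Butterworth (20 Hz
  high-pass, rectify, 10 Hz low-pass).  Whole-bin integration is used (no
  per-cycle time normalisation).
* **TMS screening** — stages in order: absolute background cut (0.1 mV);
  per-pulse-type mean ± 2.5 SD of background on stage-1 survivors; Tukey
  fences `Q1 − 1.5·IQR, Q3 + 1.5·IQR` on MEP amplitudes per
  (timepoint × pulse type) cell on stage-2 survivors.  Quartiles use
  linear interpolation (Tukey hinges available).  Cells below four trials
  are left unfenced.  Response window 15–60 ms post-pulse (configurable).
* **SICI and SI** — ratios of cell *means* (trials are unpaired in the
  protocol).  The printed overlapping break windows (3.5–22, 7.5–27.5,
  12.5–33.5 s) are supported — a pulse contributes to every window that
  contains it — alongside the non-overlapping narrative 0–10/10–20/20–30 s
  bins; the generator labels trials with their bin directly.  The
  surround-inhibition subject gate excludes subjects with Pre SI ≥ 1
  (no inhibition at baseline); the threshold 1.0 is the natural boundary
  but was not stated numerically in the source protocols.
* **Alpha envelope** — zero-phase band-pass (alpha preset 8–14 Hz;
  a narrow 8–12 Hz variant ships as well), rectification, and
  non-overlapping 1 s block means ("sliding average, no overlap" is
  contradictory; block means honour the "no overlap"; a true moving
  average is available).  Break epochs are means over seconds 0–10,
  10–20, 20–30.

## What passing tests show — and what they do not

The synthetic data reproduce the *statistical structure* the analyses
assume: renewal tap streams with a drifting rate, envelope-coded EMG
bursts, log-normal MEPs with planted screening violations, and
exponentially recovering band amplitudes.  They do not contain realistic
motor-unit waveforms, volume conduction, coil-position drift, or
behavioural lapses.  Green parameter-recovery tests therefore certify the
estimators and their conventions (binning, screening order, ratio
definitions), not robustness to every artefact of real recordings.

Problem sizes used by the test suite and the acceptance script — 17
subjects, 2 trials per condition, 24 break-cell / 18 Pre-Post TMS trials
per cell, 4 EEG breaks per condition — mirror the scale of a typical
single-site study of this phenomenon and keep a full run in the tens of
seconds.

## Known limitations

* The model is macroscopic: a single gain stands in for interneuron
  dynamics, and an upstream (afferent-drive) account of the same breakdown
  is observationally equivalent here; only the local-gain form is
  implemented.
* Group inference is deliberately out of scope: the pipeline exports tidy
  long-format tables (subject × condition × time) ready for external
  mixed-effects tooling and reports only means ± SEM.
* Single-session SICI estimates at the default noise (σ_log 0.3, 24
  trials/cell) have a standard deviation of ~0.07 in the most released
  bin; planted-profile recovery to ±0.05 is a *group-level* property and
  is validated as such.
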