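# Methods

## Problem setting

`phasecode` asks how much stimulus information a single sensory neuron's
spike train carries under three read-out schemes applied to the same
response window of length T:

* **time-partitioned** — counts in N equally spaced, stimulus-locked time
  bins (the experimenter's clock);
* **phase-partitioned** — counts in N equally spaced bins of the
  instantaneous phase of a slow local-field-potential (LFP) oscillation
  (a clock intrinsic to the network);
* **spike count** — the total count in T, either as a scalar or as a
  bin-shuffled vector that preserves the dimensionality of the
  partitioned codes.

A long continuous stimulus stream is repeated over trials; K = 10
non-overlapping epochs of length T sampled from the stream act as the
"stimuli" of a decoding problem, the repeats as trials.  Stimulus
information is measured as leave-one-out single-trial decoding performance
(percent correct), averaged over independently re-drawn epoch sets.
Because slow (theta, 2–6 Hz) oscillations entrain to dynamic stimuli, the
oscillation phase approximates a stimulus-locked time axis, and the
phase-partitioned code can recover much of the information available to
stimulus-locked binning — while being more robust when the decoder is
uncertain about the absolute window position.

## Synthetic data generator

No public recordings exist for this paradigm, so the package ships a
generator whose output has the statistical structure the analysis assumes.

**LFP.** One latent stimulus-locked phase trajectory φ\*(t) is drawn per
recording: base frequency `osc_freq_hz` (default 4 Hz) plus a slow random
drift (`freq_jitter_hz`, default 0.2 Hz, 500 ms correlation length).  Each
trial's oscillation is φ\*(t) + δ with a constant per-trial offset
δ ~ von Mises(0, `entrainment_kappa`): κ = 0 means no stimulus locking,
κ = ∞ perfect locking.  The LFP is `osc_amplitude`·cos(phase) plus
1/f-power-shaped Gaussian noise scaled by `noise_amplitude`.  Constant
within-trial offsets are the simplest model that yields a tunable
inter-trial phase coherence (ITC); mean ITC is monotone in κ.

**Spikes.** The rate on trial j is

    rate(t, j) = r0 · [1 + d·s(t) + b_j(t)] · [1 + c·cos(phase(t, j) − φ_pref)]

floored at zero, with baseline r0 = `baseline_rate_hz` (10 Hz), stimulus
modulation depth d = `rate_mod_depth`, and phase coupling c =
`phase_coupling`.  The stimulus profile s(t) is a moving average of white
noise (box width `profile_timescale_ms` = 50 ms), standardized to zero
mean and unit variance — smooth "naturalistic-like" slow structure without
committing to a stimulus model.  b_j(t) is an optional trial-unique
background profile of the same form whose r.m.s. relative to s(t) is set
by `noise_level_db`: x dB (target re background) maps to amplitude
10^(−x/20), so the −6 dB ("high noise") condition has a background r.m.s.
twice that of the target.  Spikes are drawn by thinning at 1 ms resolution
(at most one spike per millisecond, consistent with the 1 kHz LFP
resolution); at per-bin probabilities of order 0.01 the window counts are
Poisson to well within a chi-square test's resolution.

**Randomness.** One master seed spawns named, order-stable sub-streams
(`lfp`, `profile`, `spikes`, `noise`, `shuffles`, `epochs`, `jitter`,
`classifier`), so components can be varied in isolation: e.g. changing
only `noise_level_db` leaves the target profile, oscillation, and thinning
draws untouched, making noise-level comparisons paired.  Every experiment
is bit-reproducible from (config, seed).

## Signal processing

Bands are extracted with a zero-phase (forward-backward) 3rd-order
Butterworth band-pass by default; a Kaiser-window FIR (also
forward-backward) and a complex Morlet kernel (whose angle is the phase
directly) are available, and phase-code performance is insensitive to the
choice.  Zero-phase filtering is used so the extracted phase is not
lag-distorted relative to the spikes.  The phase is the angle of the
analytic signal mapped to [0, 2π), with cosine peaks at phase 0; every
phase-bin edge in the package derives from this single convention, and the
phase at a spike time is the phase at the nearest 1 ms sample.  Samples
within an edge margin (two time constants of the slowest band edge for
IIR, half the tap count for FIR, 3 temporal standard deviations for
Morlet) are treated as contaminated; epoch sampling avoids them.  ITC is
the resultant length of the trial-averaged unit phasor per sample, and
window coherence its arithmetic mean over a window.

## Decoding

All classifiers use leave-one-out cross-validation: each trial is decoded
against per-stimulus mean responses ("codebook") computed without it.
Six classifiers are provided: nearest-mean template matching (Euclidean;
Bayes-optimal under i.i.d. Gaussian ensembles), linear and quadratic
Gaussian discriminants (pooled / per-stimulus covariance, with i.i.d.
Gaussian jitter of sd 0.001 added to the counts and redrawn on every fold
to keep the covariances invertible), Poisson and multinomial naive Bayes,
and k-nearest neighbours (k = 5).  Numerical choices where the procedure
is otherwise under-determined:

* every tie (distance, likelihood, vote) breaks to the lowest stimulus
  index — deterministic and testable;
* Poisson means are floored at 1/(2·n_training_trials);
* multinomial tables use add-one smoothing over the observed count range;
* the bin-shuffled count code is decoded 20 times with fresh shuffles and
  averaged.

The vectorised implementations compute full-data statistics once and apply
a per-fold correction to the test trial's own stimulus only; they are
verified against exhaustive brute-force enumeration on small ensembles.

## Experiments

Epoch sets are drawn uniformly over non-overlapping placements using the
order-statistics construction (sorted uniform slack offsets plus stacked
windows).  Rejection sampling would have acceptance probability zero in
the exact-tiling case, which the construction handles naturally; sets are
independent across repetitions.

Temporal uncertainty J jitters only the codebook: each training trial's
window is shifted by an i.i.d. uniform lag in [−J/2, +J/2] while the test
trial is read out at its true position (an option to jitter the test side
exists but is off by default).  Epoch margins respect J/2 so shifted
windows stay inside the valid range.  Across J values the same seed reuses
identical epoch sets and scaled lag draws, so J-dependence is estimated on
paired samples.

The frequency sweep decodes the phase code with bands centred 4–32 Hz
(4 Hz width) and reports the chance-subtracted phase/count ratio; the
parameter sweep covers T = 80–480 ms at N = 8 and N = 2–16 at T = 160 ms.
The coherence analysis correlates per-epoch window coherence with
per-epoch decoding accuracy (confusion diagonal / trials) within each
epoch set, then averages the coefficient over sets; both Pearson and
Spearman are reported, and sets with zero coherence variance are flagged
as degenerate rather than counted as zero.

## Choice of default generator conditions

The generator knobs without a principled a-priori value (modulation depth,
phase coupling, LFP noise) were fixed once so that the qualitative
phenomena of interest emerge, and then frozen: κ = 8, c = 0.6, d = 0.8, oscillation amplitude 1,
broadband noise amplitude 1.5.  With the 50 ms stimulus-profile
correlation length, the synthetic time code carries no millisecond-scale
structure, so the margin between the time- and phase-partitioned codes is
governed almost entirely by how noisy the extracted phase is.  Two
documented populations, differing only in oscillation signal-to-noise, are
therefore used by the test suite:

* **code-ordering population** (noise amplitude 1.5, the package default):
  time ≥ phase > count for every classifier, with phase recovering most of
  the time code's excess over the count — the entrained-regime ordering;
* **temporal-uncertainty population** (noise amplitude 1.0): cleaner
  phase, used for the jitter study, where the phase code overtakes the
  time code from J = T/2 on while all codes degrade with J.

Real recordings exhibit both effects in a single dataset because cortical
spike patterns carry genuinely fine-grained stimulus-locked structure that
the smooth synthetic rate profile does not emulate; the split into two
regimes is a stated limitation of the generator, not of the analysis code.

## Problem sizes

The shipped tests use desk-scale designs chosen for stable Monte-Carlo
estimates: units of 6 s × 24 trials; 2–3 epoch sets per unit; 40 units for
the six-classifier ordering study; 24 units for the partitioned-code
jitter study and 60 units × 20 sets for the count code's much smaller
jitter effect (count vectors need no filtering and are one-dimensional, so
this larger design is cheap); 8 units for the frequency sweep and 12 for
the noise-level study.  Chance recovery uses the standard design of the
decoding analysis: 50 trials, 10 epochs of 160 ms, 100 epoch sets, 50
generator seeds.

## Known limitations

* The generator's "stimulus" is a latent smooth rate profile; no sensory
  transduction, receptive fields, or real sound/movie waveforms are
  modelled, and single units only (no populations, no inter-spike-interval
  codes).
* Per-trial phase offsets are constant within a trial; slow within-trial
  decoherence is only captured indirectly via the shared frequency drift.
* Information is quantified as decoding percent correct throughout; no
  bit-valued estimators are provided.
* The pseudo-inverse variant of the Gaussian classifiers is not
  implemented; the jitter regularization is the supported route.
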