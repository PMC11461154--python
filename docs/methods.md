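# Methods

## Pipeline

Per participant, on the continuous recording and in this order:

1. **Common-average reference** over all recorded channels (analysis
   channels plus any others in the cap).
2. **Broadband filter** 0.5–40 Hz, then **band split** into delta
   (0.5–4 Hz), theta (4–8 Hz) and alpha (8–13 Hz). Filters are
   least-squares FIR (`scipy.signal.firls`) applied forward and backward,
   so the net phase response is identically zero — any phase delay here
   would corrupt the synchrony statistic directly. Default length is the
   next odd integer ≥ 3·rate/low-edge (≈ 6 s of taps for a 0.5 Hz edge),
   capped at a third of the recording; the transition band defaults to half
   the low edge. The zero-phase pass is realised as one FFT convolution
   with the filter's autocorrelation after odd-reflection padding, which is
   numerically identical to `filtfilt` (unit tested at 1e-10) and much
   faster for long kernels. Bands are cut from the broadband-filtered
   signal; cutting them from the raw referenced signal is an equivalent
   alternative (the operations commute in the interior) and is not
   separately exposed.
3. **Epoching** by the event stream: half-open sample windows with
   floor-rounding at both edges, so abutting epochs tile the recording
   without sharing samples. Filtering precedes epoching so filter
   transients never sit inside an epoch.
4. **Instantaneous phase** per channel, per epoch: the angle of the
   analytic signal (`scipy.signal.hilbert`), computed once over the whole
   epoch and windowed afterwards — computing phase inside each 0.5-s
   window would put analytic-signal edge artifacts in every window.
5. **Phase-synchrony values.** Per window, the mean resultant length of
   the phase difference; all 66 pairs come from one Gram-matrix product of
   unit phasors per window. Trailing partial windows are dropped, never
   padded. Unweighted means aggregate windows → epoch, epochs → condition.
   Rest blocks use a 75-s analysis span starting 15 s after rest onset,
   5-s windows with 50 % overlap.
6. **Inference.** Per electrode pair, a split-plot RM-ANOVA: the
   between-participant stratum (Group) is a one-way ANOVA on orthonormally
   scaled participant means; each within effect (Posture, Stimulus, and
   interactions) is tested in an orthonormal Helmert contrast space
   against its participant-nested error stratum. Greenhouse–Geisser ε is
   estimated from the pooled covariance of the contrast scores and clips
   to [1/q, 1]; for the 2-level factors of this design sphericity holds by
   construction and ε ≡ 1, but the machinery is generic so k-level within
   factors are supported. Level contrasts are Bonferroni-protected
   (pooled-variance two-sample t between groups, paired t within);
   Group×Posture interactions are followed up by simple group effects per
   posture with a ×2 Bonferroni factor. GG p-values of one effect are
   BH-FDR adjusted across the 66-pair family. Standard BH guarantees
   adjusted ≥ raw p; published tables in this literature sometimes print
   "pFDR" columns smaller than the GG p-values they derive from, which no
   step-up adjustment can produce — this package reports the standard
   adjusted values. Missing design cells abort that pair's ANOVA with an
   error naming the cell; nothing is imputed.

Unbalanced group sizes are accepted (effects use weighted grand means);
within-participant cells must be complete.

### Numerical edge cases

Zero error variance with zero effect variance reports F = 0, p = 1 (all
values identical); zero error with positive effect reports F = ∞, p = 0.
Degenerate contrast covariance (trace of S² ≈ 0) reports ε = 1. PSV windows
are mapped to samples by flooring the start and rounding the length, so a
5-s window at 256 Hz is always 1280 samples.

## Bad-channel interpolation

Inverse-distance weighting with power 2 (Shepard's method) on the montage's
2-D coordinates, weights normalised over the good channels. IDW is
transparent and directly testable (a channel midway between two identical
neighbours reproduces them exactly; a linear scalp gradient is recovered
within a few percent); spherical-spline interpolation would need a head
model this package deliberately avoids.

## Synthetic cohort generator

Each analysis channel is a noisy phase oscillator pulled toward a latent
delta driver:

    dφ_c = 2π f_c dt + G κ_c sin(φ_d − φ_c) dt + σ dW

* driver frequency 2 Hz; per-epoch driver and per-channel frequency jitter
  SD `drift_hz` = 0.25 Hz (detunes uncoupled channels so long-window PSV
  decays toward chance);
* phase diffusion σ = 1.2 rad/√s;
* coupling gain G = 6 rad/s at κ = 1 (locks strongly: PSV ≥ 0.9 at low σ);
* emitted signal 10 µV·cos(φ_c) plus 1/f background noise at 0.6× the
  oscillator amplitude (`noise_gain`).

These four values were fixed together so that the whole-stimuli delta PSV
response spans ≈ 0.29 at κ = 0 to ≈ 0.59 at κ = 1 — a usable dynamic range
with the target cohort means on its steep part.

**Reference realism.** Only coupled channels would make the common-average
reference subtract the shared oscillation itself (synchrony would then
*fall* with coupling). The generator therefore adds `n_background` = 20
uncoupled 1/f channels emulating the rest of a 128-channel cap, so the
reference is dominated by unrelated activity, as in real recordings.

**Design.** 2 groups × 22 participants; four 120-s rest blocks
(sitting/standing × eyes open/closed, group-identical coupling); 16
demonstration epochs (8 demonstrations × symbolic/geometric) in two posture
blocks, durations uniform on 13–68 s, pseudo-random posture and style
order; 2-s inter-stimulus gaps. Sampling rate defaults to 256 Hz (the
pipeline is rate-agnostic; acquisition-grade 2048 Hz adds nothing to a
≤ 40 Hz analysis).

**Group/posture effects** are injected through electrode communities
(left fronto-parietal F3/CP3/P1/PPO1, right F4/CP4/P2/PPO2, midline
Fz/FCz/Cz/Pz): novices couple at κ = 0.28 everywhere; experts at κ = 0.39
over left + midline in both postures, extending to the right community
(κ = 0.45) when standing. The two κ anchors were calibrated once, by
bisection/interpolation on simulated cohorts, so the cohort-mean
whole-stimuli delta PSV of the midline Cz–Pz pair lands at ≈ 0.42
(experts) and ≈ 0.35 (novices); they are not re-tuned per run.

**Between-participant variability** comes from coupling jitter
(participant-level SD 0.03, channel-level SD 0.12, clipped to [0, 1]) and
mean-one lognormal noise-amplitude jitter (participant log-SD 0.15,
channel log-SD 0.50). The channel level dominates deliberately: pair-level
PSV variability in real EEG is driven largely by electrode-specific factors
(impedance, local noise), and it keeps different electrode pairs only
partially correlated within a participant, which is what makes the spatial
pattern of the inference stage testable. The resulting cohort SDs
(≈ 0.07–0.10) sit somewhat below the ≈ 0.12–0.13 a real cohort shows; the
within-participant covariance across pairs is a modelling choice, not a
measured quantity.

**Determinism.** Per-participant random streams derive from
`SeedSequence([cohort_seed, crc32(participant_id)])`, so any participant
can be regenerated independently of cohort order. The epoch layout is drawn
before any sample, so manifests are rate-independent.

### What the generator does not emulate

Eye/muscle/line-noise artifacts (artifact removal is out of scope), volume
conduction and field spread (nearby electrodes share no signal beyond the
injected coupling, so the simulated spatial maps are cleaner than scalp
EEG), theta/alpha oscillators (those bands contain only 1/f noise — their
null behaviour is exactly null), realistic electrode geometry beyond a 2-D
sketch, and within-participant covariance structure across pairs. Passing
tests therefore validate the *machinery* — filters, phase extraction,
windowing, averaging hierarchy, ANOVA strata, FDR — under a favourable,
known-truth signal model; they do not certify effect sizes on real scalp
data.

## Scales used by the test suite and acceptance script

Monte-Carlo checks run at reduced scale chosen so each quantity is
invariant to the reduction:

* **Type-I error** (group-exchangeable null cohorts): n = 10/group,
  256 Hz, epochs 8–9.5 s (one 5-s analysis window each), 2 epochs per
  condition cell, no rest blocks, no background channels. Exchangeability
  of the two groups — hence the null distribution of the Group test — is
  unaffected by any of these; 500 cohorts give an exact binomial check of
  the 5 % level.
* **Effect recovery**: n = 22/group at 100 Hz with 13–16-s epochs. The
  expected PSV is set by the phase dynamics, not by the sampling rate or
  epoch length (extra windows only reduce within-participant noise, which
  is small against the jitter), and the calibrated anchor means were
  re-verified at this scale (0.418 / 0.353, pooled over ≥ 60 participants
  per group).
* Theta/alpha specificity is checked on a cohort subset; the post-FDR
  familywise error bound (≤ α per band) gives the binomial criterion.

## Known limitations

* Several 1:1 phase-synchrony statistics circulate under the PSV name; this
  package defines PSV as the standard mean-resultant-length PLV of the
  Hilbert phase difference (n:m locking is out of scope).
* Overlapping windows are not coverage-weighted; all aggregation levels use
  unweighted means.
* PLV inflates under volume conduction; no leakage correction (imaginary
  PLV, phase-lag index) is applied — classic PLV is the statistic on
  purpose.
* EDF output quantises to 16 bits over the per-file physical range and
  zero-pads the final 1-s data record; the `.npz` container exists for
  lossless round trips.
* With unequal group sizes the ANOVA uses weighted (sequential) sums of
  squares, not Type III; the target design is balanced.
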