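# Methods

`cardioscreen` implements a desk-scale, fully synthetic analogue of an
AI-stethoscope screening study for clinically significant valvular heart
disease (VHD): a seeded phonocardiogram cohort generator, a deterministic
spectrogram front end, per-site recurrent classifiers fused by maximum
probability, covariate-adaptive minimisation allocation, and a
screening-test evaluation layer. This note records the models, the defaults
and why they were chosen, and what the synthetic experiments do and do not
show.

## The screening label

Every patient carries an echocardiographic grid: one severity grade
(none/trace < mild < moderate < severe) for each of the eight valve-lesion
slots (AS, AR, MS, MR, PS, PR, TS, TR). The binary screening outcome,
*clinically significant VHD*, is true iff any valve shows at least **mild
stenosis** or at least **moderate regurgitation**. Mild regurgitation alone
is common in elderly populations and deliberately does not qualify; this
asymmetry is what makes the classification task non-trivial, because mild
regurgitant murmurs are audible but must not trigger referral.

## Synthetic cohort generator

The generator replaces a clinical dataset that cannot be redistributed. Its
defaults emulate an echocardiography-referral case mix:

* **Epidemiology.** Significance prevalence 0.45; per-slot severity
  frequencies follow a degenerative-VHD distribution (e.g. severe AS 9.8%,
  moderate MR 12.0%, TS absent) expressed as counts out of 1767; atrial
  fibrillation 10.3% marginally, enriched in diseased patients (19% vs 3%);
  recruitment setting (acute hospital vs primary care) strongly associated
  with disease (87% vs 32% acute). Because the slot marginals alone imply a
  ~51% significance rate under independence, the generator first draws the
  significance label at the configured prevalence and then
  rejection-samples the grade grid from the slot marginals conditional on
  that label. Multi-valve co-occurrence is otherwise independent across
  slots.
* **Recordings.** One recording per present site, 8 s at 4 kHz (16-bit PCM
  when exported). Aortic, tricuspid and mitral sites are each present with
  probability 0.9967 so that all three are jointly present in ~99% of
  patients; the pulmonary site in 70%.
* **Acoustics.** S1/S2 are Gaussian-enveloped damped sinusoids (~45 Hz /
  ~60 Hz, S2 at 0.8 amplitude). Murmurs are white noise band-passed to a
  lesion-specific band and shaped by a lesion-specific temporal envelope:
  systolic crescendo–decrescendo at 150–400 Hz for outflow stenosis (AS,
  PS), holosystolic plateau at 100–400 Hz for AV regurgitation (MR, TR),
  early-diastolic decrescendo at 200–500 Hz for semilunar regurgitation
  (AR, PR), and a mid-diastolic 40–150 Hz rumble for AV stenosis (MS, TS).
  Murmur loudness is a grade-dependent SNR relative to the S1 RMS (mild −6
  dB, moderate 0 dB, severe +6 dB — separations that make the task
  learnable but not trivial) multiplied by a per-lesion per-site radiation
  gain (AS loudest at the aortic site radiating to the tricuspid site, MR
  loudest at the apex, and so on). A component is injected only if its
  effective level clears an audibility floor (−16 dB); the injected-murmur
  flag per site is stored as the pretraining label.
* **Timing.** Sinus rhythm jitters RR intervals with 2% CV; atrial
  fibrillation uses i.i.d. log-normal RR with CV 0.2; paced rhythm is
  near-metronomic; "other" reuses sinus timing. Systole occupies 35% of the
  running RR interval. A cycle is emitted only if at least half of it fits
  inside the recording.
* **Nuisance structure.** Ambient white noise at −20 dB relative to S1;
  Poisson friction spikes (0.1/s, amplitude 2–4, exactly what the spike
  remover must handle); one of two mild IIR stethoscope colourations
  (first-order low-pass vs a high-shelf emphasis) assigned per patient,
  which the per-bin z-normalisation is designed to cancel.

What the generator does **not** model: haemodynamics, ECG, respiration,
paediatric/congenital/rheumatic acoustics, pacing artefacts, inter-observer
grading noise, or realistic clinical recording artefacts beyond spikes and
stationary noise. Passing the end-to-end tests therefore demonstrates that
the pipeline machinery (preprocessing, training, fusion, evaluation) works
and that the classifier can exploit the kind of band-limited,
envelope-structured evidence real murmurs produce — it says nothing about
clinical accuracy on real patients.

## Preprocessing

1. **Spike removal** (Schmidt-style): the waveform is divided into 0.5 s
   windows; while the largest per-window maximum absolute amplitude exceeds
   3× the median of those maxima, the offending spike sample and its
   neighbourhood out to the nearest zero-crossings are zeroed. The output
   length is unchanged and the global peak never increases.
2. **Unit rescaling** to peak absolute amplitude 1 (identically-zero input
   passes through), making the chain invariant to global gain.
3. **Log-Mel spectrogram, z-scored per bin**: 25 ms Hann windows, 10 ms
   hop (frame count exactly `1 + floor((n − window)/hop)`), FFT zero-padded
   to 256 points so that narrow low-frequency Mel triangles are never
   empty, 64 HTK-scale triangular filters over 20–1000 Hz, log10 with a
   1e−10 floor. Each Mel bin is then standardised over time within the
   recording (epsilon 1e−8 in the denominator). Per-recording, per-bin
   z-scoring is the right reading of "normalise the device transfer
   function": a fixed stethoscope colouration is an additive per-bin offset
   in log power and is removed exactly; it also equalises energy across
   frequency so the quiet murmur bands are not swamped by the
   low-frequency heart sounds. Resampling to the 4 kHz target uses
   polyphase filtering; recordings under 0.5 s are rejected.

## Classifier

One recurrent model per auscultation site, because each site hears a
different lesion subset. The default is a 1-layer bidirectional GRU with
hidden size 32 per direction, a linear per-frame head, mean-logit temporal
pooling and a sigmoid output; max-logit and attention pooling are
implemented alternatives. The head is zero-initialised so an untrained
model outputs exactly 0.5. The stack is written directly in numpy (forward,
backpropagation through time, Adam) so that training is single-threaded and
bit-reproducible; analytic gradients are checked against central finite
differences in the test suite. The hidden size sits at the small end of the
{32, 64, 128} grid exposed to cross-validation: with full-length
spectrograms (~800 frames) and CPU-only linear algebra, the smallest
configuration that cleanly solves the synthetic task is the right default,
and `cross_validate` (patient-level, stratified, 5 folds by default) exists
precisely to revisit that choice per dataset.

Training: fixed-length 5 s crops with random offsets (full-length
inference), batches grouped by frame count, class-balanced binary
cross-entropy (prevalence is configurable, so balancing is not optional),
Adam at 3e−3, at most 10 epochs per phase with early stopping (patience 5)
on a stratified 15% patient-level validation split. The best-epoch weights
are shipped only if they beat the *initial* weights beyond validation
noise: the paired per-recording loss gain must clear a small absolute
floor (0.005 nats) and a one-sided test at z > 1.645; otherwise the
initial weights are returned. A desk-scale validation split of 50–100
patients estimates the cross-entropy with a standard error of several
hundredths of a nat, so a marginal dip spread thinly over the split is
indistinguishable from noise and must not win selection. This matters for
negative controls: a finite label permutation retains O(1/√n) chance
overlap with the true labels, and because ranking metrics are
scale-invariant, a noise-fitted tilt would otherwise masquerade as strong
(anti-)discrimination; with the significance gate the learner correctly
returns the constant predictor under uninformative labels, while genuine
training gains (an order of magnitude larger) always pass. Transfer recipe:
**pretrain** on the generator's per-site murmur flags, then **fine-tune**
on the patient-level significance label attached to each recording
(provenance is tracked per site model). Per-site probabilities over
multiple recordings combine by maximum (configurable to mean), and the
patient-level probability is the maximum over the sites used — disease
anywhere should trigger referral, and the max makes fused probability
provably monotone under site-set inclusion.

## Allocation

Prospective train/test assignment uses Pocock–Simon-style marginal
minimisation over three factors: recruitment setting, dominant (most
severe) lesion slot, and its grade. For arms with target weights
w_train : w_test (default 79:21, matching a 973:263 style split; 4:1 in the
acceptance experiments), arm *g*'s *ratio-adjusted* count at a factor level
is `count_g / w_g`, and the score of assigning the incoming patient to *g*
is the sum over factors of the range of adjusted counts with one adjusted
unit added to *g*. With probability 0.8 the lower-scoring arm is taken;
ties — including the empty state — and the remaining probability mass fall
to a ratio-weighted draw. This convention was chosen because it makes the
very first assignment an exact tie (so the marginal allocation probability
equals the target ratio), drives the realised train fraction tightly to the
target, and balances every factor margin between arms; all three properties
are exercised in the tests. Pre-recruited patients can be preassigned; they
seed the counts before sequential allocation starts.

## Evaluation

AUROC uses the Mann–Whitney convention (ties half-credit); "refer" means
score ≥ threshold. `threshold_for_specificity` returns the smallest
observed cut-point whose specificity meets the target (thereby maximising
sensitivity subject to the constraint), warning and refusing everyone when
the target is unattainable. Expected calibration error uses 10 equal-width
bins by default. Confidence intervals are percentile bootstrap over
patients (the natural resampling unit here since every patient contributes
one fused probability); resamples on which a statistic is undefined are
skipped and counted. McNemar is the exact two-sided binomial test on
discordant pairs — discordant counts at desk scale are small, where the
chi-square approximation is poor; paired sensitivity comparisons restrict
to disease-positive patients and specificity comparisons to
disease-negative ones. Cohen's and Fleiss' kappa follow the standard
chance-corrected definitions and raise on degenerate marginals. Per-lesion
sensitivity tables report each (lesion, grade) cell among patients whose
grade individually qualifies as significant, optionally restricted to
isolated disease; site-combination tables re-derive a threshold per
combination at a fixed 82% specificity. Majority voting over raters refers
on ties.

## Problem sizes and numerical choices

The end-to-end experiments run on 600-patient cohorts with a 4:1 split and
at most 10 epochs per training phase — sizes at which the synthetic task is
comfortably solved (held-out AUROC ≥ 0.9) while the whole suite remains a
desk-scale computation. Degenerate cases are handled explicitly: zero-width
waveforms and empty cohorts raise; constant spectrogram bins z-score to ~0
via the epsilon guard; single-class label sets raise `UndefinedMetricError`
rather than returning a number; allocation ties break by ratio-weighted
draw; equal-seed runs of any stage are bit-identical (pure numpy, single
thread, one named seed stream per stage).

## Known limitations

* The acoustic model is a convention, not physiology; absolute
  probabilities and operating thresholds learned on synthetic data do not
  transfer to real recordings.
* Murmur grading is binary presence at pretraining time; no S1/S2/state
  segmentation is modelled.
* The per-bin z-normalisation discards absolute loudness, so severity
  information survives only through spectral spread and envelope shape —
  intentional, as the device-normalisation trade-off is part of the design
  being studied.
* Only two allocation arms are supported.
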