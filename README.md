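# cardioscreen

Screening for clinically significant valvular heart disease (VHD) from
multi-site electronic-stethoscope recordings — as a fully self-contained,
desk-scale research pipeline. The package is aimed at people studying
AI-stethoscope screening methodology (signal preprocessing, transfer
learning, covariate-adaptive allocation, screening-test statistics) who do
not have access to clinical heart-sound data: a seeded synthetic
phonocardiogram generator stands in for the patient cohort, and every later
stage is the real method.

## What it implements

**Label.** A patient has *clinically significant VHD* iff echocardiography
shows ≥ mild stenosis or ≥ moderate regurgitation in any valve (AS, AR, MS,
MR, PS, PR, TS, TR graded none/trace < mild < moderate < severe). Mild
regurgitation alone does not qualify.

**Model.** For each auscultation site s ∈ {A, P, T, M}, a recurrent network
f_s maps the z-normalised log-Mel spectrogram X of a recording to a
probability; the patient-level score is fused by maximum,

    p(patient) = max over used sites s of  max over recordings r at s  f_s(X_r),

because disease at any single valve should trigger referral. Each f_s is a
bidirectional GRU over spectrogram frames with a linear frame head, pooled
(mean-logit by default) into one sigmoid output — implemented directly in
numpy with backpropagation through time, so training is single-threaded and
bit-reproducible. Training is transfer-style: pretrain on murmur-presence
labels, then fine-tune on the patient-level VHD label.

**Around the model.**

* `cardioscreen.simulate` — seeded cohort generator (45% prevalence, 10%
  atrial fibrillation, per-lesion severity frequencies of a degenerative
  case mix, lesion-specific murmur bands/envelopes with grade-dependent SNR
  and site radiation, noise, friction spikes, two stethoscope colourations,
  occasional missing sites).
* `cardioscreen.preprocess` — Schmidt-style spike removal, unit rescaling,
  64-bin log-Mel spectrogram z-scored per bin over time.
* `cardioscreen.detector` — `VHDDetector(cohort).fit()` →
  `VHDDetectorResults` (statsmodels-style model/results pair) plus
  functional APIs `pretrain_murmur`, `finetune_vhd`, `predict_patient`,
  patient-level stratified `cross_validate`.
* `cardioscreen.allocation` — Pocock–Simon-style minimisation assignment to
  train/test with a target ratio, balancing recruitment setting and
  dominant lesion type/grade.
* `cardioscreen.evaluation` — AUROC (Mann–Whitney), operating points at a
  fixed specificity, reliability bins and expected calibration error,
  patient-level percentile bootstrap CIs, exact McNemar, Cohen's and
  Fleiss' kappa, majority voting, Youden index, per-lesion and
  per-site-combination sensitivity tables.
* `cardioscreen.pipeline` / `cardioscreen.cli` — one-config, one-seed
  orchestration: `cardioscreen run-all --out dir/ --seed 1` (also
  `simulate`, `allocate`, `train`, `predict`, `evaluate`).

See `docs/methods.md` for the modelling choices and their rationale.

## Worked example

```python
from cardioscreen import SimConfig, simulate_cohort, VHDDetector, ModelConfig
from cardioscreen.allocation import AllocationConfig, allocate_cohort
from cardioscreen.detector import precompute_features
from cardioscreen.preprocess import PreprocConfig

cohort = simulate_cohort(SimConfig(n_patients=200, seed=8))
split = allocate_cohort(cohort, {}, AllocationConfig(target_ratio=(4, 1), seed=8))
train = [p for p in cohort if split[p.id] == "train"]
test = [p for p in cohort if split[p.id] == "test"]

feats = precompute_features(cohort, PreprocConfig())
res = VHDDetector(train, ModelConfig(seed=8), features=feats).fit(pretrain=True)
print(res.evaluate(test, spec_target=0.82, n_boot=500, seed=8, features=feats).summary())
```

prints (exact numbers for these seeds):

```
Screening evaluation
================================================
n patients               40
AUROC                    0.957 (0.872-1.000)
operating threshold      0.533
sensitivity              94.1% (78.8%-100.0%)
specificity              82.6% (65.1%-95.7%)
Youden index             0.767
expected calibration err 0.214 (0.149-0.294)
```

Reading it: on the 40 held-out patients the fused probability ranks a
random diseased patient above a random healthy one 95.7% of the time; the
threshold was set as the smallest cut-point reaching 82% specificity on
this cohort, where 16/17 diseased patients are referred. The calibration
error is large here simply because 40 patients spread over 10 reliability
bins — it tightens on bigger test sets. All intervals are percentile
bootstrap over patients.

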