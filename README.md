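# asbestoscreen

AI-assisted screening for asbestosis state-aid eligibility, rebuilt as a
tested, desk-scale Python package.

In several countries, workers who developed asbestosis from occupational
asbestos exposure can apply for government compensation. Each application
is reviewed by a panel of three pulmonologists; the majority vote decides.
The process is costly, slow, and subject to inter-rater variability.
`asbestoscreen` implements a complete screening pipeline around that
decision for method development and evaluation:

* **Phantom cohorts** — synthetic chest volumes (two ellipsoidal lungs,
  fibrosis-like peripheral/basal lesions, pleural plaques) with simulated
  panel votes, lung-function values and the cohort-level statistics of a
  real applicant population (≈46 % positive verdicts, ≈76 % unanimity,
  weak DLCO–imaging coupling), so everything is testable without patient
  data.
* **Curation** — HU clipping to [−1024, 3072] and scaling to [0, 1], lung
  segmentation, 13 × 13 × 5 pleura-inclusive mask dilation, masking,
  cropping and resampling.
* **Anomaly detection** — a variational autoencoder trained on healthy
  lung slices; its reconstruction error yields a voxel-wise anomaly
  heatmap.
* **Classification** — a 3-D residual network on CT (+ heatmap), trained
  with *hard* labels (the binary verdict) or *soft* labels (the fraction of
  positive votes), emitting an eligibility probability.
* **Lung function** — AMA impairment classes from FVC/DLCO bands (worst
  parameter rule; class ≥ 2 qualifies), the simple fusion
  `((1 − DLCO) + AI)/2`, the DLCO-as-input "advanced" fusion, and a triage
  rule sending probabilities in [0.35, 0.60] back to the full panel.
* **Statistics** — majority verdicts, unanimity decomposition,
  Krippendorff's alpha, ROC-AUC with bootstrap CIs, McNemar's paired test,
  agreement-stratified prediction distributions, and input-gradient
  saliency maps.

The neural networks are compact NumPy implementations with explicit,
finite-difference-verified backpropagation (`asbestoscreen.nn`); see
`docs/methods.md` for the models, the phantom design and its limits.

## Worked example

```python
import asbestoscreen as asc

# panel agreement from a vote table (cases counted by positive votes 0..3)
table = asc.VoteTable((219, 55, 67, 166))
print(asc.agreement_summary(table))
# {'n': 507, 'pct_positive': 46.0, 'pct_unanimous': 75.9,
#  'pct_unanimous_positive': 71.2, 'pct_unanimous_negative': 79.9}
print(round(asc.krippendorff_alpha(table), 3))   # 0.676

# lung-function rules
print(asc.ama_class(fvc_pct=65, dlco_pct=80))    # 2  (FVC band 60-69 dominates)
print(asc.lf_eligible(2))                        # True
fused = asc.simple_combine(ai=0.8, dlco_pct=60)
print(round(fused.combined, 2), fused.triage)    # 0.6 review
```

Reading: 46 % of the 507 applications got a positive verdict, three in four
panels were unanimous, and chance-corrected agreement is moderate
(α ≈ 0.68). The example case has AMA class 2 (eligible on lung function);
its fused imaging+DLCO score of 0.60 sits on the edge of the uncertainty
band, so it is routed to full panel review.

The full synthetic study — generate a cohort, preprocess, train the VAE
and both classifiers, fuse and evaluate — is one call:

```python
res = asc.run_desk_experiment(n=200, seed=7)
print(res["auc_imaging"]["auc"], res["auc_combined"]["auc"])
```

or from the shell, stage by stage or end to end:

```bash
asbestoscreen simulate --n 60 --seed 0 --out cohort/
asbestoscreen run --out run_output --seed 0 --n 60
asbestoscreen panel-stats --votes cohort/cohort.csv
```

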