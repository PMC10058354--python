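# armuse

Detection and quantification of **functional arm use** from a single
wrist-worn inertial sensor, aimed at people who use an upper-limb
prosthesis.  Clinicians and rehabilitation researchers need an objective,
low-cost way to measure how much a prosthetic (or impaired) limb is actually
*used* — reaching, grasping, gesturing — outside the clinic, as opposed to
moving passively with gait or resting.  `armuse` implements a complete
pipeline that turns raw 6-channel wrist IMU recordings (3-axis linear
acceleration + 3-axis angular velocity at 200 Hz) and per-frame video
annotations into block-level functional / non-functional classifications
and per-subject functional-use percentages.

## Method

1. **Annotation fusion.** Up to three annotators code each video frame with
   one of five behavioural categories (no activity `0`, nonfunctional
   movement `1`, nontask-related functional `2`, task-related `3`, Unknown
   `−1`).  Codes are fused by two-of-three majority (no majority → Unknown),
   mapped onto sensor samples, and collapsed to binary labels:
   `{2,3} → functional`, `{0,1} → nonfunctional`, `−1 → excluded`.

2. **Segmentation.** Either *fixed* — consecutive 800-sample (4 s) blocks,
   with blocks containing both classes ("mixed") discarded — or *variable* —
   a change-point scheme in which the trailing 2000 samples of a growing
   segment are compared with the next 2000 samples by the two-sample
   Hotelling statistic

   T² = (mn/(m+n)) · (x̄₁ − x̄₂)ᵀ S_p⁻¹ (x̄₁ − x̄₂),

   advancing in 600-sample steps until T² exceeds a threshold calibrated to
   an 80% true-positive rate on recordings with known transitions.  Variable
   blocks keep all data and are labelled by simple majority (> 50%).

3. **Features.** Each block yields 21 features: per-channel histogram
   Shannon entropy (16 bins), mean and variance, plus the zero-lag Pearson
   correlation of the three axis-matched accelerometer/gyroscope pairs.

4. **Classification.** A random forest (100 trees, unlimited depth, 4
   features per split, seed 123) classifies blocks, evaluated by
   intra-subject 10-fold cross-validation and inter-subject leave-one-out,
   with chunk-size-weighted accuracy so both segmentations are comparable.

5. **Evaluation.** Per-subject accuracy, functional-use percentage of time
   (FU%) and |predicted − true| FU error, summarised as medians and ranges;
   Mann-Whitney U between groups and Wilcoxon signed-rank between methods.

A seeded synthetic generator (`armuse.synthetic`) produces regime-switching
rest / gait / functional recordings with known per-sample ground truth,
per-subject idiosyncrasies and noisy simulated annotators, so the whole
pipeline is testable without human-subject data.

## Worked example

```python
from armuse.synthetic import GeneratorConfig, generate_cohort
from armuse.pipeline import evaluate_cohort

cohort = generate_cohort(GeneratorConfig(duration_s=300.0), 3, 1)
datasets = {s.series.subject_id: s.dataset for s in cohort}
ev = evaluate_cohort(datasets, "fixed")
for row in ev.report["per_subject"]:
    print(f"{row['subject_id']}: intra acc {row['acc_intra']:.3f}, "
          f"inter acc {row['acc_inter']:.3f}, "
          f"FU truth {row['fu_truth']:.1f}%, "
          f"FU predicted (intra) {row['fu_pred_intra']:.1f}%")
```

prints

```
S01: intra acc 1.000, inter acc 1.000, FU truth 47.5%, FU predicted (intra) 47.5%
S02: intra acc 1.000, inter acc 1.000, FU truth 39.0%, FU predicted (intra) 39.0%
S03: intra acc 1.000, inter acc 1.000, FU truth 36.8%, FU predicted (intra) 36.8%
```

Three 5-minute synthetic subjects are generated, cut into pure 800-sample
blocks, and classified.  The synthetic regimes are well separated, so both
protocols classify every block correctly and the predicted functional-use
percentage matches the annotation-derived truth exactly; on real recordings
the mixed-block exclusion and annotator noise make these numbers degrade,
which is what the evaluation module is there to quantify.

The same pipeline is available from the shell:

```bash
armuse simulate --subjects 4 --duration 600 --seed 1 --out data/
armuse crossval --data-dir data/ --protocol both --method fixed --out results.json
armuse report --results results.json --out report.md
```

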