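# mfiq — quartile-resolved muscle fat infiltration in the deep cervical extensors

`mfiq` is an analysis pipeline for studying *where* fat accumulates inside the
deep cervical extensor muscles (multifidus + semispinalis cervicis) after
whiplash injury, and whether that spatial pattern separates patients by
recovery status. It is aimed at musculoskeletal imaging researchers working
with fat/water-separated (2-point Dixon) MRI of the cervical spine.

The pipeline:

1. **MFI mapping** — voxelwise muscle fat infiltration from paired fat/water
   images, `MFI = 100 · I_F / (I_F + I_W)`; zero-signal voxels are treated as
   missing, never as 0 %.
2. **Quartile geometry** — each bilateral muscle ROI cross-section is split
   into four contiguous medial→lateral, equal-area quartiles (Q1 nearest the
   spinous process, Q4 most lateral) along the column distance from a
   per-slice spinous-process landmark.
3. **Aggregation** — MFI per participant × vertebral level (C4–C7) ×
   quartile, pooling both sides over the three central slices of each level.
4. **Cohort flow** — Neck Disability Index (NDI) recovery groups
   (severe ≥ 30 %, mild 10–29 %, recovered < 10 %) and participant-flow
   accounting from enrolment to the analysed sample.
5. **Inference** — one repeated-measures linear mixed model per cervical
   level: fixed effects group × quartile + age + sex + BMI, per-participant
   random intercept and medial-lateral slope, REML; pairwise intra-quartile
   group contrasts as estimated-marginal-mean differences (α = 0.05).
6. **Synthetic cohort generator** — fat/water volumes, masks and metadata
   with known ground truth, calibrated to the study conditions (n = 10/26/25
   severe/mild/recovered), so the whole chain is testable without any data
   download.

See `docs/methods.md` for the model, calibration and numerical choices.

## Worked example

Run the full pipeline on a default synthetic cohort (61 participants,
10/26/25 across severe/mild/recovered, C4–C7, 3 slices per level):

```bash
mfiq run-all --out demo --seed 1
```

or in Python:

```python
from mfiq.config import PipelineConfig
from mfiq.pipeline import run_pipeline

out = run_pipeline(PipelineConfig(out_dir="demo", seed=1))
print(out.analysis_table.head(4))
```

The analysis table has one row per participant × level × quartile
(61 × 4 × 4 = 976 rows):

```
participant_id level  quartile       mfi  n_voxels       age    sex       bmi  ndi_percent  group
          S000    C4         1 24.545787       828 27.909739 female 30.675005    33.573598 severe
          S000    C4         2 15.459441       822 27.909739 female 30.675005    33.573598 severe
          S000    C4         3 10.317316       822 27.909739 female 30.675005    33.573598 severe
          S000    C4         4 11.201758       822 27.909739 female 30.675005    33.573598 severe
```

`demo/report.txt` summarises the per-level contrasts; for this seed the C4
model prints:

```
Level C4 (n_obs=244, participants=61, converged=True)
  Q1 severe-recovered     +7.27 (SE 1.28) p = 0.0000 *
  Q1 mild-recovered       +5.17 (SE 1.01) p = 0.0000 *
  Q1 severe-mild          +2.10 (SE 1.21) p = 0.0875
  Q2 severe-recovered     +3.75 (SE 1.36) p = 0.0080 *
  Q2 mild-recovered       +2.27 (SE 1.07) p = 0.0380 *
  ...
  Q4 severe-recovered     +0.68 (SE 1.66) p = 0.6844
```

Reading: the most medial quartile (Q1) carries the highest MFI in every
group, and the symptomatic groups exceed the recovered group by ~5–7 MFI
percentage points there, while the lateral quartiles (Q3/Q4) show no group
differences — the medial concentration of fat, with symptomatic elevation
confined to the medial quartiles, that the pipeline is designed to detect.

Other useful commands:

```bash
mfiq simulate --out ds --seed 2            # synthetic cohort with ground truth
mfiq aggregate --dataset ds --out analysis.csv
mfiq fit --table analysis.csv --out contrasts.csv
mfiq flow-report --enrolled 97 --attrition 19 --poor-quality 1 --not-amenable 16
```

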