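# fluorotrack

Dynamic target tracking for videofluoroscopic swallowing studies (VFSS)
and similar low-contrast grayscale fluoroscopy video.

In a VFSS, a patient swallows a barium-sulfate bolus under X-ray video.
Clinicians need two very different things tracked at once: the **bolus**
— dark, flowing, with no stable shape or intensity — and the
**tissues/organs** around it (chin, palate, spine anchor), which are
rigid but get occluded by the bolus, the helper's hand, or the patient
leaning out of frame. `fluorotrack` implements a matched pair of
trackers plus the plumbing around them:

* **Discrete-point bolus tracking** — random points `P_r = random(γ_p, S_p)`
  sampled inside the current bolus region (default ratio γ_p = 0.1);
  each frame the search box is advanced by the last displacement,
  expanded ×1.2, partitioned by level-controlled watershed, and each
  region scored by

  `Eva = θ0 + θ1·(points in region / all points) + θ2·(points in region / region area) + θ3·|gray(region) − g_avg|`

  with recursive re-segmentation at lower levels and gray-band
  thresholding at the floor. Points are resampled from every new mask —
  the bolus has no appearance to remember.
* **Improved inter-frame difference** — `seg_c = (d_frame ∪ seg_p) \ d_seg`:
  the thresholded frame difference is united with the previous region of
  interest and the *residual* (vacated pixels now showing bright
  background) is subtracted, so no background model is stored at all.
  ViBe and a balloon-estimator EGMM are included as baselines.
* **Combined correlation-filter tracking** for rigid targets — a
  kernelized position filter (ridge regression over all cyclic shifts,
  Gaussian kernel, gray+HOG channels; response
  `res = Re(F⁻¹(α̂ ⊙ F(k)))`), a DSST-style 1-D scale filter over a
  33-level pyramid (step 1.02), the exponential template update
  `α̂ ← (1−θ)·α̂ + θ·α`, watershed edge correction of the reported box,
  and a confidence guard that freezes learning during occlusion. MOSSE
  is included as the classical baseline.
* **Detection-free multi-target tracking** — targets are registered
  manually (no birth model), tracked online and independently, with
  inter-target distances/overlaps compiled afterwards in a
  spine-anchored rotated coordinate frame.
* **Metrics** — APE (mean center distance, px), AOR (mean IoU), success
  rate at IoU ≥ 0.5 — and comparison harnesses for both method families.
* **Synthetic data** — a seeded generator of fluoroscopy-like sequences
  (deformable advecting bolus, textured rigid patches, occluder bars,
  Gaussian + Poisson-like noise) with exact ground truth, since
  clinical VFSS recordings are not publicly distributable.

## Worked example

```sh
python examples/04_track_organ_occlusion.py
```

```
occlusion guard fired on frames [16, 17, 18, 19, 20, 21]
center error before occlusion: 0.71 px
center error last 10 frames:   0.71 px
```

A bright bar fully covers the tracked organ for six frames. The
response peak collapses, so the tracker freezes its templates and lets
the box coast on the last confident displacement; when the bar passes,
the peak recovers and tracking resumes — the post-occlusion error
equals the pre-occlusion error and the target is never lost.

```sh
python examples/03_detector_comparison.py
```

```
method       APE px     AOR  detected
improved       0.03   0.996      100%
vibe           8.57   0.704       88%
egmm          17.42   0.539      100%
```

On a lateral swallow (bolus held, then transported), the improved
frame difference stays on the bolus almost perfectly, while the
sample-based background models pay for the ghost left at the held
position — the same qualitative gap the method was designed to close.

The other examples cover simulation (`01`), bolus tracking (`02`),
multi-target relations (`05`) and the correlation-filter ablation
(`06`). Every pipeline is also exposed on the command line:

```sh
fluorotrack simulate --preset side_view --seed 7 --out data/
fluorotrack track-bolus data/frames --init 14,16,22,20 --out run/
fluorotrack evaluate --pred run/bolus.csv --truth data/truth_bolus.csv
```

## Layout

```
src/fluorotrack/     core, config, io, preprocess, bolus, framediff,
                     background, correlation, multitarget, metrics,
                     synthetic, cli
examples/            one narrative script per capability
tests/               pytest suite (unit, property and acceptance tests)
docs/methods.md      models, parameters, design choices, limitations
```
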