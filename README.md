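# strobolabel

Automatic keypoint annotation for pose-estimation training data from
stroboscopic dual-illumination video.

## The problem

Markerless pose trackers such as DeepLabCut need hundreds of hand-labeled
frames before they can be trained. For rodent gait studies this labeling is
slow (about a minute per frame for eight paw keypoints) and is the main
human bottleneck in the workflow. `strobolabel` removes it by exploiting a
hardware trick: the animal's paws are marked with UV-fluorescent ink that is
invisible under white light, and the camera's exposures alternate between UV
and white LED flashes at the full frame rate (720 Hz in the reference
setup). Every video therefore interleaves two modalities:

- **UV frames** — dark background, four colored fluorescent paw markers
  glowing (one color per paw);
- **white frames** — normal appearance, markers invisible; these are the
  frames a network should be trained on.

Because adjacent frames are only 1/720 s ≈ 1.4 ms apart, paw displacement
between a UV frame and the following white frame is negligible. Marker
positions detected on a UV frame can be transferred *unchanged* to the next
white frame, yielding labeled training images with no human annotation.

## The method

For each UV frame *I* and marker color *c* with HSB bounds
(*l*, *u*) — hue in degrees on the circle, saturation and brightness in
[0, 1] — the binary detection mask is

&nbsp;&nbsp;*M<sub>c</sub>*(x, y) = 1 iff HSB(*I*(x, y)) ∈ [*l*, *u*]
(hue wrap-aware) and (x, y) lies in the view mask,

where two static binary view masks separate the direct wheel-surface
(bottom) view from the 45° mirror (side) view, so four ink colors encode
4 paws × 2 views = 8 keypoints. The keypoint is the unweighted centroid of
the largest 8-connected component of *M<sub>c</sub>* with area ≥ `min_area`;
a runner-up component holding ≥ ½ of the winner's area flags the detection
as ambiguous. Centroids are copied to the adjacent white frame (identity
transfer), a diverse subset of frames can be chosen by k-means on
downscaled images, split into train/test sets, and everything is written in
the DeepLabCut `CollectedData_<scorer>.csv` layout.

The evaluation half computes per-image mean Euclidean distances
√(Δx² + Δy²) between predicted and ground-truth keypoints, group summaries
(mean, sample SD, SEM = sd/√n), and the independent two-sample t test —
both the classical pooled-variance form and the
t = (m₁ − m₂)/√(SEM₁² + SEM₂²) form used when only group means and SEMs
are reported.

A fully seeded synthetic-video generator reproduces the recording
structure (alternating modalities, four marker colors, two views,
sub-pixel inter-frame motion, ground-truth manifest) so the entire
pipeline is testable without any recorded data.

## Worked example

Generate a 3-pair synthetic recording and annotate it:

```sh
strobolabel simulate --out vid --n-pairs 3 --seed 2
strobolabel annotate vid/frames --config vid/config.yaml --out ds --seed 2
```

The annotate step prints its stage report:

```json
{
  "n_frames": 6,
  "n_pairs": 3,
  "n_skipped_frames": 0,
  "n_found": 24,
  "n_missing": 0,
  "n_ambiguous": 0,
  "n_records": 3,
  "n_excluded_sparse": 0,
  "n_exported": 3
}
```

All 6 frames were classified and paired (3 UV→white pairs), all
3 × 8 = 24 markers were found, and 3 labeled white frames were exported to
`ds/labeled-data/frames/` with their `CollectedData_strobolabel.csv`.
Comparing a prediction CSV against ground truth
(`strobolabel evaluate --pred-a … --pred-b … --truth … --out rep`) writes a
stats block with each model's mean/SD/SEM pixel error and the pooled
two-sample t test; identical inputs give `t = 0.0, p = 1.0`.

HSB bounds can be fitted from a handful of marked pixels instead of being
hand-tuned: `strobolabel calibrate vid/frames --seeds seeds.txt --out
bounds.yaml`, where each seed line is `frame_idx x y color_name`.

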