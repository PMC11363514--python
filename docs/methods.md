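# Methods

## Demultiplexing

Illumination modality is inferred per frame from image content rather than
assumed from index parity: a recording may begin on either phase of the
strobe, and content-based classification degrades gracefully when frames
are dropped. The score is the *dark fraction* — the fraction of pixels
whose value channel (max of R, G, B) falls below `dark_value_cutoff`
(default 60/255). A frame is UV when the dark fraction exceeds
`dark_fraction_threshold` (default 0.5). UV frames are dark everywhere
except the fluorescent blobs (well under 2% of the image area), so their
dark fraction is close to 1, while white-light frames sit close to 0; the
0.5 threshold is far from both distributions. A `parity` override
(`uv-even` / `uv-odd`) exists for pathological footage. The score is kept
on the frame for diagnostics, and re-classification is idempotent.

Pairing emits one unit per (UV at *i*, white at *i + 1*) adjacency; a UV
frame labels only the *following* white frame, since its marker positions
are a 1.4 ms-old snapshot of the paw that the next exposure shows. Frames
in no such adjacency are skipped and counted, and a skip rate above 5%
raises a strobe-desynchronization warning rather than an error — isolated
dropped frames should not abort an otherwise usable recording. The scan is
streaming (one lookahead frame in memory).

## Color model and detection

All color arithmetic uses a single canonical HSB convention — hue in
degrees [0, 360), saturation and brightness in [0, 1] — regardless of the
underlying library's internal scale, so configuration files stay portable.
Hue is angular: a bound pair with lower hue > upper hue denotes the
interval through 0° (needed for red inks), and every membership test is
wrap-aware.

Detection is per color × view: HSB thresholding, conjunction with the
view's binary mask, then 8-connected component analysis. Components with
area below `min_area` (default 9 px) are discarded; this rejects
single-pixel chroma noise while keeping the smaller mirror-view markers.
The keypoint is the *unweighted* centroid (arithmetic mean of member-pixel
coordinates) of the largest surviving component, matching the
center-of-mass labeling convention used for the paw region. Ties on area
are broken toward the smaller (y, x) centroid so results are deterministic.
A runner-up component with ≥ 0.5 × the winner's area marks the detection
AMBIGUOUS; the winner's centroid is still reported, and the pipeline
exports it but flags it in the run report, because a competing blob
usually means color bleed rather than a wrong paw. An optional 3×3
morphological opening before component analysis is off by default — the
detection model is pure color filtering, and any extra cleanup should be
an explicit choice.

## Calibration

Interactive bound tuning is replaced by estimation from seed pixels
(`frame_idx x y color_name` lines, ≥ 3 seeds per color). For each color
the HSB values of a 3×3 neighborhood around every seed are pooled;
saturation and brightness bounds are the componentwise [min, max] widened
by `margin` × range (default margin 0.25 — seeds undersample the marker's
chromatic spread, so some slack is needed, but not so much as to collide
with a neighboring ink's hue). Hue bounds are the *minimal covering arc*:
the circle is cut at the largest angular gap between sorted seed hues and
the complementary arc is taken, which resolves wrap-around unambiguously;
the arc is then widened by `margin` × width on each side. A seed set whose
hue arc exceeds 180° is rejected as not color-coherent. Estimation is
invariant to seed order and monotone in the margin.

## Label transfer and export

Transfer is strict coordinate identity: no motion compensation, because at
1/720 s separation the expected displacement (bounded at 0.5 px/frame in
the synthetic model) is below the detector's own localization noise.
Records with fewer than `min_keypoints` (default 4) present keypoints are
excluded from export — partially labeled frames are valid training input,
but mostly-empty frames add noise for no information.

Frame selection for training diversity follows the k-means recipe: frames
are converted to grayscale, downscaled to 30×30, flattened, clustered into
k groups (seeded), and at most one record is drawn per cluster — the
at-most-one-per-cluster rule is what enforces pose diversity. Train/test
splitting is a seeded uniform disjoint split.

Export writes white frames as `labeled-data/<video>/img{index:04d}.png`
plus `CollectedData_<scorer>.csv` with the three header rows (scorer;
bodyparts, each name twice; coords alternating x/y), one row per image
keyed by its relative path. Body parts are named `{paw}_{view}` with views
`bottom` and `side`. Coordinates are 0-based pixel indices (x rightward,
y downward) written with full float `repr`, so a read-back reproduces
every value bit-exactly; ABSENT keypoints are empty cell pairs. The CSV is
canonical; the companion HDF serialization some consumers derive from it
is out of scope.

## Evaluation statistics

Per-image error is the mean over keypoints present in *both* prediction
and truth of the Euclidean distance; absent keypoints are excluded
pairwise, never imputed, and images sharing no keypoint are dropped and
counted. Group summaries use the sample SD (n − 1) and SEM = sd/√n.

Two t-statistic routes are deliberately provided. `from_sem` computes
t = (m₁ − m₂)/√(SEM₁² + SEM₂²) with df = n₁ + n₂ − 2 (Welch–Satterthwaite
df optional) — the arithmetic needed to reproduce a comparison stated as
group means and SEMs. `pooled` is the classical pooled-variance test from
the raw distance lists. The two agree only when the reported SEMs are
consistent with the group sizes and variances; published summaries are not
always internally consistent (a reported SD of 0.68 px with SEM 0.23
implies n ≈ 9, not 25), so the package computes the reproduction
(`from_sem`) and the statistically standard answer (`pooled`) side by side
rather than silently choosing one. Degenerate inputs are defined: zero
variance with equal means gives t = 0, p = 1; zero variance with unequal
means is an error rather than an infinite statistic.

## Synthetic data

The generator renders what the detection model needs to be true of the
real recordings and nothing more: alternating modalities starting on UV
(even indices); a dark UV background (brightness 0.05) carrying
anti-aliased elliptical markers in four colors approximating the inks used
(blue 230°, green 120°, red 0°, turquoise 175°; saturation 0.85,
brightness 0.95); a bright white-light frame (brightness 0.85) with a gray
mouse-like silhouette and *no* marker coloring, since fluorescence is
invisible under white light; additive Gaussian pixel noise (SD 2/255 per
channel, a realistic sensor-noise floor at short exposures); and two
disjoint horizontal view bands. Marker radii are 6 px in the bottom view
and 4 px (flattened 0.8:1) in the mirror view, which appears smaller;
the values are arbitrary but fixed. Paw centers follow per-paw sinusoids
with phases (0, π, π/2, 3π/2) to mimic alternating footfalls and produce
pose variety for the selection step — a rendering convenience, not a
biomechanical claim. The gait amplitude (12 px stride, 3 px vertical at
4 Hz) is validated at construction against the 0.5 px/frame displacement
bound. Per-frame RNG streams are keyed by (seed, frame index), so
generation is bit-reproducible and frames can be rendered in any order.

What the generator does **not** emulate: fur/skin reflectance, UV
bleed-through, motion blur, compression artifacts, marker smearing, or
photometric drift. Passing recovery tests therefore demonstrates the
correctness of the demultiplexing, filtering, localization, transfer and
export logic — not that any particular HSB bounds will work on a given
real recording, which is what the calibration step is for.

An occlusion schedule can suppress chosen markers on chosen frames
(updating the manifest's visibility flags) to exercise MISSING handling
end to end.

## Problem sizes and tolerances

The acceptance run uses a 100-pair recording at the full 720×364 geometry
with default noise — large enough that detection-rate and error statistics
are stable across seeds, while a full run stays under a minute on one
core. Unit tests use a 240×160 geometry with 2–8 pairs. Recovery
thresholds: detection rate ≥ 95% and mean keypoint error ≤ 1.0 px against
the UV-frame truth (measured values are typically 100% and < 0.1 px;
rasterization alone accounts for ≤ 0.5 px). Centroid and t-test
implementations are held to 1e-9 against independent brute-force oracles.

## Known limitations

- Marker identity is resolved purely by color and view; two same-color
  blobs in one view (reflections, ink transfer onto the wheel) yield an
  AMBIGUOUS flag, not a tracking decision.
- Decoding AVI/MP4 containers requires an imageio plugin with a codec
  backend; a directory of numbered PNG frames is always supported and is
  the lossless interchange format the generator emits.
- The paper-level comparison of networks trained on automatic vs. manual
  annotations requires recorded videos and trained models; the package
  reproduces the published statistic from its reported summaries and
  validates its own pipeline on synthetic ground truth instead.
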