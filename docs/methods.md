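# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind `seedage`. Nothing here is an empirical claim beyond
what the test suite and `scripts/acceptance.py` compute.

## The classification problem

Six rice varieties (Akitakomachi, Fusaotome, Hatsuboshi, Koshihikari,
Okiniiri, Yang Dao-8) photographed as isolated single seeds, each harvested
in 2012, 2016 or 2020, with two cells never collected (Okiniiri-2020 and
Yang Dao-8-2016) — 16 (variety, year) classes, 5982 images in the emulated
full-size dataset. Identification is two-stage: a 6-way variety decision,
then a 2- or 3-way age decision by the predicted variety's own model, seven
classifiers in total. Stage-2 routing uses the *predicted* variety, so
variety errors propagate; age models are nevertheless *trained* on
true-variety subsets, which keeps their training labels clean.

## Segmentation

Backgrounds are removed by color-distance thresholding: the background
color is the per-channel median of the one-pixel border frame, pixels with
Euclidean RGB distance above a threshold (default 40) are foreground
candidates, the largest connected component is kept, and a disk-radius-2
morphological closing fills pinholes. This is deterministic and exact for
high-contrast single-seed scenes; it will fail on cluttered or low-contrast
backgrounds, which are out of scope. Crops keep a 2 px margin (clipped at
image borders) so the seed/background boundary survives for the edge
histogram.

## Feature descriptors (159 dimensions)

The six blocks and their design points:

- **color_structure (32)** — HSV quantized to 8 hue × 2 saturation × 2
  value bins; an 8×8 window slides with stride 1 and contributes one
  presence count to every bin among its foreground pixels; counts are
  L1-normalized so the block sums to 1. Crops smaller than the window are
  edge-replicated.
- **edge_histogram (80)** — 4×4 sub-image grid; non-overlapping 2×2 pixel
  blocks classified by the strongest of five filter responses (vertical,
  horizontal, two diagonals, non-directional) above threshold 11 on the
  0–255 scale; histograms normalized by the total counted blocks. Computed
  on the full crop: the seed boundary is the dominant shape edge, and
  discarding it would blind the descriptor to exactly the cue that
  separates elongated from round varieties.
- **region_shape (35)** — angular radial transform magnitudes |F(n,m)|,
  n ∈ {0,1,2}, m ∈ {0,…,11}, over the mask mapped to the unit disk
  (centroid at origin, farthest pixel at radius 1), DC-normalized with the
  DC entry dropped. Translation-, rotation- and scale-invariant up to
  lattice discretization, which decays roughly like 1/r (≈2% effects for
  seed-sized masks; the suite checks symmetry claims on large shapes).
- **glcm (6)** — foreground luminance min–max quantized to 8 levels;
  symmetric co-occurrence at offset (0,+1); contrast, dissimilarity,
  homogeneity, energy, correlation, angular second moment. Energy is
  reported as ΣP² (no square root), so it equals the ASM entry; both are
  kept so the block stays 6-wide with the conventional field names.
- **rgb_mean (3)** and **column_layout (3)** — foreground channel means and
  the mean foreground luminance of the left/middle/right column thirds
  (widths w//3, w//3, remainder; an empty third contributes 0). The column
  layout is a deliberate minimal interpretation of a spatial-layout
  feature; it fills the 3 remaining dimensions of the 159 total.

All other blocks restrict to foreground pixels — after segmentation the
background carries no seed information.

## Base classifiers

Three gradient-boosting implementations behind one adapter surface, fixed
hyperparameters, no tuning sweep:

| slot | backend | key settings |
| --- | --- | --- |
| 1 | XGBoost | colsample_bytree 0.5, lr 0.3, max_depth 6, alpha 10, 750 trees, subsample 0.7 |
| 2 | sklearn HistGradientBoosting | 90 iterations, lr 0.04, max_depth 4, 64 leaves |
| 3 | LightGBM | 31 leaves, lr 0.1, gbdt |

Each adapter emits hard class indices (`predict_scalar`). A single-class
training set degenerates to a constant predictor with a warning. LightGBM's
objective is left to its wrapper (binary for 2-class age tasks, multiclass
softmax otherwise).

## The ANFIS unit and hybrid learning

The fusion element is a two-input one-output first-order Sugeno system:
3 Gaussian membership functions per input (grid-partition initialization
over the observed input range, σ = spacing/2), the full 3×3 rule grid, and
linear consequents f_k = p_k·x1 + q_k·x2 + r_k. The forward pass is the
standard five layers; normalized firing strengths sum to 1, with a uniform
1/9 fallback when the total firing underflows (inputs far outside the
training range).

Hybrid training alternates, per iteration (default 100):

1. **LSE pass** — the 27 consequent coefficients solve a linear
   least-squares problem with premises fixed (ridge λ=1e−6 fallback when
   rank-deficient). Post-pass training RMSE is therefore never worse than
   the entering model's; the suite asserts this.
2. **GD pass** — one full-batch gradient step (default rate 0.01) on every
   center and width, differentiated through the firing normalization;
   widths are clamped at 1e−8. The analytic gradient is verified against
   central finite differences to 1e−5 relative.

RMSE is recorded after each LSE pass; training stops early at the target
error and returns the best-RMSE parameters seen (a guard against a final
GD overshoot). A huge target error therefore stops after one pass; an
unreachable target (0 on noisy data) runs the full iteration budget.

## Cascades and the fusion structure

The generic cascade screens every unordered pair of current inputs with a
1-iteration ANFIS fit, matches each input with its lowest-RMSE partner
(duplicates merged — an input may appear in several pairs), trains the
chosen units fully, and feeds their outputs to the next level until the
target error, the level cap, or a single unit is reached. The last level is
reduced to its best unit, the model output. Level-wise best RMSE is
non-increasing, because any next-level unit can reproduce the previous best
output through the identity consequents (p=1, q=0, r=0).

The booster fusion fixes the structure instead of screening: exactly two
levels, level 1 = units for (booster1, booster2) and (booster2, booster3),
level 2 = one unit over the two level-1 outputs. Level-2 input ranges are
re-estimated from the level-1 outputs, which are not bounded a priori.

**Class encoding.** Classes are encoded as integer scalars 0…K−1 and
decoded by nearest code (ties to the lower index). Because squared-error
training makes the continuous output approximate a conditional *mean* of
codes, classes the base learners confuse must sit on adjacent integers or
the rounded mean lands on an unrelated middle class. The class→code
bijection is therefore chosen by spectral seriation: the Fiedler vector of
the symmetrized pooled confusion graph of the meta-training predictions
orders the classes, deterministically and from training data only. This is
a structural requirement of scalar fusion, not a tuning knob: with an
arbitrary class order, two confusable classes at distant codes make every
disagreement round to an unrelated class between them.

**Meta-training inputs.** The fusion trains on the final boosters' own
training-set outputs (resubstitution). Out-of-fold stacking — the textbook
hygiene — is available via `stacking_mode="oof"` but is *not* the default:
with hard-label inputs the fold models are systematically weaker than the
final boosters, so the OOF (b1,b2,b3) label cells misrepresent the cells
seen at test time, and the meta-learner calibrates to the wrong confusion
structure. Resubstitution hard labels, by contrast, carry little
overfitting signal for the meta-learner to exploit — they are close to the
truth for all three boosters — while matching the test-time input
distribution. The suite's fusion-vs-booster checks run under this default.

## Evaluation

Averaged accuracy is the per-class mean of (tp+tn)/(tp+fp+fn+tn); for two
classes it reduces to plain accuracy. Precision/recall/F-β are reported
under micro, macro and weighted averaging side by side, because for
single-label tasks micro precision = micro recall = accuracy — a published
table with unequal micro P and R cannot be purely micro-averaged, so all
three variants are always emitted. β defaults to 1.

## The synthetic generator

Emulates the photographed dataset's *structure*, not its appearance. Each
image is one rotated ellipse on a uniform dark-green 128×128 canvas (the
post-crop resolution of the source data is undocumented; 128 px is a
guess). Shape separates varieties; surface darkening and speckle separate
ages:

- per-variety mean length (px) / aspect ratio, defaults:
  Akitakomachi 52/1.90, Fusaotome 56/2.05, Hatsuboshi 50/2.20,
  Koshihikari 60/1.75, Okiniiri 55/2.35, YangDao8 72/3.10 (Yang Dao-8 is
  the clearly elongated outlier, matching its real morphology); 5%
  relative jitter on both.
- per-age darkening factor (foreground luminance × (1−factor)):
  2012 → 0.30, 2016 → 0.15, 2020 → 0.00; multiplicative speckle sd:
  0.14 / 0.08 / 0.03. Older seeds are darker and rougher, the cues aging
  actually produces in pericarps. A per-age hue shift exists but defaults
  to 0° so the darkening factor is exactly the luminance ratio between
  ages.
- per-class counts equal the emulated dataset (5982 total); a scale factor
  rounds counts half away from zero.

The "easy" preset (`SyntheticSpec.easy()`) widens the shape gaps and age
effects and shrinks jitter; it is the wide-class-separation condition under
which end-to-end joint accuracy is required to exceed 0.95.

What the generator does **not** emulate: within-seed shading gradients,
specular highlights, husk texture anisotropy, shadows, JPEG artifacts
(a quality-90 re-compression option exists), multi-seed scenes, or any
correlation between shape and age. Passing tests therefore demonstrate the
pipeline's mechanics and the fusion's behavior under realistic confusion
structure — not field performance on photographs.

## Problem sizes

Desk-scale runs (test suite and acceptance script) use 10% of the emulated
per-class counts: ≈600 images, ≈415 training rows for the variety task and
40–130 per age task, split 7:3 stratified by (variety, year). The full
5982-image generation is exercised once for the class-structure check.

## Numerical choices

- Degenerate input range at unit init: widened by 1e−6 with a warning.
- Zero total firing: uniform normalized firings (1/9).
- Rank-deficient consequent systems: ridge λ=1e−6.
- σ floor 1e−8 after each GD step.
- Pair-screening ties: lexicographically smallest pair.
- Decode ties: lower code index.
- Feature CSVs serialize floats with %.17g and parse with the round-trip
  parser, so tables survive a save/load cycle bit-exactly.
- Min–max feature normalization is fit on the training split only
  (config-switchable off); zero-range features map to 0.

## Known limitations

- Scalar-coded fusion is intrinsically ordinal: even with seriation, a
  K-way task whose confusion structure is not chain-like cannot be
  represented faithfully on one axis, and the meta-learner can trail the
  best single booster by a small margin (it is bounded within 0.03 on the
  desk-scale variety task rather than required to win).
- Three membership functions per input cannot localize six classes; the
  fusion's resolution is coarsest exactly on the variety task.
- The age models reach perfect desk-scale accuracy because synthetic age
  cues are cleaner than real pericarp aging; real-data age accuracy would
  be substantially lower.
- Booster backends are pickled, not JSON-serialized; a saved model
  directory is not portable across library versions.
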