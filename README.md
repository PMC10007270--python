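# seedage

Classification of rice seeds by **variety** and **harvest age** from RGB
photographs of single seeds.

Seed age strongly affects germination rate, and in regions where aged seed
stock is routinely cultivated there is real value in verifying the
word-of-mouth age of a seed lot from images alone. `seedage` implements a
full pipeline for this task: classical image descriptors feed three
gradient-boosted base classifiers whose outputs are fused by a small
neuro-fuzzy meta-learner, and prediction is two-stage — variety first, then
the predicted variety's own age model.

## Method

**Features (159 dimensions).** Each seed is segmented from its background
(color-distance thresholding against the border-estimated background color,
largest component, morphological closing), cropped, and described by six
blocks: a windowed HSV color-structure histogram (32), a five-orientation
local edge histogram over a 4×4 sub-image grid (80), angular radial
transform shape magnitudes |F(n,m)|, n∈{0,1,2}, m∈{0,…,11}, DC-normalized
(35), gray-level co-occurrence statistics (6), foreground RGB means (3) and
a left/middle/right luminance profile (3).

**Base classifiers.** XGBoost, scikit-learn's
`HistGradientBoostingClassifier` and LightGBM, with fixed hyperparameters,
each emitting a hard class label.

**Fusion (cascaded ANFIS).** The three label streams enter a two-level
cascade of two-input first-order Sugeno fuzzy units (3 Gaussian membership
functions per input, 9 rules, consequents f_k = p_k·x1 + q_k·x2 + r_k).
Level 1 holds units for the pre-assigned pairs (booster1, booster2) and
(booster2, booster3); level 2 combines the two level-1 outputs. Each unit
is trained by the classic hybrid rule — exact least squares for the
consequents in the forward pass, gradient descent on the membership
centers/widths in the backward pass. Class labels are encoded as integer
scalars (ordered so that frequently-confused classes sit on adjacent codes)
and the continuous output is decoded to the nearest code.

**Two-stage prediction.** One 6-way variety model plus six per-variety age
models — seven classifiers in all. At predict time the age model is chosen
by the *predicted* variety, so variety errors propagate exactly as they
would in deployment.

**Evaluation.** Confusion matrices with per-class averaged accuracy and
precision / recall / F-β under micro, macro and weighted averaging (for
single-label tasks micro precision = micro recall = accuracy).

Because the original photographed dataset is an external download, the
package ships a synthetic generator that emulates its structure: six
varieties that differ in seed shape (Yang Dao-8 markedly more elongated),
2–3 harvest years per variety that differ in pericarp darkening and speckle
texture, and the same per-class sample counts (16 (variety, year) classes).

## Worked example

```python
import tempfile
from seedage import (SyntheticSpec, generate_dataset, split_dataset,
                     train_two_stage, evaluate_two_stage)
from seedage.descriptors import extract_features_table

with tempfile.TemporaryDirectory() as workdir:
    spec = SyntheticSpec(rng_seed=0)
    manifest = generate_dataset(spec, workdir, scale=0.1)
    features = extract_features_table(manifest, workdir)
    features = split_dataset(features, ratio=0.7, rng_seed=0)
    model = train_two_stage(features, seed=0)
    report = evaluate_two_stage(model, features, split="test")
```

Printing the report fields gives:

```
classifiers trained : 7
test samples        : 188
variety accuracy    : 0.6915
age accuracy        : 1.0000
joint accuracy      : 0.6915
micro precision     : 0.6915
```

i.e. at one tenth of the emulated dataset size, the fused model identifies
the variety of 69% of held-out seeds, and whenever the variety is right the
routed age model recovers the harvest year; micro precision equals accuracy,
as it must for a single-label task.

The same pipeline is scriptable from the shell:

```sh
seedage synth data/ --scale 0.1 --seed 0
seedage extract data/ features.csv
seedage split features.csv --ratio 0.7 --seed 0
seedage train features.csv model/ --seed 0
seedage evaluate model/ features.csv --out metrics.json
seedage predict model/ data/images/Koshihikari_2016_0000.png
```

## Layout

| module | contents |
| --- | --- |
| `seedage.imagedata` | image I/O, segmentation, cropping, synthetic generator, manifests |
| `seedage.descriptors` | the six feature descriptors and batch extraction |
| `seedage.anfis` | two-input Sugeno unit with hybrid LSE/gradient learning |
| `seedage.cascade` | pair screening, level-wise cascades, booster fusion |
| `seedage.pipeline` | splitting, booster adapters, the two-stage scheme |
| `seedage.evaluation` | confusion-matrix metrics |
| `seedage.cli` | `seedage` command-line interface |

See `docs/methods.md` for modelling assumptions, parameter choices and
known limitations.
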