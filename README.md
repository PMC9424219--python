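# icgperf

Machine-learning assessment of intestinal blood perfusion in
indocyanine-green (ICG) fluorescence laparoscopy.

During laparoscopic colorectal surgery, ICG injected into the patient
makes well-perfused bowel fluoresce green under near-infrared light.
Whether the segment at an anastomosis site is *adequately* perfused is
traditionally judged by eye — a subjective, experience-dependent call
with real consequences (inadequate perfusion raises the risk of
anastomotic dehiscence). `icgperf` implements a decision-support
pipeline that makes this call objectively, frame by frame:

1. **Tracking** — a MOSSE adaptive correlation filter follows the
   operator-selected rectangular ROI through the video, pausing
   automatically when the target disappears (peak-to-sidelobe ratio
   below threshold) and resuming when it reappears.
2. **Feature extraction** — the tracked ROI is divided into 20 equal
   vertical slices; for slice *i* the green-channel histogram is
   computed and summarised by its thresholded area

   $$A_i = \sum_{l=k}^{255} \mathrm{count}_i(l)\,[b(l{+}1) - b(l)],
   \qquad 1 \le i \le 20,$$

   where $\mathrm{count}_i(l)$ is the number of slice pixels with green
   intensity $l$, $b$ are the histogram bin edges (unit bins by
   default, making $A_i$ an exact pixel count) and $k = 25$ excludes
   pixels with low green. The 20 areas capture both the *amount* and
   the *uniformity* of fluorescence across the ROI.
3. **Classification** — a small feed-forward neural network (one
   20-unit ReLU hidden layer, sigmoid output, trained with Adam on
   binary cross-entropy, 100 epochs, batches of 5) maps the feature
   vector to *adequate* (1) or *inadequate* (0) perfusion. The
   architecture is chosen by 10-fold cross-validated grid search over
   one- and two-hidden-layer networks and SVM baselines, the choice is
   statistically validated (one-way ANOVA + paired t-tests at
   α = 1 %), and the winner is retrained on all data for deployment.

The surgical videos the method was clinically evaluated on are not
publicly deposited, so the package ships a seeded synthetic generator
(`icgperf.synthetic`) that emulates the three scene classes — uniformly
bright (adequate), uniformly dim, and spatially non-uniform ICG
diffusion (both inadequate) — plus moving-target sequences with ground
truth for tracker evaluation. All experiments in the test suite run on
this generator.

## Worked example

```python
import numpy as np
from icgperf import (SceneParams, generate_roi_patch, generate_dataset,
                     GreenHistogramFeatures, ModelConfig, cross_validate)

# one ROI with non-uniform ICG diffusion: bright left half, dim right half
patch = generate_roi_patch(SceneParams(perfused_fraction=0.5, seed=0))
feats = GreenHistogramFeatures(k=25).fit([patch.patch]).transform([patch.patch])[0]
print("label:", patch.label)
print("features:", np.array2string(feats, precision=0))

# the evaluation protocol on a balanced 470-frame synthetic dataset
samples = generate_dataset(n=470, class_balance=0.5, seed=1)
X = GreenHistogramFeatures(k=25).fit(0).transform([s.patch for s in samples])
y = np.array([s.label for s in samples])
cfg = ModelConfig(family="FFNN_1L", neurons_l1=20, activation="relu",
                  epochs=100, batch_size=5, seed=0)
res = cross_validate(X, y, cfg, K=10, seed=0)
print(f"10-fold CV accuracy: {res.mean_accuracy:.1f} +/- {res.sigma:.1f} %")
```

prints

```
label: 0
features: [144. 144. 144. 144. 192. 144. 144. 144. 144. 192.  48.  49.  48.  58.
  66.  46.  49.  52.  50.  56.]
10-fold CV accuracy: 99.8 +/- 0.7 %
```

The first ten slices of the half-perfused ROI contain essentially every
pixel (full 48-row slices of width 3 or 4 → areas 144/192), the dim
right half only the noise tail above k=25 — exactly the non-uniformity
signature the classifier keys on, hence label 0. On the balanced
synthetic dataset the selected one-hidden-layer network separates the
classes almost perfectly.

The same workflow is available from the shell:

```sh
icgperf simulate --n 470 --seed 1 --out data/train
icgperf extract  --dataset data/train --out data/features.csv
icgperf train    --features data/features.csv --seed 1 --out model.npz
icgperf simulate --sequence --frames 60 --velocity 2,0 --seed 2 --out data/seq
icgperf run      --input data/seq --roi 64,96,64,48 --model model.npz \
                 --out predictions.csv --annotate annotated/
```

`evaluate` runs the full hyperparameter grid plus the
activation-function statistics and writes ranked CSV reports.

Note on baselines: the SVM baselines perform very well on the clean
synthetic features here; the markedly weaker SVM accuracy reported in
the original clinical evaluation may reflect unscaled count features on
much noisier surgical imagery (an optional `standardize` flag exists,
off by default to mirror that protocol).

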