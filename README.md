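# spikecount

Wheat grain number per spike is a core yield component, and counting grains by
hand is slow and error-prone. `spikecount` implements an image-based
segmentation-and-counting pipeline for single wheat-ear photographs taken at
the grain-filling stage:

1. **Segmentation** — a high-resolution multi-branch network (HRNetV2-style,
   w18/w32 variants) classifies every pixel as *grain* or *background*.
   Optionally, Convolutional Block Attention (CBAM) gates — sequential
   channel-wise then spatial multiplicative attention — are inserted in the
   representation head's upsampling path.
2. **Counting** — grains touch and apparently merge ("adhesion") in the
   predicted mask, so connected components undercount.  The counting model
   separates adherent grains by thresholding the normalized Euclidean distance
   transform: grayscale → binarize (threshold 120) → erode → distance
   transform → normalize to [0,1] → re-binarize at a fraction α of the peak →
   opening → external-contour count.
3. **Spike totals** — grains sit in pairs along the rachis, so the whole-spike
   count is either **Method I**: 2 × one-side count, or **Method II**: side A
   + side B.

Because real ear photographs are not redistributable, the package ships a
synthetic ear generator (two staggered columns of grain-shaped ellipses along
a vertical rachis, field-like or white-paper backgrounds, controlled adhesion)
whose masks carry exact per-side count ground truth. It is first-class,
tested code and the substrate for all quantitative tests.

The neural-network stack (reverse-mode autodiff, convolution/batch-norm/
attention layers, Adam/SGD) is implemented in `spikecount.nn` on numpy, so the
package has no deep-learning framework dependency.

## Core quantities

Segmentation is scored from the pixel confusion matrix per class
(grain/background):

    Precision = TP/(TP+FP)    Recall = TP/(TP+FN)    IoU = TP/(TP+FP+FN)

with mPA the mean per-class pixel accuracy and mIoU the mean per-class IoU.
Counting is scored against manual truth x_i with predictions y_i:

    p_i = |x_i−y_i|/x_i·100    MAE, RMSE    MRE = mean(p_i)
    R² = 1 − Σ(x_i−y_i)² / Σ(x_i−x̄)²

Training follows a two-phase transfer schedule: epochs [0, 50) freeze the
backbone and train only the head (batch 16), epochs [50, 300) fine-tune
everything (batch 8); Adam (lr 5e-4, no weight decay) or SGD (lr 4e-3,
weight decay 1e-4).

## Worked example

Generate 10 synthetic two-sided spikes with moderate adhesion (0.2 of the
minor axis) and score both counting rules on the ground-truth masks:

```bash
spikecount synth --n-spikes 10 --out demo --seed 7 --adhesion 0.2
spikecount evaluate --counts-pred demo/masks --counts-truth demo/truth.csv --out demo/eval
```

The run prints (abridged):

```json
{
  "method_I":  {"MAE": 3.3, "MRE_percent": 8.64, "RMSE": 3.96, "R2": 0.22},
  "method_II": {"MAE": 0.0, "MRE_percent": 0.0,  "RMSE": 0.0,  "R2": 1.0}
}
```

and `demo/eval/per_sample_counts.csv` holds the per-spike detail:

```
id,side_a,side_b,true_total,method_I_total,method_II_total
0000,23,17,40,46,40
0001,21,16,37,42,37
```

Reading: at adhesion 0.2 the distance-transform separation recovers every
side count exactly, so Method II is error-free (MAE 0, R² 1). Method I errs
here only because the generator draws the two sides of a spike independently
(side A 23 vs side B 17), so doubling one side misestimates the total — on
real ears the two sides are strongly correlated and Method I is a cheap
one-photo approximation.

Other commands: `prepare` (polygon-annotation JSON → masks, 480×480
normalization, rotation/flip/blur augmentation, 9:1 or k-fold splits),
`train`, `predict`, `count` (single images, with `--stages` audit PNGs of
every pipeline stage).

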