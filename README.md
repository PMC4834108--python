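# rifm — regional image features for glaucoma screening

`rifm` is a Python implementation of a regional-image-features pipeline for
automatic classification of optic-disc-centred retinal images (colour
fundus or two-channel red/green SLO frames) into *normal* and *glaucoma*.
It is aimed at researchers in retinal image analysis who want a complete,
testable reference pipeline: every stage is exposed as a library function,
and the whole chain is wrapped in a statsmodels-style model object.

Glaucoma erodes the neuroretinal rim: the cup enlarges relative to the disc
(rising cup-to-disc ratio, CDR) and peripapillary atrophy (PPA) often
appears beside the disc. The pipeline captures both the geometric and the
appearance/texture signatures of these changes:

1. **Localise** the disc centre from two weighted feature maps —
   `F1 = minmax(½·(|∂Y/∂x|+|∂Y/∂y|) + ½·FRST_r(Y))` enhancing the disc and
   `F2` = mean oriented matched-filter response enhancing the vasculature —
   by an exhaustive band/window search (horizontally in F2, vertically in F1).
2. **Segment** the disc boundary with an active-shape-style model: profiles
   of a 48-map Gaussian filter bank (N, N_x, N_y, N_xx, N_xy, N_yy at
   σ = 2, 4, 8, 16 on vessel-inpainted red and green channels) are sampled
   along each contour normal and matched to trained per-point statistics by
   Mahalanobis distance, with Procrustes/PCA shape regularisation; the disc
   centre is re-estimated as the vertex mean x_c = Σ X_x(i)/N,
   y_c = Σ X_y(i)/N.
3. **Divide** the 2×-disc-diameter crop into optic disc (OD) and inferior /
   superior / nasal / temporal quadrants; eye side follows the intradisc
   vessel asymmetry.
4. **Extract** six regional feature families — Gaussian-bank means, GLCM
   texture over offsets 1–10 and over scales σ = 2–16, centre-surround
   dyadic Gaussian channels, a 560-filter Gabor grid, and one-level DWT
   subband statistics — 9175 columns with full per-column provenance.
5. **Select** features by a Welch-t significance filter (p ≤ 0.05) followed
   by greedy wrapper forward selection maximising cross-validated AUC (or
   LDA/QDA accuracy).
6. **Classify** with a linear Twin SVM — two non-parallel hyperplanes from
   two small QPs, nearest-plane prediction — with kernel SVMs, LDA and QDA
   as alternatives and ERUS under-sampling for class imbalance. Performance
   is reported as Acc/Sn/Sp from pooled confusion counts, Dice for
   segmentation, and McNemar's χ² for method comparison.

A fully controlled synthetic-eye generator (bright elliptical disc and cup
with controllable CDR, nasally-biased vessel arcades, optional PPA
crescent, illumination gradient, noise) makes every stage testable without
clinical data.

## Worked example

```python
from rifm.model import GlaucomaScreeningModel, PipelineConfig
from rifm.synthetic import generate_eye, sample_specs

specs = sample_specs(25, 25, seed=11)          # 25 normal + 25 glaucoma
eyes = []
for spec, label in specs:
    img, gt = generate_eye(spec)
    gt.label = label
    eyes.append((img, gt))
train = eyes[:15] + eyes[25:40]                # 15 + 15
test = eyes[15:25] + eyes[40:50]               # 10 + 10

model = GlaucomaScreeningModel.from_synthetic(
    train, test, PipelineConfig.synthetic(seed=11))
print(model.fit().summary())
```

prints:

```
Regional image features screening model
==============================================
training eyes: 30   test eyes: 20
features extracted: 9175
features selected (auc): 5
final wrapper criterion: 1.000
localisation error (px): mean 6.0, max 8.5
segmentation Dice (train): 0.992
segmentation Dice (test):  0.992
cross-validation accuracy: 100.0%
test confusion: TP=10 FN=0 TN=10 FP=0
test accuracy 100.0%  sensitivity 100.0%  specificity 100.0%
selected features:
  texoff|OD|red|autocorrelation,d8
  texoff|OD|red|autocorrelation,d9
  texoff|OD|red|sum_average,d8
  texoff|OD|red|sum_average,d9
  texoff|OD|red|autocorrelation,d10
```

Reading the output: all 50 discs were localised within 8.5 px (disc radius
≈ 25 px) and segmented at Dice 0.99 against ground truth; the wrapper
selected five optic-disc texture features — co-occurrence autocorrelation
and sum-average of the red channel at large offsets, which rise with the
bright enlarged cup of a glaucomatous disc — and the Twin SVM classified
all 20 held-out eyes correctly.

A thin CLI mirrors the stages (`rifm synth`, `rifm localize`,
`rifm vessels`, `rifm pipeline`, `rifm metrics`, `rifm compare`); run
`rifm --help`.

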