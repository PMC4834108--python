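# Methods

`rifm` implements a complete screening pipeline for normal-vs-glaucoma
classification of optic-disc-centred retinal images (colour fundus or
red/green scanning-laser-ophthalmoscope frames). This note records the
models, the parameter choices that matter, the numerical conventions, and
what the synthetic test bed does and does not demonstrate.

## Pipeline overview

1. **Disc localisation** from two weighted feature maps: F1 (disc) combines
   the summed gradient magnitudes of the BT.601 luma with a fast radial
   symmetry transform (FRST) at plausible disc radii; F2 (vessels) is the
   mean of twelve oriented matched-filter responses. An exhaustive two-stage
   search picks the column whose `w_max`-wide band carries the most F2 mass
   (the arcades cross the disc vertically), then the row centring the
   `d_max × d_max` window with the most F1 mass.
2. **Disc segmentation**: an active-shape-style fit. Red and green channels
   are vessel-inpainted, convolved with a Gaussian filter bank
   (N, N_x, N_y, N_xx, N_xy, N_yy at σ = 2, 4, 8, 16 → M = 48 maps);
   feature profiles sampled along each contour point's outward normal are
   scored against a trained per-point mean/covariance by Mahalanobis
   distance; a Procrustes/PCA shape model regularises each update; the disc
   centre is re-estimated as the vertex mean of the final contour.
3. **Region division**: the disc-centred crop (side = 2 × the maximum disc
   dimension) is split into the optic disc (OD) plus four quadrants bounded
   by the lines from the disc centroid to the crop corners: superior (top),
   inferior (bottom), and nasal/temporal, assigned by eye side. Eye side
   comes from intradisc vessel asymmetry (nasal half carries the vessel
   trunk); ties resolve to "right" with a logged warning.
4. **Feature extraction**: six families per region and channel (counts for
   the default grids, five regions, two channels):
   gaussian-bank means (240), GLCM texture at offsets 1–10 (2000), GLCM at
   offset 1 after blurring at σ = 2–16 (800), centre-surround dyadic
   Gaussian responses (135), Gabor magnitude means over a
   4σ × 5γ × 7f × 4θ grid (5600), and one-level DWT subband
   average/energy for five wavelet families (400) — 9175 columns, or 1835
   when the whole crop is a single "global" region.
5. **Normalisation and selection**: column z-scores from training rows only
   (population SD; zero-variance columns dropped); a per-column two-sided
   Welch t-test keeps features with p ≤ 0.05 (no multiplicity correction —
   the filter is a recall-oriented pre-screen, and its type-I rate is itself
   a tested property); greedy wrapper forward selection then maximises the
   mean stratified 5-fold criterion (ROC AUC of linear-discriminant scores
   by default; LDA or QDA accuracy as alternatives) until the improvement
   falls below 1e-3, with a floor of 5 and a cap of 30 features.
6. **Classification**: a linear Twin SVM by default (two non-parallel
   hyperplanes, one QP per class; nearest-plane prediction normalised by
   ‖w‖), with kernel SVMs (linear, RBF, polynomial, sigmoid), LDA and QDA
   available. Class imbalance is handled by ensemble random under-sampling
   (ERUS): B = 11 members, each trained on all minority samples plus an
   equal-size majority subsample, majority vote at prediction, applied
   inside each training fold (leak-free).

## Parameter defaults and their rationale

| Parameter | Default | Why |
|---|---|---|
| matched-filter σ | 4 px (fundus), 1.5 px (SLO) | vessel half-width at each modality's resolution |
| matched-filter orientations | 12 (0°–165°, step 15°; 30° between paired symmetric kernels) | orientation-mean response is near-isotropic (tested to ≤ 5%) |
| max disc dimension `d_max` | 400 (fundus), 150 (SLO) px | upper bound on disc size at each resolution |
| max vessel width `w_max` | 50 (fundus), 12 (SLO) px | search-band width for the vessel column |
| FRST radii | {d_max/8, d_max/6, d_max/4} for modality defaults; {0.35, 0.5, 0.65}·diameter when the nominal disc diameter is known | plausible disc radii |
| F1 weights | 0.5 gradient + 0.5 FRST | both maps are min-max normalised to [0, 1], so equal weights are meaningful; configurable |
| contour points N | 64 | smooth closed boundary at these resolutions |
| profile half-length L / candidates P | 20 / 21 (desk-scale synthetic runs use 8 / 13) | ±L px normal profiles and ±(P−1)/2 px search range; the smaller setting matches the ~25 px synthetic disc radius and keeps the run desk-sized |
| profile covariance ridge | λ = 1e-3 · trace/dim (floor 1e-10) | keeps Mahalanobis finite under low-rank training covariance |
| shape modes kept | 95% variance, weights clamped at ±3√λ | standard active-shape convention |
| GLCM quantisation | 16 grey levels, per-region min-max | region-adaptive contrast; one matrix accumulated over the four orientations at each offset magnitude |
| Twin SVM | C1 = 6, C2 = 6.14, ε1 = 0.2, ε2 = 0.1, ridge δ = 1e-6 | the parameter set at which the classifier performs best; ε values scale the ones-vectors (textbook Twin SVM at ε = 1) |
| kernel SVMs | linear C = 4; poly Γ = 0.9, d = 1, C = 1; RBF Γ = 0.05, C = 4; sigmoid Γ = 0.05, coef0 = 1, C = 1 | best-performing settings per kernel |
| wrapper | k = 5 folds, tol = 1e-3, min 5 / max 30 features | "little or no improvement" stopping rule; the floor guards against single-feature saturation (below) |
| CDR baseline cutoff | 0.55, strict (a CDR equal to the cutoff is normal) | clinical screening threshold |

## Numerical conventions

* Coordinates are 0-based `(x, y)` = (col, row), origin top-left; images are
  float64 in [0, 1] from load time. Luma uses BT.601 weights.
* Min-max normalisation raises on constant input; pipeline call sites fall
  back to an all-zero map. Responses whose absolute range is below 1e-9 are
  treated as featureless rather than rescaled noise.
* Convolution boundaries: `np.pad(mode="reflect")` (mirror without edge
  repeat) for the matched filter; scipy's `reflect` (edge-repeating) for
  Gaussian filtering and grey morphology. The brute-force test oracles pin
  both conventions.
* The matched-filter kernel is zero-mean over its support, truncated to a
  rotated square |u|, |v| ≤ 3σ on a grid of half-width ⌈3σ√2⌉ so the
  support is identical at every orientation (rotation covariance).
* FRST votes that leave the frame are discarded, not clipped (clipping
  piles spurious votes on the border).
* In the exhaustive search, a contiguous run of tied window positions
  resolves to its central element: a window wider than the structure ties
  over a whole run and the centre is the unbiased representative.
* GLCM entropies use log base 2; 0·log 0 = 0. Pairs are counted only when
  both pixels are inside the region.
* Dice is `2|A∩B| / (|A|+|B|)` (range [0, 1]; both-empty → 1); the
  union-denominator variant, which can exceed 1, is available behind a
  flag for comparison.
* Sensitivity/specificity follow Sn = TP/(TP+FN), Sp = TN/(TN+FP).
* McNemar's statistic is the continuity-corrected
  (|c1−c2|−1)²/(c1+c2) on the two methods' misclassification counts, df=1
  (p-value from the χ² upper tail). This count-based form — rather than
  the classical discordant-pair b/c form — is deliberate and documented;
  it assumes the two methods' errors are weakly overlapping.
* The Gabor carrier runs along the rotated axis x̂ (rotation-covariant);
  frequencies above 0.5 cycles/pixel alias on the pixel grid and act as
  additional low-frequency channels — they are kept for grid completeness.
* Wavelet subband statistics divide by p·q and p²·q² with p × q the
  region bounding box (not the subband size), making the energy statistic
  resolution-dependent by construction.
* The Twin SVM dual (a box-constrained convex QP) is solved with L-BFGS-B
  using the analytic gradient; tests cross-check against an exact
  active-set enumeration on small problems.
* The per-point profile covariance is never formed: Mahalanobis distances
  go through the Woodbury identity on the low-rank training deviations,
  so the default 1968-dimensional profiles stay cheap in memory.

## Design choices where the design was open

* **Eq.-style feature-map combination**: the disc map is an equal-weight
  sum of two normalised maps and the search is the band/window argmax
  described above; both weights and window sizes are configurable because
  no single canonical algebra exists for this construction.
* **Dyadic channels**: with a two-channel acquisition the blue-yellow
  opponent channel cannot exist; the "yellow" channel Y_rg = R+G−2|R−G|
  takes its place, and the blue channel is identically zero for SLO (and
  ignored for fundus feature extraction for cross-modality comparability).
* **Pyramid and interpolation**: Gaussian blur (σ = 1) + ×2 decimation per
  level; surround levels are brought back to centre resolution by bilinear
  interpolation.
* **Per-point (not pooled) profile covariance**, Welch (not pooled-var)
  t-test, stratified (not plain random) folds: in each case the more
  robust variant was chosen where the method description is silent.
* **Wrapper feature floor**: on a few dozen training samples the
  cross-validated criterion saturates — a single lucky column can separate
  the whole training set, and the improvement-based stopping rule would
  then halt at one feature, which is fragile out of sample. The wrapper
  therefore keeps accepting features (breaking criterion ties by the
  per-column Welch statistic) until a minimum set size (default 5),
  yielding a small ensemble of the strongest complementary signals.
* **I/S/N/T exclude disc pixels** so regional features never double-count
  the disc; the OD label overrides quadrant labels inside the contour.
* **Repository shape**: the pipeline is exposed both as composable stage
  functions and as a statsmodels-style `GlaucomaScreeningModel` →
  `ScreeningResults` pair, because the final stage genuinely is a model
  fitted to data and benefits from a fit/results/summary interface.

## The synthetic test bed

`rifm.synthetic` renders, at desk scale (192×192 px, disc radius ≈ 25 px),
the structures each stage keys on: a bright elliptical disc with a brighter
cup (controllable vertical CDR), a central vessel trunk crossing the disc
slightly nasal of centre with arcades fanning nasally (this asymmetry
drives the eye-side rule), an optional bright speckled peripapillary-
atrophy crescent in the inferior/temporal sector, a linear illumination
ramp, and Gaussian pixel noise. Class-conditional study conditions:
normal CDR ~ U(0.2, 0.5), glaucoma CDR ~ U(0.6, 0.9); PPA probability 0.1
vs 0.7; all other geometry drawn once per eye from fixed jitter ranges;
every random draw descends from a single seed.

What passing the synthetic suite shows: the implementation of each stage
is internally correct (oracle equivalence), the stages compose (the
pipeline localises within half a disc radius on ≥ 95% of eyes, segments
held-out discs at Dice ≥ 0.90, recovers planted discriminative features,
and classifies held-out synthetic eyes at ≥ 85% accuracy). What it does
not show: performance on real fundus/SLO images, whose vessel trees,
illumination fields, pigmentation variation and annotation ambiguity are
far richer than this generator. Quantities reported on real datasets in
the literature are not reproducible from this repository and are only
used as worked examples where they are self-contained (confusion-count
arithmetic).

Problem sizes in the recovery studies (20 eyes for localisation, 20
train / 10 held-out for segmentation, 20 seeds × (100 × 52) for wrapper
recovery, 30 train / 20 test for the end-to-end run, 1000 noise features
at n = 40 for filter calibration) are the package's chosen desk-scale
study conditions: large enough for stable rates, small enough to re-run
anywhere.

## Known limitations

* The vessel segmenter is a deliberate simple stand-in (matched filter +
  iterated Otsu + small-component removal); it suffices for inpainting and
  eye-side determination but is not a competitive vessel segmentation
  method for real images.
* Cup segmentation is not automated; CDR enters only through annotations
  or the generator, and the CDR baseline classifier consumes given values.
* The Twin SVM is linear only; kernelised twin formulations are out of
  scope.
* Profile-model training assumes annotated contours share a comparable
  starting vertex and orientation after arc-length resampling; wildly
  inconsistent annotation conventions would need pre-alignment.
* Table-based GLCM feature definitions vary across the literature; the 20
  statistics implemented are the standard extended Haralick set, pinned by
  the brute-force oracle in the tests.
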