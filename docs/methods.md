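# Methods

`radsurv` implements a deep-learning-and-radiomics pipeline for predicting
right-censored time-to-event outcomes (overall survival, recurrence-free
survival, distant control, local control) from paired CT/PET tumor patches
plus a small clinical table. This note records the models, the synthetic
data they are exercised on, and the numerical choices a maintainer would
want to know.

## The model

Each case contributes two fixed-size 3-channel inputs: an 80×80 CT-like
patch stack and a 28×28 PET-like patch stack (tumor cropped to its
bounding box and centered on a zero canvas; channels are the middle slice
and its two neighbors, or three concentric crops in multi-scale mode).
Two small CNNs — conv(3×3, 32, ReLU) → pool(2×2) → conv(3×3, 32, ReLU) →
pool(2×2) → FC(32, ReLU) → FC(1, linear) — map each modality to a scalar
risk. They are trained by stochastic gradient descent on the negative Cox
partial log-likelihood with risk sets restricted to each mini-batch of 32
(an approximation to the full-cohort likelihood; event-free batches are
skipped). The two risks then join age, gender, SUVmax and radiation dose
in a Cox proportional-hazards model

    h(t | x_i) = h0(t) · exp(β1·CT_i + β2·PET_i + β3·Age_i
                             + β4·Gender_i + β5·SUV_i + β6·Dose_i),

fitted by Newton–Raphson on the partial likelihood with backward stepwise
selection: the covariate with the largest nested-model likelihood-ratio
p-value ≥ 0.05 is dropped and the model refitted until all survivors are
significant. When nothing survives, the report carries no concordance
("NA") — a c-index from a predictor-free model would be noise. The
baseline hazard h0 is never estimated; the model is used only for ranking
(hazard ratios and the concordance index).

Ranking accuracy is Harrell's concordance: the fraction of permissible
ordered pairs (i uncensored, T_j > T_i) whose predicted ordering matches.
Tied predictions count 1/2 by default so a constant predictor scores 0.5;
a strict mode awards ties 0 (the literal indicator form).

Two comparison arms accompany the deep model: (1) 42 hand-crafted
radiomics features (7 shape, 8 first-order intensity, 6 GLCM texture per
modality) reduced to 18 principal components and passed through the same
stepwise Cox; (2) a random survival forest over the six predictors with
logrank splitting, Nelson–Aalen terminal-node cumulative hazards, ensemble
CHF prediction, out-of-bag error = 1 − c-index, and variable importance by
random daughter assignment.

## Synthetic cohorts

The in-house imaging cohort this design targets is private, so every stage
is exercised on seeded synthetic cohorts (`radsurv.cohort`). Each case
gets 1–2 elliptical tumor blobs rendered on both modalities with random
size, orientation, mean intensity, and a smoothed-noise texture whose
amplitude is the "roughness" parameter; per-tumor SUV increases with size
and intensity, and PET uptake tracks SUV. The latent log-hazard of a tumor
is z(area) + z(mean ROI intensity) + z(roughness), standardized within the
cohort, so shape, intensity and texture features all carry signal. Event
times are exponential with rate `baseline_rate · exp(beta_image·latent +
beta_clinical·z(clinical))`; censoring is the minimum of an independent
exponential and a 60-month administrative horizon; OS/RFS/DC are drawn per
case (index tumor = highest SUV), LC per tumor. Clinical covariates enter
the hazard as within-cohort z-scores — with raw units a mean age of ~75
would swamp any chosen baseline rate.

Defaults (132 cases, baseline 0.015/month, censoring 0.012/month) give a
median observed time near 27 months and 50–60 % observed events, i.e. a
follow-up profile typical of an SBRT lung cohort. The fixture used by the
end-to-end recovery tests plants a purely image-driven hazard
(`beta_image = 1.5`, clinical effects zero, n = 200): with that effect
size the *oracle* c-index — scoring by the true latent risk — is ≈ 0.80,
leaving headroom for a learned model to clear 0.70. These blobs lack real
anatomy, scanner noise, resolution effects and registration error, so
passing tests demonstrate that the machinery recovers a planted
image-encoded hazard, not that it would achieve any particular accuracy on
clinical data.

## Numerical and design choices

- **Ties** in event times use the Breslow convention everywhere (partial
  likelihood, its gradient, the Newton fit).
- **Cox solver**: zero initialization, analytic gradient/Hessian
  accumulated over tie groups, step-halving line search, stop at gradient
  norm < 1e-8 (max 100 iterations). Covariates are centered internally
  (the partial likelihood is invariant). A converged |β| > 20 is reported
  as separation. If a multivariable stepwise fit fails to converge, the
  covariate whose removal leaves the best-converging restricted model is
  dropped and elimination continues.
- **Significance** of a covariate is the 1-df likelihood-ratio chi-square
  of the restricted-vs-unrestricted comparison — the standard nested-Cox
  test — at level 0.05.
- **Cut-offs**: maximally selected logrank over midpoints of consecutive
  unique values, both groups ≥ 10 % of subjects; the reported p-value is
  the uncorrected p of the maximal statistic and is therefore optimistic.
  Cut-offs and Kaplan–Meier curves in pipeline reports are fitted on
  training cases only.
- **Coordinates** are 0-based with half-open boxes; centering biases odd
  remainders toward the top-left. Multi-scale channels (margins 0/10/20 px
  per side, clipped at the border) are zero-padded onto the base canvas
  when they fit and bilinearly resized only when larger, so the margin-0
  channel is identical to the standard crop-and-pad path.
- **Intensity normalization**: each modality is min–max scaled to [0, 1]
  using training-set extremes only.
- **GLCM**: 32 levels quantized over the ROI intensity range, offsets
  (0,1), (1,0), (1,1), (1,−1) at distance 1, pairs restricted to the mask,
  accumulated, symmetrized and normalized jointly. Shape definitions:
  area regularity = 4πA/P²; perimeter regularity = hull-perimeter /
  perimeter and the coefficient of variation of boundary-pixel radii
  (interior pixels would give a disc CV 1/√8 ≈ 0.354 by geometry alone);
  bilateral symmetry = Jaccard overlap with reflections about the
  horizontal, vertical and two diagonal axes through the centroid. These
  instantiate the count structure 1 + 2 + 4 of the shape family.
- **PCA** is fit jointly over the 42 CT+PET features after z-scoring with
  training statistics; zero-variance features are dropped with a warning;
  the component count is capped so the Cox design stays smaller than the
  training sample.
- **CNN engine**: a compact float32 engine on im2col/GEMM products with
  numba-compiled patch and pooling kernels and reusable buffer pools;
  max-pool ties go to the earliest quadrant; initialization is seeded
  Glorot-uniform. Pooling is applied to raw conv maps and ReLU to the
  pooled maps (equal to conv→ReLU→pool because ReLU is monotone, at a
  quarter of the memory traffic). The first conv layer's patches are
  extracted once per training set since they depend only on the data.
- **Optimizer schedule**: the reference configuration is plain SGD,
  lr 1e-5, 2000 epochs, batch 32. The desk-scale preset used by tests and
  examples runs 150 epochs starting at lr 1e-3 with a linear decay to
  zero: the large early steps make up for the 13× shorter schedule and
  the decaying tail removes the gradient-noise floor that a constant step
  leaves at these batch sizes. Both schedules are plain SGD without
  momentum or weight decay. The desk-scale preset additionally applies
  train-time dihedral augmentation (random flips and 90° rotations, under
  which the generator's latent image features are exactly invariant) to
  offset overfitting of the ~4×10⁵-parameter CT branch on ~160 training
  cases; scoring always uses the unaugmented patches.
- **CAE pre-training**: encoder = the conv/pool trunk; decoder = two
  (nearest-neighbor ×2 upsample → conv 3×3, 32, ReLU) stages and a linear
  3-channel conv; MSE loss; trunk weights transfer into the risk network.
  The pre-training set is a second, disjoint synthetic cohort.
- **Forest**: bootstrap with replacement; √p candidate variables per node;
  candidate thresholds are midpoints of in-node unique values; daughters
  must keep ≥ min_node_size members; depth ≤ 10. The reference ensemble
  size is 10,000 trees; tests use ≤ 200, at which point importance
  rankings on 100-case problems are stable. The 2-year risk score sums the
  ensemble CHF over event-time grid points up to the horizon. VIMP =
  OOB error with random daughter assignment minus the original OOB error;
  a variable never used in a split scores exactly 0.
- **Problem sizes in tests** are desk-scale by design: cohorts of 16–500
  cases, forests of ≤ 200 trees, networks trained 1–150 epochs; the
  end-to-end recovery experiment uses ten 200-case cohorts at 150 epochs.

## Known limitations

- The batch-restricted Cox loss is a biased estimate of the full partial
  likelihood; with batch 32 and desk-scale cohorts this is the standard
  trade-off, not a calibrated approximation.
- The maximally-selected cut-off p-value carries no multiplicity
  correction.
- VIMP values are raw error differences in [−1, 1]; they order variables
  but their magnitudes are not comparable across implementations that
  scale importance differently.
- The synthetic generator encodes hazard through three interpretable image
  properties; a model could score well by learning any of them. It cannot
  certify performance on real PET/CT, where signal is subtler and
  preprocessing (SUV computation, registration, segmentation variability)
  adds noise the generator does not model.
- Combined deep + hand-crafted modelling is provided only as concatenation
  of both predictor sets into one stepwise Cox.
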