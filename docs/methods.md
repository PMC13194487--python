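# Methods

## Model

The staging model maps heterogeneous patient records to GOLD stages 1–4.
Records come from two cohorts with different feature sets: a shared
clinical core present in both (age, sex, smoking status, pack-years, FEV₁,
FVC, FEV₁/FVC) and cohort-private measurements (CAT score and exacerbation
count in the source cohort; two six-minute-walk distances in the target
cohort).

Three encoder pathways feed one prediction head:

- shared encoder: `2·d_shared → 32 → 16`, ReLU;
- one private encoder per cohort: `2·d_private → 8`, ReLU;
- head: linear `24 → 3`, sigmoid per output.

Each patient row is routed through the shared encoder and through *its
cohort's* private encoder; the head never sees both private embeddings at
once. The three outputs estimate the cumulative threshold probabilities
P(stage ≥ 2), P(stage ≥ 3), P(stage ≥ 4) of the ordinal encoding
GOLD k ↦ (1[k≥2], 1[k≥3], 1[k≥4]). Because the three sigmoids are
independent, predicted probability vectors need not be monotone; decoding
therefore uses the counting rule `stage = 1 + #{p > 0.5}`, which is exact
on monotone vectors, total on non-monotone ones, and treats an exact 0.5
as "not exceeded" so ties favor the milder stage. The claim that the
threshold formulation by itself enforces ordinal consistency holds only
for the targets, not the outputs; the counting decoder is this package's
resolution and is used identically during training-time validation and
final evaluation.

Inputs are value-mask encoded: each feature contributes a value column and
a binary availability column, with missing cells as (0, 0) and a measured
zero as (0, 1). No imputation of any kind is performed. Shared features
are min-max normalized with *fixed clinical ranges* (age 40–100 y,
sex 0–1, smoking 0–2, pack-years 0–110, FEV₁ 0.4–4.0 L, FVC 0.5–6.0 L,
FEV₁/FVC 0–1) and clamped to [0, 1]; ranges are constants of the schema,
never data statistics, so train/validation leakage through normalization
is impossible. Private features enter in raw clinical units, unscaled and
unclamped. Categorical shared features (sex, smoking) pass through the
same min-max map rather than one-hot coding, matching the integer codings
of the schema.

## Training

Full-batch gradient descent with Adam (lr 3·10⁻⁴, β₁ = 0.9, β₂ = 0.999,
ε = 10⁻⁸), one update per epoch for at most 3000 epochs, no mini-batching,
no dropout, no early stopping. The loss is binary cross-entropy averaged
over every threshold entry of every training row, pooled across both
cohorts without per-domain reweighting (the entire source cohort plus the
target training split). Gradients are clipped to global L2 norm 1.0 before
each update. Probabilities are clipped to [10⁻⁷, 1−10⁻⁷] inside the loss
value; gradients follow the exact logits formulation (p − t), so saturated
sigmoids still train. Validation metrics are computed every 10 epochs
(including epoch 0, the untouched initialization) and the returned
parameters are those of the evaluation with minimum validation stage-MAE,
earliest epoch on ties. Weights initialize fan-in-scaled uniform
(U(±1/√fan_in)) with zero biases from a seeded generator; the whole loop
is deterministic given the seed. The forward/backward pass and Adam are
implemented directly in numpy — the network is small enough (1163
parameters at the default widths) that explicit gradients are clearer and
exactly reproducible; a central-difference oracle in the test suite checks
the backprop for every variant.

A practical note on the unscaled private features: walk distances enter at
magnitudes of several hundred meters, which saturates the head's sigmoids
early in training. Learning still proceeds through the logits gradient,
but the private pathway matures late (typically the last third of the
epoch budget), which is why checkpoint selection commonly lands near the
end of training for the full model.

## Baselines and ablations

- `multiclass`: the shared encoder architecture with a 4-way softmax head
  and cross-entropy loss — the nominal-classification control. It sees
  shared features only, which is also what makes it a clean control for
  the ordinal head given identical inputs (the shared-only ordinal
  ablation).
- `logistic`: multinomial logistic regression (scikit-learn, lbfgs) on the
  full value-mask design `[shared | source-private | target-private]` with
  the absent cohort's private block zeroed — exactly the value-mask
  convention for never-measured features. The L2 strength is selected by
  stratified 3-fold cross-validation on the training rows over
  C ∈ {0.01, 0.1, 1, 10, 100}. A fixed penalty was rejected after
  measurement: the design mixes unit-scale normalized columns with raw
  clinical magnitudes, and any single C systematically over-shrinks one
  group (a fixed C = 1 costs the baseline ≈0.1 QWK on the default
  synthetic cohorts), which would understate the linear reference point.
- `shared_only_ordinal` / `private_only_ordinal`: sever one pathway; the
  head input narrows to 16 or 8 accordingly. Both are trained with the
  identical recipe.

All variants in a suite share one stratified 20% validation split of the
target cohort (split seed 42; the source cohort is never split). Per-class
validation counts use largest-remainder rounding of `fraction ×
class_count` reconciled to the global total `round(fraction × N)`, which
reproduces the 81/20 partition of a 101-row cohort with stage counts
(23, 43, 27, 8). Run-to-run variation comes from the parameter-init seed
only; `freeze_run_seeds` pins all repeats to one seed, which reproduces
the zero-variance regime of fully frozen conditions and is exposed as an
explicit CLI flag rather than a silent default.

## Synthetic cohorts

The generator produces the data regime the architecture exists for, with
severity injected through FEV₁ %predicted — the quantity that defines
GOLD bands (≥80 → 1, [50, 80) → 2, [30, 50) → 3, <30 → 4):

1. Each patient's stage is drawn from the cohort's stage distribution
   (defaults proportional to 80/60/43/41 and 23/43/27/8). A latent FEV₁
   %predicted is drawn uniformly inside the stage's band and jittered with
   N(0, noise_sd²) (default 4 percentage points), so patients near band
   boundaries are genuinely ambiguous.
2. Observed spirometry derives from the latent value through a
   demographic predicted-FEV₁ with substantial *hidden* anthropometric
   variation (SD 0.30 L) plus multiplicative session error, making raw
   FEV₁ in liters an informative but imperfect severity readout — as it is
   clinically, since staging normalizes by predicted volume.
3. The target population's predicted-FEV₁ baseline sits `domain_shift`
   liters lower (default 1.5 L): identical measured volumes then
   correspond to different severities across cohorts. This concept shift
   is the core difficulty: a model pooling both cohorts through shared
   features alone mis-calibrates the target cohort, while the full model
   can condition on cohort identity, which its private pathway exposes.
4. Private features carry strong severity signal scaled by
   `signal_strength` (default 1.25): CAT rises convexly with stage
   (confounded by pack-years); walk distance falls convexly with stage
   with a small residual (10 m) but is heavily confounded by age and sex,
   including a nonlinear decline past age 60. Marginally the walk test is
   ambiguous; only the shared demographics deconfound it, and the
   nonlinear part of that deconfound is inaccessible to a linear model.
5. Every non-label cell is masked missing completely at random at
   `missing_rate` (default 10%; the real cohorts' missingness rates are
   unpublished, so this default is an explicit guess).

What passing tests on these cohorts do and do not show: they demonstrate
that the pipeline's components behave as specified and that the
architecture's qualitative advantages (ordinal head, two pathways,
cohort-conditional calibration) materialize on data engineered to contain
exactly those structures. They do not validate performance on the original
cohorts — the published headline numbers require external data that is not
redistributed here — and MCAR missingness plus fully synthetic feature
dependencies are idealizations of real clinical records. One published
result is knowingly not reproduced in magnitude: the near-total collapse
of the multiclass softmax baseline (QWK ≈ 0.09). A faithfully trained
softmax network on learnable synthetic data stays well above chance; the
suite reproduces the *ordering* (full > logistic > multiclass, ablations
markedly degraded), not that collapse, which the published variance
pattern suggests was an optimization artifact of the original runs.

## Numerical and design choices

- Round-half-away-from-zero for the global validation count; largest
  remainder per class, ties broken toward larger classes then lower
  stage index.
- CSV cells "", "NA", "NaN" (any case) parse as missing; columns whose
  name contains "predicted" are dropped on read (noisy derived
  lung-capacity metrics); other undeclared columns are ignored with a
  logged warning.
- Out-of-range shared values clamp to [0, 1] after normalization; private
  values are never clamped.
- QWK uses the fixed 4×4 stage grid even when a class is absent; the
  degenerate case of both marginals concentrated on one identical class is
  defined as 1.0. The quadratic penalty Σw·O grows monotonically as a
  prediction moves farther from truth; kappa itself can move either way
  locally because the chance-correction denominator shifts with the
  marginals — the test suite asserts the former, mathematically true,
  property.
- The within-±1 rate is computed over misclassified pairs only and is 1.0
  by convention when there are no errors.
- Problem sizes in the test suite and acceptance script match the study
  regime (224 + 81 training rows, 20 validation rows, 3000 epochs); the
  stability check runs 50 seeds and the ordering check 10 suite seeds with
  2 repeats, sizes chosen so the full suite completes in minutes on one
  CPU.

## Known limitations

- The 20-row validation split makes every metric coarse (one patient is
  5% accuracy); per-seed variation of QWK is large, which is why ordering
  claims use majority rule across suite seeds.
- The counting decoder and independent sigmoids do not enforce monotone
  probability vectors; rank-consistent heads (shared weight vector with
  ordered biases) would, but are a different method.
- No class-weighting or imbalance correction anywhere, matching the
  method; the rare GOLD 4 class is correspondingly fragile.
- The generator's coefficient choices are plausible clinical magnitudes,
  not fitted to any real dataset.
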