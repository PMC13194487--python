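# copdord

Ordinal neural networks for COPD severity staging across heterogeneous
clinical cohorts.

## The problem

Chronic Obstructive Pulmonary Disease severity is graded on the ordered
GOLD scale (stages 1–4, mild to very severe, defined spirometrically on
FEV₁ %predicted). Two practical obstacles complicate learned staging from
real cohort data:

- **Feature heterogeneity.** Different cohorts measure different variables.
  Here a *source* cohort records symptom burden (CAT score) and annual
  exacerbations, a *target* cohort records six-minute-walk distances
  (MWT1/MWT2), and both share a spirometric/demographic core (age, sex,
  smoking status, pack-years, FEV₁, FVC, FEV₁/FVC).
- **Ordinality.** Predicting GOLD 4 for a GOLD 1 patient is far worse than
  confusing adjacent stages, which nominal multiclass losses ignore.

`copdord` implements a shared-private ordinal network for this setting: a
common encoder for the shared clinical core (2·d_shared → 32 → 16, ReLU),
one private encoder per cohort for its exclusive features (2·d_private → 8,
ReLU), and a linear head on the concatenated 24-d representation emitting
three sigmoid threshold probabilities.

Stages use the cumulative threshold encoding

    y(k) = (1[k ≥ 2], 1[k ≥ 3], 1[k ≥ 4]),   k ∈ {1,…,4}

so GOLD 1 ↦ (0,0,0) … GOLD 4 ↦ (1,1,1); decoding counts thresholds with
probability above ½: k̂ = 1 + #{j : p_j > 0.5}. Training minimizes the mean
binary cross-entropy over the N×3 threshold grid with full-batch Adam
(lr 3·10⁻⁴, ≤3000 epochs, global gradient-norm clipping at 1.0), selecting
the checkpoint with minimum validation stage-MAE. Missing measurements are
never imputed: each feature carries a binary availability mask
(value-mask encoding), so a measured 0.0 stays distinguishable from an
absent cell and block widths are 2·d.

Evaluation is ordinal: exact accuracy, stage-MAE, quadratic weighted kappa

    κ = 1 − Σᵢⱼ wᵢⱼ Oᵢⱼ / Σᵢⱼ wᵢⱼ Eᵢⱼ,   wᵢⱼ = (i−j)²/(K−1)²,

the 4×4 confusion matrix, and the fraction of *errors* within ±1 stage.
Baselines and ablations: a multiclass softmax network on the shared
encoder, CV-regularized multinomial logistic regression on the full
value-mask design, and shared-only / private-only single-pathway ablations.

A synthetic cohort generator (`copdord.synthetic`) reproduces the study's
data regime — cohort sizes 224/101, stage mixes 80/60/43/41 and 23/43/27/8,
clinical value ranges, MCAR missingness, and a cross-cohort population
shift — so the entire pipeline is exercisable without any external data.

## Worked example

```sh
copdord simulate --seed 0 --outdir cohorts/
copdord train --source cohorts/source.csv --target cohorts/target.csv \
    --variant full_ordinal --seed 0 --outdir run/
```

which prints

```
wrote cohorts/source.csv (224 rows) and cohorts/target.csv (101 rows)
best epoch 1120 (val MAE 0.150); val accuracy 0.850, QWK 0.903
```

i.e. the target cohort was split 81/20 by stratified sampling (seed 42),
the full model's best checkpoint (by validation MAE, evaluated every 10
epochs) misstages a validation patient by 0.15 stages on average, places
85% exactly, and reaches strong ordinal agreement (QWK 0.90 > 0.8). The
same library calls are available in Python:

```python
from copdord import SimSpec, generate_pair, prepare_experiment, run_suite

source, target = generate_pair(SimSpec(seed=0))
suite = run_suite(source, target, repeats=5, base_seed=0)
print(suite.summary[["variant", "qwk_mean", "mae_mean"]])
```

`run_suite` trains every variant on one frozen split and reports
mean ± sd per metric; on the default cohorts the full shared-private
ordinal model leads in QWK, the tuned logistic baseline follows, the
multiclass softmax baseline trails it, and both single-pathway ablations
degrade markedly — the qualitative pattern that motivates the
architecture.

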