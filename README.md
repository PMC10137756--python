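# ttsurv

Transformer-based time-dependent survival prediction for tabular clinical
data with mixed continuous and ordinal-categorical covariates.

## The problem

Prognosis models for aggressive lymphoma (the motivating disease is diffuse
large B-cell lymphoma, DLBCL) must combine continuous measurements (age,
LDH) with ordinal-categorical clinical scores — ECOG performance status,
Ann Arbor stage, IPI, extranodal site count, and the Deauville score from
interim PET — under heavy right-censoring (~70% of patients never reach the
event during follow-up). Those scores are neither continuous nor purely
categorical: stage IV is worse than stage I, and a Deauville score of 4–5
is qualitatively worse than 1–3. `ttsurv` treats them as categories and
lets a transformer encoder learn the inter-class structure.

## The model

The hazard for covariates x is

    h(t | x) = h0(t) · exp g(t, x)

where g(t, x) is a neural **time-dependent relative risk**: categorical
covariates pass through *column embedding* (one learned d-vector per
(feature, level) pair, plus a per-column identifier in place of positional
encoding, plus t special tokens — Σᵢ cᵢ + t + N learned vectors in total)
and a self-attention encoder; the encoder outputs are flattened,
concatenated with the continuous covariates and standardised time, and fed
to a residual dense block with a scalar head. Training minimises the
time-dependent Cox partial likelihood in risk-set relative form

    L = (1/n_e) Σ_{i: dᵢ=1} log Σ_{j ∈ R̃ᵢ} exp( g(tᵢ, xⱼ) − g(tᵢ, xᵢ) ),

with R̃ᵢ ∋ i plus controls sampled from the risk set {j : tⱼ ≥ tᵢ}. The
baseline cumulative hazard is recovered afterwards by the Breslow estimator

    ΔH₀(tᵢ) = eᵢ / Σ_{j: tⱼ ≥ tᵢ} exp g(tᵢ, xⱼ),

giving per-patient survival curves S(t|x) = exp(−Σ ΔH₀(tᵢ) e^{g(tᵢ,x)}),
median-life point predictions, the concordance index (strict pairwise
form), and the event-only mean absolute error in days.

A linear, time-free risk model (`LinearCoxModel`, a Cox
proportional-hazards predictor trained with the same machinery) ships as a
sanity baseline, and a cohort simulator generates DLBCL-like synthetic data
with known true risks so every stage is testable without clinical data.

## Worked example

```python
from ttsurv import (TTSurvModel, LinearCoxModel, TrainingConfig,
                    linear_ph_scenario, simulate_cohort, c_index)

scenario = linear_ph_scenario(n=2000, seed=0)   # ~71% censoring
train = simulate_cohort(scenario)
test = simulate_cohort(scenario, n=500, seed=1)

results = TTSurvModel(train).fit(TrainingConfig(seed=0))
print(results.summary())
print(f"test C-index : {results.c_index(test):.4f}")
print(f"test MAE     : {results.mae(test):.1f} days")
print(f"oracle C     : {c_index(test.t, test.true_risk, test.d):.4f}")

days, crossed = results.predict_median(test.subset(range(3)))
print("median life (days):", days.round(1), "crossed 0.5:", crossed)
```

Output:

```
TTSurvModel fit results
==============================================
n (train)                                 1599
events (train)                             474
epochs run                                  55
best epoch                                  25
best validation loss                    4.9786
baseline hazard steps                      474
==============================================
test C-index : 0.6819
test MAE     : 1219.0 days
oracle C     : 0.6844
median life (days): [2747.2 2085.7 2992.3] crossed 0.5: [ True  True False]
```

The summary reports the training split (an internal stratified split
provides the validation set used for early stopping), the epoch whose
full-risk-set validation loss selected the returned weights, and the number
of Breslow hazard steps. The fitted model's held-out concordance (0.682)
sits close to the oracle using the simulator's true risks (0.684); the MAE
averages |true − predicted median life| over patients with observed events
only. A `crossed` flag of `False` marks a curve that never reaches 0.5, in
which case the last grid time (a lower bound) is reported.

The same protocol is scriptable from the shell:

```sh
ttsurv simulate --scenario linear-ph --n 2000 --seed 0 --out cohort.csv
ttsurv train-cv --config experiment.yaml --seed 0 --out run/
ttsurv compare-stages --config experiment.yaml --out run/   # +/- Deauville
ttsurv predict --model run/model_fold0.npz --cohort cohort.csv --out preds/
```

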