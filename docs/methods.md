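# Methods

## Model

`ttsurv` fits a time-dependent relative-risk survival model
h(t|x) = h0(t)·exp g(t, x) to right-censored tabular data. The assumptions
are those of the Cox framework with the proportionality constraint lifted:
non-informative right censoring, no competing risks, no left truncation or
interval censoring, and durations measured in days.

g(t, x) has two input branches. Categorical covariates are column-embedded:
feature i with cᵢ levels owns cᵢ learned vectors of dimension `d_embed`, a
per-column identifier vector is added so identical codes in different
columns embed differently (this replaces positional encoding — tabular
columns have no order, and the encoder is permutation-equivariant over
tokens), and `n_special_tokens` extra learned tokens are appended, giving
Σᵢ cᵢ + t + N learned vectors. The token sequence passes through a post-norm
transformer encoder (multi-head self-attention with the 1/√k scaling,
residual connection, LayerNorm, then an MLP with residual and LayerNorm).
Special tokens are excluded from pooling: the N feature-token outputs are
flattened and concatenated with the continuous covariates and the
standardised evaluation time, then fed to a residual dense block (two ReLU
hidden layers of width `hidden` plus a linear skip from block input to
block output) ending in a scalar head. Time enters the dense block only,
standardised by the mean/SD of the *training event times* — raw day counts
in the thousands destabilise a small network.

Ordinal scores (stage, IPI, Deauville, ECOG, extranodal count) are stored
as codes in the schema's level order so the ordering is recoverable, but
the model treats them as categories and leaves the severity structure for
the encoder to learn.

## Training objective

The printed full-likelihood form (d·log f + (1−d)·log S) and the "partial
likelihood" reading of time-dependent Cox training differ; this package
trains on the risk-set relative form, which needs no baseline hazard during
optimisation:

L = (1/n_e) Σ_{i: dᵢ=1} log Σ_{j∈R̃ᵢ} exp(g(tᵢ,xⱼ) − g(tᵢ,xᵢ)),

where R̃ᵢ contains i itself plus `sampled_controls` subjects drawn
uniformly with replacement from the risk set {j : tⱼ ≥ tᵢ} (ties: subjects
with tⱼ = tᵢ are at risk). The j = i summand contributes exp(0) = 1, so the
loss is non-negative, and adding any constant to g cancels inside the
exponent — the baseline hazard absorbs location. Optimisation is Adam with
decoupled weight decay; after every epoch the *full-risk-set* loss on the
validation split is evaluated (deterministically, no sampling) and the
parameters from the best epoch are returned, with early stopping after
`patience` epochs without improvement. Everything is driven by a single
integer seed; training is bit-reproducible.

The Breslow step follows fitting: ΔH₀(tᵢ) = eᵢ / Σ_{j:tⱼ≥tᵢ} exp g(tᵢ,xⱼ),
with g re-evaluated at tᵢ for every at-risk subject and tied events sharing
one increment (Breslow tie handling; Efron is out of scope). With g ≡ 0
this is exactly Nelson–Aalen. Survival curves are right-continuous step
functions on the training event-time grid, with no interpolation. The
median life is the first grid time with S ≤ 0.5; when a curve never
reaches 0.5 the last grid time is returned with `crossed=False`, and such
patients still enter the MAE (the event-only mean of |yᵢ − ŷᵢ| admits no
exclusions). The scalar risk score used for concordance is the total
predicted cumulative hazard −log S(t_max|x), which summarises the whole
curve and avoids ties among never-crossing patients.

The C-index uses strict inequalities — tied risk scores earn nothing; a
`tie_credit` flag switches to the conventional half-credit variant. The
log-rank test is the K-sample observed-minus-expected statistic with
hypergeometric variance and an asymptotic chi-square p-value.

## Defaults and their rationale

| parameter | default | why |
|---|---|---|
| `d_embed` | 16 | capacity matched to cohorts of ~600–4000 patients |
| `n_layers` / `n_heads` | 1 / 4 | one attention layer suffices for ≤10 tokens |
| `mlp_hidden` / `hidden` | 32 / 32 | same capacity argument |
| `n_special_tokens` | 1 | reserved capacity; excluded from pooling |
| `learning_rate` | 2e-3 | Adam; stable across the shipped scenarios |
| `batch_size` | 64 events/step | more steps per epoch on small cohorts |
| `sampled_controls` | 16 | lower-variance loss; full sets for validation |
| `weight_decay` | 1e-3 | decoupled; controls partial-likelihood overfit |
| `max_epochs` / `patience` | 200 / 30 | early stopping does the real work |

The capacity/regularisation choices matter: at these cohort sizes a larger
encoder (e.g. d=32, two layers, no decay) drives the validation partial
likelihood to its minimum while still at an essentially linear solution —
model selection then stops before the interaction structure is learned.
The shipped defaults let validation loss keep improving long enough for the
non-linear signal to be captured; all are overridable per run.

Preprocessing standardises continuous features by training mean and
population SD (fitted on the training split only; constant columns are an
error); categorical codes pass through. Missing values are rejected at
load — imputation would fabricate clinical data, and the schema
(a YAML document) is authoritative: no type inference, and labels absent
from the schema's level list are load-time errors even in external cohorts.

## Synthetic cohorts

The simulator emulates a DLBCL registry's covariate structure: age uniform
on 36–81 years, LDH log-uniform on 144–8402 IU/L, and the categorical
marginals of a 604-patient cohort (sex, ECOG 1–4, extranodal 0–6,
bone-marrow involvement, B symptoms, stage I–IV, IPI 0–5, Deauville 1–5,
the last being the sole on-treatment feature). Event times follow a
Weibull proportional-hazards mechanism T = (−log U/(λ e^r))^{1/κ} with
κ = 1.2, λ = 5·10⁻⁵ (typical event times in the hundreds-to-thousands of
days); censoring is an independent exponential whose rate is root-found
(Brent) so the expected censored fraction matches the target — default
70.86%, the censoring level typical of such registries — followed by an
administrative follow-up cap at 3000 days. The minimum achievable
censoring is the administrative floor P(T > cap); targets below it raise.

Two stock scenarios ship. `linear_ph_scenario` makes the log hazard exactly
linear in the model design (standardised continuous values, integer level
codes) with monotone severity slopes, enabling coefficient-recovery checks
against the linear baseline. `interaction_scenario` adds a strong
stage × Deauville interaction (on codes normalised to [0,1]), a U-shaped
log-LDH effect, and a Deauville ladder whose 4–5 jump dwarfs the 1–2–3
steps; its effect sizes are chosen so that the least-squares projection of
the true risk onto the linear design loses ≥ 0.05 of C-index against the
true-risk oracle — i.e. no linear-in-codes model can close the gap, which
is the regime the transformer exists for. True per-patient log risks are
returned for oracle evaluation.

What the simulator does *not* emulate: joint covariate dependence (levels
are drawn independently; real IPI is a deterministic function of its
components), informative censoring, measurement error, missingness, and
any claim of survival-time realism beyond scale. Passing tests therefore
demonstrate correctness of the machinery and learnability of known signal,
not clinical performance.

## Experimental protocol

`run_cross_validation` mirrors a two-institution design: event-stratified
k-fold splits (stratification by the event indicator only — the minimal
reading of "stratified"; folds are dealt round-robin so per-fold event
counts differ by at most one), per-fold preprocessing fitted on the fold's
training split, training with per-fold seeds derived from the run seed,
Breslow fitting on the training split, and evaluation on the fold's
held-out split and on an external cohort that never touches fitting or
model selection. External metrics average the k per-fold-model evaluations
rather than ensembling predictions. `compare_stages` runs the protocol
twice on byte-identical folds, with and without the on-treatment feature
group (the on-treatment view is a superset of the pretreatment view).

## Problem sizes used by the checks

The acceptance-level checks run at: n=100 (concordance endpoint), 500
draws of n=50 (chance level), n=6 batches (loss/gradient oracles), n=4000
train / 1500 test with seeds 0–2 (parameter recovery and the nonlinearity
advantage, reported as the median over seeds), n=10000 (censoring
calibration), n=800 with 2 folds over 5 seeds (stage comparison), and
n=300 with 2 folds (bit-level determinism). These sizes make every check
reproducible on a single CPU while keeping the stochastic margins
comfortable.

## Known limitations

- No competing risks, recurrent events, left truncation, or interval
  censoring; no time-varying covariates.
- Breslow ties only; no Efron option.
- The MAE depends on the no-crossing convention for flat curves; with
  heavy censoring many predicted curves never reach 0.5 and the reported
  lower bound compresses MAE differences between models.
- The log-rank p-value is asymptotic; no permutation option.
- Median-life predictions cannot exceed the largest training event time
  (the Breslow grid ends there).
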