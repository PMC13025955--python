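# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `medhg`. It is written for a reader who wants to know
exactly what the package computes and what its tests do and do not
demonstrate.

## The prediction problem

Each surgical hospital encounter carries three binary safety outcomes:
prolonged length of stay (PLOS; post-operative LOS strictly above the
cohort's 75th-percentile threshold), 30-day mortality, and 90-day mortality
(death offset ≤ 30 / ≤ 90 days after the index surgery; the 30-day label
implies the 90-day label). Predictors are demographic and perioperative
covariates known by the end of surgery, plus two care-coordination
channels: which providers (in five role groups) were assigned to the
encounter, and which care-unit acuity levels (intermediate / intensive /
acute) the patient stayed in pre-operatively.

## Heterogeneous graph

Node types: one encounter type `ENC`, five provider subgroups
(`P_surgical`, `P_other_clin`, `P_nurse`, `P_tech`, `P_other`) and three
care-unit types (`C_intermediate`, `C_intensive`, `C_acute`). Edges are
undirected and only run encounter↔provider (weight 1 per distinct
assignment pair) and encounter↔unit (weight = number of pre-op stays in
that unit type). Unit *duration* is deliberately not an edge weight; it
enters as encounter features (per-unit pre-op hours), keeping adjacency
integer-valued. Only encounters carry an input feature matrix; providers
and care units are featureless.

## ie-HGCN classifier

Three stacked heterogeneous convolution layers. For a target type Ω with
previous-layer representations H:

- self projection: `Z_Ω = H_Ω W_{Ω−Ω}`;
- neighbor projection per adjacent type Γ: `Z_Γ = Â_{Ω−Γ} H_Γ W_{Γ−Ω}`,
  with `Â` the row-normalized adjacency (zero rows stay zero, so isolated
  nodes have a well-defined forward pass);
- type-level attention: per node, logit for relation r is
  `ELU([Z_r W_k^r ‖ Z_Ω W_q^Ω] · w_a^Ω)`; coefficients are a softmax over
  {self} ∪ neighbor relations, so they are non-negative and sum to one per
  node;
- update: `H'_Ω = ELU(Σ_r a_r ⊙ Z_r + b_Ω)`.

The trailing per-type bias `b_Ω` is a deliberate addition to the otherwise
bias-free update: without it, a neighbor type whose message is nearly
constant across nodes (e.g. a role group present on almost every
encounter) can be co-opted as a free intercept, which props up its
attention coefficient for reasons unrelated to outcome signal and muddies
meta-path rankings. With an explicit bias the constant component is
absorbed where it belongs.

The final encounter representation has two columns; a row softmax gives
outcome probabilities (for two classes this equals the sigmoid of the
logit difference). Training minimizes binary cross-entropy (probabilities
clamped at 1e-7) with Adam and L2 weight decay; the loss is mini-batched
over labeled training encounters (default batch 512) while message passing
always runs on the full graph — the setting is transductive and the graphs
are small, so neighbor sampling is unnecessary. Early stopping monitors
validation AUROC (default patience 10). Featureless node types receive
trainable per-node embedding vectors (width = first hidden dimension);
an identity one-hot mode exists for exactness tests. All randomness
(initialization, batch order, dropout masks) flows from a single seed, so
same-seed runs are bit-identical.

Gradients come from a small reverse-mode automatic-differentiation engine
(`medhg/_autodiff.py`) written for exactly the operations the layer needs;
its correctness is pinned by central finite-difference checks in the test
suite. Hyperparameter search (`iehgcn.tune`) offers seeded random search
and a tree-structured Parzen estimator over the model's grid (learning
rate and L2 in [1e-7, 1e-1] log-uniform, dropout [0, 0.8], hidden
dimension {32, 64, 128, 256}, attention dimension {8, 16, 32, 64, 128},
batch-norm on/off).

Dropout is applied to layer inputs and batch normalization (when enabled)
to pre-activations; in evaluation mode dropout is off and batch statistics
are used as-is (no running averages — the full graph is one batch here).

## Meta-path importance

After training, per-node attention coefficients are averaged per layer,
target type and relation. A meta-path is a chain of node types starting at
`ENC` (e.g. `ENC–C_acute–ENC`); its importance is the product of the mean
coefficients of its **edges**, read from the output layer inward — and of
nothing else. An alternative convention pads shorter paths with the
terminal type's self-relation coefficients on the remaining inner layers;
we rejected it after measuring both on identical trained models: the
padding factor is a property of the terminal type's own update, unrelated
to the path's channel, and it degraded planted-channel recovery severely
(4/10 vs 10/10 seeds on the acute-unit experiment). The length-0
feature-only path (`ENC` alone) is scored by the product of the encounter
type's self coefficients across all layers. Conservation is stated on
full relation-choice sequences: enumerating every sequence of {self,
neighbor} choices across the three layers yields importances summing to
exactly 1 (products of softmax-normalized means), which the tests assert.
Neighbor-relation means are taken over nodes that actually
have at least one neighbor of that type ("mean coefficient of the edges"):
a node with no technicians, say, has no technician edge, and its
coefficient for that relation is a softmax artefact rather than a
statement about technician influence. Self-relation means are taken over
all nodes. The per-(layer, target) means are renormalized to sum to one
after this masking so that the conservation property is preserved.

## Local attributions

`shapley_attribution` is a permutation-sampling Shapley estimator: each
permutation draws one background row and walks the features in permuted
order from the background value to the instance value, crediting each
feature with the prediction change. Per permutation the credits telescope
to f(instance) − f(background row), so the efficiency property holds
exactly in expectation and within Monte-Carlo error in realization (the
suite checks both, plus agreement within 0.01 with exact 2^6 enumeration
on a six-feature toy). `lime_explain` fits a weighted least-squares linear
surrogate on Gaussian perturbations with an exponential proximity kernel;
a rank-deficient design falls back to a tiny ridge penalty with a warning.
Both hold the graph fixed and perturb one encounter's feature row.

## Network-science baseline arm

The comparison arm mirrors common practice: a holistic provider–provider
graph (edge weight = number of shared encounters) and one directed
transfer graph per encounter (self-transitions are not drawn as edges;
re-entries still count as stays on the heterograph side). Per encounter,
provider metrics are computed on the induced subgraph of that encounter's
providers within the holistic graph. The battery is degree and weighted
degree, betweenness / closeness / eigenvector centrality, average
neighbor-degree connectivity, local clustering, HITS authority and
PageRank (damping 0.85, tolerance 1e-12), aggregated by max / min / mean /
median / IQR (linear-interpolation quartiles), plus density, node count
and total edge weight, with an explicit empty-graph flag column. On an
undirected graph the HITS authority vector coincides with the principal
adjacency eigenvector (a test pins this). Baselines: L2-penalized logistic
regression (Newton-CG, 500 iterations), a 3-hidden-layer ReLU MLP (Adam,
initial learning rate 1e-3, ≤200 iterations, mini-batch 200), and
gradient-boosted trees (λ₂ = 1, λ₁ = 0) with seeded random-search tuning
on validation AUROC over the standard grid. By default the provider graph
for feature extraction may be built holistically (as the comparison method
prescribes) or from training encounters only as a leakage guard.

## Cohort preprocessing

Continuous covariates outside plausibility ranges (BMI 10–80, height
120–220 cm, weight 30–300 kg, age 18–110 years, intervals ≥ 0) are treated
as missing. Missing continuous values are imputed with the training mean
and standardized by training mean / population SD; zero-variance or
all-missing columns are dropped with a warning. Missing or unseen
categorical levels map to an explicit `Unknown` one-hot level. The PLOS
threshold quantile uses linear interpolation between order statistics and
is computed on training rows by default (configurable). Splits are random
8:1:1 at encounter level; a patient-grouped mode keeps all encounters of a
patient in one split. Class rebalancing offers undersampling (negatives
reduced to the positive count, no duplicates) and oversampling (positives
duplicated with replacement up to the negative count), applied to training
ids only.

## Synthetic cohort generator

The generator emulates the schema and statistical structure of a
perioperative EHR extract so that every downstream stage is testable
without restricted data. Marginals are plausible rather than faithful:
age N(55.7, 18.0) clipped to [18, 100], 60.4% female, race/ethnicity at
64.7 / 12.8 / 4.6 / 17.8% (NHW / NHB / Hispanic / other), height by sex,
BMI N(28.5, 6) with weight derived so BMI ≡ weight/height², CCI
Poisson(1.6) capped at 16, ASA-PS on {1..5}, gamma-distributed procedure
intervals, ~1.33 encounters per patient (1 + Poisson). Provider role
counts per encounter are sampled independently per role
(surgical 1–3, other clinicians 1–3, nurses 1–4, technicians 0–2, other
0–2) from shared pools (80/120/200/90/60), which makes each role's
connectivity term identifiable and induces cross-encounter co-occurrence.
Pre-op unit stays are Poisson(1.5) over {intermediate, intensive, acute}
at 25/15/60% with gamma durations; per-unit hours are the sums of stay
durations, so the covariates and the transfer table agree.

Outcome risk is planted on the logit scale:
`logit P = baseline + Σ_j w_j z_j` with cohort-standardized covariate or
connectivity terms. Baselines are logit(0.25) for PLOS and logit(0.0532)
for 90-day mortality, with 59.4% of deaths in the first 30 days (offsets
uniform on [1, 30] and [31, 90], making the labels nested). Default effect
weights put moderate load on age, CCI, ASA-PS, acute-unit exposure and
team size — covariate-dependent *and* connectivity-dependent risk, as the
modeling framework assumes. PLOS is realized by sampling LOS below or
above a fixed 6-day threshold, so with zero effect weights the prevalence
is Bernoulli-exact and testable against a binomial band. Missingness is
MCAR at the robustness-experiment rates (BMI and height 4.3%, marital
status 2.11%, CCI 8.3%, ASA-PS 1.7%).

What the generator does **not** emulate: informative missingness,
temporal drift, coded diagnoses/procedures (categories are
pre-aggregated), inter-provider skill differences, or any real marginal
beyond the documented summary values. Passing tests therefore demonstrate
the *mechanics* of the pipeline and the recoverability of planted signals,
not clinical performance.

## Planted-signal recovery experiments

Two experiment families check that meta-path analysis finds a planted
channel: (a) risk loaded only on the technician-assignment count (weight
2.0 per SD), where the technician length-1 meta-path should rank first
among length-1 paths; (b) risk loaded only on acute-unit exposure, where
the acute-care path should rank in the top two. In (b) the pre-op
unit-hour columns are excluded from the encounter features, because the
premise is that risk reaches the model *only* through the graph channel.
The runs use 5,000-encounter cohorts, hidden width 16, attention width 8,
per-node embeddings of width 4 (narrow embeddings limit how much label
noise individual provider nodes can memorize, which otherwise props up
uninformative channels' attention), learning rate 1e-2, weight decay
1e-4, loss batches of 1,024, a fixed 90-epoch budget (no early stopping)
so that attention — which converges more slowly than accuracy — has
settled, and attention snapshot-averaging every 5 epochs from epoch 50,
which smooths stochastic-gradient noise out of the recorded coefficients.
These problem sizes keep a ten-seed experiment within a desktop-scale
compute budget.

## Evaluation statistics

AUROC is the tie-corrected Mann–Whitney statistic via midranks (checked
against all-pairs counting on random fixtures and invariant under monotone
score transforms); AUPRC is step-integrated average precision.
Thresholded metrics come from the confusion matrix at an explicit,
recorded threshold (default 0.5; Youden-J selection on validation data is
available and flagged). Zero-denominator ratios are reported as 0 and
flagged rather than silently dropped. DeLong's paired test uses
structural components computed by midranks; identical score vectors give
z = 0, p = 1 by convention. Bootstrap intervals are stratified percentile
intervals (cases and controls resampled separately), which keeps rare
outcome replicates two-class; the suite verifies ~95% nominal coverage at
true AUROC 0.8 and a null rejection rate within [2%, 9%] at the 5% level.

## Known limitations

- Transductive only: the model cannot score encounters outside the built
  graph.
- Attention-based importance is a heuristic: per-node attention can
  correlate strongly with a planted channel while the cross-relation mean
  ranking remains noisy at small scale; the recovery experiments
  quantify exactly this.
- Batch normalization uses batch statistics in evaluation mode (full-graph
  batches), which differs from running-average conventions.
- The TPE tuner is a minimal Parzen sampler, adequate for the small search
  budgets used here, not a general-purpose optimizer.
- The synthetic missingness is MCAR; imputation quality under informative
  missingness is untested.
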