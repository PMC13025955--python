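# medhg

Heterogeneous-graph modelling of **care coordination** for postoperative
risk prediction. The package links surgical hospital encounters to the
provider teams that treated them (five role groups) and to the care-unit
acuity levels they moved through (intermediate / intensive / acute),
trains an interpretable heterogeneous graph convolutional network
(ie-HGCN) on the resulting typed graph, and reads meta-path importances
out of its type-level attention — alongside a classical comparison arm of
network-science features fed to logistic regression, an MLP, and
gradient-boosted trees.

It is aimed at clinical-informatics researchers who want to study how
provider interactions and patient transfers add predictive signal for
three patient-safety outcomes: prolonged length of stay (PLOS, LOS above
the cohort's 75th percentile), 30-day mortality and 90-day mortality.
Because real perioperative EHR extracts are access-restricted, the
package ships a synthetic cohort generator with *planted* outcome effects
so every stage — graph building, training, explanation, evaluation — is
testable end to end against a known ground truth.

## The model

A heterogeneous graph 𝒢 = (𝒱, ℰ) has node types {ENC, 𝒫₁..𝒫₅, 𝒞₁..𝒞₃};
only encounters carry features H⁰ ∈ ℝ^{|ENC|×F}. Each of three layers
computes, per target type Ω:

    Z_Ω = H_Ω W_{Ω−Ω}                       (self)
    Z_Γ = Â_{Ω−Γ} H_Γ W_{Γ−Ω}              (per neighbor type Γ)
    e_r = ELU([Z_r W_k^r ‖ Z_Ω W_q^Ω] w_a^Ω)
    a   = softmax_r(e)                      (per node, over {self} ∪ Γ)
    H'_Ω = ELU(Σ_r a_r ⊙ Z_r + b_Ω)

with Â the row-normalized adjacency. The final encounter representation
(2 columns) passes through a softmax; training minimizes binary
cross-entropy with Adam and early stopping on validation AUROC. A
meta-path such as Encounter–AcuteCareUnit–Encounter is scored by the
product of the mean attention coefficients of its edges, read from the
output layer inward; ranked meta-paths name the relations that drive the
prediction. Permutation-sampling Shapley values and a LIME-style local
surrogate attribute predictions to individual encounter features.

## Worked example

```python
from medhg import (SyntheticConfig, generate_cohort, derive_outcomes,
                   split_indices, build_heterograph, IEHGCNClassifier,
                   mean_attention, metapath_importance,
                   classification_metrics)
from medhg.cohort_features import build_feature_matrix
import numpy as np

cfg = SyntheticConfig(n_patients=3000, seed=1)      # ~4,000 encounters
enc, asg, trf = generate_cohort(cfg)
splits = split_indices(enc, seed=1)                 # random 8:1:1
labels = derive_outcomes(enc, reference_rows=splits.train)
X, _ = build_feature_matrix(enc, splits.train)
graph = build_heterograph(enc, asg, trf, X)

y = labels.set_index("encounter_id")["plos"]
model = IEHGCNClassifier(hidden_dim=16, attn_dim=8, lr=1e-2,
                         batch_size=1024, max_epochs=60, patience=12,
                         weight_decay=1e-4, seed=1)
model.fit(graph, y, splits)

pos = {e: i for i, e in enumerate(graph.schema.ids["ENC"])}
test = np.array([pos[e] for e in splits.test])
p = model.predict_proba(graph)[:, 1]
m = classification_metrics(y.loc[splits.test].to_numpy(), p[test])
print(f"test AUROC {m.auroc:.3f}  recall {m.recall:.3f}")

for path in metapath_importance(mean_attention(model, graph))[:3]:
    print(f"{path.name:<28s} {path.importance:.3f}")
```

Output (seed 1):

```
test AUROC 0.738  recall 0.188
ENC-C_acute                  0.250
ENC-C_acute-ENC              0.223
ENC                          0.134
```

The test AUROC of ~0.74 reflects the planted risk model (moderate
covariate and connectivity effects at 25% prevalence, so even a perfect
model would sit well below 1.0). The two top meta-paths both run through
the acute care unit, matching the generator's default effect weights —
acute-unit hours and stays are the largest planted connectivity effects
for PLOS — with the encounter's own feature path third. Recall at the
default 0.5 threshold is low because the outcome is imbalanced;
`evalstats.youden_threshold` picks an operating point on validation data
instead.

The same pipeline runs from the shell:

```sh
medhg simulate --out run/tables --seed 1
medhg prepare  --in run/tables --out run/prep --seed 1
medhg run      --config experiment.yaml     # full orchestration + manifest
```

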