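# headachedx

Knowledge-driven, interpretable diagnosis support for **primary headache
disorders** (migraine, tension-type headache, cluster headache).

Diagnosing a primary headache means matching a patient's attack history —
duration, location, severity, pain character, associated symptoms — against
the diagnostic criteria of the ICHD rulebook. `headachedx` implements that
matching as a machine-learning pipeline in which the expert criteria are a
first-class, machine-readable object, used at every stage:

1. **Knowledge base** (`headachedx.kb`): each diagnosis is a *class
   concept*, a conjunction of restrictions over a discrete attribute
   vocabulary (`one-of`, `fixed`, `subset-of`, `at-least-m-of`). Concepts
   are rendered as RDF-style knowledge graphs and can count how far a
   patient *deviates* from a putative diagnosis (raising an alert for
   atypical presentations).
2. **Semantic codec** (`headachedx.codec`): per-attack journal records are
   aggregated into per-patient feature vectors and round-tripped losslessly
   to `(sample, has-attribute, value)` triple graphs (Turtle import/export).
3. **Synthetic cohorts** (`headachedx.synth`): constraint-consistent
   patients are sampled directly from the concepts, with a tunable feature
   noise rate — every experiment below runs without any external dataset.
4. **Class balancing** (`headachedx.balance`): cluster headache is an order
   of magnitude rarer than migraine (the package's default cohort mix is
   71.73 % / 21.67 % / 6.60 % over 849 patients). Five strategies are
   compared: none, class-balanced sample weights `N/(C·n_c)`, SMOTE,
   ADASYN, and **prior-knowledge over-sampling**, which tops minority
   classes up with samples drawn from the encoded criteria — needing no
   data at all.
5. **Similarity features** (`headachedx.kernels`): a fast
   **Weisfeiler–Lehman subtree kernel** for directed, edge-labeled graphs
   scores each patient graph against each concept graph,

   `k(g₁,g₂) = Σ_{t=0..h} ⟨φ_t(g₁), φ_t(g₂)⟩`,

   where `φ_t` counts vertex- and edge-rooted subtrees of depth `t`
   (iterative relabeling, exact string interning). Because concept graphs
   come from the knowledge base alone, nearest-concept prediction on these
   similarities is a **cold-start classifier** that uses no labeled sample.
   Data-driven RBF/cosine similarities to class centroids/medoids are the
   baseline counterpart.
6. **Interpretable trees** (`headachedx.pipeline`): CART over a transparent
   numeric encoding, optional reduced-error pruning on a held-out fraction,
   wrapper genetic-algorithm feature selection, exhaustive grid search.
7. **Evaluation** (`headachedx.evaluation`): stratified k-fold CV with
   strictly leakage-free per-fold fitting, accuracy and unweighted Cohen's
   `κ = (p_o − p_e)/(1 − p_e)`, per-class sensitivity/specificity, repeated
   simulations (mean ± SD) and paired bootstrap significance tests.

## Worked example

```python
import numpy as np
from headachedx import (
    CohortSpec, PipelineConfig, accuracy, cohen_kappa, fixture_knowledge_base,
    generate_cohort, nearest_class_predict, sensitivity_specificity,
    stratified_kfold_predict, wf_similarity_block,
)

kb = fixture_knowledge_base()                       # migraine/tension/cluster
ds = generate_cohort(kb, CohortSpec(n=849, noise_rate=0.05, seed=7))
print(ds.class_counts())
# {'migraine': 609, 'tension': 184, 'cluster': 56}

for tech in ("none", "prior-knowledge"):
    ps = stratified_kfold_predict(ds, 5, PipelineConfig(balance=tech, kb=kb), seed=7)
    sens, _ = sensitivity_specificity(ps, "cluster")
    print(tech, round(accuracy(ps), 4), round(cohen_kappa(ps), 4), round(sens, 4))
# none            0.9847 0.9645 0.9286
# prior-knowledge 0.9847 0.9648 0.9464

block = wf_similarity_block(ds, kb)                 # no labels used
pred = np.asarray(nearest_class_predict(block))
print(round(float(np.mean(pred == np.asarray(ds.labels))), 4))
# 0.9894
```

Reading: on one noisy 849-patient cohort, 5-fold CV accuracy is ~0.985
either way, but prior-knowledge balancing lifts the sensitivity for the
rare cluster class from 0.929 to 0.946 — exactly the failure mode class
imbalance causes. The cold-start classifier, which never sees a label,
still reaches 0.989.

A command-line interface mirrors the stages:

```sh
headachedx generate --n 849 --noise 0.05 --seed 7 --out cohort.csv
headachedx balance --method pk --in cohort.csv --out balanced.csv
headachedx features --metric wf --in cohort.csv --out with_sims.csv
headachedx train --in cohort.csv --balance pk --model-out rules.txt
headachedx simulate --sims 100 --out table.csv
```

`rules.txt` contains the tree as indented if/else rules over readable
tests such as `location=unilateral <= 0.5` and `duration <= 5.5`.

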