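# Methods

This note records the models, defaults and design choices behind
`headachedx`, in the spirit of a statistical software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The knowledge base

A diagnosis is modeled as a *class concept*: a conjunction of restrictions
over a vocabulary of discrete patient attributes. Four restriction kinds
cover the clauses that occur in headache criteria:

| kind             | applies to        | semantics                                   |
|------------------|-------------------|---------------------------------------------|
| `fixed`          | scalar attribute  | value equals the single allowed value       |
| `one-of`         | scalar attribute  | value lies in the allowed set               |
| `subset-of`      | set-valued attr.  | every member lies in the allowed set        |
| `at-least-m-of`  | set-valued attr.  | ≥ m of the listed members are present       |

`one-of`/`fixed` are deliberately confined to scalar attributes and
`subset-of`/`at-least-m-of` to set-valued ones; mixed semantics would make
the zero-deviation sampling contract (below) ambiguous. Restrictions are
conjunctive; criteria containing a genuine disjunction must be approximated
(see the fixture notes). The schema is plain YAML rather than OWL: the
restrictions used here need no description-logic reasoning, and a readable
file keeps the criteria auditable. Concept graphs contain one
`(concept, has-<attribute>, value)` triple per allowed value and **no**
typing triple, so they can be compared with unlabeled patient graphs.

**Deviation counting.** A sample's deviation count against a concept is the
number of violated restrictions; a missing attribute conservatively counts
as one violation. The alert threshold defaults to τ = 2 violations — "the
patient matches the putative diagnosis except on ≥ 2 criteria" is the point
at which a physician should re-examine the case. τ is configurable; no
published value exists for it.

**Bundled fixture.** The shipped knowledge base is a *simplified* ICHD-3
rendering written by the package authors as a test/demo fixture (it is not
a transcription of the rulebook): migraine = duration bucket H (4–72 h),
unilateral, pulsating, moderate/severe, ≥ 5 previous attacks, at least two
of {nausea, vomiting, photophobia, phonophobia}; tension-type = duration
F–I, bilateral, pressing, mild/moderate, symptoms within {photophobia,
pericranial tenderness}; cluster = duration E–F (15–180 min), orbital,
severe, ≥ 5 previous attacks, at least one cranial autonomic symptom. The
ICHD migraine clause "nausea and/or vomiting, **or** photophobia and
phonophobia" is a disjunction and is approximated conjunctively as
*at-least-2-of* the four symptoms. The three concepts are mutually
exclusive by construction (location alone separates them), which the
rule-recovery and cold-start tests rely on.

## Semantic codec

Per-attack records aggregate into per-patient vectors as follows: severity
from the rounded mean intensity (1–3 mild, 4–7 moderate, 8–10 severe);
duration bucket from the **median** attack duration (the robust choice; no
convention is published for which aggregate to use); modal location and
pain character with ties broken by declared domain order; per-symptom
occurrence probabilities thresholded at 0.5 into the binary schema flags
(raw probabilities are kept in `FeatureVector.meta` for data-driven
similarity features); attack count bucketized into the previous-attacks
categories. Encoding to graphs is one triple per (attribute, value) pair,
sample nodes named `sample-<row>`; decode is the exact inverse, and the
round trip is the subject of a dedicated identity test.

## Synthetic cohorts

`sample_from_concept` draws uniformly from each restriction's choices
(uniform value for `one-of`/`fixed`; for `at-least-m-of`, a uniform size in
m..|values| then a uniform subset of that size; an independent fair coin
per allowed member under `subset-of`) and uniformly over the full domain
for unrestricted attributes. Samples therefore have zero deviations by
construction — the same mechanism powers the prior-knowledge over-sampler.

Cohorts use largest-remainder rounding of `n · proportions` (for the
default 849-patient migbase mix this gives 609/184/56) and then corrupt
each sample independently: every categorical value is resampled uniformly
from its full domain with probability ε, every binary/set-membership flag
flips with probability ε. The default ε = 0.05 places baseline tree CV
accuracy in the high-nineties regime reported for real questionnaire data;
it is a stand-in for unknown real-world noise, not an estimate of it, and
passing tests on these cohorts demonstrates pipeline correctness, not
clinical performance. Real data features the generator does **not**
emulate: correlated symptom noise, label noise, missing answers, class
overlap beyond the shared duration buckets, and temporal attack structure.

Attack-log generation inverts the aggregation contract: durations fall
inside one allowed duration bucket's printed second-range, intensities
inside the target severity's band, the target location/character appear in
≥ 70 % of attacks (guaranteeing the mode) and target symptoms in ≥ 75 %
with spurious symptoms < 25 % (guaranteeing the 0.5 threshold). The
previous-attacks bucket is fixed by the caller's `n_attacks`.

## Balancing

All over-samplers preserve original rows verbatim (first in order) and top
every class up to the majority count. SMOTE/ADASYN operate on the numeric
encoding (ordinal codes in domain order, one-hot nominals, 0/1 flags) and
snap interpolations back to valid discrete cells: ordinals round-to-nearest
and clip, flags threshold at 0.5, one-hot blocks snap to the argmax with
exact ties resolved toward the base parent (SMOTE-NC-style behaviour
without an extra dependency; the published methods do not specify handling
of categorical attributes). Neighbour search is Euclidean on that encoding
with k = 5 by default; a single-sample minority class is duplicated with a
warning and k is clipped to n_c − 1. ADASYN allocates synthetics per
minority sample proportionally to the other-class fraction among its k
neighbours (largest-remainder rounding), falling back to uniform when all
neighbourhoods are pure. Class-balanced weights are `N/(C·n_c)`.

## Weisfeiler–Lehman kernel

The kernel operates on rooted, directed, edge-labeled multigraphs. The
subgraph within `d` hops of the root is extracted; vertex and edge labels
are then relabeled iteratively `h` times: an edge's new label combines its
old label with its target vertex's label, a vertex's new label combines its
old label with the lexicographically sorted multiset of its (new) out-edge
labels. After `t` rounds a vertex label identifies its unordered depth-`t`
out-subtree. The kernel is the sum over iterations 0..h of the dot product
of label-count vectors, normalized to `k₁₂/√(k₁₁k₂₂)` by default so values
are comparable across concepts of different sizes. Implementation choices:

- exact string interning in one dictionary shared across graphs (no rolling
  hash, so no collisions; at desk scale correctness beats speed);
- vertex and edge alphabets are tagged apart at iteration 0, so a vertex
  token never aliases a predicate token;
- every graph root receives the canonical label `root`, making sample and
  concept graphs comparable despite different node identifiers;
- defaults d = 2, h = 2: concept and sample graphs are depth-2 stars, so
  larger values only grow the dictionary without adding signal. No
  published defaults exist for d, h, γ or centroid-vs-medoid; all are
  configurable.
- an empty graph has similarity 0 (with a warning), and h = 0 reduces the
  kernel to a dot product of raw label counts.

The test suite checks the kernel exactly against an independent brute-force
subtree-enumeration oracle on random graphs, plus symmetry, unit normalized
self-similarity and spot-checked positive semidefiniteness.

Data-driven similarities use per-class centroids (default) or medoids (ties
to the lowest row index) on the same numeric encoding; RBF
`exp(−γ‖x−c‖²)` with γ defaulting to 1/dimension, cosine with 0 for zero
norms. Minimum-distance prediction takes the per-row argmax with ties —
including all-zero rows — resolved to the first class in canonical order
and logged.

## Trees, selection, tuning

The learner wraps scikit-learn's CART honouring criterion, depth,
min-samples-split and sample weights; because all features are threshold
tests on the transparent encoding, exported rules read as
`location=orbital > 0.5` etc. Unseen categorical values encode to all-zero
indicator blocks and route deterministically. *Error-based pruning*
withholds a stratified 20 % of the training rows, grows the tree on the
remainder, and collapses (bottom-up) every subtree whose replacement by a
majority leaf does not increase held-out error — this never increases
held-out error or node count. `max_depth = 0` yields a weighted-majority
stump; a single-class input yields a constant leaf with a warning.

The GA wrapper evolves binary attribute masks: population 50, 20
generations, tournament size 3, elitism 1, uniform crossover applied with
probability 0.5, per-bit mutation 1/n, fitness = 3-fold stratified CV
accuracy of the tree on the masked attributes (cached per mask). The best
mask ever evaluated is returned; ties prefer fewer features, then the
lexicographically smaller mask; the all-zero mask scores 0 and is never
returned. No published GA settings exist; these are conventional small-GA
defaults. Grid search enumerates the full product grid (default: criterion
× depth {3,5,7,∞} × min-split {2,5} × pruning on/off) and returns the first
argmax of mean stratified-CV accuracy.

## Evaluation protocol

Out-of-fold predictions come from stratified k-fold CV (k = 5, reduced
with a warning when a class is smaller than k). Everything that learns from
data — over-sampling, class vectors, the tree — is fitted on training folds
only; the WL similarities to concept graphs depend only on the knowledge
base and are leakage-free by construction. This is deliberately stricter
than balancing the full dataset before cross-validation, which would let
synthetic copies of test-fold information into training.

Metrics: accuracy; unweighted Cohen's κ with p_o shared with the accuracy
computation and κ defined as 0 (with a warning) in the degenerate p_e = 1
case; one-vs-rest sensitivity/specificity per class, with zero-denominator
cases reported as 0-with-warning so report shapes stay rectangular.

Repeated simulations re-seed the fold split with `seed + s` (and regenerate
the cohort when a generator is supplied — both "fixed data, new folds" and
"fresh cohorts" modes are supported, since either interpretation of a
repeated-simulation protocol is defensible). Reports carry means ± SD per
technique and render tables with `+`/`−` marks against the baseline.

The bootstrap test is **paired** on per-simulation differences: resample
the differences with replacement (default 10,000 replicates), and take the
two-sided p as the add-one-smoothed fraction of resampled means at least as
far from the observed mean as the observed mean is from zero. This
shift-to-null construction is symmetric under swapping the two techniques
and calibrates to ~5 % rejections under a true null (verified over 500
simulated nulls). α = 0.05.

## Problem sizes

The shipped experiments run at the package's native scale: cohorts of 849
patients (the canonical migbase size), 100 simulations × 5 techniques ×
5 folds for the balancing comparison, 200 random graphs for the kernel
oracle check, 500 repeats for bootstrap calibration, 10,000 bootstrap
replicates for the headline comparison. These sizes keep the full suite and
the acceptance script in the single-digit-minutes range on one CPU.

## Known limitations

- The fixture criteria are simplified and mutually exclusive; real ICHD
  criteria overlap and contain disjunctions the restriction vocabulary can
  only approximate.
- The noise model is independent per feature; correlated or systematic
  reporting errors will degrade all methods differently than tested.
- Only the decision-tree learner is specified; other classifiers can be
  plugged in at the `fit_tree` seam but are out of scope.
- `headache_days` aggregation from attack logs is heuristic: the printed
  bucket boundaries of the questionnaire schema overlap, so the mapping
  picks the first applicable bucket.
- Prior-knowledge over-sampling is exactly as good as the encoded
  knowledge; a wrong restriction produces confidently wrong synthetic
  minorities.
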