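# Methods

`lgibtree` implements a case-identification pipeline for lower
gastrointestinal bleeding (LGIB) in coded hospital administrative data:
cost-sensitive classification trees over ICD-9-CM indicator features, three
fixed validated decision rules shipped as data, the evaluation arithmetic
around them, and a calibrated synthetic cohort generator that stands in for
the (non-public) hospital records.

## The classification model

Each admission contributes binary indicator features: one per
`(field, code)` pair, where the field is one of principal diagnosis,
secondary diagnosis, principal procedure, secondary procedure. Codes are
opaque strings compared exactly after trimming — `578.1` and `578.10` are
distinct — because the decision rules depend on exact coded values and
administrative systems print codes with mixed precision.

**Altered priors.** LGIB prevalence in a general-medicine cohort is ~4%, so
an unweighted tree maximizes accuracy by sacrificing sensitivity. A prior
LGIB probability π is converted into per-class weights

    w_case / w_noncase = [π / (1 − π)] / [N_case / N_noncase],

with `w_noncase ≡ 1`, so that the *weighted* case fraction at the root node
equals π. The weights enter every node proportion, impurity and
misclassification risk. This is the standard equivalence between altered
priors and asymmetric misclassification costs: with the derivation cohort's
class counts (297 cases, 6,677 non-cases), π = 0.20 makes a case weigh
≈5.62× (≈6×) a non-case and π = 0.70 makes it weigh ≈52.5× (≈52×).

**Impurity and splitting.** Node impurity is the two-class Gini index
`i(t) = p(1 − p)` with `p` the weighted case proportion (no factor 2; the
argmax is unaffected). A split s of node t into t_L, t_R is scored by

    Δi(s, t) = i(t) − p_L · i(t_L) − p_R · i(t_R),

where p_L, p_R are the children's *weighted* shares of the parent's mass.
The learner searches every `(field, code)` indicator present in the node,
requires both children to hold at least `min_node` **raw** observations
(default 7 — the stopping size is stated in observations, not weighted
mass), and requires Δi > 0. Exact Δi ties break deterministically: earlier
field in the order (principal dx, secondary dx, principal proc, secondary
proc), then lexicographically smaller code. The search is vectorized over a
sparse CSR indicator matrix, so a full cohort scan is O(nnz).

**Pruning.** Cost-complexity (weakest-link) pruning on the weighted
misclassification risk, normalized by the root's total weight, yields the
nested subtree/α sequence; candidate penalties are geometric midpoints of
consecutive α's. Ten (configurable) seeded, class-stratified
cross-validation folds each grow and prune their own tree; the subtree at
the risk-minimizing penalty is returned, ties going to the larger penalty
(smaller subtree). A one-standard-error variant is available via
`selection="1se"`; minimum-CV is the default since the selection rule used
originally is not recorded. Exact reproduction of the published trees from
raw records is not claimed (the records are unavailable); the learner is
instead validated by an exhaustive-search oracle on small cohorts, an
independent reference implementation cross-check, and its ability to
rediscover principal 562.12 as the root split on calibrated synthetic
cohorts.

**Flattening.** A fitted tree becomes an ordered first-match rule list:
depth-first, positive branch first, one clause per LGIB-predicting leaf,
default non-LGIB. Negative path literals implied by the failure of an
earlier single-test clause are dropped, so a single-branch tree — the shape
the validated rules have, since a record has only one principal diagnosis —
flattens to plain IF/ELSE-IF code tests. General trees keep conjunction
clauses; tree and flattened list agree on every admission (property-tested).

Predicted class at a node is the weighted majority; an exact tie predicts
non-LGIB (conservative for a low-prevalence target).

## The shipped rules

Three rules are embedded as JSON data files (auditable, replaceable, row
order contractual): the 36-code screening OR-rule over both diagnosis
fields (72 clauses), the 11-clause high-specificity rule (grown at π =
0.20), and the 14-clause balanced rule (π = 0.70), the latter two with
their per-clause correct/incorrect derivation tallies and default-row
tallies attached. Procedure-code clauses (colonoscopy, 45.23) match exactly
like diagnosis clauses.

## Evaluation arithmetic

`evaluate` classifies every labeled admission, tallies TP/FP/TN/FN (which
always sum to the cohort size) plus per-clause correct/incorrect counts,
and derives sensitivity, specificity, PPV and NPV. Ratios with zero
denominators are reported as undefined with a warning, never silently 0.
Percentages print to one decimal, round-half-up; raw ratios are retained.

The ROC-over-priors sweep grows, prunes, flattens and evaluates one tree
per grid value, scoring by resubstitution on the supplied cohort (matching
how derivation-cohort operating characteristics are conventionally
reported); a holdout cohort can be supplied instead. The default grid is
0.05 to 0.95 in steps of 0.05 — the original grid is unreported, so this is
a stand-in.

The unscreened-case adjustment treats an assumed LGIB rate r among
never-screened admissions (upper bound 0.2%, ten times a published
population hospitalization rate) as `r × n` additional false negatives:
adjusted sensitivity = TP / (TP + FN + r·n), specificity unchanged. The
extra term is kept fractional (13.948 for n = 6,974), which reproduces the
published 82.3 / 88.1 / 95.5 one-decimal figures; rounding it to 14 would
too.

## Synthetic cohorts

No public record-level data exist, so the package generates its own in two
modes.

**Exact fixtures** rebuild a cohort from a rule's printed per-clause
tallies: clause k contributes `n_correct` LGIB and `n_incorrect` non-LGIB
admissions carrying exactly clause k's code, with filler codes elsewhere,
so no earlier clause can fire; the default row contributes label-only
admissions. Replaying the rule reproduces every printed cell identically,
and both shipped tally tables sum to 6,974 admissions with 297 LGIB. In the
real cohort clause match-sets overlapped (e.g. some principal-211.3
patients matched an earlier secondary-code clause); only the per-clause
tallies are contractual, so the disjoint construction is valid and
simplest. The screening fixture similarly plants one screening code per
screened admission (768 screened, 297 LGIB, 6,206 filler-only),
apportioning admissions over the per-code principal/secondary slots by
largest remainder on each slot's published class tallies; per-code
overlap structure is not reproduced there either.

**Stochastic cohorts** are drawn from a `GeneratorConfig` listing, per
`(field, code)` slot, a marginal rate and a conditional LGIB probability,
plus cohort-level calibration. The default config uses the published
derivation-cohort values: per-slot rates = per-code counts / 6,974,
conditional probabilities = the printed percentages, screened fraction
768/6,974, prevalence 297/6,974, secondary-diagnosis count mean 8.0 / SD 4.6
(negative binomial matched by moments, truncated at the 30-slot cap;
Poisson when the variance would not exceed the mean), principal-procedure
rate 5,068/6,974, secondary-procedure count mean 1.2 / SD 1.9, and
synthetic filler pools (`FDX###`, `FPR###`) that can never collide with a
real rule code.

A design point worth recording: the published per-code tallies count a
patient once per code carried, so multi-code patients are double counted —
the 768 screened patients hold 1,017 code-slots, and the 297 LGIB patients
hold ≈457 LGIB code-slots. A generator that sampled each slot independently
at its marginal rate and assigned the label from the highest-priority
carried code would therefore inflate the screened fraction to ≈13.6% and
prevalence to ≈6.5%. The sampler instead factorizes retrospectively:

1. screened ~ Bernoulli(768/6,974);
2. for screened admissions, LGIB ~ Bernoulli(297/768);
3. a bundle of `1 + Poisson(λ_class)` distinct slots is drawn from
   class-conditional slot weights (cases: rate × p; non-cases:
   rate × (1 − p)), with λ_class matching the class's expected
   slots-per-patient; at most one principal-diagnosis and one
   principal-procedure slot is kept;
4. unscreened admissions are LGIB at a configurable rate (default 0);
5. signal-free decoration (filler secondaries up to the drawn target count,
   procedures) is added.

In expectation this reproduces the per-code marginal counts, the per-code
conditional LGIB rates, the screened fraction and the prevalence
simultaneously (up to small deductions from bundle deduplication), which no
overlap-agnostic independence model can do. The bundle-size law and the
within-class slot independence are modeling choices, not facts about the
source data — the true joint distribution of screening codes is unreported.
Consequently, passing stochastic tests show the pipeline behaves correctly
under these calibrated conditions, not that the generator matches the real
hospital's code co-occurrence structure. Demographic covariates (age, sex,
mortality) carry no signal for any tree and are not generated.

`config_from_rule_counts` derives a config from a rule's own tallies (one
slot per clause, rate = row total / 6,974, conditional probability =
correct / row total, default-row LGIB rate for the unscreened), giving
cohorts on which the rule's expected operating point equals its derivation
value. This is how held-out validation is emulated as a stochastic
property: the real validation records (and their published 80.1/95.8 and
87.8/90.9 operating points) cannot be recomputed, so the test contract is
agreement within ±5 percentage points on an independent seeded draw.

## Numerical choices and problem sizes

- Delta ties and risk ties use an absolute tolerance of 1e-12.
- Fold assignment is seeded (`numpy.random.default_rng`) and stratified by
  class; all sampler randomness flows from one generator per call.
- The prevalence and per-code calibration tests use 3 Monte-Carlo standard
  deviations at the realized sample size.
- Test problem sizes: exhaustive-oracle checks run on cohorts of ≤200
  records; tree/rule equivalence and ROC sweeps use synthetic cohorts of
  800–1,500; the 50-replicate root-split study draws full-size (6,974)
  cohorts and inspects the root split via `max_depth=2`, which leaves the
  root split unchanged while skipping irrelevant deep growth.

## Known limitations

- Rules are ICD-9-CM only; no ICD-10 mapping, no code-dictionary validation.
- No surrogate splits or missing-data handling beyond absence-is-false; no
  multiclass targets; no boosting or ensembles (interpretable single-branch
  rules are the point).
- The generator's independence and bundle assumptions are a stand-in for an
  unreported joint code distribution; secondary-diagnosis volume drift
  (e.g. coding-system upgrades raising the mean from 8.0 to 10.6) is
  expressible via the config but not modeled by default.
- Duplicate secondary codes within one record collapse to set membership;
  slot multiplicity is assumed to carry no information.
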