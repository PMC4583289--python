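# lgibtree

Identify hospitalizations for **lower gastrointestinal bleeding (LGIB)** in
coded hospital administrative data — without chart review.

There is no accepted ICD-9-CM standard for LGIB, a common cause of acute
admission whose costs and outcomes are hard to study at scale. This package
provides, for epidemiologists and health-services researchers working with
claims/administrative records:

- the three **validated decision rules** for LGIB as machine-readable,
  auditable data: a 36-code screening OR-rule (100% sensitivity by design),
  a high-specificity rule (derivation: 86.2% sensitivity / 96.7%
  specificity), and a balanced rule (92.3% / 92.3%) — each an ordered list
  of IF/ELSE-IF tests on single diagnosis or procedure codes;
- a from-scratch **cost-sensitive classification-tree learner** (CART-style)
  over sparse `(field, code)` indicator features, so the same methodology
  can be re-run or applied to other phenotypes: altered class priors
  π ⇒ per-class weights `w_case/w_noncase = [π/(1−π)]/[N_case/N_noncase]`,
  Gini impurity `i(t) = p(1−p)` on weighted proportions, split score
  `Δi(s,t) = i(t) − p_L i(t_L) − p_R i(t_R)`, minimum terminal size 7,
  cost-complexity pruning with seeded stratified 10-fold CV, and flattening
  of single-branch trees into plain rule lists;
- **evaluation arithmetic**: confusion counts with per-clause tallies,
  sensitivity/specificity/PPV/NPV, an ROC sweep over priors, and the
  conservative unscreened-case sensitivity adjustment;
- a **synthetic cohort generator** (exact tally-replaying fixtures and
  seeded stochastic cohorts calibrated to the published derivation-cohort
  characteristics), since the original hospital records are not public.

## Worked example

Rebuild the high-specificity rule's derivation cohort from its per-clause
tallies and score the rule on it:

```python
import lgibtree as lt

rule = lt.high_specificity_rule()          # 11 ordered clauses, default Not LGIB
cohort = lt.fixture_cohort(rule)           # 6,974 admissions, 297 with LGIB
counts, metrics = lt.evaluate(rule, cohort)
print(counts.tp, counts.fp, counts.tn, counts.fn)
print(lt.to_percent(metrics.sensitivity), lt.to_percent(metrics.specificity),
      lt.to_percent(metrics.ppv), lt.to_percent(metrics.npv))
```

prints

```
256 219 6458 41
86.2 96.7 53.9 99.4
```

— i.e. on the derivation cohort the rule finds 256 of the 297
chart-confirmed bleeds (86.2% sensitivity), mislabels 219 of 6,677
non-bleeds (96.7% specificity), and a positive call is right 53.9% of the
time. Growing a tree on a calibrated synthetic cohort rediscovers the same
leading signal:

```python
cohort = lt.sample_cohort(lt.default_generator_config(), seed=1)
tree = lt.grow_tree(cohort, pi=0.20)       # cases weigh ~6x non-cases
print(tree.root.feature)
```

```
(<Field.PRINCIPAL_DX: 'principal_dx'>, '562.12')
```

(principal diagnosis 562.12, diverticulosis of colon with hemorrhage — the
single best discriminator). The same workflows are scriptable from the
shell via the `lgibtree` CLI (`generate`, `fit`, `evaluate`, `roc`,
`adjust`); try `lgibtree evaluate table3 cohort.csv`.

## Data format

Cohorts are CSV files with header
`id,principal_dx,secondary_dx,principal_proc,secondary_proc,lgib`;
multi-code cells are `;`-separated (at most 30 codes each), and `lgib` is
`1`/`0`/empty for case/non-case/unreviewed. Rules serialize to JSON (see
`src/lgibtree/data/`). See `docs/methods.md` for the model, calibration and
design decisions.
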