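# Methods

## The analysis

`menutargets` audits restaurant menu items against the UK Government's
voluntary reduction targets for sugar, salt, and calories. Each target is a
category-specific ceiling: sugar targets apply per 100 g, calorie targets
per serving, and salt targets per 100 g or per serving depending on the
target table row (out-of-home rows are typically per serving,
retailer/manufacturer rows per 100 g). An item *meets* its target when its
value is **equal to or lower than** the target value; adherence for a
group is the met count divided by the number of *eligible* items (those
matched to a category for that programme), never by the full menu.

The pipeline is: exclusion → nutrient completion → target assignment →
adherence evaluation → descriptive summaries, with two families of
sensitivity re-runs.

## Nutrient completion

Menu nutrition panels arrive incomplete: energy sometimes only in kJ, salt
sometimes only as sodium, and roughly half of items report only one basis
(per 100 g or per serving) with no serving weight. Completion is purely
deterministic label arithmetic, applied in a fixed order:

1. **Exclusion.** An item is dropped only if kcal, salt and sugar are all
   missing on both bases and none is derivable (kJ ⇒ kcal; sodium ⇒ salt;
   a full protein/fat/carbohydrate panel ⇒ kcal).
2. **Unit conversions**, per basis: `kcal = kJ/4.184` (and vice versa);
   `sodium (mg) = salt (g)·1000/2.5` (and vice versa); the Atwater-style
   fallback `kcal = 4·protein + 9·fat + 3.75·carb` only when both kcal and
   kJ are absent. Conversions run before basis scaling so a kJ-only item
   can still seed serving-size derivation.
3. **Basis scaling** with serving size S (g): `per100g = per_serving/(S/100)`,
   `per_serving = (S/100)·per100g`, and `S = (100/per100g)·per_serving`
   when S is missing but some nutrient is present on both bases. Serving
   derivation tries nutrients in the order kcal, salt, sugar, carb, fat,
   protein — kcal first because it is the most consistently reported
   field. When a nutrient present on both bases disagrees with the serving
   size by more than 5%, a warning is logged and reported values are kept.
4. **Subcategory fallback.** Items still without a serving size receive
   their subcategory's mean serving size (lower/upper quartile in the
   sensitivity runs), computed only over serving sizes that were reported
   or derived — imputed sizes never feed back into the statistics.
   Quartiles use linear interpolation between order statistics; this
   definition is shared by every quantile in the package.

Reported values are never overwritten; every filled field is tagged
`derived` or `subcategory_imputed` in a per-field provenance map, which
downstream locality checks rely on. The pipeline is idempotent. The
energy fallback is applied on whichever basis carries all three macros.
The code keeps the formulas in their printed arithmetic form
(`salt·1000/2.5`, not `salt·400`) so independent recomputations agree bit
for bit.

## Target assignment

Category matching is rule-driven configuration: ordered rules per
programme match on subcategory and/or an explicit per-item category label,
first match wins. The real-world judgement of which guidance category an
item belongs to is an input (the label column / rule file), not something
this package infers from item names. The hierarchy is mechanical:

* sugar targets are matched before calorie targets, so no item ever holds
  both (the sugar programme predates the calorie programme);
* out-of-home salt targets are matched before retailer/manufacturer ones.

This yields exactly four eligibility states per item: none, one programme,
salt + calorie, or salt + sugar.

**Pizzas.** Per-serving reporting conventions differ by restaurant, so the
package fixes one: the `per_serving` panel is the restaurant's own
reported serving; when the restaurant declares a serving count, that
serving is a single person's share, otherwise it is the whole pizza.
Calorie adherence for whole-pizza data divides by an assumed serving
count: the declared count when present, 1 for Italian-style pizzas, 3 for
large and 4 for extra-large takeaway pizzas, 1 for small/medium. A sharing
pizza is "large or above, or ≥ 11.5 inches" (either suffices). A takeaway
pizza with no declared count, size label, or diameter is unassignable for
the calorie target and leaves that denominator only, with an audit entry.
Descriptive per-serving summaries always use the restaurant's own
convention, without the serving-count division.

## Adherence accounting

Counts are exact integers; proportions become rounded percentages only at
report time. An item missing the required value for one programme (e.g. no
sugar anywhere) is dropped from that programme's denominator only, with an
audit entry. "All applicable" is true iff the item met every programme it
is eligible for; items eligible for none are excluded from that
denominator. Denominator conservation across groupings (restaurant,
subcategory, restaurant type) is asserted on every aggregation call.

## Descriptive summaries

Mean, median and sample SD (n−1; reported as 0 for single-item groups) of
kcal, salt, sugar and fat, on three bases: per 100 g, per reported
serving, and per subcategory-average serving (every item rescaled to its
subcategory's mean serving size, `per100g·mean_serving/100`, as a parallel
column family). The reported-serving basis includes values obtained via
imputed serving sizes — this is what lets the quartile sensitivity shift
per-serving means. Collected values are sorted before statistics are
computed so summaries are bitwise invariant to input row order.
Five-number summaries (min/LQ/median/UQ/max) support box-plot style
distribution exports.

## Sensitivity analyses

* **exclude_lto** — limited-time-offer items dropped before analysis; the
  whole pipeline (including serving statistics) is recomputed on the
  filtered corpus.
* **serving_lq / serving_uq** — the imputation statistic switches from the
  subcategory mean to the lower/upper quartile. These runs reuse the
  primary run's serving statistics, so the perturbation is confined to the
  imputation step; by provenance tracing, outputs can change only through
  items whose serving size was imputed.

Diff tables report primary vs perturbed values per overall metric, and a
three-strategy comparison table (six nutrient-basis rows, four adherence
rows) summarises the quartile family.

## The synthetic corpus generator

Real scraped menu corpora are not redistributable, so the package ships a
seeded generator whose defaults mirror the structure such an audit faces:
21 chains across five restaurant types (4 burger, 2 chicken, 4 pizza, 5
sandwich, 6 other-mains), item counts per restaurant from a truncated
normal (mean 148, clipped to [40, 330]), and type-specific subcategory
profiles over the 12 subcategories. Per-100 g kcal, salt, sugar and fat
are log-normal per subcategory (medians chosen to be nutritionally
plausible — e.g. desserts ~380 kcal and 32 g sugar per 100 g, sauces the
saltiest at ~2 g per 100 g); protein and carbohydrate are then solved so
the macro-implied energy is within ±3% of the drawn kcal (a labelling-
rounding factor), with carbohydrate ≥ sugar. Serving sizes are truncated
normals per subcategory; pizzas get size labels, diameters, Italian or
takeaway style, and (for half the pizza chains) declared serving counts.

Masking reproduces the observed missingness pattern: with probability
0.526 an item loses its serving size and one whole basis (the rate
observed in a real 3,099-item audit, 1630/3099); otherwise it may lose one basis while keeping the serving
size (losslessly restorable); 5% of items are kJ-only for energy and 5%
sodium-only for salt. A rate-0-by-default "unusable" pattern strips all
three nutrients of interest to exercise the exclusion rule. After masking,
one serving size per subcategory is restored if masking removed them all,
so the imputation precondition (at least one known serving size per
subcategory) always holds.

**Target placement.** For each target category, the designed met fraction
f determines k = round(f·n) over the eligible items' true compared values,
and the target is placed at the midpoint between the k-th and (k+1)-th
order statistics. Exactly k items meet it, and the gap to the boundary is
large relative to the ~1-ulp float noise that kJ→kcal and sodium→salt
round-trips can introduce, so ground-truth recovery is sharp rather than
statistical. Boundary inclusivity (equality meets; +ε fails) is exercised
separately with hand-built fixtures. Default designed fractions are 0.61
(calorie), 0.58 (salt) and 0.36 (sugar).

What the generator does *not* emulate: real restaurants' actual nutrient
values, item-name semantics, correlated missingness within restaurants,
sales weighting, or reporting errors (e.g. systematic under-reporting by a
chain). Passing tests therefore demonstrate the *mechanics* — completion,
hierarchy, denominators, locality — not calibration to any real market.

## Numerical choices and degenerate cases

* Quantiles: linear interpolation everywhere (configurably documented,
  shared between serving stats and distribution exports).
* Sample SD with n−1; 0 for n = 1.
* Unit-pair identities validated to relative tolerance 1e-6.
* Zero is a legitimate nutrient value and is distinct from missing
  (empty cell) end-to-end; a zero value meets any positive target.
* Duplicate (restaurant, item) rows are kept with a warning —
  de-duplication is an explicit upstream step, not silent behaviour.
* Empty target tables are allowed (everything ineligible, with a warning);
  empty subcategories in serving statistics are an error naming the
  subcategory.

## Problem sizes used in the shipped checks

The acceptance checks run the full pipeline on one study-scale corpus
(~3,000–4,000 items, 21 restaurants, serving-size missingness ≈ 0.53) and
its lossless twin, plus small hand-built fixtures; the whole suite
completes in well under a minute on one CPU.

## Known limitations

* Category judgement is out of scope by design: garbage-in rule files
  yield garbage assignments (the lint subcommand catches structural
  mistakes only).
* Salt targets for pizzas are compared on the target row's basis; per-slice
  salt conventions are expressible through the target table, not special-
  cased in code.
* Adherence treats each menu row as one item — size variants listed as
  separate rows count separately, and no sales weighting is applied.
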