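# menutargets

Audit restaurant menu nutrition against the UK Government's voluntary
sugar, salt and calorie reduction targets.

The UK reduction programmes set category-specific ceilings for foods sold
out of home: sugar targets per 100 g, calorie targets per serving, and
salt targets per 100 g or per serving depending on whether the
out-of-home or retailer/manufacturer table applies. Assessing a menu
against them is fiddly in practice: menus report nutrients per 100 g
and/or per serving, often without a serving weight, sometimes with energy
only in kJ or salt only as sodium; an item may be eligible for one, two or
none of the programmes (never both sugar and calorie targets); and pizza
serving conventions vary by restaurant. `menutargets` is a tested pipeline
for exactly this audit, aimed at nutrition-epidemiology and food-policy
researchers working with scraped or exported menu tables.

The core machinery:

* **Nutrient completion** — deterministic label arithmetic
  (`kcal = kJ/4.184`; `kcal = 4·protein + 9·fat + 3.75·carb` as fallback;
  `sodium (mg) = salt (g)·1000/2.5`; basis scaling
  `per100g = per_serving/(S/100)` with serving weight `S`), plus a
  subcategory-mean fallback when `S` is underivable. Every filled field
  carries provenance (`reported` / `derived` / `subcategory_imputed`);
  reported values are never overwritten.
* **Hierarchical target assignment** — sugar before calorie (an item never
  holds both), out-of-home salt before retailer/manufacturer salt; pizza
  serving-count conventions for the calorie target.
* **Boundary-inclusive adherence** — an item meets its target when its
  value ≤ the target value; denominators count eligible items only, and
  "all applicable" means meeting every programme the item is eligible for.
* **Descriptive summaries** — mean/median/SD of kcal, salt, sugar, fat per
  group on three bases (per 100 g, per reported serving, per
  subcategory-average serving), plus box-plot-ready five-number summaries.
* **Sensitivity analyses** — limited-time-offer exclusion, and
  lower/upper-quartile serving-size imputation in place of the mean.
* **Synthetic corpora with exact ground truth** — a seeded generator
  produces realistic multi-restaurant menus with the observed missingness
  patterns and places target values so that designed adherence fractions
  are realised exactly, making every downstream number testable.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import menutargets as mt

corpus = mt.generate(mt.SyntheticConfig(seed=42))      # ~3,300 items, 21 chains
result = mt.run_pipeline(corpus.items, corpus.category_map, corpus.group_map)

print("items analysed:", len(result.items))
print("serving sizes imputed:", result.report.n_serving_size_imputed)
for programme, (n_met, n_elig) in result.overall_adherence().items():
    print(f"{programme:15s} {n_met:5d}/{n_elig:<5d} ({100*n_met/n_elig:.0f}%)")
print("mean kcal per 100 g:", round(result.overall_mean("kcal", "per100g"), 1))
print("mean salt per serving:", round(result.overall_mean("salt", "reported_serving"), 2))
```

prints

```
items analysed: 3300
serving sizes imputed: 1719
all_applicable   1164/3027  (38%)
calorie          1372/2321  (59%)
salt             1384/2452  (56%)
sugar             223/575   (39%)
mean kcal per 100 g: 247.7
mean salt per serving: 2.81
```

Of 3,300 generated items, 1,719 lacked a serving weight and received their
subcategory's mean; 2,321 items matched a calorie target category and
1,372 of those (59%) were at or below their target. The generator designed
61% calorie / 58% salt / 36% sugar adherence into the corpus; the engine's
figures differ only through the items whose serving size had to be
imputed (run the same example with
`mt.generate(mt.lossless_config(seed=42))` and the designed fractions are
recovered *exactly*).

The same analysis is available from a shell:

```bash
menutargets simulate --out-dir corpus --seed 42
menutargets run --menu corpus/menu.csv --targets corpus/targets.csv \
    --category-map corpus/category_map.yaml --group-map corpus/group_map.yaml \
    --out-dir results
menutargets sensitivity --menu corpus/menu.csv --targets corpus/targets.csv \
    --category-map corpus/category_map.yaml --group-map corpus/group_map.yaml \
    --out-dir results/sensitivity
menutargets lint --targets corpus/targets.csv --category-map corpus/category_map.yaml
```

`run` writes adherence tables (counts, eligible denominators and percents
per restaurant, subcategory, restaurant type and overall), nutrient
summaries on all three bases, distribution tables, a completion audit
trail, and run metadata with content hashes; identical inputs and seed
reproduce identical outputs byte for byte.

## Input formats

Menu tables are UTF-8 CSV/TSV with canonical columns (`kcal_100g`,
`salt_serv`, `serving_size_g`, …); a YAML dialect file maps arbitrary
source headers onto them so heterogeneous exports need no code changes.
Empty cells are *missing*, never zero. Target tables (CSV or YAML) carry
programme, category, nutrient, basis and value per row; category rules and
restaurant/subcategory group maps are YAML. `menutargets lint` validates
all three before a run.

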