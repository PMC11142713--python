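# snakerisk

Ensemble species-distribution modelling and incidence estimation for
snakebite, built for epidemiologists and spatial ecologists who want to go
from predictor rasters and hospital case records to (1) occurrence-probability
maps, (2) population-scaled incidence totals under current and future
climate/population scenarios, and (3) demographic and seasonal case
summaries — with every stage testable on synthetic data of known truth.

Snakebite is a neglected tropical disease whose burden is chronically
under-recorded: hospital registers see only the victims who reach them. The
approach implemented here treats snakebite occurrence as a species
distribution problem — bite locations are "presence" records, random points
in the study area are "background" — and couples the resulting suitability
surface with a regression-based risk score multiplied by a human-population
raster to estimate how many bites a region could see per year.

## Model core

**Occurrence models.** Five presence/background models share one
`fit`/`predict` contract, each scoring cells in [0, 1]:

- *climate envelope* (Bioclim-style): per layer v, `p_v(x) = #(train ≤ x)/n`,
  similarity `s_v = 1 − |2 p_v − 1|`, score `min_v s_v`, 0 outside the
  training range;
- *binomial GLM*: logistic regression `P(y=1|x) = expit(β₀ + βᵀx)` fitted by
  IRLS (tolerance 1e−8, ≤50 iterations, Wald standard errors);
- *Gaussian GLM*: ordinary least squares on per-cell case counts, map
  predictions min–max normalized to [0, 1];
- *random forest*: bagged Gini decision trees (default 500 trees,
  `mtry = ⌊√p⌋`), score = fraction of trees voting presence;
- *maxent-like*: a ridge-penalized presence/background logistic regression
  (penalty λ on slopes only), the glass-box surrogate for maximum-entropy
  modelling.

**Ensemble.** The consensus map is a cellwise weighted mean of the five model
maps with weights ∝ max(AUC − 0.5, 0) on held-out test points (20% of a
stratified split); AUC is the Mann–Whitney pair statistic.

**Incidence.** A backward-elimination regression (drop the least significant
term until all p ≤ α = 0.05) relates presence/background labels to the
standardized predictors plus human population. Its linear score
`B₀ + Σ Bⱼ xⱼ`, clamped to [0, 1] (or passed through a logistic link for the
binomial family), is a per-cell risk that multiplies the population raster;
summing over valid cells gives the regional incidence total. Scenario stacks
(e.g. a 2070 climate projection) are standardized with the *training-period*
parameters so coefficients transfer.

## Worked example

The bundled demo simulates everything — autocorrelated climate surfaces with
a built-in collinear precipitation pair, a known-coefficient logistic
occurrence process, and a 4,371-row hospital-style case table:

```sh
snakerisk run-all --config configs/demo.yaml --out runs/demo
```

Key numbers from that run (fully deterministic under the config's seed):

- `prepared/pruned_pairs.csv` — `bio16,bio13,0.969`: the wettest-month layer
  is dropped because it correlates at r = 0.97 with the wettest-quarter
  layer and ranks lower in the priority list.
- `eval/evaluation.csv` — held-out AUCs of 0.630 (envelope), 0.729 (binomial
  GLM), 0.724 (Gaussian GLM), 0.650 (random forest), 0.729 (maxent-like):
  the moderate-signal truth of the demo world, evaluated on 172 presence and
  200 background test points.
- `incidence/regression.csv` — backward selection retains exactly the four
  layers that carry truth coefficients (`bio1`, `bio12`, `bio15`,
  `elevation`, all ***), discarding the noise layers.
- `incidence/totals.json` — incidence totals of ≈899,000 (current) and
  ≈1,317,000 (2070 scenario, which warms the mean temperature layer by 2°C
  and grows the population 2%).
- `epi/summary.json` — 3,991 of 4,371 records carry sex (2,682 male /
  1,309 female, 67.2%); the rainy season holds 54.6% of dated cases; cobra
  bites average 11.8% of yearly records.

Re-running with the same config reproduces every artefact byte-for-byte;
`manifest.json` records a SHA-256 per artefact plus the config hash.

Individual stages are available as subcommands (`simulate`, `prep`,
`dataset`, `fit`, `evaluate`, `consensus`, `incidence`, `epi`), each reading
the previous stage's on-disk artefacts.

Applying a published coefficient block verbatim to a raster stack:

```python
from snakerisk.incidence import load_coefficients, risk_map
eq = load_coefficients("configs/eq1.yaml")
risk = risk_map(eq, standardized_stack)   # per-cell risk in [0, 1]
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's reported quantity from scratch: it loads the
ten-term published equation bundled in `configs/eq1.yaml` and evaluates its
linear predictor at an all-zero standardized predictor vector (i.e. every
predictor at its training mean), writing the result as JSON.
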