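# maxrange

Automated, reproducible **range estimation for presence-only species data**
on regular latitude/longitude grids. The package implements the full
workflow used for large-scale plant range screening: occurrence cleaning
into three data types, maximum-entropy niche modelling within native-region
masks, variable selection, cross-validated model calibration over a
candidate grid, model selection, and a presence-background / reference-range
evaluation framework — plus seeded synthetic worlds with *known* niches so
every stage can be tested end-to-end without any downloads.

It is aimed at biodiversity informaticians and macroecologists who need
defensible range estimates for many species at once (e.g. red-list
screening), and at methodologists who want a transparent, pure-Python
maxent pipeline to experiment with.

## The model

For a species with presence cells $x_1,\dots,x_n$ inside its native region
(the background $B$ = every native cell), the maximum-entropy model is the
Gibbs density over background cells

$$q_\beta(x) = \frac{\exp(\beta^\top f(x))}{\sum_{b \in B}\exp(\beta^\top f(b))}$$

where $f(x)$ are feature transformations of the min/max-scaled
environmental variables — linear, quadratic, product, hinge and threshold,
in the six canonical combos `l, lq, h, lqh, lqhp, lqhpt`. Coefficients
minimize the L1-penalized negative presence log-likelihood

$$F(\beta) = -\tfrac1n\sum_i \beta^\top f(x_i) + \log\!\sum_{b\in B} e^{\beta^\top f(b)} + \sum_j \lambda_j|\beta_j|,\qquad
\lambda_j = \mathrm{rm}\cdot\beta_{\mathrm{default}}(\mathrm{kind}, n)\cdot \frac{s_j}{\sqrt n}$$

with the classic per-feature-class default regularization tables and a
global regularization multiplier rm ∈ {1, 2, 3, 5, 10}. The **raw** output
$q_\beta$ is a relative occurrence rate summing to 1 over the background;
the **cloglog** output $1 - \exp(-e^{H} q_\beta(x))$ (H = entropy of the
trained raw distribution) is a suitability index in (0, 1).

Per species, the workflow fits up to **96 models**: Model 0 (6 combos at
rm = 1, all variables) ranks variables by permutation importance and prunes
Spearman-correlated ones (|ρ| ≥ 0.7); then each eligible occurrence data
type — raw data (Model 1), presence cells (Model 2), thinned data
(Model 3) — gets a 6 × 5 combo-by-rm grid, cross-validated by leave-one-out
jackknife (n < 25) or 4-quadrant spatial blocks (n ≥ 25). Within a data
type the winner is chosen by AICc (mean test AUC when AICc cannot decide);
across data types by the highest harmonic mean of AUC and AUC_PR against
the species' presence cells.

## Worked example

```python
import maxrange as mx

world = mx.make_world(seed=11, n_climate=6, n_active=2)   # known 2-variable niche
table = mx.simulate_species(world, n_records=80, seed=11) # presence-only records
bundle = mx.run_species(table, world.native, world.env,
                        mx.PipelineConfig(n_knots=10, seed=11))
print(bundle.metadata)
```

Output (from `python examples/04_full_pipeline.py`):

```
status: ok
models fitted: 96
selected variables: CHELSA_BIO2,CHELSA_BIO6,CHELSA_BIO1,CHELSA_BIO4
winning model: Model 2 (presence_cells), combo=h, rm=3
evaluation vs presence cells: AUC=0.840, AUC_PR=0.473, max F1=0.579
degree of overfit (train - test AUC): 0.0410
binary-map thresholds: no-omission=0.3425, max-F1=0.6288
```

96 models = 6 (Model 0) + 3 × 30 (candidate grids for all three data
types). The selected variables include both true niche drivers
(`CHELSA_BIO1`, `CHELSA_BIO2`); the winning model was trained on presence
cells with hinge features at regularization multiplier 3. AUC is the
probability that a presence cell outranks a background cell under the
prediction; the degree of overfit is the gap between calibration and
testing AUC; the two thresholds convert the continuous suitability map
into "possibly suitable" (no omitted presence) and "probably suitable"
(max-F1) binary ranges. `examples/` contains one short script per
capability.

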