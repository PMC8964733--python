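"""Fit one maximum-entropy model and inspect its outputs.

The model is an L1-regularized Gibbs density over the native background:
raw output is a relative occurrence rate summing to 1, the cloglog
transform rescales it into a (0, 1) suitability index.
"""

import numpy as np

import maxrange as mx
from maxrange.maxent import raw_from_features

world = mx.make_world(seed=3, n_climate=4, n_active=2)
table = mx.simulate_species(world, n_records=100, seed=3)
raw_set = mx.filter_records(table, world.native)

expansion = mx.build_features(
    world.env, world.native, world.env.variables, combo="lqh", n_knots=10
)
print(f"feature expansion 'lqh' over {len(expansion.variables)} variables: "
      f"{expansion.n_features} features")

rows, cols = world.native.cells()
X = world.env.values_at(expansion.variables, rows, cols)
F_bg = expansion.transform(X)
cell_index = {c: i for i, c in enumerate(zip(rows.tolist(), cols.tolist()))}
F_pres = F_bg[[cell_index[c] for c in raw_set.cells]]

model = mx.fit_maxent(expansion, F_pres, F_bg, rm=1.0)
raw = raw_from_features(model, F_bg)
cloglog = mx.predict_cloglog(model, raw)
print(f"nonzero coefficients: {model.n_nonzero} of {expansion.n_features}")
print(f"raw output sums to {raw.sum():.9f} over the background (must be 1)")
print(f"cloglog range: {cloglog.min():.3f} .. {cloglog.max():.3f}")

imp = mx.permutation_importance(model, X[[cell_index[c] for c in raw_set.cells]], X, seed=0)
for var, pct in sorted(imp.items(), key=lambda kv: -kv[1]):
    print(f"  importance {var}: {pct:.1f}%")
print(f"(true niche variables: {list(world.niche.active_variables)})")

value = mx.aicc(model, raw[[cell_index[c] for c in raw_set.cells]], raw.sum())
print(f"AICc: {value:.1f}" if value is not None else "AICc unavailable")

rho = np.corrcoef(
    np.argsort(np.argsort(cloglog)), np.argsort(np.argsort(world.true_suitability[rows, cols]))
)[0, 1]
print(f"rank correlation with the true suitability: {rho:.3f}")
# High permutation importance should land on the true niche variables and
# the cloglog map should rank cells like the true suitability does.
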