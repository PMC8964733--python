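"""Score a prediction against presence-background data and an expert-style range.

Presence-background metrics (AUC, AUC_PR, max F1) compare models for the
same species; reference-range metrics treat the expert range as actual
presence/absence, making scores comparable across species.
"""

import maxrange as mx

world = mx.make_world(seed=5, n_climate=6, n_active=2)
table = mx.simulate_species(world, n_records=80, seed=5)
bundle = mx.run_species(table, world.native, world.env, mx.PipelineConfig(n_knots=5, seed=5))

rows, cols = world.native.cells()
pred = bundle.prediction_cloglog[rows, cols]

# 1) against the species' own presence cells (background = all native cells)
raw = mx.filter_records(table, world.native)
pc = mx.to_presence_cells(raw)
import numpy as np

member = np.zeros(world.native.grid.shape, dtype=bool)
for r, c in pc.cells:
    member[r, c] = True
pc_mask = mx.RegionMask(grid=world.native.grid, member=member)
rep_pb = mx.evaluate(pred, pc_mask, world.native, mode="presence_background")
print("presence-background:",
      f"AUC={rep_pb.auc:.3f} AUC_PR={rep_pb.auc_pr:.3f} maxF1={rep_pb.max_f1:.3f}")

# 2) against the synthetic expert reference range (upper suitability half)
ref = mx.make_reference_range(world, quantile_q=0.5)
rep_ref = mx.evaluate(pred, ref, world.native, mode="expert_range")
print("reference range:    ",
      f"AUC={rep_ref.auc:.3f} AUC_PR={rep_ref.auc_pr:.3f} maxF1={rep_ref.max_f1:.3f}")
print(f"no-omission threshold (reference): {rep_ref.threshold_no_omission:.4f}")
# A good model ranks reference-range cells above the rest of the native
# region; AUC ~0.5 would mean the prediction is no better than random.
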