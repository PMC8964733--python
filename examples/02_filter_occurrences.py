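"""Clean raw occurrence records into the three modelling data types.

Simulated records include labelled contaminants (missing coordinates,
pre-2000 years, points outside the native region, exact duplicates).
The filter removes them, then within-cell duplicates collapse to
presence cells, and spatial thinning enforces a two-cell minimum
distance.  Moran's I of the per-cell counts quantifies how spatially
clumped the sampling is.
"""

import maxrange as mx

world = mx.make_world(seed=7, n_climate=4, n_active=2)
table = mx.simulate_species(world, n_records=120, seed=7, contaminant_fraction=0.2)
print(f"simulated table: {len(table)} rows "
      f"({(table['contaminant_type'] != '').sum()} labelled contaminants)")

raw = mx.filter_records(table, world.native)          # quality/temporal/native/dedup
presence = mx.to_presence_cells(raw)                  # one record per occupied cell
thinned = mx.thin(presence, min_dist_cells=2, seed=7) # >= 2 cells apart pairwise

print(f"raw data:       {raw.n_records} records in {raw.n_cells} cells")
print(f"presence cells: {presence.n_cells}")
print(f"thinned data:   {thinned.n_cells}")

counts = mx.count_per_cell(raw)
moran = mx.morans_index(counts, world.native)
print(f"Moran's I of per-cell counts: {moran:.3f}")
# Positive Moran's I means records cluster in space — the pattern the
# presence-cell and thinned data types are designed to counteract.
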