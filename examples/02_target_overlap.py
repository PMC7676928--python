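"""Therapeutic targets = drug targets ∩ disease genes.

Generates a synthetic study with the published shape (126 drug targets,
2207 disease genes, 83 overlapping) and recovers the overlap exactly —
the generator constructs the overlap, the set algebra rediscovers it.
"""

from herbnet import SimConfig, intersect_targets, simulate_target_universe, union_targets

cfg = SimConfig(seed=42)
ctmap, drug, disease = simulate_target_universe(cfg)

print(f"compound-target pairs : {len(ctmap)}")
print(f"distinct drug targets : {len(union_targets(ctmap))}")
print(f"disease genes         : {len(disease)}")
overlap = intersect_targets(drug, disease)
print(f"therapeutic targets   : {len(overlap)}  (drug ∩ disease)")
# The 83 therapeutic targets are the genes the herb can actually act on in
# this disease; everything downstream (PPI, enrichment, C-T-P) uses them.
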