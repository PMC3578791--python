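"""How well does a fast-evolving partial region track full-gene distances?

Simulates a 5000-column gene in which a 550-column region evolves 1.4x
faster than the background, then regresses the region's pairwise distances
on the full-gene distances.
"""

from protistdiv import (
    SimulationConfig,
    distance_matrix,
    evolve_sequences,
    extract_region,
    paired_region_fit,
    simulate_yule_tree,
)

cfg = SimulationConfig(
    seed=0, seq_length=5000, base_rate=0.04,
    region_spans={"V4V5": (2001, 2550)},
    region_rate_multipliers={"V4V5": 1.4},
)
tree = simulate_yule_tree(n_tips=30, birth_rate=1.0, seed=3)
aln = evolve_sequences(tree, cfg, seed=4)

full = distance_matrix(aln, on_undefined="nan")
partial = distance_matrix(extract_region(aln, cfg.region_spans["V4V5"]),
                          on_undefined="nan")
fit = paired_region_fit(full, partial, "V4V5")

print(f"region {fit.region_name}: slope m = {fit.m:.3f}, "
      f"intercept = {fit.intercept:.4f}, R = {fit.R:.3f} ({fit.n_pairs} pairs)")
print()
print("A slope above 1 means the region overestimates full-gene divergence")
print("by that factor; R close to 1 means the region is a reliable proxy.")
print("Here the region runs at 1.4x the background, and the full gene is a")
print("mix of both, so the expected slope is 1.4 / mean-gene-rate ~ 1.34.")
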