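"""Dominance of the O allele per trait, with bootstrap CIs.

h = (Z_TT - Z_OT) / (Z_TT - Z_OO): 0 = O recessive, 0.5 = additive,
1 = O dominant.  The generator uses trait-specific dominance (crown 0.81,
cheek 0.91, breast 0.56, flank 0.35), so the estimates should straddle
additivity in opposite directions -- "opposing dominance" at one locus.
"""

from hzkit import bootstrap_h, default_scenario, simulate_zone

ds = simulate_zone(default_scenario(seed=5))
modern = ds.epoch_index(2)
g = ds.genotypes.dosage[modern, ds.causal_column]

print(f"{'trait':<8} {'true h':>7} {'est h':>7}  95% CI")
for spec in ds.truth.trait_specs:
    y = ds.trait_values(spec.name)[modern]
    est = bootstrap_h(g, y, n_iter=5000, seed=11)
    lo, hi = est.ci95
    print(f"{spec.name:<8} {spec.h:7.3f} {est.h:7.3f}  [{lo:.3f}, {hi:.3f}]")
print(f"\nclass counts: {est.class_counts}")
# The CIs typically cover the generating h (95% nominal coverage, so the
# occasional near-miss is expected); crown/cheek sit above 0.5 (O partially
# dominant) while flank sits below (O partially recessive).
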