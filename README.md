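# hzkit

Analysis toolkit for hybrid zones sampled along a one-dimensional transect.
It was built around the classic question of avian contact zones — what keeps
two closely related species distinct where they meet and interbreed? — and
bundles the four analyses that answer it from SNP genotypes, continuous
phenotypes, and transect metadata:

1. **Geographic cline fitting.** Allele frequencies across the zone follow
   the equilibrium sigmoid cline
   `p(x) = ½(1 + tanh(2(x − c)/w))` with center *c* (km) and width *w*
   (km, the inverse of the maximum slope). Fitted by maximum likelihood
   (binomial for allele counts, gaussian for continuous hybrid indices),
   with site-bootstrap confidence intervals.
2. **Two-epoch width test against neutral diffusion.** A neutral cline
   widens with dispersal as `w(t)² = w(0)² + 2πσ²t`. Given two sampling
   epochs separated by Δt generations, the test asks whether the observed
   `w₂² − w₁²` is less than `2πσ²Δt` — evidence of selection maintaining a
   narrow transition.
3. **Differentiation scans.** Per-SNP Weir–Cockerham *F*<sub>ST</sub>
   (variance components *a*, *b*, *c*; θ = a/(a+b+c)), the ratio-of-sums
   genome-wide weighted average, non-overlapping 10-kb window summaries,
   outlier flagging, and genomic PCA (EV1 as a genomic hybrid index).
4. **Association and inheritance.** EIGENSTRAT-style structure-corrected
   score-test GWAS (`χ² = (n − k − 1)·r²` of axis-residualized trait and
   dosage) with genomic-control λ, plus the dominance coefficient of the O
   allele at a focal SNP, `h = (Z̄_TT − Z̄_OT)/(Z̄_TT − Z̄_OO)`, with
   bootstrap CIs.

A ground-truthed synthetic-zone simulator (`hzkit.simulate`) generates
two-epoch datasets with a weakly differentiated background, a near-fixed
"island" locus on a narrow cline, trait-specific dominance, and missing
calls, so every stage has parameter-recovery tests.

## Worked example

```python
from hzkit import (bootstrap_clines, default_scenario, simulate_zone,
                   width_change_test)

ds = simulate_zone(default_scenario(seed=2))   # 2 epochs x 300 birds, 2001 SNPs
series = ds.site_series()                      # focal-locus counts per site
draws = bootstrap_clines(series, replicates=500, seed=7)
test = width_change_test(draws, sigma=20.0, delta_t=3.0)
print(draws.fits[1].params, draws.fits[2].params)
print(test.delta_w2, test.ci95, test.neutral_expectation, test.less_than_neutral)
```

prints (seed 2)

```
ClineParams(center=1214.8421868740927, width=32.15824174991797) ClineParams(center=1212.0937919202543, width=37.54728176612015)
375.6458555782517 (-1768.6181206600656, 2331.622279617481) 7539.822368615503 True
```

Both epoch fits recover the generating cline (center 1216 km, width 42 km)
from 25 sites of 12 birds; the squared-width change of ~376 km² has a
bootstrap CI that excludes the neutral expectation of 7540 km², so the
zone-stability verdict `less_than_neutral` is True — the cline is too
stable for pure dispersal, the signature of selection.

The `examples/` directory holds one short narrative script per capability
(simulation, cline + width test, GWAS, F_ST + PCA, dominance); each prints
the numbers it computes and a line on what they mean. A thin CLI mirrors
the library:

```bash
hzk simulate --out zone/ --seed 1
hzk widthtest --sites sites.tsv --sigma 20 --delta-t 3 --out wt.json
hzk run --config analysis.yaml --out results/
```

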