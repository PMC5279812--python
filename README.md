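# dnaloop

Monte-Carlo modelling of DNA looping in the presence of bound proteins.

Enhancers regulate transcription by looping to a distal promoter.  A
repressor bound a few tens to ~150 bp from a loop terminus can "quench"
activation without touching either the promoter or the activator.  This
package implements a biophysical model of that effect: double-stranded DNA
is a discrete semi-flexible self-avoiding chain of width *w* = 4.6 nm and
Kuhn length *b* = 106 nm, bound proteins are hard spheres of radius *R*ₒ
hung off the chain at a helical phase angle γ, and a chain of length *L*
counts as looped when its distal terminus falls into a small looping
volume δ**r** (a radial shell *d*min ≤ |Δ**r**| ≤ *d*min + ε intersected
with a cone of solid angle δω′ about an orientation axis).

The central quantity is the looping-probability ratio

    F(L) = P_looped^object(L) / P_looped^baseline(L),

whose large-*L* plateau *F*∞ measures length-independent repression in the
entropic regime (*L* ≫ *b*).  The package also implements the analytic
*eclipse* approximation: the plateau reduction equals the fraction of the
sky that the bound sphere occludes from the looping volume,

    F∞ ≈ 1 − I_object/(4π δr − I_chain) + I_chain∩object/(4π δr − I_chain),

with the quadratic small-object law *F*∞ ≈ 1 − A_K (Rₒ + w/2)² + B_K, and
an enhancer front end that turns binding-site tables (positions in bp,
protein radii, occupancy) into simulations — including an activator-anchored
looping criterion for an enhancer–promoter chain of ~3900 bp.

## How it works

Chains grow link by link.  Bend angles are drawn from the exact Boltzmann
density ∝ exp(−a(1−cos θ)) sin θ by inverse CDF (the bending constant *a*
follows from *b/l* = (a − 1 + a coth a)/(a + 1 − a coth a)), so elastic
energy never enters the weights; hard walls (chain–chain under a
neighbour-exclusion window Δi, chain–protrusion, protrusion–protrusion,
optional spherical confinement) act by discarding the chain.  A surviving
chain therefore carries Rosenbluth weight 1 and the sampler is exact
rejection sampling — which a validation suite verifies against an
independent vectorized whole-chain sampler.  Chains are generated in two
resolutions (base-pair links of 0.34 nm where proteins bind, then *w*-sized
links), looping observables are recorded at every intermediate length, and
per-chain counter-based RNG streams make ensembles deterministic and
mergeable.

## Worked example

A 9.2 nm sphere (about a nucleosome) bound 95 bp from the loop origin, in
phase with the looping volume, on a chain grown to *L* ≈ 4 Kuhn lengths:

```yaml
# ex.yaml
kind: floop
seed: 7
n_chains: 200000
params: {N1: 100, N2: 85}
protrusion: {link_index: 95, radius: 9.2, phase_deg: 0}
criteria: {d_min: 4.6, epsilon: 13.8, domega_over_2pi: 1.0}
plateau_window: 30
```

```text
$ dnaloop floop --config ex.yaml --out out/
F_inf = 0.9416 +- 0.0894 (window 30)
```

`out/fcurve.csv` holds the full curve.  At short lengths the in-phase
sphere blocks looping almost completely (F ≈ 0.12 at L ≈ 115 bp — the
elastic regime), while for L ≫ b the curve converges to a plateau slightly
below 1: the residual, length-independent eclipse effect of a modest-sized
protein at this distance.  `out/plateau.json` records the plateau, its
±1.96 SE halfwidth, and a flatness diagnostic; every output embeds the
config hash and package version.

The same experiment through the library:

```python
from dnaloop import (SimulationParams, Protrusion, LoopCriteria,
                     two_stage_schedule, generate_ensemble,
                     looping_probability, f_ratio, estimate_f_infinity)

params = SimulationParams(N1=100, N2=85)          # 100 bp fine + 85 coarse links
crit = LoopCriteria(d_min=4.6, epsilon=13.8, domega=6.283)
prot = Protrusion(kind="on_chain", link_index=95, radius=9.2, phase=0.0)
base = generate_ensemble(two_stage_schedule(params), params, 200_000,
                         seed=7, criteria=crit)
obj = generate_ensemble(two_stage_schedule(params, [prot]), params, 200_000,
                        seed=7, criteria=crit)
f = f_ratio(looping_probability(obj, crit), looping_probability(base, crit))
print(estimate_f_infinity(f, window=30))
```

Other entry points: `dnaloop eclipse` (rod / terminating-segments / full
eclipse estimates for a static sphere), `dnaloop eve` (bare vs fully-bound
enhancer occupancy states; see `examples/eve37_synthetic.tsv` for the
bundled *synthetic* illustrative layout), `dnaloop fit` (quadratic eclipse
fit of tabulated plateaus), `dnaloop validate`.

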