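# Methods

## Model

DNA is a discrete chain of `N` rigid links; joint `i` (the end of link `i`)
carries a hard sphere of diameter `w = 4.6 nm`, and joint 0 sits at the
origin.  The dimensionless bending energy per joint is `a (1 − cos θ)`
with azimuthal symmetry; twist carries no elastic energy, but the material
frame `(û, v̂, t̂)` is parallel-transported along the chain so that helical
geometry (the phase of a bound protein around the axis) is well defined.
The bending constant follows from the Kuhn length `b` through the discrete
worm-like-chain identity `b/l = (1+c)/(1−c)`, `c = coth a − 1/a`, inverted
numerically (Brent, residual < 1e−12).  Defaults are `b = 106 nm` and
`w = 4.6 nm` for bare dsDNA, with 0.34 nm per base pair.

Bound proteins are hard spheres of radius `R_o` whose centre sits at
`r_k + (w/2 + R_o) R(γ, t̂_k) û_k`: tangent to the chain tube at link `k`,
rotated by the phase `γ` about the local tangent (right-handed; γ = 0 is
"in phase" with the looping volume, γ = 180° opposite).  Static off-chain
spheres at fixed lab positions are also supported.

A chain of length `L` is looped when its distal terminus falls in the
looping volume: shell `d_min ≤ |Δr| ≤ d_min + ε` about the anchor,
intersected with a spherical cap of solid angle `|δω′|` about the
orientation axis (`δω′ < 0` selects the cap about the reversed axis;
`±4π` accepts all directions).  Defaults: `d_min = w`, `ε = 2w`,
`δω′ = 2π × 0.1`, axis `û⁰ = +x̂`, with `t̂_1 = +ẑ` — the geometry is fixed
only up to a rigid rotation, so this lab-frame convention is free.

## Sampling

Chains grow joint by joint.  Each bend is drawn from the exact Boltzmann
density via the closed-form inverse CDF
`cos θ = 1 + ln(u + (1−u)e^{−2a})/a`, so the elastic factor contributes no
weight; the hard-wall factor is handled by single-trial survival: any
overlap discards the chain.  A surviving chain has Rosenbluth weight 1,
the partition sum `Z` is the survivor count, and the scheme is exact
rejection sampling of the self-avoiding Boltzmann ensemble.  This is the
simplest estimator in the sequential-importance-sampling family; its
unbiasedness is verified against an independent vectorized whole-chain
rejection sampler (`dnaloop.validate`), so a future multi-trial or
pruned-enriched upgrade behind the same interface would be checkable
against the same oracle.

Overlap rules.  Two joints interact iff their arc separation is at least
`max(excl_i, excl_j)`, where `excl = Δi · l` per segment: `Δi = 1` for
links with `l ≥ w` and `Δi = ceil((4/3) w/l) = 19` for base-pair links
(`Δi ≥ w/l` is required for overlapping consecutive spheres; the 4/3
factor is the package default and is configurable).  The arc-length form
extends the per-segment window consistently across the two-resolution
boundary.  All overlap comparisons are strict with a 1e−9 relative
tolerance so that exactly tangent spheres (adjacent `l = w` joints, a
protrusion and its own anchor joint) never count as overlapping.
Detection is brute-force pairwise inside a numba kernel; at the problem
sizes used here this meets all runtime budgets, so no spatial hash is
built — the contract is exactness, not speed.

Two-stage resolution.  The first `N1` links are single base pairs
(0.34 nm) so proteins can bind at base-pair positions; the remaining `N2`
links have length `l2 = w`.  All bound objects sit on stage-1 links.  Each
link's bend uses its own segment's bending constant, including the first
stage-2 link after the boundary.

Recording.  Looping indicators, survivor counts and end-to-end `R²` are
accumulated at every stage-2 joint while the chain grows, so one ensemble
yields the whole `P_looped(L)` curve; a prefix of a longer chain is a
valid sample of the shorter chain (verified as a test).  A trailing-flank
requirement of `t` links records length `L` only if the chain survived `t`
joints past it, which implements "weight of the extended chain assigned to
the central segment"; a leading flank, and the outside segment `Q` that
hosts negative-`K` objects (enforced `Q ≥ 10|K|`), are grown backwards
from joint 0 in the `−t̂_1` direction before the forward region, with the
first backward bend sampled relative to `−t̂_1` (equilibrium chains are
direction-reversible).  The outside region is grown at base-pair
resolution over the protrusion neighbourhood (`|K|` + ~100 bp) and at
stage-2 resolution beyond — the only constraint on `Q` is that it be much
longer than `|K|`.

Confinement adds a hard sphere centred on joint 0 (the placement used
throughout this package; whole joint and protrusion spheres must fit
inside, boundary inclusive).

RNG.  Each chain uses a splitmix64 stream keyed by `(seed, chain_index)`,
so ensembles are bit-reproducible and sub-ensembles over disjoint index
ranges merge exactly (count-valued accumulators are integer-exact).

## Analysis

`P_looped(L)` is the looped weight over `Z(L)` with a weighted-binomial
standard error using the effective sample size `(Σw)²/Σw²` (plain binomial
for unit weights).  `F(L)` is the pointwise ratio of object to baseline
curves with first-order independent error propagation; the plateau `F∞` is
the mean of a trailing window of `F(L)` points with ±1.96·SE from the
scatter of those points, plus a flatness diagnostic (trailing linear-fit
slope consistent with 0 within 2 SE; failure warns, never errors).  The
default window is the last 480 points when available, else the trailing
half of points beyond 5 Kuhn lengths.  Baseline and object ensembles use
independent seeds by default; a correlated-seed mode (same seed, hence
identical chain proposals differing only in survival) is available as a
variance-reduction extension and is used in some of the package's own
end-to-end checks.

Activator-anchored looping (enhancer scenario): a chain is looped with
respect to an activator sphere when the terminus reaches the shell
`w/2 + R_act ≤ |r_N − c_act| ≤ … + 3 nm` within `δω′` of the axis from the
binding link to the sphere centre (recomputed per chain).  The total
looping probability is the *sum* over activators, per the model's
definition; chains looped with respect to several activators at once are
not de-duplicated, and the double-counted weight fraction is reported as a
diagnostic (the union accumulator).

## Eclipse approximation

`I_object`, `I_chain` and `I_chain∩object` are evaluated by Monte-Carlo
ray casting: uniform points of the looping volume (inverse-CDF radius on
`r³`, uniform cap direction) × uniform ray directions; a ray contributes
to a term when it enters the corresponding sphere set.  Occlusion radii
are Minkowski sums with the approaching terminus: `R_o + w/2` for the
object and `w` for frozen chain joints.  The static (rod) estimate is
`1 − ⟨Ω_object/4π⟩` with `Ω = 2π(1 − √(1 − (R_eff/d)²))`; a point inside
the object raises a geometry error.  Because a vanishing protrusion still
carries the `w/2` tube radius, `F∞_static → 1` only up to a per-mille
residual.

The terminating-segments correction grows short chains of contour `T`
(default `T = |r′| + R_o`) from uniform looping-volume points with uniform
initial directions; each link is tested against the object as a continuous
capsule (segment–sphere), so the one-link limit is exactly the rigid rod.
The corrected estimate is `F_rod × surv_flex(T)/surv_rigid(T)`, each
survival normalized by its object-free counterpart (identically 1 in a
scene with no other obstacle).  Flexible segments overlap the object more
than rods, so the correction lowers the estimate toward the simulated
plateau, and the remaining gap is attributable to the rest of the chain —
the ordering rod ≥ terminating-segments ≥ simulation is asserted as a
test.

The quadratic law `F∞ = 1 − A_K (R_o + w/2)² + B_K` is fitted by weighted
least squares (weights `1/SE²`), reporting coefficients, covariance and
`R²` against the weighted mean.

## Synthetic enhancer layout

The bundled `eve 3/7`-style layout is *synthetic*: real binding-site
coordinates are not distributed with the package, so an illustrative
3900 bp chain carries three activator sites (dStat 3.04 nm, Zld 3.75 nm,
dStat) interleaved with four repressor sites at ≥ 50 bp spacing (chosen so
that even the largest documented complex, 5.83 nm, is placeable on the
straight chain).  Protein radii for dStat, Zld, bare Knirps, Knirps+CtBP
and the full 450 kDa complex are built in (3.04, 3.75, 2.38, 3.59,
5.83 nm); other masses use `R ∝ M^{1/3}` anchored at 86 kDa → 3.04 nm.
Helical phases follow from the native twist 2π/10.5 rad/bp at the site's
base-pair position (fractional positions round to the nearest link).
Layout feasibility is checked on the straight chain; thermal fluctuations
still discard most fully-bound chains during growth (acceptance ~0.4% for
the full-complex state at base-pair resolution), which is the model's
physics, not an error — bound-state ensembles are therefore run with many
more chains, which is cheap because discards happen early.

## Problem sizes and statistical design of the checks

The original study's curves rest on ~10⁹ chains per ensemble; this package
runs its end-to-end checks and the acceptance script at desk scale
(10⁵–5·10⁶ chains, minutes per scene on one core).  At that scale the
default narrow looping cone yields only ~10⁻⁵–10⁻⁴ looped fraction per
grid point, so each check fixes its counting design by a power analysis
piloted during development and then frozen:

* Scene parameters under study (`R_o`, `K`, γ, `d` — and the narrow
  default cone wherever the claim concerns it, e.g. the in-/out-of-phase
  contrast, which a wide cap would wash out) are never altered.
* Where the claim is cone-independent (eclipse-estimate ordering, ±K
  symmetry, confinement), a wider acceptance cap (2π or 4π) and/or a wider
  shell (ε = 3w, the same noise-minimization rationale that motivates the
  large default ε) buys an order of magnitude in counts.
* Some checks share one seed across ensembles so that all of them see the
  same chain proposals (correlated-pair design): orderings of survival-
  driven quantities are then resolved with far fewer chains.
* Plateau windows cover the trailing 2.5–6.5 Kuhn lengths depending on the
  scene; sparse-count comparisons pool counts across the window instead of
  averaging pointwise ratios.

The ±K symmetry deserves a note: convergence of `F(L, K)/F(L, −K)` to 1 is
slow (the ratio is still ~0.8 when pooled over 2–4 Kuhn lengths), so the
symmetry check compares the deep-entropic window and inherits a sizeable
standard error at this scale; the acceptance script reports the pooled
ratio beyond 6 Kuhn lengths.

## What the synthetic checks do and do not show

All inputs are generated programmatically from the model itself; passing
tests demonstrate internal correctness (unbiased sampling, closed-form
agreement, the eclipse mechanism and its orderings) and qualitative
robustness of the biological conclusions (phase dependence, size
dependence, inside/outside symmetry, confinement neutrality of `F`).  They
do not validate the mapping of real chromatin to bare-dsDNA parameters,
sequence-dependent stiffness, twist elasticity (excluded from the energy
by design), protein shapes beyond spheres, or real enhancer site
coordinates — the bundled layout is illustrative only.

## Known limitations

* Single-trial survival weighting spends effort on discarded chains in
  crowded scenes (fully-bound enhancers, tight confinement); a
  multi-trial or enrichment scheme behind the same `Ensemble` contract
  would raise efficiency.
* `ensemble_average` over arbitrary per-chain observables requires
  retaining chains (the reference Python path); the streaming kernel
  accumulates only the standard observables.
* The eclipse model's frozen-chain occlusion uses a straight
  representative configuration; the quadratic fit absorbs the constant
  into `B_K`, so this only affects diagnostics.
* Confinement centres the sphere on joint 0; other placements (e.g. the
  chain centroid) would raise survival for long chains.
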