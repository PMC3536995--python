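# Methods

## The model

A linear polymer is represented as a self-avoiding walk (SAW) on a simple
cubic lattice of constant `a`.  Successive segments are joined by bond
vectors that are signed permutations of `(0, 2a, 3a)` — the "(023)" move
set — giving a coordination number ω = 24 and a bond length
b = √13·a ≈ 3.606a.  The high coordination makes the chain very flexible,
so entropy differences converge quickly.  The simulation box is a finite
cube of 601³ sites; a proposed site outside the box is treated as blocked
(a centrally started chain of ≤ 100 segments can only touch a face in the
measure-zero fully stretched configuration, so this convention is inert in
practice).  The model is athermal: the only interactions are the excluded
volume of the chain with itself and with the solid surface.  Chains are
either free (started at the box centre) or end-grafted to a rough surface,
in which case the first segment sits one lattice unit above the chosen
surface element, where 16 of the 24 continuations are open above a flat
wall.

## Chain growth and entropy estimation

Conformations are generated by static Rosenbluth–Rosenbluth growth: at each
step the set of free neighbour sites (inside the box, unvisited, outside
the solid) is enumerated, one is chosen uniformly, and the count `k_i` is
recorded.  Chains that dead-end are discarded whole and regrown; the
discard count is reported with every ensemble, and a run aborts if the
dead-end fraction exceeds a configurable threshold (default 50%), which
signals a pathological grafting site rather than a sampling problem.

The number of conformations Ω(i) grows per step by the effective
coordination number ϖ_eff(i) = Ω(i+1)/Ω(i), and the chain entropy is

    S/k_B = Σ_{i=1}^{N−1} ln ϖ_eff(i).

Two estimators of ϖ_eff are provided:

* `plain` — the arithmetic mean of `k_i` over sampled chains, the classic
  statistical-counting recipe.  It is exact for i ≤ 2 but biased beyond,
  because Rosenbluth growth over-visits conformations with small weights.
* `rosenbluth` (default) — the ratio of Rosenbluth-weighted sums,
  `ϖ_eff(i) = Σ W_i k_i / Σ W_i` with `W_i = Π_{j<i} k_j`, which is an
  unbiased estimator of Ω(i+1)/Ω(i).  All weighted accumulation happens in
  log space (log-sum-exp); no product of counts is ever formed.

The bias of the plain estimator is not cosmetic: for a chain grafted to a
flat wall it drags the fitted planar anchoring slope from ≈ −0.49 to
≈ −1.37.  The unbiased estimator is therefore the default and the one used
for every entropy-difference result; the plain mode is kept for comparing
with the historical recipe and for the convergence/precision diagnostics,
which probe the plain method's scatter.  Unbiasedness is verified against
exhaustive enumeration (all SAWs up to five segments, free and grafted,
flat, bumped, and random fixtures) to within three standard errors at 10⁵
samples.

The compiled growth kernel marks chain sites in a flat occupancy byte array
of the whole box and unmarks them after each chain, so every candidate move
costs O(1); a self-contained xorshift64* generator keeps seeded runs
bit-reproducible.  A transparent pure-Python grower implements the same
contract and is cross-checked against the kernel and against exact
second-step arithmetic.

## Rough surfaces

Surfaces are square integer heightfields; all sites with `z < z_S(x, y)`
are solid.  Parents are generated at 1024² and cropped to the 601-site box
around the grafting site.

**Uncorrelated Gaussian (uGm).**  Every cell altitude is the integer part
of an independent normal variate with mean `z0` and standard deviation σ.
"Integer part" defaults to truncation toward zero (a `floor` option
exists); the two coincide when `z0` keeps altitudes positive, which the
package's standard runs do (`z0 = 300`, mid-box).  A literal single-uniform
Box–Muller variant (the same uniform draw in both factors) is kept behind a
flag for fidelity comparisons; the default draws proper normals.

**Brownian / fractional Brownian (Bm/fBm).**  Built by random midpoint
displacement: at refinement level `l` (mesh halved per level) midpoints are
displaced with standard deviation σ·2^(−lH), where H is the Hurst exponent
(H = 1/2 Brownian, larger H smoother).  After the recursion every site
receives successive random additions with the faster-decaying schedule
√p·σ·2^(−l·β·H) per level (p = `addition_prob`, default 0.5;
β = `addition_decay`, default 2.2).  Two choices here deserve comment:

* σ parametrizes the displacement *amplitude*; the empirical altitude SD of
  the finished grid is smaller and is always measured, not assumed.  An
  optional `rescale_to` forces an exact altitude SD, but rescaling cannot
  be the default: a rescaled field has an H-independent ratio of
  lattice-scale to total roughness, which contradicts the strong H
  dependence of the empirical fractal dimension this generator is required
  to reproduce (see below).
* the additions carry the √p amplitude rather than firing as a per-level
  coin.  The injected noise power is identical, but a literal coin at the
  coarsest level flips the roughness of the whole realization, making
  seed-averaged metrics needlessly unstable.

The addition decay β = 2.2 was fixed analytically so that the integerized
fields reproduce the reference empirical fractal dimensions of Brownian
(H = 0.5, σ = 1 → D_F ≈ 2.109) and fractional (H = 1.0, σ = 1 →
D_F ≈ 2.055) surfaces through the relation D_F ≈ 2 + ln(1 + 2·E|Δz|)/ln L,
where E|Δz| is the mean adjacent-column altitude jump.  Seed-averaged
values from the generator land at 2.096 and 2.053.

**Grafting site.**  From the central region of the parent (fractions
301/1024–723/1024 per axis) the anchor is the site of minimum or maximum
altitude (valley/apex, ties uniform), the site closest to the global mean
altitude, or a uniformly random site.  For fixed sites the surface is
re-cropped around the anchor and shifted so the anchor sits at the box
centre.  For random grafting the ensemble sampler can draw a fresh anchor
per chain; chains that dead-end are discarded together with their anchor,
so open sites are visited more often — the behaviour expected of a
random-attachment experiment in which failed growth attempts are rejected.
The acceptance runs use this per-chain mode.

## Roughness metrics

The total exposed area X of a heightfield is the sum of the L² unit cell
tops plus |Δz| wall panels over all interior 4-neighbour pairs; boundary
cells contribute no exterior walls (window artifacts).  The empirical
fractal dimension is D_F = ln X / ln L, 2 for a flat plane and → 3 for
extreme roughness.  It is computed on the reduced 601-site window, the
geometry the chain actually sees; with L = 601 the uGm values follow the
normal-difference expectation E|Δz| ≈ 2σ/√π (checked by a 1-D numeric
oracle).  D_F increases monotonically with σ for every family.

## Scaling analysis

The anchoring entropy ΔS/k_B = S^A − S^F (negative; the cost is
D = −ΔS/k_B) is summarized by two fits:

* planar wall: ΔS/k_B = Δγ·ln N + const, fitted over N ∈ [10, 100] at ten
  logarithmic points.  The free intercept absorbs the short-chain constant.
  The measured Δγ ≈ −0.49 corresponds to γ^A = Δγ + 7/6 ≈ 0.68.
* rough surfaces: D = A·N^ζ on the log-log line.  The exponent is extracted
  on the long-chain window N ∈ [40, 100] of a 13-point grid: at small N the
  local anchor-environment constant (the C^A/C^F term of the
  renormalization-group form) contaminates the slope, and including it
  biases ζ upward by ~0.05.

On self-similar (Brownian) surfaces the fitted ζ(D_F) falls with roughness,
reaches a plateau just above the critical fractal dimension D_F ≈ 2.5, and
— unlike in a generator with scale-free local structure — rises again at
very large amplitudes, when the σ-scaled lattice-level jaggedness starts to
dominate the relief.  The plateau values are therefore read off at
roughness levels just above critical for random grafting (σ ∈ {32, 40, 48},
D_F ≈ 2.52–2.58) and across σ ∈ {128, 256, 384} for apex grafting.  The
per-surface exponent of a single apex is at the mercy of that apex's
geometry (a long right tail up to ζ ≈ 0.8 appears in a few draws), so the
plateau estimate is the *median* over 12–15 independent surfaces; it lands
at ζ* ≈ 0.19 for random grafting and ζ* ≈ 0.29 for apex grafting.  In the
extreme-roughness limit ζ → 1 (rod-like confinement between spikes), which
the uGm family approaches from below.

The renormalization-group entropy form S/k_B = ln C + (γ−1) ln N +
N ln ω_eff is linear in (ln C, γ−1, ln ω_eff) and fitted by exact linear
least squares, optionally with γ pinned to the universal free-chain value
7/6.

## Continuum superposition model

The grafted coil is modelled as the unperturbed radial segment density

    ρ_F(r) = B·N·(r/b)²·exp(−(9/N)(r/b)²)·exp(−(1/72)·N²a³/r³)

(a Gaussian envelope times an excluded-volume depletion hole), cut by the
cumulative free-site profile of a wall with Gaussian altitude scatter σ:

    ρ_S(u) = ½(1 + erf(−(u − R_G)/(√2 σ))),

and the anchoring entropy is ΔS/k_B = ln(∫ρ_A dV / ∫ρ_F dV), with B
cancelling.  Two geometric conventions are implemented.  The default
applies the cut to the radial coordinate — the wall envelope seen from the
coil centre sits at one coil radius, and the cut removes the cloud's outer
shell — with the coil radius identified with the most probable segment
radius of the density itself, r* = b√(N/9).  Under this convention the
fitted exponent of ln D vs ln N over N ∈ [10, 100] at σ/a = 10 is
ζ = 0.157, consistent with the plateau exponents measured by simulation at
mean/random grafting.  The alternative axial convention (a half-space cut
at a Flory-scaled offset R_G = (b/a)N^(3/5)/√6) is retained and compared by
`rg_convention_sweep`; because the Flory offset grows faster than the
printed density's √N width, every axial/Flory variant yields a *negative*
exponent (the cost decays with N), so it cannot describe a grafted coil
whose anchoring cost grows with chain length.  This sensitivity is exactly
why the coil-radius convention is reported explicitly.

One property flips sign between the geometries: in the axial cut, larger σ
removes more density and ΔS decreases monotonically (tested over
σ/a ∈ {1, 3, 10, 30}); in the radial-shell cut the sharp cut already
removes the outer shell, and smearing it restores outer mass, so ΔS
*increases* with σ.

Quadrature is a product grid (1-D radial, or 2-D cylindrical for the axial
geometry) with automatic refinement until the entropy changes by < 0.1%,
cross-checked against adaptive quadrature to < 0.5%.

## Numerical choices

* Entropy accumulation entirely in log space; weighted ratios via
  log-sum-exp.
* Kernel RNG: xorshift64* seeded through splitmix64; library-level
  randomness through `numpy.random.default_rng`.  One master seed fans out
  through named `SeedSequence` substreams (surface, anchor, chains,
  replicates), all below 2³¹.
* Degenerate inputs: σ = 0 surfaces are exactly flat; midpoint relief below
  integer resolution (< 10⁻⁶ a peak-to-peak) is flattened outright so the
  sign of vanishing noise cannot dither cells across an integer boundary;
  ρ_S with σ = 0 is a sharp step; r = 0 takes the continuous limit
  ρ_F → 0.
* Fit ties/weights: least squares on the log-log (or semi-log) line,
  optional 1/SE² weights; r² always reported.

## Problem sizes

Default study conditions mirror the validated range: chains up to N = 100
(longer chains warn), ensembles of 10³–10⁵ conformations, parent surfaces
1024², box 601³.  The criterion suite runs ensembles of 3·10³–10⁵ chains
and finishes in about a minute on one core; the acceptance script uses
10⁴-chain ensembles per point for the planar slope and coordination
numbers, 4–6·10³ per point across 12–15 surfaces for the plateau
exponents, and 5·10⁴ free chains for the precision extrapolation.

## What the generators emulate — and what they do not

The synthetic surfaces reproduce integer-valued, single-valued
heightfields with tunable amplitude and correlation: uncorrelated spike
brushes (uGm) and self-affine relief (Bm/fBm) whose empirical fractal
dimension matches the reference values at σ = 1.  They do not contain
overhangs, pores, chemical heterogeneity, or adsorption energetics — the
wall is purely repulsive, so every surface effect on the chain is entropic.
Collisions are defined on lattice sites only: a bond may pass diagonally
"through" a thin wall edge, a known property of site-based lattice models.
Passing tests therefore demonstrates correctness of the entropy estimator
and scaling machinery for this model class, not quantitative transfer to
any particular experimental surface.

## Known limitations and discrepancies

* The unbiased terminal effective coordination of a *free* 100-segment
  chain is 22.856 ± 0.005, and grafted ensembles are necessarily below
  this ceiling (22.73–22.75 across surface types).  A quoted reference
  value of ≈ 22.9 for grafted chains exceeds the free-chain ceiling and
  cannot be reached by any anchored ensemble in this model; the
  corresponding check is kept at its nominal band and fails by ~0.06,
  documenting the discrepancy.
* The replicate-set scatter of S(100) measured here (relative SD
  ≈ 2.5·10⁻⁶ when extrapolated to sets of 10⁵ free chains) is about a
  factor two below the historical reference value of 5·10⁻⁶; grafted
  ensembles scatter an order of magnitude more.  The reference protocol
  cannot be pinned down further from the printed description.
* Fixed-site grafting on very rough surfaces can legitimately exceed the
  default dead-end threshold (deep wells); the random-grafting ensembles
  used for production runs raise the threshold to 75% and report discard
  counts.
* The theta-solvent variant of the continuum model (removing the
  excluded-volume factor with compensating attraction) is out of scope.
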