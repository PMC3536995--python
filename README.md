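# graftropy

Conformational entropy of a lattice polymer chain end-grafted to rough
surfaces.

Grafting a polymer to a solid wall costs conformational entropy: the wall
excludes part of the conformation space of the coil.  How large that cost
is, and how it scales with chain length, depends on the geometry of the
wall — a flat plane, a brush of uncorrelated spikes, or self-affine fractal
relief all behave differently.  `graftropy` measures this cost by direct
Monte Carlo simulation of a self-avoiding walk (SAW) on a cubic lattice and
compares it with a simple analytical superposition model.  It is aimed at
polymer physicists and surface scientists studying tethered chains,
mushroom/brush coatings, and steric stabilization on rough or fractal
substrates.

## The model in brief

* **Chain**: SAW on a cubic lattice with (023) moves — bond vectors are
  signed permutations of (0, ±2a, ±3a), coordination number ω = 24, bond
  length b = √13·a ≈ 3.606a.  Athermal: excluded volume only.
* **Sampling**: static Rosenbluth–Rosenbluth growth.  Each step records
  the number of free neighbour sites k_i; the effective coordination
  number ϖ_eff(i) estimates the ratio of SAW counts Ω(i+1)/Ω(i), and the
  chain entropy is the statistical-counting sum

      S/k_B = Σ_{i=1}^{N−1} ln ϖ_eff(i).

  The default estimator Rosenbluth-weights the per-step counts, which
  makes it exactly unbiased (verified against exhaustive enumeration).
* **Surfaces**: integer heightfields — uncorrelated Gaussian (uGm),
  Brownian and fractional Brownian relief built by random midpoint
  displacement with successive random additions (Hurst exponent H).
  Roughness is characterized by the altitude SD and the empirical fractal
  dimension D_F = ln(total area incl. side walls)/ln(edge length).
* **Anchoring entropy**: ΔS/k_B = S^A − S^F ≤ 0 between grafted and free
  chains of equal length.  On a flat wall ΔS/k_B ≈ Δγ ln N with
  Δγ = γ^A − γ^F ≈ −0.47 (γ^F = 7/6).  On rough surfaces the cost follows
  a power law −ΔS/k_B = A·N^ζ whose exponent rises with the fractal
  dimension toward the rod limit ζ → 1, with a plateau ζ* above the
  critical roughness where coil and relief become commensurate.
* **Continuum model**: the free-coil segment density
  ρ_F(r) ∝ N (r/b)² e^{−(9/N)(r/b)²} e^{−N²a³/72r³} multiplied by the
  wall's cumulative free-site profile (an erf in the altitude scatter σ);
  the anchoring entropy is the log-ratio of the integrated densities, and
  its fitted exponent matches the simulated plateau at mean/random
  grafting.

## Worked example

```python
import numpy as np
from graftropy import (generate_rmd, characterize, select_anchor,
                       anchored_environment, free_environment,
                       sample_ensemble)
from graftropy.entropy import estimate_profile

# A Brownian-relief surface (H = 0.5), amplitude 3a, 1024^2 parent grid.
surf = generate_rmd(1024, z0=300, H=0.5, sigma=3.0, seed=0)
rep = characterize(surf)
print(f"D_F={rep.D_F:.3f}  sigma_emp={rep.sigma_emp:.2f}")

# Graft at the site closest to the mean altitude; compare with free chains.
anchor = select_anchor(surf, "mean", seed=0)
env, fenv = anchored_environment(surf, anchor), free_environment()
for N in (10, 100):
    sa = estimate_profile(sample_ensemble(env, N, 2000, seed=1))
    sf = estimate_profile(sample_ensemble(fenv, N, 2000, seed=2))
    print(f"N={N}: S_A={sa.S:.2f}  S_F={sf.S:.2f}  dS={sa.S - sf.S:.3f}")
```

Output:

```
D_F=2.182  sigma_emp=1.56
N=10: S_A=27.32  S_F=28.24  dS=-0.923
N=100: S_A=307.77  S_F=309.91  dS=-2.144
```

The surface has empirical fractal dimension 2.18 (mildly rough).  Grafting
costs about 0.9 k_B of conformational entropy for a 10-segment chain and
2.1 k_B for a 100-segment chain; fitting such ΔS(N) curves across many
chain lengths yields the anchoring exponents analysed above.

The same pipelines are scriptable from the shell:

```
graftropy gen-surface --type bm --L 1024 --sigma 3 --seed 0 --out surf.txt
graftropy characterize surf.txt
graftropy simulate --surface surf.txt --anchor mean --N 10,22,46,100 \
                   --samples 2000 --seed 1 --out run/
graftropy fit --input run/entropies.csv --model power --nmin 10 --nmax 100
graftropy continuum --sigma 10 --out continuum.json
```

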