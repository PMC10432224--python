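# chemosense

How accurately can a cell tell *where* a chemical signal comes from, using
only its first few receptor binding events?

Many cell types — yeast orienting toward a mating partner, *Dictyostelium*
and neutrophils chasing chemoattractants, growth cones following guidance
cues — must infer the direction of a diffusive source from sparse, noisy
binding of ligand molecules to membrane receptors, often long before the
extracellular concentration field reaches steady state.  `chemosense`
implements and cross-validates a minimal quantitative model of this
*pre-steady-state* directional sensing:

* a cell is the unit sphere carrying `N` static circular receptor caps of
  common radius `a` (combined surface fraction `σ = N a²/4`), centred on
  the Fibonacci spiral;
* `M` ligand molecules are released at `x₀ = (0, 0, R)` and diffuse with
  diffusivity `D` until they bind a receptor or escape to infinity;
* the direction estimate is the elevation `z_k = cos θ_k` of the k-th
  binding site relative to the source axis, or the average `Z_K` of the
  first `K` of them.

The package is aimed at quantitative cell biologists and biophysicists who
want either the particle-level stochastic simulation or the matching
analytic laws (and their cross-validation) without re-deriving them.

## What is inside

| module | contents |
|---|---|
| `chemosense.geometry` | Fibonacci receptor layouts, cap sizing `a = 2√(σ/N)`, point-in-cap queries |
| `chemosense.homogenized` | the homogenized Robin boundary condition `D ∂_r p = κ p` with `κ(σ, a)` from boundary-homogenization theory; closed-form capture-time density ρ(t); capture probability `1/((1+D/κ)R)`; spectral surface flux `J(θ,t)` via numerically inverted spherical-Bessel Laplace transforms; the directional signal `χ(t) = ψ₁/ψ₀` |
| `chemosense.extremes` | short-time survival asymptotics, Gumbel centering/scale `(b_M, a_M)` of the fastest arrivals, the k-th arrival law `exp(kx − eˣ)/(k−1)!`, exponential angular-error law `1 − z_k ~ Exp(λ_k)` with `λ_k = (2D/R)(b_M + a_M ln k)`, and the hypoexponential law of the K-averaged error with closed-form mean `Σλᵢ/K` and variance `Σλᵢ²/K²` |
| `chemosense.kmc` | numba-accelerated kinetic Monte Carlo particle simulator: exact escape probabilities, first-passage (Lévy) jump times, time-conditioned hit angles, near-surface Brownian dynamics with Brownian-bridge contact detection |
| `chemosense.analysis` / `chemosense.cli` | running-average elevation curves, figure-level validation experiments (`fig2`–`fig5`), theory tables, and the `chemosense` command-line tool |

## Worked example

```python
import numpy as np
from chemosense import (ReceptorConfig, SimulationConfig, simulate,
                        kappa_from_receptors, HomogenizedParams,
                        capture_probability, mean_elevation_chi,
                        gumbel_scaling, lambda_k, error_moments,
                        running_average)

# reference cell: N=201 receptors covering 5% of the membrane, source at R=5
rec = ReceptorConfig.fibonacci(201, 0.05)
kappa = kappa_from_receptors(rec.sigma, rec.a, D=1.0)
params = HomogenizedParams(R=5.0, D=1.0, kappa=kappa)

events = simulate(SimulationConfig(M=20_000, R=5.0, receptors=rec, seed=17))
ra = running_average(events, 101)

sc = gumbel_scaling(100_000, HomogenizedParams(R=4.4, D=1.0, kappa=3.36))
e1, e5 = error_moments(1, sc), error_moments(5, sc)
```

Output of the accompanying print statements:

```
cap radius a            = 0.031544
kappa                   = 3.3641
capture probability     = 0.15417
bound / released        = 2964 / 20000  (fraction 0.14820)
first binding event     : t1 = 0.5433, cos(theta_1) = 0.8156
running avg (Ms=101)    : z_bar = 0.599 near t = 1.48; chi(t) = 0.608
bM, aM (M=1e5, R=4.4)   = 0.3857, 0.0454
lambda_1                = 0.1753
mean error increase K=5 = 11.3%
variance reduction      = 4.02x
```

Reading this: the 201-cap surface homogenizes to a leakage parameter
κ ≈ 3.36, predicting that ~15.4% of released molecules ever bind (the
simulation finds 14.8%; the homogenization formula is a small-σ
asymptote and overestimates capture by a couple of percent at σ = 0.05).
The *first* binding event lands at cos θ ≈ 0.82 — strongly aligned with
the source — and the sliding-window average of binding elevations tracks
the analytic signal χ(t) as information decays toward isotropy.  For
M = 10⁵ molecules at R = 4.4, the first event errs by λ₁ ≈ 0.175 in
`1 − cos θ` on average; averaging the first five events raises the mean
error by ~11% but cuts its variance four-fold — the accuracy/precision
trade-off that makes "wait for a few more bindings" a sensible cellular
strategy.

The same experiments are available from the shell:

```bash
chemosense simulate --R 5 --N 201 --sigma 0.05 --M 100000 --seed 17 --out events.csv
chemosense theory --outdir theory/
chemosense extremes --R 4.4 --M 100000
chemosense reproduce --name fig3 --scale 0.1 --seed 17 --outdir out/
```

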