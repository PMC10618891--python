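# patchcoex

Species coexistence through habitat-patch geometry: competition–diffusion
dynamics on bounded 1-D and 2-D patches with absorbing boundaries,
synthetic island outlines, boundary-complexity metrics, and Monte-Carlo
protocols linking patch shape to the ease of multispecies coexistence.

## The problem

Classic competition–colonization theory lets inferior competitors persist
by dispersing better. On a *finite* habitat patch surrounded by hostile
matrix, dispersal cuts the other way: individuals that cross the boundary
are lost, so high dispersal is a mortality load near edges. This package
implements and explores the resulting *reverse* trade-off: `S` species
with abundances `u_i(x, t)` obeying

    ∂u_i/∂t = D_i Δu_i + u_i (r_i − Σ_j a_ij u_j),   u_i = 0 on ∂Ω,

(growth rates `r_i`, diffusion coefficients `D_i`, competition
coefficients `a_ij`, `a_ii = 1`) can coexist stably when the competitive
hierarchy is *aligned* with the dispersal hierarchy: the superior
competitor-and-disperser holds the patch interior while inferior species
dominate the boundary zone. Patches are either the unit interval, loaded
GeoJSON polygon outlines, or synthetic island outlines with independently
tunable macro-scale structure (lobes, peninsulas) and micro-scale
jaggedness. Two landscape metrics quantify boundary complexity — the
isoperimetric perimeter deficit `m1 = P − 2√(πA)` and the
compressibility `m2` of the quantized turning-angle sequence — and an
end-to-end experiment measures how each predicts the mean number of
randomly assembled species that coexist per patch. It is intended for
theoretical/spatial ecologists studying geometric coexistence mechanisms.

## Worked example

Two species on the unit interval, species 1 superior in both competition
(`a21 = 1.2`, `a12 = 1/a21`) and dispersal (`D1 = 3e-3 > D2 = 5e-4`):

```python
from patchcoex import (Ecosystem, IntervalDomain, SimulationConfig,
                       StateField, run_to_equilibrium)

domain = IntervalDomain(199)
eco = Ecosystem.two_species(a21=1.2, D1=3e-3, D2=5e-4)
res = run_to_equilibrium(StateField.uniform(domain, 2, 0.1), eco,
                         SimulationConfig())
u = res.state.u
print(res.converged, res.steps)           # True 33788
print([round(t, 4) for t in res.totals])  # [0.813, 0.0783]
print(round(u[1, 0] - u[0, 0], 4))        # 0.0097  (sp2 leads at the edge)
print(round(u[0, 99] - u[1, 99], 4))      # 0.9978  (sp1 leads at midpoint)
```

Without space this pair would collapse to species 1 by competitive
exclusion; with absorbing boundaries both persist — species 2's entire
population (total 0.078 vs 0.813) lives in narrow bands along the two
boundaries where species 1's dispersal mortality depresses it.

The same pipeline scales up via the CLI (`patchcoex --help`:
`islands generate`, `simulate 1d|2d`, `scan plane`, `ease`, `search`,
`metrics`, `experiment`, `erode`) or the numbered drivers under
`analysis/`, which generate the synthetic archipelago, the two-species
profile and parameter-plane scan, dominance maps of coexisting
quadruples, the complexity-vs-coexistence experiment, and the
habitat-loss experiment, writing tables under `results/`.

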