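# symring

Symmetric ring assembly of protein oligomers, rigid-body energy landscapes,
interface/burial mapping, and enzyme-kinetics analysis.

## The problem

NAD-dependent methanol dehydrogenase (MDH) from *Bacillus methanolicus*
reversibly interconverts formaldehyde and methanol and assembles as a decamer:
two monomers form a C2 dimer, and five dimers close a five-fold ring. Variants
with improved formaldehyde-reduction activity carry substitutions (F213V,
F289L, F356S) that sit at oligomerisation interfaces rather than in the
cofactor pocket, so understanding them requires (a) building candidate ring
geometries, (b) asking which residues sit at which interface and how buried
they are, and (c) quantifying the catalytic consequences from steady-state
kinetics and progress curves.

`symring` implements that workflow as a reusable library. The ring model has
two free variables:

- **R** — the spin of each dimer about one of its own principal axes
  (2–360° in 2° steps by default), and
- **D** — the distance between the centers of geometry of the nearest
  monomers of adjacent dimers (40–50 Å in 2 Å steps by default).

For each (R, D) the ring of five dimers is built exactly (the placement
radius is solved so the realised D matches the request to <10⁻³ Å) and scored
with a capped 12-6 Lennard-Jones inter-chain potential on Cα atoms,

E = Σ_pairs min( 4ε[(σ/r)¹² − (σ/r)⁶], cap ),  r < r_cut,

giving an energy landscape whose minima are candidate decamer geometries and
whose positive ridge marks spin angles where neighbouring dimers collide.
The kinetics module fits v = V_max·S/(K_m+S) by weighted nonlinear least
squares, computes k_cat/K_m and fold efficiencies relative to wild type, and
reads half-decay times (NADH consumption) and growth-resumption times (OD600
after formaldehyde arrest) directly off progress curves.

All inputs can be generated synthetically with known ground truth
(`symring.synthetic_data`), so the whole pipeline is testable without
downloading any structure or dataset.

## Worked example

```python
import numpy as np
from symring import (ToySpec, make_toy_monomer, make_c2_dimer_template,
                     build_dimer, closest_axis_choice, scan_landscape, find_minima)

monomer  = make_toy_monomer(ToySpec(n_residues=30, shape="helical_bundle"))
template = make_c2_dimer_template(monomer, separation=48.0)
dimer    = build_dimer(monomer, template)
axis     = closest_axis_choice(dimer, direction=(0, 0, 1))   # spin about the C2 axis

landscape = scan_landscape(dimer, R_grid=np.arange(10.0, 361.0, 10.0),
                           D_grid=[40.0, 44.0, 48.0], rotation_axis_choice=axis)
for r, d, e in find_minima(landscape)[:2]:
    print(f"R = {r:5.1f} deg  D = {d:4.1f} A  E = {e:9.4f} kcal/mol")
```

prints

```
R =  60.0 deg  D = 40.0 A  E =   -5.7513 kcal/mol
R = 240.0 deg  D = 40.0 A  E =   -5.7513 kcal/mol
```

the two lowest minima are exactly degenerate and 180° apart in R — the spin
degeneracy forced by the dimer's C2 symmetry — and the mean energy at
D = 40 Å (+266 kcal/mol over this grid) far exceeds that at 48 Å
(−1.5 kcal/mol), the collision regime at short inter-dimer distances.

On the kinetics side:

```python
from symring import relative_efficiency
from symring.reference_data import MDH_VARIANT_KINETICS

wt = MDH_VARIANT_KINETICS["WT"].kcat_over_km           # 165.9 /hr/mM
mt = MDH_VARIANT_KINETICS["F213V/F289L"].kcat_over_km  # 4200.4 /hr/mM
print(relative_efficiency(mt, wt))                     # 25.3
```

the F213V/F289L double mutant is 25.3-fold more catalytically efficient than
wild type.

More narrative scripts live in `examples/` (assembly + scan, interface and
burial mapping, the kinetics table, progress-curve readings, and a full
pipeline run); each prints its results with a line on what they mean. A thin
CLI (`symring run|build-dimer|scan|minima|interface|kinetics|simulate`) wraps
the same functions for shell use.

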