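# Methods

## Ring parameterisation and construction

An oligomeric ring of n units (default n = 5, units = C2 dimers, hence a
decamer of 10 chains) is parameterised by two variables: the spin angle R of
the unit about one of its own principal axes, and the neighbour distance D,
defined between the centers of geometry of the nearest monomers (chains) of
adjacent units. Construction proceeds by (i) computing the unit's principal
axes as eigenvectors of the unweighted gyration tensor about its center of
geometry (sorted by descending moment, signs fixed toward (1,1,1) with ties
broken toward +x); (ii) aligning the chosen axis with the global z axis and
spinning the unit by R about z through its own center — mathematically
identical to spinning about the original axis first, but numerically cleaner;
(iii) placing the unit's center at radius ρ on +x and replicating it by
rotations of 360/n about z, relabelling chains A, B, … so unit k holds chains
(km+1 … km+m).

The placement radius ρ is not free: it is solved by bisection on
ρ ∈ [D/4, 4D] so that the realised nearest-chain-COG distance between
adjacent units equals the requested D. The contract is 10⁻³ Å, but the
bisection is iterated to machine precision (relative bracket 10⁻¹³, ≤200
iterations): a loosely converged radius would leak through the steep
Lennard-Jones core and break the exact spin-degeneracy of symmetric units at
the 10⁻⁶ kcal/mol level. If the requested distance cannot be bracketed the
build fails with the achieved range; during a grid scan such points are
recorded at the per-pair cap with a warning instead of aborting.

Which principal axis "the" spin axis should be is genuinely open (elongated
units put a symmetry axis at the largest moment, flat ones at the smallest),
so the choice is exposed (`rotation_axis_choice`, default "first") and a
helper (`closest_axis_choice`) selects the choice closest to a known
direction such as a dimer's C2 axis.

Angle convention: R is interpreted modulo 360° with 360° as the label for a
full turn, and the default grid runs 2–360° in 2° steps (180 values) with
distances 40–50 Å in 2 Å steps (6 values).

## Inter-chain energy

Assemblies are scored with a capped 12-6 Lennard-Jones potential summed over
atom pairs in *different* chains within a cutoff:

E = Σ min( 4ε[(σ/r)¹² − (σ/r)⁶], cap ),  r < r_cut

with defaults ε = 0.2 kcal/mol, σ = 5.0 Å (minimum at 2^{1/6}σ ≈ 5.6 Å,
about a Cα–Cα contact distance across an interface), r_cut = 12 Å,
cap = 100 kcal/mol per pair, evaluated on Cα atoms only. The cap keeps
colliding geometries finite and plottable; intra-chain pairs are excluded so
the score measures only chain packing. No minimisation is performed — the
scan is rigid-body and fully deterministic. This potential is intentionally
simple: the analysis needs the qualitative structure of the landscape (where
rings clash, where they pack) rather than absolute energies, and the settings
are exposed so assemblies can be re-scored externally. Neighbour search uses
a k-d tree; the test suite requires exact agreement (10⁻⁹) with an O(N²)
pair loop.

Limitations: no bonded terms, electrostatics, solvation or flexibility, so
absolute energies and the precise minima locations of any particular protein
are outside what this score can reproduce; only landscape structure
(degeneracies, clash regimes, relative basin depths on one system) is
meaningful.

## Geometry

Center of geometry, radius of gyration and principal axes are unweighted
(the pipeline operates on Cα traces, where mass weighting is moot).
Superposition uses the Kabsch least-squares rotation (via
`scipy.spatial.transform.Rotation.align_vectors`, which includes the
reflection guard) with positional 1:1 correspondence — the inputs are copies
of one monomer, so no sequence alignment is needed. RMSD is reported after
the transform; `rmsd` itself never superposes.

## Interface and burial

An interface residue has ≥1 heavy atom within a cutoff (default 5 Å,
a common heavy-atom contact convention; no standard exists, so it is
configurable and echoed in report headers) of the partner chain. Burial is a
neighbour-count proxy for solvent accessibility: the number of Cα atoms of
all chains within 10 Å of the residue's Cα, classified buried (≥28),
intermediate, or exposed (≤18). The thresholds are package conventions
calibrated to typical all-atom protein packing; on sparse synthetic shells
most residues classify as exposed, which is expected. Hydrogens are excluded
everywhere. `residues_near_points` lists residues near arbitrary probe
coordinates (e.g. a docked cofactor) the same way. Distances are exact
all-pairs computations; structures at this scale do not need an index.

## Kinetics and progress curves

`fit_michaelis_menten` fits v = V_max·S/(K_m+S) by nonlinear least squares
(trust-region reflective, positivity bounds, relative tolerances 10⁻¹⁰),
initialised at V_max⁰ = max rate and K_m⁰ = the interpolated S at half-max.
The default weighting is *relative* (σᵢ ∝ vᵢ): initial-rate assays have
errors that scale with the signal (constant CV), and relative weighting is
the matching variance model (the classic "1/Y²" weighting of enzymology);
unweighted fitting is available via `weighting="absolute"`. Noise-free data
are recovered to 10⁻⁶ relative; at 5 % CV and n = 8 concentrations spanning
0.1–10 mM the median K_m error over 200 replicates is below 5 %.
k_cat = V_max/[E] is computed only when the molar enzyme concentration is
supplied — published assays often state enzyme mass, and guessing a molar
mass (monomer vs decamer) would bake in an error.

Relative efficiency is the ratio of catalytic efficiencies rounded half-up
to one decimal, matching how such tables are printed. Note that published
kcat/Km columns are typically replicate-wise means of ratios, not ratios of
the tabulated mean kcat and Km; the package keeps both quantities distinct
(`catalytic_efficiency` of fitted parameters vs a reported-efficiency
column).

Half-decay time is read directly off the curve — the first crossing of half
the initial value, linearly interpolated between samples — rather than by
exponential fitting, because that is how such readings are quoted; a curve
that never reaches half raises an error carrying the final fraction.
Growth resumption after a toxic treatment is the first sample exceeding the
OD at treatment by 20 % (relative threshold δ, configurable) and
non-decreasing over the next 2 samples; a lone final point cannot qualify
(sustained growth needs at least one later sample), and "never resumed"
returns a sentinel (None) rather than a time.

## Synthetic data

Generators are pure functions of spec + seed (bit-reproducible) and embed
their ground truth in the returned object's metadata.

Structures are Cα-only toys: full side chains would add nothing the Cα-based
energy and interface machinery can see. The `helix` shape is an ideal
α-helical trace (rise 1.5 Å/residue, twist 100°/residue, radius 2.3 Å). The
`helical_bundle` shape winds the trace around a cylinder of radius 20 Å —
chosen to give a 30-residue toy the ~40 Å footprint of a globular,
MDH-sized (~380-residue) subunit, so the default 40–50 Å distance scan spans
the physically relevant touching-to-separated regime. The C2 dimer template
places two monomer copies with centers `separation` apart; for the default
z axis the 180° map is the exact sign flip diag(−1,−1,1), so the C2 symmetry
holds to the last bit and the spin-degeneracy tests are exact rather than
approximate. Fixtures use separation 48 Å, which puts the two shells'
closest atoms near the Lennard-Jones minimum (a favourable contact
interface). Kinetic rates carry multiplicative noise (CV-scaled, matching
assay behaviour); OD curves carry additive noise.

What the toys do *not* emulate: real packing density, side-chain chemistry,
sequence effects, or the specific homology-model geometry of any real
protein. Passing tests therefore demonstrate the correctness and the
symmetry/clash structure of the machinery, not the energetics of a
particular MDH decamer.

## Pipeline and determinism

`run_decamer_analysis` executes monomer → dimer (template superposition) →
landscape scan → minima → decamer models → interface/burial reports →
optional kinetics table, all under one output directory with a JSON manifest
recording the resolved config, package version, seed and outputs. All
tabular outputs are written with fixed formats so a re-run from the same
config (or from the manifest alone) is byte-identical. The scan itself is
deterministic; the seed is recorded for the synthetic-data subcommands.
Failures mark the manifest with the failing stage and exit non-zero.

## Problem sizes

Default test and acceptance workloads use a 60-atom C2 dimer over the full
180×6 grid (≈10 s), 200 kinetic-fit replicates (≈5 s), and 100 superposition
trials against 1000 random placements — sizes at which every check, including
the full-grid ring-distance fidelity sweep, completes on a single CPU in
well under a minute.
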