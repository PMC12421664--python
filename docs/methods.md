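# Methods

## Scope and model

`ledkit` implements the desk-side machinery of a local energy decomposition
(LED) study: everything before and after the quantum-chemistry engine runs.
The supersystem interaction energy is defined as the supersystem energy
minus the sum of the part energies at the supersystem geometry (geometric
deformation energy is deliberately not considered). It is decomposed as

    dE_int = Σ_X dE_el-prep^X + Σ_{X>Y} ε(X,Y)

with ε(X,Y) = ε_elstat + ε_exch + ε_no-disp + ε_disp (+ ε_solv under an
implicit solvent). All energies are carried in Hartree internally and
converted once, at the matrix layer, with 1 Eh = 627.5094740631 kcal/mol.

Matrix semantics. In the *standard* layout the diagonal holds the cumulative
electronic preparation dE_el-prep^X = intra_X(supersystem) − intra_X(part);
off-diagonal cells hold ε components — differential (supersystem minus the
subsystem's own calculation) for pairs within one subsystem, direct
supersystem values for spanning pairs. The *fp* layout redistributes the
diagonal over pairs (see below) so every element is a pair quantity with
zero diagonal. Two-body matrices are populated only at spanning-pair cells;
cells with no two-body counterpart are *absent* (NaN internally, empty in
exports — never zero, so sums are unaffected). Cooperativity is the
cellwise N-body minus two-body difference; where the two-body term is
absent the N-body value passes through and the pair cell is flagged fully
cooperative (the diagonal is excluded from that flag — full cooperativity
is a pair-cell notion).

Counterpoise handling. In corrected mode every part (subsystem or monomer)
is computed in an enlarged basis with the partner atoms as ghosts; the
enumeration emits two monomer inputs per spanning pair with real and ghost
fragments exchanged. Uncorrected mode uses isolated parts and one monomer
per fragment. The supersystem and pair calculations are shared between the
two modes physically; the campaign bookkeeping counts them in each setup,
which yields the per-setting totals 1+S+P+F (uncorrected) and 1+S+3P
(corrected) — 18 and 30 for two three-fragment subsystems. Whether both
setups of one setting could share one supersystem file is a deduplication
question the bookkeeping deliberately ignores.

HFLD. For HFLD (or multilevel-equivalent) records the non-dispersive
correlation components and the correlation part of the electronic
preparation are zeroed and flagged, record totals are recomputed, and
reference-level terms plus dispersion survive. The operation is idempotent
and guarded against non-HFLD records.

## fp electronic-preparation partitioning

The exact mutual-perturbation formula behind the original fp scheme is not
reproduced here; the contract every scheme must honour is exact
conservation, Σ_{X>Y} dE_el-prep^XY = Σ_X dE_el-prep^X. Two built-ins are
provided and the scheme id is stamped into output metadata:

* `equal` (default): fragment X's preparation splits evenly over its F−1
  partners; the (X,Y) cell collects both members' shares.
* `prop_eps`: X's shares are proportional to |ε_total(X,Y)| over its
  partners, falling back to the equal split when all magnitudes vanish.

The reference and correlation parts of the preparation are redistributed
with the same weights, so the split stays consistent under extrapolation.
Implementers with the original pairwise formula can register it behind the
same conservation contract.

## Fragmentation engine

Atoms i, j are bonded when dist(i,j) ≤ cutoff_scale·(r_i + r_j) with
bundled single-bond covalent radii (Cordero 2008 values; high-spin entries
where the source lists two), or when dist ≤ absolute_cutoff if that
override is set. Defaults: cutoff_scale = 1.15 (a common covalent-bond
heuristic), absolute_cutoff unset; both are user parameters. Coordination
caps prune an over-coordinated atom's edges farthest-first with ties broken
toward the lower neighbour index; custom bond/break entries are applied
last and have the final word. Fragments are connected components, numbered
1..F by lowest atom index, which makes labels reproducible and is what the
label-alignment step presupposes. Distances are in Å throughout.

## Label alignment and merging

Child fragments (subsystem/pair/monomer files use local labels) are mapped
onto supersystem labels by exact element-sequence match plus per-atom
coordinate agreement within 1e-4 Å (configurable); assignment is greedy
nearest-neighbour with conflict detection, so the result is bijective onto
its image and invariant to fragment storage order. Merging an alternative
output fills only fields the main record lacks; a disagreement on a field
both carry keeps the main value and logs a warning, and every filled field
is recorded in the merged record's provenance.

## Extrapolation

Reference-level quantities (ε_elstat, ε_exch, ε_solv, reference part of the
preparation) follow E(n) = E_CBS + A·exp(−α√n); correlation quantities
(ε_no-disp, ε_disp, correlation preparation) follow E(n) = E_CBS + B·n^−β.
Defaults α = 4.420, β = 2.460 for cardinals 2/3 and α = 5.460, β = 3.050
for 3/4 ship as a user-overridable CSV table keyed by basis family — table
data, not constants. CPS applies E = E_X + F·(E_Y − E_X) (default F = 1.5,
overridable) to correlation quantities only; reference terms pass through
from the tighter-threshold calculation, since PNO truncation does not
affect the reference energy. ε_solv is treated as reference-level: the
implicit-solvent contribution enters at the SCF level. Both forms are
affine in (E_X, E_Y), so extrapolation commutes with any linear combination
of LED terms; matrix extrapolation is elementwise with totals recomputed
and absent cells preserved. Degenerate parameter sets (coinciding
exponential factors or cardinals) raise rather than returning noise.

## Mock-data generator

The generator stands in for the engine. Geometries are rigid O-H-H units
(O–H ≈ 0.96 Å, ±0.02 Å seeded jitter) on a 4.2 Å grid, so intra-unit
distances bond and inter-unit distances never do. Energies are planted
additively — supersystem terms = isolated terms + perturbations — with
magnitudes imitating real data: monomer intra energies near −76 Eh,
interfragment components within roughly −30…+10 kcal/mol, preparation
perturbations of a few kcal/mol, and counterpoise lowerings that keep every
corrected monomer at or below its uncorrected energy. Every record's total
is the exact sum of its parts, so conservation between dE_int and both
matrix layouts holds to machine precision by construction. For
extrapolation tests the two settings are generated exactly on the CBS/CPS
model forms with per-term random coefficients, alongside the planted limit.

What this does and does not show: passing tests certify the bookkeeping,
parsing, assembly arithmetic, conservation laws and extrapolation algebra —
not the physics of any electronic-structure method. Mock energies have no
geometry dependence, no basis-set meaning beyond the planted model forms,
and real engine outputs may print cosmetic variants outside the documented
grammar.

## Numerical choices

* Writer prints energies at 12 decimal places; pair blocks carry a stored
  total validated against the component sum to 1e-9 Eh.
* Coordinate matching tolerance 1e-4 Å; coordinates printed at 6 decimals.
* Conservation assertions in the tests use 1e-6 kcal/mol on end-to-end
  (file-mediated) paths and 1e-9 on in-memory paths; extrapolation recovery
  is asserted to 1e-10 Eh.
* Problem sizes in tests and the acceptance script (S ≤ 3, f_i ≤ 4, 100
  campaign draws, 50 random geometries) keep every suite analytic and
  exact while covering all branch combinations; they are generator
  settings, not statistical samples, since every check is deterministic
  given the seed.
* Heat maps use a diverging colormap centered at zero (red = attraction,
  blue = repulsion); overlay boxes are derived from the subsystem map,
  never user-drawn. Spreadsheets store full-precision values with a
  2-decimal display format; CSV mirrors carry full precision.

## Known limitations

* No covalent fragment cutting: fragments are connected components, so
  bonded entities cannot be split into separate fragments (break-bonds can
  sever specific edges, but no capping or valence handling is done).
* Open-shell LED, atomic-level dispersion partitioning, triples-dispersion
  estimation and the distribution of implicit-solvation terms among
  fragments are out of scope; a parsed ε_solv component is carried but not
  further decomposed.
* The parser targets the documented grammar only; engine-version cosmetic
  variants need a thin translation step.
* The two fp partitioners are conservation-exact but heuristic; pairwise
  preparation values depend on the scheme and should be quoted with the
  scheme id (exports include it).
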