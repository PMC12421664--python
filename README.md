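# ledkit

Automation for **local energy decomposition (LED)** studies of molecular
interactions — the workflow around DLPNO-CCSD(T)/HFLD-level interaction
energies in multifragment systems such as DNA assemblies, protein–ligand
complexes, solute–solvent clusters and molecular crystals.

A complete LED study is mostly bookkeeping: a modest six-fragment system
already needs 18–30 single-point calculations per computational setting
(120 for a counterpoise-corrected study with combined CBS and CPS
extrapolation), and each output file yields dozens of decomposed energy
terms that must be matched across files. `ledkit` automates both ends:

* **Input side** — detects molecular fragments in an XYZ geometry from
  interatomic distances and covalent radii, then enumerates and renders
  every calculation an N-body and two-body LED analysis needs, with and
  without counterpoise (BSSE) correction, ghost atoms included.
* **Output side** — parses LED output files, aligns fragment labels across
  files, merges alternative outputs from partially crashed runs, assembles
  component-resolved interaction-energy matrices (standard and
  fragment-pairwise layouts), subtracts two-body from N-body matrices to
  expose cooperativity, extrapolates to the complete-basis-set and
  complete-PNO-space limits, and exports spreadsheets and heat maps.

Everything is testable without a quantum-chemistry engine: a ground-truth
generator plants component-resolved energies in grammar-conforming mock
output files, making conservation laws and recovery checks exact.

## The decomposition

The interaction energy of a supersystem — its energy minus the sum of its
parts' energies at the supersystem geometry — is split into intrafragment
and interfragment contributions:

```
ΔE_int = Σ_X ΔE_el-prep^X + Σ_{X>Y} ε(X,Y)                    (standard LED)
ΔE_int = Σ_{X>Y} [ ΔE_el-prep^XY + ε(X,Y) ] = Σ_{X>Y} ΔE_int^XY   (fp-LED)
```

`ΔE_el-prep^X` is the electronic preparation of fragment X — the cumulative
change of its internal energy caused by all other fragments; the
fragment-pairwise (fp) variant redistributes it over pairs so every matrix
element is a pair quantity. Each interfragment term resolves into physically
meaningful components:

```
ε(X,Y) = ε_elstat + ε_exch + ε_no-disp + ε_disp  [+ ε_solv]
```

For fragment pairs inside one subsystem (e.g. stacked bases on one DNA
strand) ε(X,Y) is a *differential* term — the perturbation of that pair's
energy by the other subsystems; across subsystems it is a genuine pair
interaction. In the HFLD scheme the non-dispersive correlation terms are
discarded and only reference-level terms plus London dispersion survive.

Two-body LED repeats the analysis on each isolated fragment pair spanning
two subsystems; subtracting the two-body matrix from the N-body matrix
isolates many-body (cooperative) effects. Reference energies are
extrapolated to the basis-set limit as `E(n) = E_CBS + A·exp(−α√n)`,
correlation energies as `E(n) = E_CBS + B·n^−β`, and PNO-truncated
correlation energies to the complete PNO space as
`E_CPS = E_X + F·(E_Y − E_X)`.

## Worked example

`examples/03_nbody_analysis.py` writes a mock counterpoise-corrected
campaign for a 2-subsystem × 2-fragment system, parses the outputs and
assembles both matrix layouts:

```
dE_int = -78.72 kcal/mol (supersystem minus counterpoise-corrected parts)

standard layout, total (diagonal = cumulative el-prep, off-diag = eps):
[[ -0.02  -2.85 -27.84 -11.12]
 [ -2.85   2.28 -17.69 -24.25]
 [-27.84 -17.69   2.77  -4.24]
 [-11.12 -24.25  -4.24   4.24]]

fp layout, total (every element a pair quantity, diagonal zero):
[[  0.    -2.1  -26.92  -9.71]
 [ -2.1    0.   -16.01 -22.08]
 [-26.92 -16.01   0.    -1.9 ]
 [ -9.71 -22.08  -1.9    0.  ]]

conservation: sum(std) = -78.719388, sum(fp) = -78.719388 kcal/mol
```

Rows/columns are fragments 1–2 (subsystem A) and 3–4 (subsystem B). In the
standard layout the diagonal holds each fragment's cumulative electronic
preparation and the off-diagonal cells the ε components (differential for
1–2 and 3–4, genuine for the four spanning pairs). The fp layout spreads
the preparation energy over pairs, so e.g. cell (1,3) = −26.92 kcal/mol is
the full pair interaction ΔE_int^XY. Both layouts sum to the same ΔE_int
exactly — they are repartitions of one number.

The other examples cover fragment detection (`01`), campaign enumeration
with the 18/30/72/120 input counts (`02`), two-body + cooperativity
analysis (`04`), and CBS/CPS extrapolation (`05`). The `ledkit` command
exposes the same stages as subcommands (`fragment`, `prep`, `nbody`,
`twobody`, `coop`, `extrapolate`, `heatmap`, `run`); `ledkit run
config.yaml` drives the whole pipeline from one YAML file.

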