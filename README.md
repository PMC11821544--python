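# pseudocage

Tools for the hierarchical design and analysis of pseudosymmetric protein
nanocages with icosahedral symmetry — the class-I Goldberg cage family in
which C3 trimers form wireframe shells of 240, 540, 960, … subunits.

Strictly symmetric protein cages top out at modest sizes because every
subunit must sit in an identical environment.  Pseudosymmetry breaks the
symmetry at the sequence level while keeping the backbone symmetric: a
homotrimer is converted into AAB/ABB heterotrimers by pairs of
interface-disrupting and rescuing mutations, the A chains keep an existing
two-fold inter-trimer interface, and the freed B chains accept one newly
designed interface to a CCC homotrimer.  Those few components then tile an
entire Goldberg lattice.  This package is aimed at protein designers and
structural bioinformaticians who want to generate, dock, size and validate
such cages computationally.

## The geometry in brief

For a lattice parameter h ≥ 2, the cage is the Goldberg polyhedron GP(h, 0)
with triangulation number **T = h²**: 20·T trimers (60·T chains) at the
polyhedron vertices, each chain pairing with exactly one chain of a
neighbouring trimer, leaving 12 pentagonal and 10(T − 1) hexagonal pores.
The component inventory follows from the lattice:

- 60 AAB heterotrimers in 12 **pentasymmetrons** (5 trimers per five-fold
  vertex, held by A:A contacts),
- 60(h − 2) ABB heterotrimers in 30(h − 2) **disymmetrons** (trimer pairs
  straddling icosahedral edges),
- 10h(h − 1) CCC and 10(h − 2)(h − 3) BBB homotrimers on the facets.

So h = 2 gives a 240-subunit cage, h = 3 gives 540, h = 4 gives 960, and
the series extends indefinitely by adding more BBB/CCC trimers and
disymmetrons — no new interface design required.

## Worked example

Command line:

```
$ cage stoich --h 3 --ratio
h=3 T=9
pentasymmetrons=12 disymmetrons=30
trimers: AAB=60 ABB=60 CCC=60 BBB=0 total=180
chains: A=180 B=180 C=180 total=540
mix AAB:ABB:CCC:BBB = 1:1:1:0
```

Read: the T = 9 cage needs 12 pentasymmetrons, 30 disymmetrons and 60 CCC
homotrimers (540 chains in total), and its components assemble at a 1:1:1
molar trimer ratio.  `cage build --h 3 --trimer synthetic --out m.cif`
writes the corresponding 540-chain atomic model (mmCIF, one label per
chain); `cage layout`, `cage dock`, `cage mutscan` and `cage compare`
expose the other stages.

The same through the library:

```python
from pseudocage import blocks, lattice

tri = blocks.synthetic_trimer(radius=3.0, n_residues_per_chain=8,
                              seed=1, bar_residues=3)
lc = blocks.recommended_lattice_constant(tri)   # 40.62 A tip-to-tip spacing
lay = lattice.layout(3, lc)
model = blocks.assemble_cage(lay, tri)

model.n_chains                 # 540
lattice.pore_census(lay)       # (12, 80) pentagonal/hexagonal pores
lattice.infer_h(model)         # 3  (recovered, not remembered)
lattice.predict_diameter(3)    # 73.5 nm, calibrated to 49 nm at h=2
lattice.predict_diameter(4)    # 98.0 nm
```

The diameter predictions are linear in h from a 49 nm calibration at h = 2
and land within 5% of measured design-model diameters (71 and 96 nm) —
flat-facet geometry accounts for the residual.

Real structures work the same way: `blocks.read_structure` accepts PDB or
mmCIF (for instance the trimeric aldolase 1WA3, or deposited cage models),
`mutscan.interface_contacts` applies the 4 Å heavy-atom contact rule to any
oligomer interface, and `cage compare design.cif observed.cif` reports
axis-aligned Cα r.m.s.d. plus per-component rotation/translation
deviations.  These real-data workflows need the files downloaded first and
are therefore not part of the automated test suite.

## Layout

```
src/pseudocage/
  symcore.py    icosahedral rotation group, axes, stabilizers, BIOMT export
  lattice.py    Goldberg layouts, stoichiometry, pores, diameters, infer_h
  blocks.py     structure I/O, synthetic trimers, pentasymmetron/disymmetron,
                cage assembly, asymmetric-unit extraction
  dock.py       4-DOF symmetric docking, contact/clash scoring, expansion
  mutscan.py    interface contacts, disrupt/rescue scan, coevolution channel
  compare.py    Kabsch, fixed-frame r.m.s.d., rigid-body deviation reports
  cli.py        the `cage` command-line interface
```

See `docs/methods.md` for the model, conventions, numerical choices and
limitations.
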