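# barrelforge

A toolkit for the rationally seeded computational design of single-chain
α-helical barrel proteins, and for analysing the coiled-coil structures the
designs are seeded from.

α-Helical barrels are assemblies of n ≥ 5 helices arranged around a central
axis with a continuous, solvent-accessible channel. Self-assembling barrel
*peptides* are well understood — the residues at the four interface
positions **g**, **a**, **d**, **e** of the heptad repeat *gabcdef*
deterministically select oligomer order and parallel/antiparallel topology —
but turning them into single-chain *proteins* requires connecting the
helices. This package implements that pipeline:

- **registers** — heptad register arithmetic; enumeration of g-a-d-e seed
  rules (e.g. the 20-rule panel g ∈ {A,G,L,M,S}, a,d ∈ {I,L}, e = A);
  installing rules into a charge-patterned "bar-magnet" background;
  threading rules onto existing scaffolds; percent-identity bookkeeping.
- **geometry** — PDB I/O (via gemmi), Kabsch superposition, backbone RMSD
  with explicit residue mappings ("middle helical turns" comparisons),
  helix detection and axis fitting, Cn-symmetry fitting and replication.
- **kih** — Socket-style knobs-into-holes detection (a knob's side-chain
  center within a 7.0/7.5 Å packing cutoff of a four-residue hole on one
  neighbouring helix), helix-interaction graphs with parallel/antiparallel
  orientations, barrel-cycle detection, and open-vs-collapsed calls from the
  maximal inscribed lumen radius along the axis.
- **connectors** — miniature tertiary-fragment search (joint superposition
  of stub windows against helix-loop-helix libraries), loop grafting with
  clash and peptide-bond checks, and Cn replication of
  helix-turn-helix-turn-helix units into single-chain scaffolds with n inner
  and n−1 buttressing helices (2n−1 helices; 13 for n = 7).
- **design_loop** — fixed/biased position constraints, surface
  hydrophobicity / net charge / energy / sequence-diversity filters, and
  convergence bookkeeping for iterative sequence design around pluggable
  (mockable) designer and predictor engines.
- **biophys** — mean residue ellipticity, MRE = θ·10⁶/(c·l·n), and the
  quadratic tight-binding isotherm
  y = B·[(c+x+K_d) − √((c+x+K_d)² − 4cx)]/(2c) fitted by bounded least
  squares for dissociation constants from dye-binding titrations.
- **fixtures** — parametric generation of ideal barrels (n = 2–8, parallel
  or antiparallel), connector units and fragment libraries from internal
  coordinates, so the whole pipeline runs and is tested without any
  structure downloads.

## Worked example

```python
from barrelforge import connectors, fixtures, geometry, kih

barrel = fixtures.make_barrel(fixtures.CrickParams(n=7), n_heptads=4)
knobs = kih.find_knobs(barrel, cutoff=7.0)
graph = kih.build_kih_graph(barrel, knobs)
profile = kih.lumen_profile(barrel, geometry.fit_cn_axis(barrel, 7))
print(len(knobs), graph.barrel_cycle, round(profile.min_radius, 2))

unit = fixtures.make_hth_unit("right", fixtures.HTHGeometry(n=7))
scaffold = connectors.assemble_parallel_scaffold(barrel, unit, 7)
print(len(scaffold.model.chains), len(scaffold.model.helices))
```

prints

```
42 ['A', 'B', 'C', 'D', 'E', 'F', 'G'] 3.48
1 13
```

i.e. the ideal heptamer shows 42 knobs (21 a-type, 21 d-type), a contiguous
seven-helix knob cycle — the barrel signature — and a 3.48 Å minimum lumen
radius (an open, water- and dye-accessible channel), and replicating the
three-helix connector unit about the C₇ axis yields the single-chain
13-helix design template. The `examples/` directory walks through each
capability the same way (seed rules, KIH analysis, short-loop fusion of an
antiparallel hexamer, parallel scaffolds, the design loop, binding/MRE
fits), and a thin CLI exposes the analysis entry points
(`barrelforge analyze | fit-binding | mre | make-fixtures | design`).

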