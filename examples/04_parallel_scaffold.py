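"""Close a parallel barrel into a single chain with buttressing helices.

Parallel neighbours are ~40 A apart end-to-start, too far for short loops,
so a helix-turn-helix-turn-helix unit is packed onto the barrel and
replicated about the Cn axis: n inner helices plus n-1 buttressing helices
threaded into one chain (2n-1 helices in total).
"""

from barrelforge import connectors, fixtures, geometry

inner = fixtures.make_barrel(fixtures.CrickParams(n=7), n_heptads=4)
gap = geometry.termini_gap(inner, inner.helices[0], inner.helices[1])
print(f"parallel termini gap: {gap:.1f} A (needs a structured connector)")

handed = connectors.select_unit_handedness(7)
unit = fixtures.make_hth_unit(handed, fixtures.HTHGeometry(n=7))
print(f"n=7 connector unit: {handed}-handed, "
      f"{len(unit.helices)} helices in one chain")

scaffold = connectors.assemble_parallel_scaffold(inner, unit, 7)
model = scaffold.model
print(f"assembled template: {len(model.chains)} chain, "
      f"{len(geometry.detect_helices(model))} helices, "
      f"{model.n_residues} residues")
print("unreconciled junctions:", scaffold.unreconciled)

for n in (5, 6, 8):
    u = fixtures.make_hth_unit(connectors.select_unit_handedness(n),
                               fixtures.HTHGeometry(n=n))
    b = fixtures.make_barrel(fixtures.CrickParams(n=n), 4)
    m = connectors.assemble_parallel_scaffold(b, u, n).model
    print(f"n={n}: {len(m.helices)} helices (2n-1 = {2 * n - 1})")
# The seven-inner-helix case gives the 13-helix single-chain template used
# to seed full sequence design.
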