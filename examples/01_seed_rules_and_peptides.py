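"""Enumerate g-a-d-e seed rules and build a seeded barrel peptide.

The interface positions g, a, d, e of the coiled-coil heptad select the
oligomer state; scanning small residue sets over them generates a design
panel, and each rule is installed into a common solvent-friendly background.
"""

from barrelforge import registers

rules = registers.enumerate_seed_rules(g_set="AGLMS", a_set="IL", d_set="IL",
                                       e_res="A")
print(f"screening panel: {len(rules)} g-a-d-e rules")
print("first five:", ", ".join(r.name for r in rules[:5]))

background = registers.BackgroundSpec.default(n_heptads=4)
peptide = registers.build_seed_peptide(registers.SeedRule("L", ("L",), ("I",), "A"),
                                       background)
print(f"\nLLIA peptide ({len(peptide)} residues, antiparallel-hexamer rule):")
print(" sequence:", peptide)
print(" register:", "".join(peptide.register))
print(" net charge:", sum(1 for r in str(peptide) if r in "KR")
      - sum(1 for r in str(peptide) if r in "ED"))

# The printed sequence repeats gabcdef with Leu at g/a, Ile at d, Ala at e,
# Glu->Lys 'bar-magnet' blocks at b/c and one Trp chromophore at an f site.
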