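"""Simulating a ground-truthed clade and round-tripping it through GenBank.

The generator emits complete annotated mitogenomes following the
canonical 37-gene vertebrate order, with the real gene overlaps
(ATP8/ATP6 -10 bp, ND4L/ND4 -7, ND5/ND6 -4, ATP6/COIII -1), incomplete
stop codons, and a fully structured control region.  Everything is
deterministic given the seed, and the truth record pins every planted
element for downstream validation.
"""

import tempfile
from pathlib import Path

from mitocomp import intergenic_table, read_genbank, write_genbank
from mitocomp.simulate import SimulationConfig, simulate_clade

clade = simulate_clade(SimulationConfig(seed=5, n_taxa=2))
g = clade.genomes[0]

print(f"{g.id}: {g.length_bp} bp, {len(g.features)} features")
print("\nconfigured gene overlaps reproduced in the annotation:")
for up, down, spacer in intergenic_table(g):
    if spacer < 0:
        print(f"  {up} / {down}: {spacer} bp")

print("\nplanted control-region elements (truth record):")
truth = clade.truth["cr"]
print(f"  ETAS: {truth['etas']['copies']} copies of a "
      f"{truth['etas']['period']} bp unit carrying TACAT")
print(f"  CSB offsets within CR: {truth['csb_offsets']}")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / f"{g.id}.gb"
    write_genbank(g, path)
    back = read_genbank(path)
    print(f"\nGenBank round trip: sequence identical = "
          f"{back.sequence == g.sequence}, features identical = "
          f"{[(f.name, f.start, f.end) for f in back.features] == [(f.name, f.start, f.end) for f in sorted(g.features, key=lambda x: (x.start, x.end))]}")
print("A byte-faithful round trip means analyses run identically from "
      "files or in memory.")
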