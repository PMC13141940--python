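"""Conservation mapping of interaction residues on a demo alignment.

Writes a tiny fictional FASTA alignment (synthetic sequences, not the real
homologs), maps salt-bridge-like positions onto it, and tabulates per-homolog
conservation. Real analyses would load a user-supplied alignment of MvaT
homologs instead.
"""

from pathlib import Path

from oligomod.conservation import (
    conservation_report,
    conserved_or_similar_counts,
    load_alignment,
    map_reference,
    report_to_tsv,
)

demo = Path("demo_alignment.fasta")
demo.write_text(
    ">refprot\nMSRLDELRAQFAAEIAALEAEGRALADELAEKEGISEREL\n"
    ">homolog1\nMSKLDELRAQYAAEVAALKAEGKALSNELAEKEGLSDREL\n"
    ">homolog2\nMSRLEELRAQFAAEI-ALEAEGRALADELAEKQGISEREL\n"
)

alignment = load_alignment(demo, "fasta")
cmap = map_reference(alignment, "refprot")
salt_bridge_positions = {3, 8, 27, 33, 37}
reports = conservation_report(cmap, salt_bridge_positions)
print(report_to_tsv(reports))
print()
for homolog, counts in conserved_or_similar_counts(reports).items():
    print(f"{homolog}: {counts['identical']}/{len(reports)} identical, "
          f"{counts['conserved_or_similar']}/{len(reports)} conserved-or-similar")
# each queried reference position is classified per homolog as identical,
# similar (same physicochemical group), different, or gap.
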