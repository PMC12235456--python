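"""Screen a protein for SRCR cysteine cores.

Builds a protein with two SRCR-like domains separated by linker sequence
and scans it with the default template (six conserved cysteines,
C-x(7,15)-C-x(10,18)-C-x(8,16)-C-x(2,6)-C-x(8,16)-C). Each hit spans the
matched cysteine core, 1-based amino-acid coordinates.
"""

from scari import ProteinRecord, instantiate_template, scan_srcr, classify_candidates

core = instantiate_template()
protein = ProteinRecord(
    protein_id="demo_p1",
    gene_id="demo_gene",
    sequence="M" + "G" * 30 + core + "S" * 25 + core + "G" * 20,
)

hits = scan_srcr(protein)
print(f"protein length {len(protein)} aa, {len(hits)} SRCR core(s):")
for h in hits:
    print(f"  {h.start}-{h.end}  ({h.n_cysteines_matched} cysteines matched)")

candidates = classify_candidates({"demo_gene": protein}, min_domains=2)
print("family candidates (>=2 domains):", candidates)
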