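"""Extract an anchor-bounded cluster and compare gene order across species.

A toy annotation mimics the real situation: RBP5/CLSTN3/PEX5 upstream,
CLEC4E/CLEC4D/CLEC6A downstream, receptor genes in between, one candidate
stranded on an unplaced scaffold. A second species carries the same genes
with two neighbours transposed; the order statistics quantify the
difference.
"""

from scari import AnchorSpec, GeneModel, compare_gene_order, extract_cluster


def annotation(species, order, scaffold_gene=None):
    genes, pos = [], 1000
    for name in order:
        symbol = name if not name.startswith("G") else ""
        genes.append(GeneModel(f"{species}_{name}", symbol, (), species,
                               "chr1", pos, pos + 500, "+", True))
        pos += 2000
    if scaffold_gene:
        genes.append(GeneModel(f"{species}_{scaffold_gene}", "", (), species,
                               "scaf_7", 100, 600, "+", False))
    return genes


layout_a = ["RBP5", "CLSTN3", "PEX5", "G1", "G2", "G3", "G4",
            "CLEC4E", "CLEC4D", "CLEC6A"]
layout_b = ["RBP5", "CLSTN3", "PEX5", "G1", "G3", "G2", "G4",
            "CLEC4E", "CLEC4D"]  # transposed G2/G3; CLEC6A missing (pig-like)

cands_a = {"spA_G1", "spA_G2", "spA_G3", "spA_G4", "spA_G5"}
cands_b = {"spB_G1", "spB_G2", "spB_G3", "spB_G4"}

cluster_a = extract_cluster(annotation("spA", layout_a, scaffold_gene="G5"),
                            AnchorSpec(), cands_a)
cluster_b = extract_cluster(annotation("spB", layout_b), AnchorSpec(), cands_b)

print("species A members:", cluster_a.member_ids(),
      "| unplaced:", [g.gene_id for g in cluster_a.unplaced_members])
print("species B members:", cluster_b.member_ids())

ortholog_map = {f"spA_G{i}": f"spB_G{i}" for i in range(1, 5)}
oc = compare_gene_order(cluster_a, cluster_b, ortholog_map)
print(f"\nshared orthologs: {oc.n_shared}")
print(f"longest common subsequence: {oc.lcs_length} "
      "(the transposition breaks one position)")
print(f"Kendall tau: {oc.tau:.3f}  (1 = identical order, -1 = reversed)")
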