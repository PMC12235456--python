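# scari

Synteny-anchored identification and standardized nomenclature for the
ungulate WC1/SCARI scavenger-receptor gene cluster.

## The problem

Scavenger receptor (SCAR) genes are innate-immunity cell-surface receptors.
Ungulates carry an expanded, primate/rodent-absent subfamily historically
called Workshop Cluster 1 (WC1): a tandem cluster of genes encoding
multi-SRCR-domain co-receptors of gamma-delta T cells, with very different
copy numbers across cattle, sheep, goat, pig and horse, and with several
members stranded on unplaced assembly contigs. Because the cluster has no
human orthologs, its members have never had systematic names. This package
implements, as tested and reusable components, the comparative-genomics
procedure for assigning standardized *SCARI* (scavenger receptor class I
member) symbols:

1. **Motif screen** — candidate family members are proteins containing
   SRCR cysteine cores (default template
   `C-x(7,15)-C-x(10,18)-C-x(8,16)-C-x(2,6)-C-x(8,16)-C`, configurable).
2. **Cluster extraction** — the cluster is located between conserved
   flanking anchors (RBP5, CLSTN3, PEX5 upstream; CLEC4E, CLEC4D, CLEC6A
   downstream) on each assembly; candidates elsewhere are "unplaced".
3. **Alignment** — representative (longest-isoform) proteins are aligned
   globally with free end gaps under Blosum62 (affine gaps, default
   open 12 / extend 3), pairwise and by progressive profile MSA.
4. **Phylogeny** — pairwise-deletion p-distances are corrected with the
   20-state Jukes–Cantor formula `d = -b ln(1 - p/b)`, `b = 19/20`; trees
   are built by neighbor-joining with bootstrap supports (default 100
   column resamples).
5. **Strict orthologs** — a query gene inherits a reference (cattle)
   gene's number iff the two are reciprocal nearest leaves, sit in a
   bootstrap-supported clade containing no other gene of either species
   (default threshold 70), and their gene order is concordant.
6. **Numbering** — reference genes are numbered consecutively along the
   chromosome (reserved numbers skipped), remaining query genes by
   position, unplaced genes last.

A birth–death gene-cluster simulator (`scari.simulate`) generates
multi-species annotations + proteins with known ortholog ground truth, so
every stage — and the pipeline end to end — is validated without any
downloads.

## Worked example

`python examples/simulate_and_name.py` simulates five species with eight
ancestral genes (no duplication/loss) and names them:

```
species  gene         symbol   rationale        true_group
cattle   cattle_g1    SCARI1   positional       L1
cattle   cattle_g2    SCARI2   positional       L2
...
cattle   cattle_g8    SCARI8   unplaced         L4
goat     goat_g1      SCARI1   strict_ortholog  L1
goat     goat_g4      SCARI8   strict_ortholog  L4
...
40/40 genes received their true ortholog group's number (cattle numbering
propagated by strict orthology).
```

Cattle genes are numbered by position (the gene from group L4 sits on an
unplaced contig, so it is named last, SCARI8); every other species' genes
recover exactly the number of their true ortholog group via the
tree+synteny strict-ortholog rule — including their own unplaced genes.
Other examples: `motif_scan.py` (SRCR hits with coordinates),
`align_and_tree.py` (JC distances vs p-distances and a 100%-supported
subfamily split), `synteny_compare.py` (LCS and Kendall tau for a
transposed gene order).

The same pipeline is scriptable from a shell:

```bash
scari simulate --seed 7 --out simdir
cd simdir && scari all --config config.yaml   # nomenclature.tsv, tree.nwk, ...
```

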