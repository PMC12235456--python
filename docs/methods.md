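# Methods

This note records the models, defaults and design choices behind the
package, and what the synthetic validation does and does not establish.

## Scope and data model

The pipeline takes per-species gene annotations (GFF3, gene features only)
and protein FASTA, plus a per-species list of placed chromosomes. All
coordinates are 1-based inclusive end to end — the GFF3 convention — so a
1-bp feature has `start == end` and no half-open conversions exist
anywhere. "Placed" is purely membership of the record's `seq_id` in the
configured chromosome list; unplaced contigs are whatever is left. Each
gene's representative protein is its longest isoform, ties broken by
lexicographically smallest protein id.

## SRCR motif screen

The family screen looks for the cysteine backbone of the SRCR domain. A
template is an ordered list of (min, max) spacing ranges between
consecutive conserved cysteines; the default,
`C-x(7,15)-C-x(10,18)-C-x(8,16)-C-x(2,6)-C-x(8,16)-C` with a nominal
domain length of 90–115 aa, is a generic SRCR-like pattern intended to be
replaced by a curated template where one exists. Scanning is left-greedy
and deterministic: positions are scanned left to right, at each position
the leftmost match with the lexicographically smallest gap vector is
taken, and scanning resumes after it, so hits never overlap. Spacers may
contain cysteines (real SRCR domains carry non-conserved cysteines beyond
the backbone). A reported hit spans the matched cysteine core only. The
template's `max_domain_len` caps the allowed core span; `min_domain_len`
is descriptive metadata for the full domain (the 41–77 aa core sits inside
a ~100 aa domain whose outer boundaries a spacing pattern cannot call), so
it is validated but not enforced on the core. A gene is a family candidate
when its representative protein contains at least `min_domains` cores
(default 1).

## Cluster extraction

Anchors are matched by symbol or alias per assembly unit; the unit with
the most anchors (at least `min_anchors_per_side` on each side, default 1
— the pig annotation lacks CLEC6A and must still work) wins. Where an
anchor is tandemly duplicated, the copy nearest the candidates bounds the
cluster ("innermost anchor"). Members are always ordered by ascending
start coordinate regardless of strand. Candidates on the winning unit but
outside the anchor interval are retained with a `split_cluster` flag
(mirroring the goat cluster, which is split by the conserved CLEC/CD163
block) rather than dropped; candidates on any other unit are unplaced
members. Gene-order conservation between two clusters is summarised by the
number of shared orthologs, the longest common subsequence of their
orderings, Kendall's tau over shared ranks (undefined below two shared
genes), and a separate count of strand flips.

## Alignment

Pairwise alignment is the Gotoh three-state affine dynamic programme under
Blosum62. A gap run of length g costs `open + (g-1)·extend`; defaults
open 12, extend 3, a common Blosum62 pairing, both configurable. With
`free_end_gaps` (the default) terminal gap runs in either sequence cost
nothing — the right mode when domain counts differ between family members.
Traceback is deterministic: ties resolve diagonal > up > left, and among
co-optimal end points the corner is preferred, then the shortest trailing
gap. The multiple aligner is progressive: a guide tree from 3-mer-identity
distances via the package's neighbor-joining, then profile–profile merges
scored by the average pairwise substitution score (gap/residue pairs score
zero), with "once a gap, always a gap". One caveat found by property
testing and worth knowing: with free end gaps, extending both sequences by
identical residues can *decrease* the optimal score (a formerly free
terminal gap becomes internal), so that monotonicity only holds in plain
global mode.

## Distances, trees, bootstrap

p-distances use pairwise deletion: columns where either row is gapped are
excluded for that pair; a pair with no comparable columns is an error. The
Jukes–Cantor correction is the 20-state generalization
`d = -b·ln(1 - p/b)` with `b = 19/20`, i.e. equal exchange rates among all
residues — chosen to match the simulator's substitution model so distance
recovery is a fair calibration. At `p >= b` the correction saturates:
the default policy is an error; the pipeline configures a cap (default
5.0 substitutions/site) so that bootstrap replicates of highly diverged
columns remain buildable.

Neighbor-joining is the standard Q-criterion agglomeration. Determinism is
pinned down: Q ties break by the lexicographically smallest taxon pair
(internal nodes keyed by their smallest descendant leaf), and negative
branch lengths are clamped to zero with the deficit logged. On additive
matrices the implementation recovers the generating topology exactly (and
agrees with scikit-bio's independent implementation in the tests).
Bootstrap resamples alignment columns with replacement; replicate r draws
from an independent stream derived from (seed, r), so supports are
reproducible and invariant to taxon input order. Support is the percentage
of replicates whose tree contains the bipartition.

## Strict orthologs and numbering

A query gene is a strict ortholog of a reference gene iff

1. the two are reciprocal nearest leaves across the species by patristic
   distance (ties by name);
2. some clade contains both and **no other gene of either species**, with
   bootstrap support at or above the threshold (default 70). The best such
   clade's support is reported. When the only containing "clade" is the
   whole unrooted tree there is no internal bipartition that could refute
   the pair, and it counts as 100;
3. the pair's gene order is concordant: the query gene lies on a longest
   common subsequence of the two cluster orderings under the
   reciprocal-pair map. Genes without order context (unplaced, or paired
   with an unplaced reference gene) are vacuously concordant.

Condition 2 deliberately does not score the literally smallest clade
containing the pair: with several species per ortholog group, the
within-group branching order is often poorly supported even when the group
itself is rock solid, and scoring the smallest clade would reject clean
1:1 pairs for noise. Requiring a supported clade that excludes all other
genes of the two species keeps those pairs while still rejecting pairs
entangled with lineage-specific duplicates (any clade isolating such a
pair from the duplicate is either absent or unsupported).

Reference-species numbering is positional: placed members in ascending
coordinate order (split-cluster members keep their coordinate rank),
skipping configured reserved numbers; unplaced members are numbered after
all placed ones, ordered by (contig, start). Query species inherit numbers
through strict orthologs — unplaced query genes included — and remaining
genes take the smallest unused numbers, placed first by coordinate, then
unplaced. Two query genes claiming one reference gene is a hard error
rather than a silent tie-break (such cases need expert review); with
reciprocal-nearest pairing this cannot arise inside the pipeline, only
through the public API. Numbering is stable (appending unplaced genes
never renumbers placed ones) and deterministic (identical inputs give
byte-identical tables).

## The simulator

`simulate_cluster` emulates the family's situation: an ancestral tandem
cluster of `ancestral_cluster_size` genes (default 8) between the six
anchor genes, evolving along a five-taxon ultrametric species tree
(cattle, sheep, goat, pig, horse; root-to-tip depth 0.2 time units). Per
branch, each gene copy undergoes a linear birth–death process
(`dup_rate` 0.05, `loss_rate` 0.02 per gene per unit time by default);
duplicates insert adjacent to the parent, preserving tandem order.
Proteins evolve by Poisson(`sub_rate` × branch length × mutable sites)
substitutions, uniform over the 19 alternative residues — exactly the
model the 20-state Jukes–Cantor correction inverts. The default
`sub_rate` 0.75 yields at most ~0.3 substitutions/site between any two
tips of one ortholog group.

All ancestral paralogs descend from a single family root, each separated
from it by `paralog_divergence` (default 0.3 substitutions/site). This
matters: were paralogs independent random sequences, every between-group
distance would saturate and free-end-gap profile alignment could stack
unrelated groups disjointly; real tandem families are homologous, and the
default keeps between-group identity around 40–55%.

Ancestral proteins (default 240 aa) carry two embedded SRCR cores whose
backbone cysteines are invariant sites — purifying selection on the
residues that define the domain — so the motif screen remains a faithful,
non-trivial pipeline stage at realistic divergence. Substitution rates
apply per mutable site. Coordinates are synthetic but deterministic
(10 kb genes, 5 kb spacing); each tip gene is emitted on its own synthetic
contig with probability `unplaced_fraction` (default 0.1). Anchor genes
receive short cysteine-free proteins so they can never pass the screen.
Everything is reproducible from the single config seed, and
`expected_tip_count` gives the closed-form birth–death expectation
(ancestral size × exp((λ−μ)·depth)), checked against Monte-Carlo in the
tests.

What the simulator does *not* model: indels (simulated protein families
are gap-free by construction — indel behaviour is exercised by hand-built
fixtures), codon-level evolution, rate heterogeneity beyond the invariant
cysteines, annotation errors other than unplaced contigs, and assembly
misorientation (strand flips are covered by fixtures). Passing the
end-to-end recovery tests therefore shows the machinery is correct under
the stated model, not that real annotations are this clean.

## Validation problem sizes

The test suite and the acceptance script size their computations for a
single CPU: 50 random additive matrices (6–10 taxa) for NJ consistency;
200 random pairs (length ≤ 6) against full enumeration of all alignments;
100 replicates × length 2000 per true distance for JC recovery; 20
simulated five-species replicates each for the no-event recovery check
(every gene must get its true group's number) and the duplication-rate
0.05 precision check (strict-ortholog precision ≥ 95%). The deposited
published nomenclature dataset is only consulted when present locally;
the corresponding test documents the expected per-species counts and
skips when the file is absent.
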