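"""End-to-end orchestration: annotations + proteins in, nomenclature out.

Stage order: motif screen -> cluster extraction -> representative protein
selection -> progressive alignment -> JC distances -> neighbor-joining with
bootstrap -> strict-ortholog calls -> nomenclature -> gene-order report.
All randomness derives from the config seed; a rerun with the same config
produces byte-identical outputs. Every written artifact is listed in a
MANIFEST with its content checksum, including partial output when a stage
fails.
"""

from __future__ import annotations

import hashlib
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as sio
from .alignment import MultipleAlignment, ScoringScheme, progressive_msa
from .errors import ConfigError, PipelineStageError, ScariError
from .motif import MotifTemplate, DEFAULT_SRCR_TEMPLATE, classify_candidates, scan_srcr
from .nomenclature import (
    OrthologAssignment,
    ReservedNumbers,
    assign_query_names,
    assign_reference_numbers,
    call_strict_orthologs,
    leaf_label,
    reciprocal_nearest_pairs,
    synteny_consistency,
)
from .phylogeny import PhyloTree, bootstrap_supports
from .synteny import AnchorSpec, ClusterRegion, compare_gene_order, extract_cluster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesInput:
    """Per-species input files and placed-chromosome list. ``gff3`` and
    ``fasta`` may be file paths or literal text (the io readers accept
    both)."""

    gff3: str
    fasta: str
    chromosomes: tuple[str, ...]


@dataclass(frozen=True)
class PipelineConfig:
    species: dict[str, SpeciesInput]
    reference_species: str
    anchors: AnchorSpec = field(default_factory=AnchorSpec)
    template: MotifTemplate = DEFAULT_SRCR_TEMPLATE
    min_domains: int = 1
    gap_open: int = 12
    gap_extend: int = 3
    free_end_gaps: bool = True
    support_threshold: float = 70.0
    reserved: frozenset = frozenset()
    n_bootstrap: int = 100
    saturation_cap: float | None = 5.0
    prefix: str = "SCARI"
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.reference_species not in self.species:
            raise ConfigError(
                f"reference species {self.reference_species!r} has no inputs"
            )
        if self.n_bootstrap < 1:
            raise ConfigError("n_bootstrap must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "PipelineConfig":
        def resolve(p: str) -> str:
            if base is not None and "\n" not in p and not Path(p).is_absolute():
                return str(base / p)
            return p

        species = {}
        for name, d in raw["species"].items():
            for key in ("gff3", "fasta"):
                p = resolve(d[key])
                if "\n" not in p and not Path(p).exists():
                    raise ConfigError(f"{key} file for {name!r} not found: {p}")
                d[key] = p
            species[name] = SpeciesInput(
                gff3=d["gff3"], fasta=d["fasta"], chromosomes=tuple(d["chromosomes"])
            )
        anchors = AnchorSpec(
            left_anchors=tuple(raw.get("anchors", {}).get("left", AnchorSpec().left_anchors)),
            right_anchors=tuple(raw.get("anchors", {}).get("right", AnchorSpec().right_anchors)),
            min_anchors_per_side=raw.get("anchors", {}).get("min_anchors_per_side", 1),
        )
        mot = raw.get("motif", {})
        template = (
            MotifTemplate(
                cysteine_spacings=tuple(tuple(x) for x in mot["spacings"]),
                min_domain_len=mot.get("min_domain_len", 90),
                max_domain_len=mot.get("max_domain_len", 115),
            )
            if "spacings" in mot
            else DEFAULT_SRCR_TEMPLATE
        )
        aln = raw.get("alignment", {})
        phy = raw.get("phylogeny", {})
        nom = raw.get("nomenclature", {})
        return cls(
            species=species,
            reference_species=raw["reference_species"],
            anchors=anchors,
            template=template,
            min_domains=mot.get("min_domains", 1),
            gap_open=aln.get("gap_open", 12),
            gap_extend=aln.get("gap_extend", 3),
            free_end_gaps=aln.get("free_end_gaps", True),
            support_threshold=nom.get("support_threshold", 70.0),
            reserved=frozenset(nom.get("reserved", ())),
            n_bootstrap=phy.get("n_bootstrap", 100),
            saturation_cap=phy.get("saturation_cap", 5.0),
            prefix=nom.get("prefix", "SCARI"),
            seed=raw.get("seed", 0),
            outdir=(
                str(base / raw["outdir"])
                if base is not None
                and raw.get("outdir")
                and not Path(raw["outdir"]).is_absolute()
                else raw.get("outdir")
            ),
        )

    def scheme(self) -> ScoringScheme:
        return ScoringScheme.blosum62(
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            free_end_gaps=self.free_end_gaps,
        )


@dataclass
class PipelineResult:
    records: list  # NomenclatureRecord, all species
    genes: dict[str, sio.GeneModel]
    clusters: dict[str, ClusterRegion]
    assignments: dict[str, list[OrthologAssignment]]
    tree: PhyloTree
    alignment: MultipleAlignment
    outputs: dict[str, str]  # filename -> content


def select_representative_protein(proteins_of_gene: list[sio.ProteinRecord]) -> sio.ProteinRecord:
    """Longest isoform; ties by lexicographically smallest protein_id."""
    if not proteins_of_gene:
        raise ScariError("gene has no proteins")
    return min(proteins_of_gene, key=lambda p: (-len(p.sequence), p.protein_id))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; see the module docstring for the order.

    Any module error propagates wrapped with the failing stage's name;
    artifacts written before the failure stay on disk with a MANIFEST.
    """
    outputs: dict[str, str] = {}
    stage = "setup"
    t0 = time.time()
    try:
        stage = "read_inputs"
        genes_by_species: dict[str, list[sio.GeneModel]] = {}
        reps: dict[str, dict[str, sio.ProteinRecord]] = {}
        for name in sorted(config.species):
            inp = config.species[name]
            genes_by_species[name] = sio.read_gff3(
                inp.gff3, inp.chromosomes, species=name
            )
            prots = sio.read_fasta(inp.fasta)
            by_gene: dict[str, list[sio.ProteinRecord]] = {}
            for p in prots:
                by_gene.setdefault(p.gene_id, []).append(p)
            reps[name] = {}
            for g in genes_by_species[name]:
                if g.gene_id not in by_gene:
                    warnings.warn(
                        f"{name}: gene {g.gene_id} has no protein; excluded",
                        stacklevel=2,
                    )
                    continue
                reps[name][g.gene_id] = select_representative_protein(
                    by_gene[g.gene_id]
                )
            logger.info(
                "stage=read_inputs species=%s genes=%d proteins=%d",
                name, len(genes_by_species[name]), len(prots),
            )

        stage = "motif_scan"
        candidates: dict[str, list[str]] = {}
        hit_lines = ["protein_id\tstart\tend"]
        for name in sorted(config.species):
            candidates[name] = classify_candidates(
                reps[name], config.template, config.min_domains
            )
            for gid in candidates[name]:
                for h in scan_srcr(reps[name][gid], config.template):
                    hit_lines.append(f"{h.protein_id}\t{h.start}\t{h.end}")
            logger.info(
                "stage=motif_scan species=%s candidates=%d", name, len(candidates[name])
            )
        outputs["hits.tsv"] = "\n".join(hit_lines) + "\n"

        stage = "cluster_extraction"
        clusters: dict[str, ClusterRegion] = {}
        cluster_lines = []
        for name in sorted(config.species):
            clusters[name] = extract_cluster(
                genes_by_species[name], config.anchors, set(candidates[name])
            )
            cluster_lines.append(clusters[name].to_tsv())
            logger.info(
                "stage=cluster_extraction species=%s members=%d unplaced=%d",
                name, len(clusters[name].members), len(clusters[name].unplaced_members),
            )
        header, *_ = cluster_lines[0].splitlines()
        body = [ln for block in cluster_lines for ln in block.splitlines()[1:]]
        outputs["clusters.tsv"] = "\n".join([header] + body) + "\n"

        stage = "alignment"
        named_seqs = []
        for name in sorted(config.species):
            for g in clusters[name].all_candidates():
                named_seqs.append(
                    (leaf_label(name, g.gene_id), reps[name][g.gene_id].sequence)
                )
        if len(named_seqs) < 2:
            raise ScariError("fewer than 2 cluster genes across all species")
        aln = progressive_msa(named_seqs, config.scheme())
        outputs["alignment.afa"] = aln.to_fasta()
        logger.info("stage=alignment n_seqs=%d length=%d", len(named_seqs), aln.length)

        stage = "phylogeny"
        tree = bootstrap_supports(
            aln, n_reps=config.n_bootstrap, seed=config.seed,
            cap=config.saturation_cap,
        )
        outputs["tree.nwk"] = tree.to_newick()
        logger.info("stage=phylogeny taxa=%d", len(tree.taxa))

        stage = "nomenclature"
        ref = config.reference_species
        ref_records = assign_reference_numbers(
            clusters[ref], ReservedNumbers(config.reserved), prefix=config.prefix
        )
        all_records = list(ref_records)
        assignments: dict[str, list[OrthologAssignment]] = {}
        for name in sorted(config.species):
            if name == ref:
                continue
            pair_map = reciprocal_nearest_pairs(tree, ref, name)
            syn = synteny_consistency(clusters[ref], clusters[name], pair_map)
            asg = call_strict_orthologs(
                tree, ref, name,
                support_threshold=config.support_threshold, synteny=syn,
            )
            assignments[name] = asg
            all_records.extend(
                assign_query_names(asg, clusters[name], ref_records, prefix=config.prefix)
            )
            logger.info(
                "stage=nomenclature species=%s strict=%d total=%d",
                name, sum(a.strict for a in asg), len(asg),
            )
        gene_index = {
            g.gene_id: g for gl in genes_by_species.values() for g in gl
        }
        outputs["nomenclature.tsv"] = sio.write_nomenclature_table(
            all_records, gene_index, prefix=config.prefix
        )

        stage = "synteny_report"
        sym_of = {(r.species, r.gene_id): r.proposed_symbol for r in all_records}
        order_lines = [
            "species_a\tspecies_b\tn_shared\tlcs_length\ttau\tstrand_flips"
        ]
        names = sorted(config.species)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                gene_by_sym_b = {
                    sym_of[(b, g.gene_id)]: g.gene_id for g in clusters[b].members
                }
                omap = {
                    g.gene_id: gene_by_sym_b[sym_of[(a, g.gene_id)]]
                    for g in clusters[a].members
                    if sym_of.get((a, g.gene_id)) in gene_by_sym_b
                }
                oc = compare_gene_order(clusters[a], clusters[b], omap)
                tau = "NA" if oc.tau is None else f"{oc.tau:.4f}"
                order_lines.append(
                    f"{a}\t{b}\t{oc.n_shared}\t{oc.lcs_length}\t{tau}\t{oc.strand_flips}"
                )
        outputs["order_conservation.tsv"] = "\n".join(order_lines) + "\n"
        logger.info("pipeline done in %.1fs", time.time() - t0)
    except ScariError as exc:
        _write_outputs(config.outdir, outputs)
        raise PipelineStageError(stage, exc) from exc

    _write_outputs(config.outdir, outputs)
    return PipelineResult(
        records=all_records,
        genes=gene_index,
        clusters=clusters,
        assignments=assignments,
        tree=tree,
        alignment=aln,
        outputs=outputs,
    )


def _write_outputs(outdir: str | None, outputs: dict[str, str]) -> None:
    if outdir is None:
        return
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for name in sorted(outputs):
        (out / name).write_text(outputs[name])
        digest = hashlib.sha256(outputs[name].encode()).hexdigest()
        manifest.append(f"{name}\t{digest}")
    (out / "MANIFEST.tsv").write_text("\n".join(manifest) + "\n")
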