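"""Readers, writers and core annotation types.

All genomic coordinates are 1-based inclusive (the GFF3 convention) and are
kept that way throughout the package; a 1-bp feature has ``start == end``.
"""

from __future__ import annotations

import io as _io
import re
import warnings
from dataclasses import dataclass, field

import gffutils.feature
import skbio
from Bio import SeqIO

from .errors import Gff3ParseError, FastaError, NomenclatureTableError, NewickError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in protein sequences: the 20 standard amino acids plus X
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")

RATIONALES = ("strict_ortholog", "positional", "unplaced")


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene on one assembly unit.

    ``placed`` is True iff ``seq_id`` is a named chromosome for the species
    (membership in a per-species chromosome list); anything else — scaffolds,
    unlocalized or unplaced contigs — is treated as unplaced.
    """

    gene_id: str
    symbol: str
    aliases: tuple[str, ...]
    species: str
    seq_id: str
    start: int
    end: int
    strand: str
    placed: bool

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence linked to its parent gene."""

    protein_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise FastaError(
                f"protein {self.protein_id}: invalid residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NomenclatureRecord:
    """Final proposed symbol for one gene, with the rule that produced it."""

    gene_id: str
    species: str
    proposed_symbol: str
    rationale: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.rationale not in RATIONALES:
            raise ValueError(f"unknown rationale {self.rationale!r}")

    def number(self, prefix: str = "SCARI") -> int:
        m = re.fullmatch(re.escape(prefix) + r"(\d+)", self.proposed_symbol)
        if not m or int(m.group(1)) < 1:
            raise ValueError(
                f"{self.proposed_symbol!r} does not match {prefix}<positive integer>"
            )
        return int(m.group(1))


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(
    path_or_text: str,
    chromosome_list: list[str] | tuple[str, ...] | set[str],
    species: str = "",
    feature_types: tuple[str, ...] = ("gene",),
) -> list[GeneModel]:
    """Read gene features from a GFF3 file (or literal GFF3 text).

    Only features whose type is in ``feature_types`` are kept; one GeneModel
    per feature. ``placed`` is True iff the feature's seq_id appears in
    ``chromosome_list``. Coordinates stay 1-based inclusive.

    Raises :class:`Gff3ParseError` (naming the line) on a malformed line or
    a start > end coordinate pair. Warns if no gene features are found.
    """
    text = _slurp(path_or_text)
    chromosomes = set(chromosome_list)
    genes: list[GeneModel] = []
    seen_ids: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if line.count("\t") != 8:
            raise Gff3ParseError(
                f"line {lineno}: expected 9 tab-separated columns, "
                f"got {line.count(chr(9)) + 1}"
            )
        try:
            feat = gffutils.feature.feature_from_line(line)
        except Exception as exc:
            raise Gff3ParseError(f"line {lineno}: malformed GFF3 line ({exc})") from exc
        if feat.featuretype not in feature_types:
            continue
        if feat.start is None or feat.end is None:
            raise Gff3ParseError(f"line {lineno}: missing coordinates")
        if feat.start > feat.end:
            raise Gff3ParseError(
                f"line {lineno}: start {feat.start} > end {feat.end}"
            )
        if feat.strand not in ("+", "-"):
            raise Gff3ParseError(
                f"line {lineno}: strand {feat.strand!r} not '+' or '-'"
            )
        attrs = feat.attributes
        gene_id = attrs["ID"][0] if "ID" in attrs else f"line{lineno}"
        if gene_id in seen_ids:
            raise Gff3ParseError(f"line {lineno}: duplicate gene ID {gene_id!r}")
        seen_ids.add(gene_id)
        symbol = attrs["Name"][0] if "Name" in attrs else ""
        aliases = tuple(attrs["Alias"]) if "Alias" in attrs else ()
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=symbol,
                aliases=aliases,
                species=species,
                seq_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                placed=feat.seqid in chromosomes,
            )
        )
    if not genes:
        warnings.warn("no gene features found", stacklevel=2)
    return genes


def write_gff3(genes: list[GeneModel], source: str = "scari") -> str:
    """Render GeneModels as GFF3 text (gene features only)."""
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = [f"ID={g.gene_id}"]
        if g.symbol:
            attrs.append(f"Name={g.symbol}")
        if g.aliases:
            attrs.append("Alias=" + ",".join(g.aliases))
        lines.append(
            "\t".join(
                [
                    g.seq_id,
                    source,
                    "gene",
                    str(g.start),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path_or_text: str, gene_id_map: dict[str, str] | None = None) -> list[ProteinRecord]:
    """Read protein FASTA.

    Header dialect: the first whitespace-separated token is the protein_id;
    the gene link comes from the second token, unless ``gene_id_map``
    (protein_id -> gene_id) is supplied, which takes precedence. Sequences
    are uppercased; gap characters are rejected; duplicate protein ids and
    empty sequences are errors.
    """
    text = _slurp(path_or_text)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        tokens = rec.description.split()
        protein_id = tokens[0]
        if protein_id in seen:
            raise FastaError(f"duplicate protein id {protein_id!r}")
        seen.add(protein_id)
        if gene_id_map is not None:
            if protein_id not in gene_id_map:
                raise FastaError(f"protein {protein_id!r} missing from gene_id_map")
            gene_id = gene_id_map[protein_id]
        else:
            gene_id = tokens[1] if len(tokens) > 1 else protein_id
        seq = str(rec.seq).upper()
        if "-" in seq or "." in seq:
            raise FastaError(f"protein {protein_id!r}: gap characters not allowed")
        records.append(ProteinRecord(protein_id=protein_id, gene_id=gene_id, sequence=seq))
    return records


def write_fasta(records: list[tuple[str, str]], width: int = 60) -> str:
    """Render (name, sequence) pairs as FASTA; used for aligned-FASTA export."""
    out = []
    for name, seq in records:
        out.append(f">{name}")
        for i in range(0, len(seq), width):
            out.append(seq[i : i + width])
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Nomenclature TSV

NOMENCLATURE_COLUMNS = (
    "species",
    "gene_id",
    "current_symbol",
    "proposed_symbol",
    "rationale",
    "seq_id",
    "start",
    "end",
    "strand",
    "placed",
    "aliases",
)


def write_nomenclature_table(
    records: list[NomenclatureRecord],
    genes: dict[str, GeneModel],
    prefix: str = "SCARI",
) -> str:
    """Render the final nomenclature report as TSV.

    Deterministic: rows sorted by (species, proposed number). Duplicate
    (species, proposed_symbol) pairs are an error. Round-trips through
    :func:`read_nomenclature_table`.
    """
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.species, r.proposed_symbol)
        if key in seen:
            raise NomenclatureTableError(
                f"duplicate proposed symbol {r.proposed_symbol} in {r.species}"
            )
        seen.add(key)
        r.number(prefix)  # validates the SCARI<n> pattern
    rows = sorted(records, key=lambda r: (r.species, r.number(prefix)))
    lines = ["\t".join(NOMENCLATURE_COLUMNS)]
    for r in rows:
        g = genes[r.gene_id]
        lines.append(
            "\t".join(
                [
                    r.species,
                    r.gene_id,
                    g.symbol,
                    r.proposed_symbol,
                    r.rationale,
                    g.seq_id,
                    str(g.start),
                    str(g.end),
                    g.strand,
                    "true" if g.placed else "false",
                    ",".join(g.aliases),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def read_nomenclature_table(
    text: str,
) -> tuple[list[NomenclatureRecord], dict[str, GeneModel]]:
    """Parse a nomenclature TSV back into records + gene models."""
    lines = [ln for ln in text.splitlines() if ln]
    if not lines or tuple(lines[0].split("\t")) != NOMENCLATURE_COLUMNS:
        raise NomenclatureTableError("missing or malformed header")
    records: list[NomenclatureRecord] = []
    genes: dict[str, GeneModel] = {}
    for ln in lines[1:]:
        f = ln.split("\t")
        if len(f) != len(NOMENCLATURE_COLUMNS):
            raise NomenclatureTableError(f"bad column count in row: {ln!r}")
        rec = NomenclatureRecord(
            gene_id=f[1], species=f[0], proposed_symbol=f[3], rationale=f[4]
        )
        records.append(rec)
        genes[f[1]] = GeneModel(
            gene_id=f[1],
            symbol=f[2],
            aliases=tuple(a for a in f[10].split(",") if a),
            species=f[0],
            seq_id=f[5],
            start=int(f[6]),
            end=int(f[7]),
            strand=f[8],
            placed=f[9] == "true",
        )
    return records, genes


# ---------------------------------------------------------------------------
# Newick


def read_newick(text: str) -> skbio.TreeNode:
    """Parse Newick text; bootstrap supports arrive as internal-node labels."""
    try:
        return skbio.TreeNode.read(_io.StringIO(text), format="newick")
    except Exception as exc:
        raise NewickError(f"invalid Newick: {exc}") from exc


def write_newick(tree: skbio.TreeNode) -> str:
    """Render a tree as Newick; internal-node labels carry supports."""
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def _slurp(path_or_text: str) -> str:
    """Accept either a filesystem path or literal file content."""
    if "\n" in path_or_text or path_or_text.startswith(">"):
        return path_or_text
    with open(path_or_text) as fh:
        return fh.read()
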