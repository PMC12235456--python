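"""Scavenger-receptor cysteine-rich (SRCR) domain screening.

An SRCR domain is a ~100 aa module with a conserved chain of cysteines at
characteristic spacings. Candidate family members are recognised by counting
such cysteine-core matches in their representative protein. The template is
configuration data: the default below is a generic SRCR-like pattern and is
meant to be replaced with a curated one where available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ConfigError
from .io import ProteinRecord


@dataclass(frozen=True)
class MotifTemplate:
    """Cysteine-spacing template for one SRCR domain.

    ``cysteine_spacings`` holds (min_gap, max_gap) residue-count ranges
    between consecutive conserved cysteines; a template with k spacings
    matches a core of k+1 cysteines. ``min_domain_len``/``max_domain_len``
    describe the full domain in aa: the scanner caps the matched cysteine
    core at ``max_domain_len``; ``min_domain_len`` is descriptive (the core
    sits inside a longer domain whose boundaries the scan does not call).
    """

    cysteine_spacings: tuple[tuple[int, int], ...]
    min_domain_len: int
    max_domain_len: int

    def __post_init__(self) -> None:
        if not self.cysteine_spacings:
            raise ConfigError("template needs at least one cysteine spacing")
        for lo, hi in self.cysteine_spacings:
            if lo < 0 or lo > hi:
                raise ConfigError(f"bad spacing range ({lo},{hi})")
        if not (0 < self.min_domain_len <= self.max_domain_len):
            raise ConfigError("need 0 < min_domain_len <= max_domain_len")

    @property
    def n_cysteines(self) -> int:
        return len(self.cysteine_spacings) + 1

    def to_regex(self) -> re.Pattern:
        # lazy quantifiers -> leftmost match with the smallest gap vector;
        # spacers may contain cysteines (SRCR domains carry non-conserved
        # cysteines beyond the template chain)
        body = "".join(f".{{{lo},{hi}}}?C" for lo, hi in self.cysteine_spacings)
        return re.compile("C" + body)


#: generic SRCR-like default: C-x(7,15)-C-x(10,18)-C-x(8,16)-C-x(2,6)-C-x(8,16)-C
DEFAULT_SRCR_TEMPLATE = MotifTemplate(
    cysteine_spacings=((7, 15), (10, 18), (8, 16), (2, 6), (8, 16)),
    min_domain_len=90,
    max_domain_len=115,
)


@dataclass(frozen=True)
class DomainHit:
    """One matched cysteine core, 1-based inclusive aa coordinates."""

    protein_id: str
    start: int
    end: int
    n_cysteines_matched: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("hit start > end")


def scan_srcr(protein: ProteinRecord, template: MotifTemplate | None = None) -> list[DomainHit]:
    """Scan a protein for SRCR cysteine cores.

    Left-greedy and deterministic: positions are scanned left to right; the
    first (leftmost, smallest-gaps) core found is reported and scanning
    resumes after it, so hits never overlap. Cores longer than
    ``max_domain_len`` are rejected. No match yields an empty list.
    """
    if template is None:
        template = DEFAULT_SRCR_TEMPLATE
    pattern = template.to_regex()
    seq = protein.sequence
    hits: list[DomainHit] = []
    pos = 0
    while pos < len(seq):
        m = pattern.search(seq, pos)
        if m is None:
            break
        span = m.end() - m.start()
        if span > template.max_domain_len:
            pos = m.start() + 1  # core too long here; try the next cysteine
            continue
        hits.append(
            DomainHit(
                protein_id=protein.protein_id,
                start=m.start() + 1,
                end=m.end(),
                n_cysteines_matched=template.n_cysteines,
            )
        )
        pos = m.end()
    return hits


def classify_candidates(
    proteins: dict[str, ProteinRecord],
    template: MotifTemplate | None = None,
    min_domains: int = 1,
) -> list[str]:
    """Return gene ids whose representative protein has >= min_domains cores.

    ``proteins`` maps gene_id to its representative protein (ties between
    isoforms are resolved upstream by the longest-protein rule). Output is
    sorted for determinism.
    """
    if min_domains < 1:
        raise ConfigError("min_domains must be >= 1")
    out = [
        gene_id
        for gene_id, prot in proteins.items()
        if len(scan_srcr(prot, template)) >= min_domains
    ]
    return sorted(out)


def instantiate_template(
    template: MotifTemplate | None = None, spacer: str = "A", gaps: list[int] | None = None
) -> str:
    """Build one sequence realising the template (midpoint gaps by default).

    Used by the simulator to embed recognisable SRCR cores and by tests.
    """
    if template is None:
        template = DEFAULT_SRCR_TEMPLATE
    if gaps is None:
        gaps = [(lo + hi) // 2 for lo, hi in template.cysteine_spacings]
    if len(gaps) != len(template.cysteine_spacings):
        raise ConfigError("one gap length per spacing required")
    parts = ["C"]
    for g, (lo, hi) in zip(gaps, template.cysteine_spacings):
        if not lo <= g <= hi:
            raise ConfigError(f"gap {g} outside range ({lo},{hi})")
        parts.append(spacer * g + "C")
    return "".join(parts)
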