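"""INTACT / PSEUDOGENE / MISSING classification by the ortholog-length rule.

A panel gene found in a genome is a pseudogene when its CDS is shorter
than 80% of the reference ortholog (strictly less than — a CDS at exactly
80% counts as intact), or when it survives only as multiple fragments, or
when the annotation itself flags it as disrupted and that flag is trusted.
A gene with no assignable CDS at all is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .annotation_io import AnnotatedGenome, CdsRecord, PanelEntry, ReferencePanel
from .orthology import (
    DEFAULT_MIN_FRAGMENT_REF_COVERAGE,
    DEFAULT_MIN_IDENTITY,
    AlignmentResult,
    ScoringConfig,
    assign_fragments,
    best_hit,
)

__all__ = [
    "INTACT",
    "PSEUDOGENE",
    "MISSING",
    "STATUSES",
    "ClassifyParams",
    "GeneStatus",
    "StatusTable",
    "classify_gene",
    "classify_genome",
]

INTACT = "INTACT"
PSEUDOGENE = "PSEUDOGENE"
MISSING = "MISSING"
STATUSES = (INTACT, PSEUDOGENE, MISSING)


@dataclass(frozen=True)
class ClassifyParams:
    """Tunable knobs of the classification stage.

    ``length_threshold`` is the ortholog-length cutoff (default 0.8: a CDS
    shorter than 80% of its reference ortholog is a pseudogene).
    ``trust_declared_pseudo`` layers the annotation's own pseudogene calls
    (e.g. internal stops found by the annotation pipeline) over the length
    rule; switch off to recompute status from length alone.
    """

    length_threshold: float = 0.8
    trust_declared_pseudo: bool = True
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_fragment_ref_coverage: float = DEFAULT_MIN_FRAGMENT_REF_COVERAGE
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.length_threshold <= 1.0:
            raise ValueError(f"length_threshold must be in (0,1], got {self.length_threshold}")


@dataclass(frozen=True)
class GeneStatus:
    """Classification of one panel gene in one genome, with evidence."""

    gene_name: str
    genome: str
    status: str
    length_ratio: float | None  # longest single fragment / reference length (aa)
    n_fragments: int
    evidence: tuple[tuple[str, AlignmentResult], ...] = ()

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == MISSING) != (self.n_fragments == 0):
            raise ValueError("MISSING if and only if no fragments")


@dataclass
class StatusTable:
    """Per-genome classification of every panel gene (missing genes included)."""

    genome: str
    records: dict[str, GeneStatus]
    unassigned_cds: tuple[str, ...] = ()

    def __getitem__(self, gene_name: str) -> GeneStatus:
        return self.records[gene_name]

    def __contains__(self, gene_name: str) -> bool:
        return gene_name in self.records

    def status_of(self, gene_name: str) -> str:
        return self.records[gene_name].status

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in STATUSES}
        for rec in self.records.values():
            out[rec.status] += 1
        return out

    @classmethod
    def from_statuses(cls, genome: str, statuses: dict[str, str]) -> "StatusTable":
        """Build a table from bare gene → status strings (curated or test data)."""
        records = {}
        for gene, status in statuses.items():
            n = 0 if status == MISSING else 1
            records[gene] = GeneStatus(gene, genome, status, None, n)
        return cls(genome, records)


def classify_gene(
    hits: Sequence[tuple[CdsRecord, AlignmentResult]],
    ref: PanelEntry,
    length_threshold: float = 0.8,
    trust_declared_pseudo: bool = True,
    genome: str = "",
) -> GeneStatus:
    """Classify one panel gene from the CDSs assigned to it.

    No hits → MISSING. A single hit at or above the length threshold and
    not flagged pseudo → INTACT. Anything else — a single short hit, a
    trusted declared-pseudo hit, or two or more fragments (disrupted
    whatever their cumulative span) → PSEUDOGENE.
    """
    if not 0.0 < length_threshold <= 1.0:
        raise ValueError(f"length_threshold must be in (0,1], got {length_threshold}")
    if not hits:
        return GeneStatus(ref.gene_name, genome, MISSING, None, 0)
    ref_len = len(ref.protein)
    length_ratio = max(c.aa_length for c, _ in hits) / ref_len
    evidence = tuple((c.id, a) for c, a in hits)
    if len(hits) == 1:
        cds = hits[0][0]
        flagged = trust_declared_pseudo and cds.declared_pseudo
        if cds.aa_length >= length_threshold * ref_len and not flagged:
            return GeneStatus(ref.gene_name, genome, INTACT, length_ratio, 1, evidence)
    return GeneStatus(ref.gene_name, genome, PSEUDOGENE, length_ratio, len(hits), evidence)


def classify_genome(
    genome: AnnotatedGenome,
    panel: ReferencePanel,
    params: ClassifyParams = ClassifyParams(),
) -> StatusTable:
    """Classify every panel gene in a genome.

    Each CDS is assigned to at most one panel gene (its best hit — one CDS,
    one gene, so paralogs are never double-counted); fragments of one gene
    are pooled; every panel gene gets a record, missing ones explicitly.
    The result is independent of CDS input order.
    """
    if not len(panel):
        raise ValueError("empty reference panel")
    assigned: dict[str, list[tuple[CdsRecord, AlignmentResult]]] = {}
    unassigned: list[str] = []
    for cds in sorted(genome.cds, key=lambda c: c.id):
        if not cds.translation:
            unassigned.append(cds.id)
            continue
        hit = best_hit(
            cds, panel, params.min_identity, params.min_fragment_ref_coverage, params.scoring
        )
        if hit is None:
            unassigned.append(cds.id)
        else:
            assigned.setdefault(hit[0], []).append((cds, hit[1]))
    records: dict[str, GeneStatus] = {}
    for entry in panel.entries:
        hits = assigned.get(entry.gene_name, [])
        if len(hits) > 1:
            # canonical fragment order: position on the reference protein
            frags = assign_fragments(
                [c for c, _ in hits], entry,
                min_identity=params.min_identity, config=params.scoring,
                alignments=[a for _, a in hits],
            )
            order = {cid: i for i, (cid, _) in enumerate(frags.fragments)} if frags else {}
            hits.sort(key=lambda h: (order.get(h[0].id, len(order)), h[0].id))
        records[entry.gene_name] = classify_gene(
            hits, entry, params.length_threshold, params.trust_declared_pseudo, genome.strain_id
        )
    return StatusTable(genome.strain_id, records, tuple(unassigned))
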