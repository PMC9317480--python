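"""Virulence-factor screening and higher-level repertoire verdicts.

Genomes are screened against a virulence-factor panel (VFDB-style protein
sequences tagged with categories) at 50% amino-acid identity and 80%
reference coverage — the classic BLASTp screen thresholds. On top of the
per-gene presence/Ψ/absence map sit two repertoire calls: flagellum
completeness (complete machine vs basal-body relic) and siderophore locus
completeness (functional vs relic ent/ybt systems).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .annotation_io import AnnotatedGenome, ReferencePanel
from .gene_status import INTACT, PSEUDOGENE, ClassifyParams, classify_genome
from .orthology import merge_intervals

__all__ = [
    "PRESENT",
    "VF_PSEUDOGENE",
    "ABSENT",
    "VirulenceMap",
    "FlagellumVerdict",
    "LocusVerdict",
    "load_default_part_map",
    "load_default_loci",
    "screen_virulence",
    "flagellum_assessment",
    "locus_completeness",
]

PRESENT = "PRESENT"
VF_PSEUDOGENE = "PSEUDOGENE"
ABSENT = "ABSENT"

FLAGELLUM_PARTS = ("basal_body", "hook", "filament", "export", "regulation")

COMPLETE = "COMPLETE"
BASAL_BODY_ONLY = "BASAL_BODY_ONLY"
PARTIAL = "PARTIAL"
NO_FLAGELLUM = "ABSENT"


@dataclass
class VirulenceMap:
    """Per-gene presence map of a genome against a virulence panel."""

    genome: str
    cells: dict[str, str]  # gene -> PRESENT | PSEUDOGENE | ABSENT
    categories: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, gene: str) -> str:
        return self.cells[gene]

    def genes_in_category(self, prefix: str) -> list[str]:
        return [g for g, c in self.categories.items() if c.startswith(prefix)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.cells),
                "category": [self.categories.get(g, "") for g in self.cells],
                self.genome: list(self.cells.values()),
            }
        )


@dataclass(frozen=True)
class FlagellumVerdict:
    """COMPLETE / BASAL_BODY_ONLY / PARTIAL / ABSENT plus per-part intact counts."""

    value: str
    intact_by_part: dict[str, tuple[int, int]]  # part -> (n present, n genes in map)


@dataclass(frozen=True)
class LocusVerdict:
    complete: bool
    missing_or_pseudo: frozenset[str] = frozenset()


def load_default_part_map() -> dict[str, str]:
    """Gene → flagellar part, from the bundled enterobacterial regulon map."""
    text = resources.files("disymbio.data").joinpath("flagellum_parts.yaml").read_text()
    parts = yaml.safe_load(text)["parts"]
    return {gene: part for part, genes in parts.items() for gene in genes}


def load_default_loci() -> dict[str, list[str]]:
    text = resources.files("disymbio.data").joinpath("loci.yaml").read_text()
    return yaml.safe_load(text)["loci"]


def screen_virulence(
    genome: AnnotatedGenome,
    vf_panel: ReferencePanel,
    min_identity: float = 0.5,
    min_ref_coverage: float = 0.8,
    params: ClassifyParams = ClassifyParams(),
) -> VirulenceMap:
    """Screen a genome against a virulence-factor panel.

    A gene is PRESENT when it classifies INTACT and its hit passes the
    screen thresholds (identity on the best hit, coverage on the merged
    fragment span); PSEUDOGENE when the ortholog machinery finds it but the
    length/fragment rule calls it disrupted; ABSENT when no hit reaches the
    assignment floor — so absence can be threshold-dependent, as a distant
    intact homolog below the screen thresholds still reports ABSENT.
    """
    for name, v in (("min_identity", min_identity), ("min_ref_coverage", min_ref_coverage)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must be in (0,1], got {v}")
    table = classify_genome(genome, vf_panel, params)
    cells: dict[str, str] = {}
    for entry in vf_panel.entries:
        rec = table[entry.gene_name]
        if rec.status == INTACT:
            best = max(a.identity for _, a in rec.evidence)
            covered = sum(
                e - s for s, e in merge_intervals(a.ref_interval for _, a in rec.evidence)
            )
            coverage = covered / len(entry.protein)
            cells[entry.gene_name] = (
                PRESENT if best >= min_identity and coverage >= min_ref_coverage else ABSENT
            )
        elif rec.status == PSEUDOGENE:
            cells[entry.gene_name] = VF_PSEUDOGENE
        else:
            cells[entry.gene_name] = ABSENT
    categories = {e.gene_name: e.category for e in vf_panel.entries}
    return VirulenceMap(genome.strain_id, cells, categories)


def flagellum_assessment(
    vmap: VirulenceMap, part_map: dict[str, str] | None = None
) -> FlagellumVerdict:
    """Classify the flagellar repertoire of a screened genome.

    COMPLETE: every flagellar gene in the map is PRESENT, in every part.
    BASAL_BODY_ONLY: some basal-body genes survive but no hook and no
    filament gene is present — a structural relic that cannot rotate
    (export and regulatory genes do not block this call; they belong to the
    surviving basal apparatus). PARTIAL: anything in between. ABSENT: no
    flagellar gene present at all.
    """
    if part_map is None:
        part_map = load_default_part_map()
    bad = set(part_map.values()) - set(FLAGELLUM_PARTS)
    if bad:
        raise ValueError(f"unknown flagellar part tags: {sorted(bad)}")
    genes = [g for g in vmap.cells if g in part_map]
    counts: dict[str, tuple[int, int]] = {}
    for part in FLAGELLUM_PARTS:
        members = [g for g in genes if part_map[g] == part]
        n_present = sum(1 for g in members if vmap[g] == PRESENT)
        counts[part] = (n_present, len(members))
    total_present = sum(n for n, _ in counts.values())
    if not genes or total_present == 0:
        return FlagellumVerdict(NO_FLAGELLUM, counts)
    if all(n == m for n, m in counts.values()):
        return FlagellumVerdict(COMPLETE, counts)
    if counts["basal_body"][0] > 0 and counts["hook"][0] == 0 and counts["filament"][0] == 0:
        return FlagellumVerdict(BASAL_BODY_ONLY, counts)
    return FlagellumVerdict(PARTIAL, counts)


def locus_completeness(vmap: VirulenceMap, locus_gene_set) -> LocusVerdict:
    """COMPLETE iff every locus gene is PRESENT; otherwise list the failures."""
    missing = frozenset(g for g in locus_gene_set if vmap.cells.get(g, ABSENT) != PRESENT)
    return LocusVerdict(complete=not missing, missing_or_pseudo=missing)
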