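"""Genome-erosion summaries and symbiont prevalence.

Reduced endosymbiont genomes are characterized by total size (plasmids
included), CDS counts, and the pseudogene fraction — the share of CDSs
annotated or classified as disrupted, a standard index of how far along
reductive evolution a symbiont is. Prevalence (fraction of surveyed host
colonies carrying the symbiont) distinguishes fixed obligate partners
(100%) from facultative ones, with an exact binomial confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats

from .annotation_io import AnnotatedGenome
from .gene_status import PSEUDOGENE, StatusTable

__all__ = [
    "GenomeSummary",
    "PrevalenceResult",
    "summarize_genome",
    "pseudogene_percent",
    "genome_size_mb",
    "prevalence",
]


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class GenomeSummary:
    """Erosion statistics for one strain; percentages rounded half-up."""

    strain_id: str
    total_bp: int
    n_replicons: int
    n_cds_total: int
    n_cds_intact: int
    n_pseudogenes: int

    @property
    def pseudogene_pct(self) -> int | None:
        if self.n_cds_total == 0:
            return None
        return _round_half_up(100 * self.n_pseudogenes / self.n_cds_total)

    @property
    def pseudogene_fraction(self) -> float | None:
        if self.n_cds_total == 0:
            return None
        return self.n_pseudogenes / self.n_cds_total

    @property
    def size_mb(self) -> float:
        return genome_size_mb(self.total_bp)

    @classmethod
    def from_counts(
        cls,
        strain_id: str,
        n_pseudogenes: int,
        n_cds_total: int,
        total_bp: int = 0,
        n_replicons: int = 1,
    ) -> "GenomeSummary":
        """Summary from externally reported counts (e.g. a published table)."""
        if not 0 <= n_pseudogenes <= n_cds_total:
            raise ValueError("need 0 <= n_pseudogenes <= n_cds_total")
        return cls(
            strain_id, total_bp, n_replicons, n_cds_total,
            n_cds_total - n_pseudogenes, n_pseudogenes,
        )


def pseudogene_percent(n_pseudogenes: int, n_cds_total: int) -> int:
    """Pseudogene share of total CDSs, as a whole percentage (half-up)."""
    if n_cds_total <= 0:
        raise ValueError("n_cds_total must be positive")
    if not 0 <= n_pseudogenes <= n_cds_total:
        raise ValueError("need 0 <= n_pseudogenes <= n_cds_total")
    return _round_half_up(100 * n_pseudogenes / n_cds_total)


def genome_size_mb(total_bp: int) -> float:
    """Genome size in Mb to two decimals, half-up (3,050,000 + 97,800 → 3.15)."""
    mb = Decimal(total_bp) / Decimal(1_000_000)
    return float(mb.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_genome(
    genome: AnnotatedGenome, table: StatusTable | None = None
) -> GenomeSummary:
    """Erosion summary of one genome.

    The pseudogene count comes from the annotation's own declared flags, or
    from a recomputed classification table when one is supplied (then a CDS
    is counted as pseudogenic when it is evidence for a PSEUDOGENE gene).
    """
    n_total = len(genome.cds)
    if table is None:
        n_pseudo = sum(1 for c in genome.cds if c.declared_pseudo)
    else:
        pseudo_cds = {
            cid
            for rec in table.records.values()
            if rec.status == PSEUDOGENE
            for cid, _ in rec.evidence
        }
        n_pseudo = sum(1 for c in genome.cds if c.id in pseudo_cds)
    return GenomeSummary(
        strain_id=genome.strain_id,
        total_bp=genome.total_bp,
        n_replicons=len(genome.replicons),
        n_cds_total=n_total,
        n_cds_intact=n_total - n_pseudo,
        n_pseudogenes=n_pseudo,
    )


@dataclass(frozen=True)
class PrevalenceResult:
    n_positive: int
    n_sampled: int
    ci95: tuple[float, float]  # Clopper–Pearson, on the percentage scale

    @property
    def prevalence_pct(self) -> float:
        return 100.0 * self.n_positive / self.n_sampled


def prevalence(n_positive: int, n_sampled: int, confidence: float = 0.95) -> PrevalenceResult:
    """Symbiont prevalence with an exact (Clopper–Pearson) binomial CI."""
    if n_sampled <= 0:
        raise ValueError("n_sampled must be positive")
    if not 0 <= n_positive <= n_sampled:
        raise ValueError("need 0 <= n_positive <= n_sampled")
    alpha = 1.0 - confidence
    if n_positive == 0:
        lo = 0.0
    else:
        lo = float(stats.beta.ppf(alpha / 2, n_positive, n_sampled - n_positive + 1))
    if n_positive == n_sampled:
        hi = 1.0
    else:
        hi = float(stats.beta.ppf(1 - alpha / 2, n_positive + 1, n_sampled - n_positive))
    return PrevalenceResult(n_positive, n_sampled, (100.0 * lo, 100.0 * hi))
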