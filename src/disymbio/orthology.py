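"""Protein-level ortholog matching by optimal local alignment.

Query CDSs are matched to reference-panel proteins by Smith–Waterman-style
local alignment (BLOSUM62, affine gaps — the classic BLASTp scoring
scheme), with deterministic content-based tie-breaking, and multiple CDS
fragments of one disrupted gene can be pooled into a single assignment
whose coverage is measured on the reference protein.

Coverage is reference-relative throughout: pseudogene fragments shorten the
query, so the intact reference protein is the stable yardstick.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .annotation_io import AA_ALPHABET, CdsRecord, PanelEntry, ReferencePanel

__all__ = [
    "ScoringConfig",
    "AlignmentResult",
    "FragmentAssignment",
    "align_local",
    "best_hit",
    "assign_fragments",
    "merge_intervals",
]

#: permissive floor for assigning eroded fragments to their parent gene,
#: as opposed to the stricter virulence-screen thresholds
DEFAULT_MIN_IDENTITY = 0.3
DEFAULT_MIN_FRAGMENT_REF_COVERAGE = 0.1


@dataclass(frozen=True)
class ScoringConfig:
    """Substitution matrix and affine gap penalties for local alignment."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0   # cost of the first residue of a gap
    gap_extend: float = 1.0  # cost of each subsequent gap residue


@lru_cache(maxsize=8)
def _aligner(config: ScoringConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(config.matrix)
    aligner.open_gap_score = -config.gap_open
    aligner.extend_gap_score = -config.gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one optimal local alignment of a query against a reference.

    ``identity`` is identical aligned positions over aligned columns
    (substitution and internal gap columns); coverages are aligned residue
    counts over full sequence lengths; intervals are 0-based half-open on
    the respective sequence.
    """

    score: float
    identity: float
    query_coverage: float
    ref_coverage: float
    query_interval: tuple[int, int]
    ref_interval: tuple[int, int]

    def __post_init__(self) -> None:
        for name in ("identity", "query_coverage", "ref_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")


def _check_protein(label: str, seq: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"{label}: non-amino-acid characters {sorted(bad)}")


def align_local(query: str, ref: str, config: ScoringConfig = ScoringConfig()) -> AlignmentResult:
    """Optimal local alignment of ``query`` against ``ref``.

    Deterministic for fixed inputs and scoring; identity and coverages are
    recomputed from the traceback's aligned blocks, not taken on trust from
    the aligner.
    """
    _check_protein("query", query)
    _check_protein("ref", ref)
    aligner = _aligner(config)
    alignment = aligner.align(ref, query)[0]
    ref_blocks, query_blocks = alignment.aligned
    identities = 0
    aligned_residues = 0
    gap_columns = 0
    prev = None
    for (rs, re), (qs, qe) in zip(ref_blocks, query_blocks):
        for i in range(re - rs):
            if ref[rs + i] == query[qs + i]:
                identities += 1
        aligned_residues += re - rs
        if prev is not None:
            gap_columns += (rs - prev[0]) + (qs - prev[1])
        prev = (re, qe)
    columns = aligned_residues + gap_columns
    return AlignmentResult(
        score=float(alignment.score),
        identity=identities / columns if columns else 0.0,
        query_coverage=aligned_residues / len(query),
        ref_coverage=aligned_residues / len(ref),
        query_interval=(int(query_blocks[0][0]), int(query_blocks[-1][1])) if len(query_blocks) else (0, 0),
        ref_interval=(int(ref_blocks[0][0]), int(ref_blocks[-1][1])) if len(ref_blocks) else (0, 0),
    )


def best_hit(
    query: CdsRecord | str,
    panel: ReferencePanel,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_ref_coverage_for_hit: float = DEFAULT_MIN_FRAGMENT_REF_COVERAGE,
    config: ScoringConfig = ScoringConfig(),
) -> tuple[str, AlignmentResult] | None:
    """Best panel match for one query CDS (or raw protein string).

    The winner is the entry with the highest alignment score among entries
    passing ``min_identity`` and ``min_ref_coverage_for_hit``; ties break by
    higher identity, then lexicographically smallest gene name — a
    content-based rule, so the result is invariant under panel order.
    Returns ``None`` when nothing passes.
    """
    if not len(panel):
        raise ValueError("empty reference panel")
    seq = query.translation if isinstance(query, CdsRecord) else query
    _check_protein("query", seq)
    aligner = _aligner(config)
    # score-only pass first (cheap), traceback only for contenders
    scored = sorted(
        ((float(aligner.score(e.protein, seq)), e) for e in panel.entries),
        key=lambda t: (-t[0], t[1].gene_name),
    )
    best: tuple[float, float, str, AlignmentResult] | None = None
    for score, entry in scored:
        if best is not None and score < best[0]:
            break  # nothing below the best passing score can win
        res = align_local(seq, entry.protein, config)
        if res.identity < min_identity or res.ref_coverage < min_ref_coverage_for_hit:
            continue
        cand = (res.score, res.identity, entry.gene_name, res)
        if best is None or (-cand[0], -cand[1], cand[2]) < (-best[0], -best[1], best[2]):
            best = cand
    if best is None:
        return None
    return best[2], best[3]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; overlaps and abutments coalesce."""
    ordered = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ordered:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class FragmentAssignment:
    """All CDS fragments of one (possibly disrupted) gene, pooled.

    ``merged_ref_coverage`` is the fraction of the reference protein covered
    by the union of fragment alignments — overlapping stretches count once.
    """

    ref_gene: str
    fragments: tuple[tuple[str, tuple[int, int]], ...]  # (cds_id, ref interval)
    merged_ref_coverage: float


def assign_fragments(
    cds_set: Sequence[CdsRecord],
    ref: PanelEntry,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    config: ScoringConfig = ScoringConfig(),
    alignments: Sequence[AlignmentResult] | None = None,
) -> FragmentAssignment | None:
    """Pool the CDS fragments assigned to one reference gene.

    ``alignments`` may supply pre-computed results (parallel to
    ``cds_set``) to avoid re-aligning; otherwise each fragment is aligned
    here. Fragments failing ``min_identity`` are dropped. Returns ``None``
    for an empty set.
    """
    if not cds_set:
        return None
    if alignments is None:
        alignments = [align_local(c.translation, ref.protein, config) for c in cds_set]
    kept = [
        (c.id, a.ref_interval)
        for c, a in zip(cds_set, alignments)
        if a.identity >= min_identity
    ]
    if not kept:
        return None
    kept.sort(key=lambda t: t[1])
    covered = sum(e - s for s, e in merge_intervals(iv for _, iv in kept))
    return FragmentAssignment(
        ref_gene=ref.gene_name,
        fragments=tuple(kept),
        merged_ref_coverage=covered / len(ref.protein),
    )
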