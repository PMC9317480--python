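"""Synthetic reference panels and degraded symbiont genomes with ground truth.

The generator emulates the erosion regime of a recently host-restricted
endosymbiont: starting from an intact reference proteome, each gene is
independently left intact, deleted outright, truncated below the 80%
ortholog-length threshold, or shattered into several CDS fragments, with
point substitutions layered on top. Truncation fractions are kept away
from the classification boundary by a margin so ground truth is
unambiguous (a separate boundary-stress mode emits CDSs at exactly 80% to
pin the strict-inequality contract). Back-translation uses uniform codon
choice under the bacterial genetic code; frameshifts are not simulated —
the classification rule under test is length-based.

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .annotation_io import (
    AnnotatedGenome,
    CdsRecord,
    PanelEntry,
    ReferencePanel,
    Replicon,
)
from .gene_status import INTACT as STATUS_INTACT
from .gene_status import MISSING as STATUS_MISSING
from .gene_status import PSEUDOGENE as STATUS_PSEUDOGENE
from .gene_status import STATUSES, StatusTable
from .pathways import Pathway, PathwayCatalog

__all__ = [
    "FATES",
    "DegradationSpec",
    "GeneFate",
    "GroundTruth",
    "generate_reference_panel",
    "panel_for_catalog",
    "degrade_genome",
    "simulate_consortium",
    "recovery_report",
    "write_genbank",
    "write_gff3_fasta",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

INTACT, TRUNCATED, FRAGMENTED, DELETED = "INTACT", "TRUNCATED", "FRAGMENTED", "DELETED"
FATES = (INTACT, TRUNCATED, FRAGMENTED, DELETED)

#: fate → status the classifier is expected to assign
FATE_TO_STATUS = {
    INTACT: STATUS_INTACT,
    TRUNCATED: STATUS_PSEUDOGENE,
    FRAGMENTED: STATUS_PSEUDOGENE,
    DELETED: STATUS_MISSING,
}

_SPACER_BP = 60


@dataclass(frozen=True)
class DegradationSpec:
    """Per-gene degradation regime.

    Probabilities are per gene and independent; the residual mass
    ``1 - (p_delete + p_truncate + p_fragment)`` leaves the gene intact.
    ``truncate_frac_range`` must stay below the classification threshold
    (0.8) by ``boundary_margin`` so truth is unambiguous, unless
    ``boundary_stress`` is on, in which case truncation lands at exactly
    80% of the reference length.
    """

    p_delete: float = 0.2
    p_truncate: float = 0.3
    p_fragment: float = 0.1
    truncate_frac_range: tuple[float, float] = (0.2, 0.6)
    n_fragments_range: tuple[int, int] = (2, 4)
    mutation_rate: float = 0.02
    seed: int = 0
    boundary_margin: float = 0.05
    boundary_stress: bool = False

    def __post_init__(self) -> None:
        probs = (self.p_delete, self.p_truncate, self.p_fragment)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError(f"fate probabilities must be in [0,1]: {probs}")
        if sum(probs) > 1.0 + 1e-12:
            raise ValueError(f"fate probabilities sum to {sum(probs)} > 1")
        lo, hi = self.truncate_frac_range
        if not (0.0 < lo <= hi):
            raise ValueError(f"bad truncate_frac_range {self.truncate_frac_range}")
        if not self.boundary_stress and hi > 0.8 - self.boundary_margin:
            raise ValueError(
                f"truncate_frac_range upper bound {hi} within boundary margin of 0.8"
            )
        klo, khi = self.n_fragments_range
        if klo < 2 or khi < klo:
            raise ValueError(f"n_fragments_range must be an integer interval >= 2")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError(f"mutation_rate must be in [0,1): {self.mutation_rate}")

    @property
    def fate_probabilities(self) -> dict[str, float]:
        residual = 1.0 - (self.p_delete + self.p_truncate + self.p_fragment)
        return {
            INTACT: residual,
            TRUNCATED: self.p_truncate,
            FRAGMENTED: self.p_fragment,
            DELETED: self.p_delete,
        }


@dataclass(frozen=True)
class GeneFate:
    gene_name: str
    fate: str
    truncation_fraction: float | None = None
    n_fragments: int = 0

    @property
    def expected_status(self) -> str:
        return FATE_TO_STATUS[self.fate]


@dataclass
class GroundTruth:
    """Realized fate of every panel gene in one simulated genome."""

    fates: dict[str, GeneFate]

    def __getitem__(self, gene_name: str) -> GeneFate:
        return self.fates[gene_name]

    def expected_statuses(self) -> dict[str, str]:
        return {g: f.expected_status for g, f in self.fates.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.fates),
                "fate": [f.fate for f in self.fates.values()],
                "truncation_fraction": [f.truncation_fraction for f in self.fates.values()],
                "n_fragments": [f.n_fragments for f in self.fates.values()],
                "expected_status": [f.expected_status for f in self.fates.values()],
            }
        )


# ---------------------------------------------------------------------------
# panel generation


def generate_reference_panel(
    n_genes: int,
    length_range: tuple[int, int] = (100, 400),
    seed: int = 0,
    category: str = "panel",
) -> ReferencePanel:
    """Random reference proteome: i.i.d. residues, lengths uniform in range."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    entries = []
    for i in range(n_genes):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        protein = "".join(rng.choice(list(AA20), size=length))
        entries.append(PanelEntry(f"g{i + 1:0{width}d}", protein, category))
    return ReferencePanel(entries)


def panel_for_catalog(
    catalog: PathwayCatalog | Pathway,
    length_range: tuple[int, int] = (150, 350),
    seed: int = 0,
) -> ReferencePanel:
    """Random panel whose gene names are the catalog's genes (for pathway sims)."""
    names = catalog.gene_names if isinstance(catalog, PathwayCatalog) else list(
        dict.fromkeys(catalog.gene_names)
    )
    rng = np.random.default_rng(seed)
    entries = []
    for name in names:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        protein = "".join(rng.choice(list(AA20), size=length))
        entries.append(PanelEntry(name, protein, "pathway"))
    return ReferencePanel(entries)


# ---------------------------------------------------------------------------
# degradation


def _mutate(protein: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return protein
    chars = list(protein)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = AA20.replace(chars[i], "")
        chars[i] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]


def _codon_map() -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    for codon, aa in _CODON_TABLE.forward_table.items():
        table.setdefault(aa, []).append(codon)
    for aa in table:
        table[aa].sort()
    return table


_CODONS = _codon_map()
_STOPS = sorted(_CODON_TABLE.stop_codons)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [_CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in protein]
    codons.append(_STOPS[int(rng.integers(len(_STOPS)))])
    return "".join(codons)


def _fragment_cuts(length: int, k: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Split [0, length) into k contiguous pieces, each detectable.

    Pieces are at least max(15, 12% of length) long — long enough that a
    near-identical fragment still aligns and clears the per-fragment
    coverage floor — and at most 70% of length, so no single fragment can
    masquerade as an intact gene near the length threshold.
    """
    min_piece = max(15, -(-12 * length // 100))  # ceil(0.12 * L)
    max_piece = max(min_piece, (70 * length) // 100)
    for _ in range(1000):
        cuts = sorted(rng.choice(np.arange(1, length), size=k - 1, replace=False).tolist())
        bounds = [0] + cuts + [length]
        pieces = [(bounds[i], bounds[i + 1]) for i in range(k)]
        if all(min_piece <= e - s <= max_piece for s, e in pieces):
            return pieces
    # fall back to an even split if rejection fails (tiny proteins)
    bounds = [round(i * length / k) for i in range(k + 1)]
    return [(bounds[i], bounds[i + 1]) for i in range(k)]


def degrade_genome(
    panel: ReferencePanel,
    spec: DegradationSpec,
    strain_id: str = "synthetic",
) -> tuple[AnnotatedGenome, GroundTruth]:
    """Emit a degraded single-chromosome genome plus its ground truth.

    Genes are laid down in panel order on one circular chromosome with
    random spacers and random strands. Intact genes emit one full-length
    CDS; truncated genes one N-terminal prefix below the 80% threshold;
    fragmented genes k CDSs partitioning the protein; deleted genes emit
    nothing. All emitted CDSs carry embedded translations and parse back
    through the annotation reader.
    """
    rng = np.random.default_rng(spec.seed)
    probs = spec.fate_probabilities
    fate_draws = rng.choice(FATES, size=len(panel), p=[probs[f] for f in FATES])

    chrom_id = f"{strain_id}_chr"
    parts: list[str] = []
    pos = 0
    cds: list[CdsRecord] = []
    fates: dict[str, GeneFate] = {}

    def _spacer() -> None:
        nonlocal pos
        spacer = "".join(rng.choice(list("ACGT"), size=_SPACER_BP))
        parts.append(spacer)
        pos += _SPACER_BP

    def _emit(cds_id: str, protein: str) -> None:
        nonlocal pos
        strand = "+" if rng.random() < 0.5 else "-"
        nt = _back_translate(protein, rng)
        if strand == "-":
            nt = str(Seq(nt).reverse_complement())
        parts.append(nt)
        cds.append(
            CdsRecord(
                id=cds_id,
                replicon_id=chrom_id,
                start=pos,
                end=pos + len(nt),
                strand=strand,
                translation=protein,
            )
        )
        pos += len(nt)

    _spacer()
    for entry, fate in zip(panel.entries, fate_draws):
        fate = str(fate)
        protein = _mutate(entry.protein, spec.mutation_rate, rng)
        length = len(protein)
        if fate == DELETED:
            fates[entry.gene_name] = GeneFate(entry.gene_name, DELETED)
            continue
        if fate == INTACT:
            _emit(f"{entry.gene_name}_cds", protein)
            _spacer()
            fates[entry.gene_name] = GeneFate(entry.gene_name, INTACT)
        elif fate == TRUNCATED:
            if spec.boundary_stress:
                keep = (8 * length) // 10  # exactly 80% when length % 5 == 0
                frac = keep / length
            else:
                frac = float(rng.uniform(*spec.truncate_frac_range))
                keep = max(15, int(frac * length))
            _emit(f"{entry.gene_name}_trunc", protein[:keep])
            _spacer()
            fates[entry.gene_name] = GeneFate(entry.gene_name, TRUNCATED, keep / length, 1)
        else:  # FRAGMENTED
            k = int(rng.integers(spec.n_fragments_range[0], spec.n_fragments_range[1] + 1))
            pieces = _fragment_cuts(length, k, rng)
            for j, (s, e) in enumerate(pieces, start=1):
                _emit(f"{entry.gene_name}_frag{j}", protein[s:e])
                _spacer()
            fates[entry.gene_name] = GeneFate(entry.gene_name, FRAGMENTED, None, k)

    sequence = "".join(parts)
    genome = AnnotatedGenome(
        strain_id=strain_id,
        replicons=[Replicon(chrom_id, len(sequence), "circular", "chromosome")],
        cds=cds,
        sequence={chrom_id: sequence},
    )
    return genome, GroundTruth(fates)


# ---------------------------------------------------------------------------
# engineered consortia


def simulate_consortium(
    panel: ReferencePanel,
    pathway: Pathway,
    scenario: dict[str, str],
    seed: int = 0,
    strain_ids: tuple[str, str] = ("symA", "symB"),
    other_fate: str = TRUNCATED,
) -> tuple[AnnotatedGenome, AnnotatedGenome, dict[str, str]]:
    """Two genomes engineered so the pathway is complete only in union.

    ``scenario`` assigns each step name to "A" or "B": the named member
    gets an intact copy of the step's first alternative, the other member
    gets that gene deleted or truncated (``other_fate``) and the remaining
    alternatives are deleted from both. Returns both genomes plus the
    provider map (step → strain id).
    """
    if not scenario:
        raise ValueError("scenario covers no steps")
    unknown = set(scenario) - {s.name for s in pathway.steps}
    if unknown:
        raise ValueError(f"scenario names unknown steps: {sorted(unknown)}")
    if set(scenario.values()) - {"A", "B"}:
        raise ValueError("scenario values must be 'A' or 'B'")
    if other_fate not in (TRUNCATED, DELETED):
        raise ValueError("other_fate must be TRUNCATED or DELETED")

    providers: dict[str, str] = {}
    fate_by_genome: dict[str, dict[str, str]] = {"A": {}, "B": {}}
    for step in pathway.steps:
        side = scenario.get(step.name)
        if side is None:
            raise ValueError(f"scenario does not cover step {step.name!r}")
        carrier = step.alternatives[0]
        other = "B" if side == "A" else "A"
        fate_by_genome[side][carrier] = INTACT
        fate_by_genome[other][carrier] = other_fate
        for alt in step.alternatives[1:]:
            fate_by_genome["A"][alt] = DELETED
            fate_by_genome["B"][alt] = DELETED
        providers[step.name] = strain_ids[0] if side == "A" else strain_ids[1]

    genomes = []
    for i, side in enumerate(("A", "B")):
        fixed = fate_by_genome[side]
        sub = panel.subset([g for g in panel.gene_names if g in fixed])
        spec = DegradationSpec(
            p_delete=0.0, p_truncate=0.0, p_fragment=0.0,
            mutation_rate=0.0, seed=seed + i,
        )
        genome, _ = _degrade_with_fixed_fates(sub, spec, fixed, strain_ids[i])
        genomes.append(genome)
    return genomes[0], genomes[1], providers


def _degrade_with_fixed_fates(
    panel: ReferencePanel,
    spec: DegradationSpec,
    fixed: dict[str, str],
    strain_id: str,
) -> tuple[AnnotatedGenome, GroundTruth]:
    """degrade_genome with fates dictated per gene instead of drawn."""
    rng = np.random.default_rng(spec.seed)
    chrom_id = f"{strain_id}_chr"
    parts: list[str] = []
    cds: list[CdsRecord] = []
    fates: dict[str, GeneFate] = {}
    pos = 0

    def _spacer() -> None:
        nonlocal pos
        spacer = "".join(rng.choice(list("ACGT"), size=_SPACER_BP))
        parts.append(spacer)
        pos += _SPACER_BP

    def _emit(cds_id: str, protein: str) -> None:
        nonlocal pos
        strand = "+" if rng.random() < 0.5 else "-"
        nt = _back_translate(protein, rng)
        if strand == "-":
            nt = str(Seq(nt).reverse_complement())
        parts.append(nt)
        cds.append(
            CdsRecord(cds_id, chrom_id, pos, pos + len(nt), strand, protein)
        )
        pos += len(nt)

    _spacer()
    for entry in panel.entries:
        fate = fixed[entry.gene_name]
        protein = _mutate(entry.protein, spec.mutation_rate, rng)
        if fate == DELETED:
            fates[entry.gene_name] = GeneFate(entry.gene_name, DELETED)
            continue
        if fate == INTACT:
            _emit(f"{entry.gene_name}_cds", protein)
            _spacer()
            fates[entry.gene_name] = GeneFate(entry.gene_name, INTACT)
        elif fate == TRUNCATED:
            keep = max(15, len(protein) // 2)
            _emit(f"{entry.gene_name}_trunc", protein[:keep])
            _spacer()
            fates[entry.gene_name] = GeneFate(
                entry.gene_name, TRUNCATED, keep / len(protein), 1
            )
        else:
            raise ValueError(f"unsupported fixed fate {fate!r}")
    sequence = "".join(parts)
    genome = AnnotatedGenome(
        strain_id,
        [Replicon(chrom_id, len(sequence), "circular", "chromosome")],
        cds,
        {chrom_id: sequence},
    )
    return genome, GroundTruth(fates)


# ---------------------------------------------------------------------------
# recovery scoring


def recovery_report(
    predicted: StatusTable, truth: GroundTruth
) -> tuple[pd.DataFrame, float]:
    """3×3 confusion (truth-expected status × predicted) and agreement fraction."""
    expected = truth.expected_statuses()
    if set(expected) != set(predicted.records):
        raise ValueError("gene sets of prediction and truth differ")
    confusion = pd.DataFrame(0, index=list(STATUSES), columns=list(STATUSES))
    agree = 0
    for gene, exp in expected.items():
        pred = predicted.status_of(gene)
        confusion.loc[exp, pred] += 1
        agree += exp == pred
    return confusion, agree / len(expected)


# ---------------------------------------------------------------------------
# file emission (parsed back by annotation_io)


def write_genbank(genome: AnnotatedGenome, path: str) -> None:
    """Emit the genome as a GenBank flat file with embedded translations."""
    records = []
    for rep in genome.replicons:
        seq = genome.sequence.get(rep.id)
        if seq is None:
            raise ValueError(f"replicon {rep.id}: no sequence to write")
        rec = SeqRecord(Seq(seq), id=rep.id, name=rep.id[:16], description=rep.kind)
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = rep.topology
        rec.annotations["source"] = genome.strain_id
        src = SeqFeature(FeatureLocation(0, rep.length), type="source")
        src.qualifiers["strain"] = [genome.strain_id]
        rec.features.append(src)
        for c in genome.cds:
            if c.replicon_id != rep.id:
                continue
            feat = SeqFeature(
                FeatureLocation(c.start, c.end, strand=1 if c.strand == "+" else -1),
                type="CDS",
            )
            feat.qualifiers["locus_tag"] = [c.id]
            if c.product:
                feat.qualifiers["product"] = [c.product]
            if c.declared_pseudo:
                feat.qualifiers["pseudo"] = [""]
            if c.translation:
                feat.qualifiers["translation"] = [c.translation]
            rec.features.append(feat)
        records.append(rec)
    SeqIO.write(records, path, "genbank")


def write_gff3_fasta(genome: AnnotatedGenome, gff_path: str, fasta_path: str) -> None:
    """Emit the genome as GFF3 (1-based inclusive) plus genomic FASTA."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"#!strain {genome.strain_id}\n")
        for rep in genome.replicons:
            fh.write(f"##sequence-region {rep.id} 1 {rep.length}\n")
            fh.write(f"#!replicon {rep.id} {rep.topology} {rep.kind}\n")
        for c in genome.cds:
            attrs = [f"ID={c.id}"]
            if c.product:
                attrs.append(f"product={c.product}")
            if c.declared_pseudo:
                attrs.append("pseudo=true")
            fh.write(
                "\t".join(
                    [
                        c.replicon_id,
                        "disymbio",
                        "CDS",
                        str(c.start + 1),  # 0-based half-open -> 1-based inclusive
                        str(c.end),
                        ".",
                        c.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
    with open(fasta_path, "w") as fh:
        for rep in genome.replicons:
            fh.write(f">{rep.id}\n")
            seq = genome.sequence[rep.id]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
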