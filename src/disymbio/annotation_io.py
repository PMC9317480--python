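"""Reading annotated genomes and reference panels; writing result matrices.

Genomes arrive either as GenBank flat files (PGAP-style, translations
embedded) or as GFF3 plus genomic FASTA (translations derived with the
bacterial genetic code). Internally all coordinates are 0-based half-open
regardless of the source dialect; GFF3's 1-based inclusive intervals are
converted on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "CdsRecord",
    "Replicon",
    "AnnotatedGenome",
    "PanelEntry",
    "ReferencePanel",
    "AnnotationParseError",
    "read_genome_annotation",
    "read_reference_panel",
    "write_reference_panel",
    "write_status_matrix",
    "read_status_matrix",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: translation table for bacterial/archaeal genomes
BACTERIAL_TABLE = 11


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be interpreted."""


@dataclass(frozen=True)
class CdsRecord:
    """One CDS feature: half-open genomic interval plus its translation.

    ``declared_pseudo`` carries the annotation's own pseudogene flag
    (GenBank ``/pseudo`` or a GFF3 pseudogene qualifier); classification
    downstream may either trust or recompute it.
    """

    id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    translation: str = ""
    declared_pseudo: bool = False
    product: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"CDS {self.id}: end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"CDS {self.id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.translation and not self.declared_pseudo:
            raise ValueError(f"CDS {self.id}: translation required unless declared pseudo")
        bad = set(self.translation) - AA_ALPHABET
        if bad:
            raise ValueError(f"CDS {self.id}: non-amino-acid characters {sorted(bad)}")

    @property
    def aa_length(self) -> int:
        return len(self.translation)


@dataclass(frozen=True)
class Replicon:
    id: str
    length: int
    topology: str = "linear"  # circular | linear
    kind: str = "chromosome"  # chromosome | plasmid | contig


@dataclass
class AnnotatedGenome:
    """Replicons and CDS records for one symbiont strain.

    ``sequence`` maps replicon id to its nucleotide string when the source
    provided one (needed for writing GenBank and for translating GFF3 CDSs).
    ``parse_issues`` collects record-level problems that were reported
    rather than raised (e.g. a CDS lacking both a translation and genome
    sequence to derive one from).
    """

    strain_id: str
    replicons: list[Replicon]
    cds: list[CdsRecord]
    sequence: dict[str, str] = field(default_factory=dict)
    parse_issues: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {r.id: r.length for r in self.replicons}
        for c in self.cds:
            if c.replicon_id not in lengths:
                raise ValueError(f"CDS {c.id}: unknown replicon {c.replicon_id!r}")
            if c.end > lengths[c.replicon_id]:
                raise ValueError(
                    f"CDS {c.id}: interval [{c.start},{c.end}) exceeds replicon "
                    f"{c.replicon_id} length {lengths[c.replicon_id]}"
                )

    @property
    def total_bp(self) -> int:
        return sum(r.length for r in self.replicons)


@dataclass(frozen=True)
class PanelEntry:
    gene_name: str
    protein: str
    category: str = ""

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValueError(f"panel entry {self.gene_name}: empty protein")
        bad = set(self.protein) - AA_ALPHABET
        if bad:
            raise ValueError(f"panel entry {self.gene_name}: bad characters {sorted(bad)}")


@dataclass
class ReferencePanel:
    """Named reference proteins: the ortholog-length yardstick and search targets."""

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        names = [e.gene_name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate panel gene names: {sorted(dupes)}")
        self._by_name = {e.gene_name: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_name: str) -> bool:
        return gene_name in self._by_name

    def __getitem__(self, gene_name: str) -> PanelEntry:
        return self._by_name[gene_name]

    @property
    def gene_names(self) -> list[str]:
        return [e.gene_name for e in self.entries]

    def subset(self, gene_names) -> "ReferencePanel":
        return ReferencePanel([self._by_name[g] for g in gene_names])


# ---------------------------------------------------------------------------
# genome reading


def _translate(nt: str, strand: str) -> str:
    seq = Seq(nt)
    if strand == "-":
        seq = seq.reverse_complement()
    aa = str(seq.translate(table=BACTERIAL_TABLE))
    if aa.endswith("*"):
        aa = aa[:-1]
    # internal stops (annotated pseudogenes) are masked, not fatal
    return aa.replace("*", "X")


def _read_genbank(path: str) -> AnnotatedGenome:
    replicons: list[Replicon] = []
    cds: list[CdsRecord] = []
    sequence: dict[str, str] = {}
    issues: list[str] = []
    strain = ""
    n_anon = 0
    records = list(SeqIO.parse(path, "genbank"))
    if not records:
        raise AnnotationParseError(f"{path}: no GenBank records found")
    for rec in records:
        topology = rec.annotations.get("topology", "linear")
        desc = (rec.description or "").lower()
        kind = "plasmid" if "plasmid" in desc else "chromosome"
        replicons.append(Replicon(rec.id, len(rec.seq), topology, kind))
        sequence[rec.id] = str(rec.seq)
        strain = strain or rec.annotations.get("source", rec.id)
        for feat in rec.features:
            if feat.type == "source" and "strain" in feat.qualifiers:
                strain = feat.qualifiers["strain"][0]
            if feat.type != "CDS":
                continue
            pseudo = "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers
            # compound (joined) locations flatten to outer bounds
            start, end = int(feat.location.start), int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            name = feat.qualifiers.get("locus_tag", feat.qualifiers.get("protein_id", [""]))[0]
            if not name:
                n_anon += 1
                name = f"cds_{n_anon:05d}"
            translation = feat.qualifiers.get("translation", [""])[0]
            if not translation and rec.seq:
                translation = _translate(str(rec.seq[start:end]), strand)
            if not translation and not pseudo:
                issues.append(f"{rec.id}:{name}: CDS without translation or sequence; skipped")
                continue
            cds.append(
                CdsRecord(
                    id=name,
                    replicon_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    translation=translation,
                    declared_pseudo=pseudo,
                    product=feat.qualifiers.get("product", [""])[0],
                )
            )
    return AnnotatedGenome(strain or records[0].id, replicons, cds, sequence, issues)


def _read_gff3_fasta(gff_path: str, fasta_path: str) -> AnnotatedGenome:
    import gffutils

    sequence = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    if not sequence:
        raise AnnotationParseError(f"{fasta_path}: no FASTA records found")
    topologies: dict[str, str] = {}
    kinds: dict[str, str] = {}
    strain = ""
    with open(gff_path) as fh:
        text = fh.read()
    for line in text.splitlines():
        # our own emission dialect records replicon metadata in directives
        if line.startswith("#!replicon"):
            _, rid, topo, kind = line.split()
            topologies[rid] = topo
            kinds[rid] = kind
        elif line.startswith("#!strain"):
            strain = line.split(None, 1)[1].strip()
    try:
        db = gffutils.create_db(
            text, dbfn=":memory:", from_string=True, force=True,
            keep_order=True, merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on malformed input
        raise AnnotationParseError(f"{gff_path}: {exc}") from exc

    # multi-line CDS features sharing an ID flatten to outer bounds
    grouped: dict[str, list] = {}
    for feat in db.features_of_type("CDS", order_by="start"):
        fid = feat.attributes.get("ID", [feat.id])[0]
        grouped.setdefault(fid, []).append(feat)

    replicons = [
        Replicon(rid, len(seq), topologies.get(rid, "linear"), kinds.get(rid, "contig"))
        for rid, seq in sequence.items()
    ]
    cds: list[CdsRecord] = []
    issues: list[str] = []
    for fid, feats in grouped.items():
        f0 = feats[0]
        start = min(f.start for f in feats) - 1  # 1-based inclusive -> 0-based half-open
        end = max(f.end for f in feats)
        strand = "-" if f0.strand == "-" else "+"
        attrs = f0.attributes
        pseudo = (
            attrs.get("pseudo", ["false"])[0].lower() == "true"
            or "pseudogene" in attrs
        )
        if f0.seqid not in sequence:
            issues.append(f"{fid}: replicon {f0.seqid} absent from FASTA; skipped")
            continue
        translation = _translate(sequence[f0.seqid][start:end], strand)
        if not translation and not pseudo:
            issues.append(f"{fid}: empty translation; skipped")
            continue
        cds.append(
            CdsRecord(
                id=fid,
                replicon_id=f0.seqid,
                start=start,
                end=end,
                strand=strand,
                translation=translation,
                declared_pseudo=pseudo,
                product=attrs.get("product", [""])[0],
            )
        )
    gname = strain or next(iter(sequence))
    return AnnotatedGenome(gname, replicons, cds, sequence, issues)


def read_genome_annotation(path: str, format: str = "genbank", fasta: str | None = None) -> AnnotatedGenome:
    """Read one annotated genome.

    Parameters
    ----------
    path
        GenBank flat file, or GFF3 file when ``format="gff3"``.
    format
        ``"genbank"`` or ``"gff3"`` (requires ``fasta``).
    fasta
        Genomic FASTA accompanying the GFF3.
    """
    if format == "genbank":
        return _read_genbank(path)
    if format in ("gff3", "gff3+fasta"):
        if fasta is None:
            raise ValueError("GFF3 input requires the genomic FASTA path")
        return _read_gff3_fasta(path, fasta)
    raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# reference panels


def read_reference_panel(path: str) -> ReferencePanel:
    """Read a protein FASTA whose headers are ``gene_name|category``."""
    entries = []
    for rec in SeqIO.parse(path, "fasta"):
        header = rec.description.strip() or rec.id
        if "|" in header:
            name, category = header.split("|", 1)
        else:
            name, category = header, ""
        if not rec.seq:
            raise AnnotationParseError(f"{path}: empty sequence for {name!r}")
        entries.append(PanelEntry(name.strip(), str(rec.seq), category.strip()))
    if not entries:
        raise AnnotationParseError(f"{path}: no FASTA records found")
    try:
        return ReferencePanel(entries)
    except ValueError as exc:
        raise AnnotationParseError(f"{path}: {exc}") from exc


def write_reference_panel(panel: ReferencePanel, path: str) -> None:
    with open(path, "w") as fh:
        for e in panel.entries:
            fh.write(f">{e.gene_name}|{e.category}\n")
            for i in range(0, len(e.protein), 70):
                fh.write(e.protein[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# status matrices


def write_status_matrix(matrix: pd.DataFrame, path: str) -> None:
    """Write a status matrix as TSV — the textual twin of a presence/Ψ/absence figure.

    Rows are (pathway, step, gene) or plain gene rows; columns are genomes
    (plus optional consortium columns); cells are status strings.
    """
    if matrix.empty:
        raise ValueError("refusing to write an empty status matrix")
    matrix.to_csv(path, sep="\t", index=False)


def read_status_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")
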