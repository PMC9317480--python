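"""Curated gene statuses for the Sipha maydis / Periphyllus lyropictus consortia.

The four strains are the Buchnera aphidicola and co-obligate Serratia
symbiotica symbionts of the cereal aphid Sipha maydis (BaSm, SsSm) and the
Norway maple aphid Periphyllus lyropictus (BaPl, SsPl). The tables below
transcribe only gene-level statements reported for these strains —
riboflavin and biotin biosynthesis genes, flagellar genes, siderophore
loci, T5SS autotransporters and YopJ-family toxins. Gene rows not
individually reported are deliberately not invented, so pathway evaluation
over these tables is restricted to the riboflavin and biotin catalogs.

These curated maps serve as fixtures for the pathway and virulome engines;
re-deriving them from sequence requires the deposited assemblies
(BioProjects PRJNA835797, PRJNA837269, PRJNA837360, PRJNA837363) and is
outside this package's test path.
"""

from __future__ import annotations

from .gene_status import INTACT, MISSING, PSEUDOGENE, StatusTable
from .virulome import ABSENT, PRESENT, VF_PSEUDOGENE, VirulenceMap

__all__ = [
    "STRAINS",
    "vitamin_status_tables",
    "virulence_maps",
]

STRAINS = ("BaSm", "SsSm", "BaPl", "SsPl")

_RIBOFLAVIN_GENES = ("ribA", "ribD", "ribB", "ribH", "ribE", "yigB", "ybjI", "yigL")
_BIOTIN_GENES = ("bioC", "bioH", "bioF", "bioA", "bioD", "bioB")

# Riboflavin: neither Buchnera strain conserved any riboflavin gene; both
# Serratia strains carry the pathway except the phosphatase step in SsSm,
# where yigB and ybjI are absent and the alternative yigL survives only as
# a pseudogene split into four pieces. In SsPl yigL is present and intact.
_VITAMIN_STATUS: dict[str, dict[str, str]] = {
    "BaSm": {g: MISSING for g in _RIBOFLAVIN_GENES},
    "BaPl": {g: MISSING for g in _RIBOFLAVIN_GENES},
    "SsSm": {
        "ribA": INTACT, "ribD": INTACT, "ribB": INTACT, "ribH": INTACT, "ribE": INTACT,
        "yigB": MISSING, "ybjI": MISSING, "yigL": PSEUDOGENE,
    },
    "SsPl": {
        "ribA": INTACT, "ribD": INTACT, "ribB": INTACT, "ribH": INTACT, "ribE": INTACT,
        "yigB": MISSING, "ybjI": MISSING, "yigL": INTACT,
    },
}

# Biotin: SsSm complements Buchnera from 7-keto-8-aminopelargonate onward
# (bioA, bioD, bioB intact), while in SsPl bioA and bioD are pseudogenized,
# leaving that consortium incomplete. Upstream pimelate-thioester steps
# (bioC, bioH, bioF) are covered by the Buchnera partners.
_BIOTIN_STATUS: dict[str, dict[str, str]] = {
    "BaSm": {
        "bioC": INTACT, "bioH": INTACT, "bioF": INTACT,
        "bioA": MISSING, "bioD": MISSING, "bioB": MISSING,
    },
    "SsSm": {
        "bioC": MISSING, "bioH": MISSING, "bioF": MISSING,
        "bioA": INTACT, "bioD": INTACT, "bioB": INTACT,
    },
    "BaPl": {
        "bioC": INTACT, "bioH": INTACT, "bioF": INTACT,
        "bioA": MISSING, "bioD": MISSING, "bioB": MISSING,
    },
    "SsPl": {
        "bioC": MISSING, "bioH": MISSING, "bioF": MISSING,
        "bioA": PSEUDOGENE, "bioD": PSEUDOGENE, "bioB": INTACT,
    },
}


def vitamin_status_tables() -> dict[str, StatusTable]:
    """Riboflavin + biotin gene statuses for all four strains."""
    tables = {}
    for strain in STRAINS:
        statuses = {**_VITAMIN_STATUS[strain], **_BIOTIN_STATUS[strain]}
        tables[strain] = StatusTable.from_statuses(strain, statuses)
    return tables


# Virulence repertoires of the two Serratia strains. SsSm retains a
# basal-body relic of the flagellum (hook/filament genes missing or
# pseudogenized); SsPl retains the full set. Enterobactin synthesis genes
# are missing or pseudogenized in both; the yersiniabactin locus keeps
# intact core genes (irp1, irp2, fyuA, ybtA) but lacks ybtS/ybtU/ybtT/
# ybtD/psn. Both retain FdeC-like adhesins and YopJ-family effectors; InvA
# and SinH are specific to SsSm.
_VF_CATEGORIES: dict[str, str] = {
    "flgB": "flagellum.basal_body", "flgH": "flagellum.basal_body",
    "fliE": "flagellum.basal_body", "fliM": "flagellum.basal_body",
    "fliN": "flagellum.basal_body", "flgC": "flagellum.basal_body",
    "flgF": "flagellum.basal_body", "flgG": "flagellum.basal_body",
    "fliI": "flagellum.export",
    "flgE": "flagellum.hook", "flgK": "flagellum.hook",
    "fliC": "flagellum.filament", "flgL": "flagellum.filament",
    "entA": "siderophore.ent", "entB": "siderophore.ent", "entC": "siderophore.ent",
    "entE": "siderophore.ent", "entF": "siderophore.ent",
    "irp1": "siderophore.ybt", "irp2": "siderophore.ybt", "fyuA": "siderophore.ybt",
    "ybtA": "siderophore.ybt", "ybtS": "siderophore.ybt", "ybtU": "siderophore.ybt",
    "ybtT": "siderophore.ybt", "ybtD": "siderophore.ybt", "psn": "siderophore.ybt",
    "fdeC": "adhesin.t5ss", "invA": "adhesin.t5ss", "sinH": "adhesin.t5ss",
    "yopJ": "toxin.yopJ",
}

_VF_CELLS: dict[str, dict[str, str]] = {
    "SsSm": {
        "flgB": PRESENT, "flgH": PRESENT, "fliE": PRESENT, "fliI": PRESENT,
        "fliM": PRESENT, "fliN": PRESENT,
        "flgK": VF_PSEUDOGENE, "flgE": VF_PSEUDOGENE, "flgC": VF_PSEUDOGENE,
        "flgF": VF_PSEUDOGENE, "flgG": VF_PSEUDOGENE,
        "fliC": ABSENT, "flgL": ABSENT,
        "entA": ABSENT, "entB": VF_PSEUDOGENE, "entC": ABSENT,
        "entE": VF_PSEUDOGENE, "entF": ABSENT,
        "irp1": PRESENT, "irp2": PRESENT, "fyuA": PRESENT, "ybtA": PRESENT,
        "ybtS": ABSENT, "ybtU": ABSENT, "ybtT": ABSENT, "ybtD": ABSENT, "psn": ABSENT,
        "fdeC": PRESENT, "invA": PRESENT, "sinH": PRESENT, "yopJ": PRESENT,
    },
    "SsPl": {
        "flgB": PRESENT, "flgH": PRESENT, "fliE": PRESENT, "fliI": PRESENT,
        "fliM": PRESENT, "fliN": PRESENT,
        "flgK": PRESENT, "flgE": PRESENT, "flgC": PRESENT,
        "flgF": PRESENT, "flgG": PRESENT,
        "fliC": PRESENT, "flgL": PRESENT,
        "entA": ABSENT, "entB": ABSENT, "entC": VF_PSEUDOGENE,
        "entE": ABSENT, "entF": VF_PSEUDOGENE,
        "irp1": PRESENT, "irp2": PRESENT, "fyuA": PRESENT, "ybtA": PRESENT,
        "ybtS": ABSENT, "ybtU": ABSENT, "ybtT": ABSENT, "ybtD": ABSENT, "psn": ABSENT,
        "fdeC": PRESENT, "invA": ABSENT, "sinH": ABSENT, "yopJ": PRESENT,
    },
}


def virulence_maps() -> dict[str, VirulenceMap]:
    """Curated virulence-factor maps for SsSm and SsPl."""
    return {
        strain: VirulenceMap(strain, dict(cells), dict(_VF_CATEGORIES))
        for strain, cells in _VF_CELLS.items()
    }
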