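"""Vitamin biosynthesis complementarity in the two di-symbiotic consortia.

Evaluates riboflavin and biotin pathway completeness per symbiont and per
host-level consortium over the curated gene-status tables for BaSm/SsSm
(Sipha maydis) and BaPl/SsPl (Periphyllus lyropictus). The expected
pattern: both Serratia strains carry riboflavin synthesis that neither
Buchnera retains (with the SsSm phosphatase step pseudogenized, yigL in
four pieces); the S. maydis consortium completes biotin via SsSm's intact
bioA/bioD/bioB, while the P. lyropictus consortium cannot (bioA and bioD
pseudogenized in SsPl).

Writes: results/vitamin_matrix.tsv, results/vitamin_verdicts.tsv
"""

from pathlib import Path

import pandas as pd

from disymbio.annotation_io import write_status_matrix
from disymbio.pathways import (
    complementarity_matrix,
    consortium_completeness,
    load_default_catalog,
    pathway_completeness,
)
from disymbio.strains import vitamin_status_tables

OUT = Path(__file__).resolve().parents[1] / "results"

CONSORTIA = {"S. maydis": ("BaSm", "SsSm"), "P. lyropictus": ("BaPl", "SsPl")}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    catalog = load_default_catalog().subset(["riboflavin", "biotin"])
    tables = vitamin_status_tables()

    matrix = complementarity_matrix(catalog, list(tables.values()))
    write_status_matrix(matrix, str(OUT / "vitamin_matrix.tsv"))

    rows = []
    for pathway in catalog:
        for strain, table in tables.items():
            verdict = pathway_completeness(pathway, table)
            rows.append({"pathway": pathway.name, "unit": strain,
                         "complete": verdict.complete, "unique_providers": ""})
        for host, members in CONSORTIA.items():
            verdict = consortium_completeness(pathway, [tables[m] for m in members])
            unique = ";".join(f"{s}:{g}" for s, g in verdict.unique_providers)
            rows.append({"pathway": pathway.name, "unit": f"consortium {host}",
                         "complete": verdict.complete, "unique_providers": unique})
            print(f"{pathway.name:<11} {host:<15} consortium "
                  f"{'complete' if verdict.complete else 'INCOMPLETE'}"
                  + (f"  (unique: {unique})" if unique else ""))
    pd.DataFrame(rows).to_csv(OUT / "vitamin_verdicts.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
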