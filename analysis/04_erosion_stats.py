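"""Genome-erosion statistics and symbiont prevalence.

Erosion arithmetic on the reported CDS counts of the two Serratia
co-obligate symbionts (SsSm: 1258 pseudogenes of 2617 CDSs; SsPl: 1172 of
3286), size aggregation of the SsPl chromosome + plasmid, and the
prevalence of the symbiont across the two S. maydis sampling campaigns
(21 + 76 colonies, all positive) with an exact binomial interval.

Writes: results/erosion_summary.tsv, results/prevalence.tsv
"""

from pathlib import Path

import pandas as pd

from disymbio.genome_stats import GenomeSummary, genome_size_mb, prevalence

OUT = Path(__file__).resolve().parents[1] / "results"

REPORTED = [
    # strain, pseudogenes, total CDSs, total bp
    ("SsSm", 1258, 2617, 2_480_000),
    ("SsPl", 1172, 3286, 3_050_000 + 97_800),
]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for strain, n_pseudo, n_total, bp in REPORTED:
        s = GenomeSummary.from_counts(strain, n_pseudo, n_total, total_bp=bp)
        rows.append({"strain": strain, "size_mb": genome_size_mb(bp),
                     "n_cds_total": n_total, "n_pseudogenes": n_pseudo,
                     "n_cds_intact": s.n_cds_intact,
                     "pseudogene_pct": s.pseudogene_pct})
        print(f"{strain}: {genome_size_mb(bp):.2f} Mb, {n_total} CDS, "
              f"{n_pseudo} pseudogenes ({s.pseudogene_pct}%)")
    pd.DataFrame(rows).to_csv(OUT / "erosion_summary.tsv", sep="\t", index=False)

    campaigns = {"2014": 21, "2016": 76}
    n = sum(campaigns.values())
    res = prevalence(n, n)
    print(f"prevalence: {res.n_positive}/{res.n_sampled} = {res.prevalence_pct:.1f}% "
          f"(95% CI {res.ci95[0]:.2f}–{res.ci95[1]:.2f}%)")
    pd.DataFrame(
        [{"n_positive": res.n_positive, "n_sampled": res.n_sampled,
          "prevalence_pct": res.prevalence_pct,
          "ci95_lower_pct": round(res.ci95[0], 2),
          "ci95_upper_pct": round(res.ci95[1], 2)}]
    ).to_csv(OUT / "prevalence.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
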