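# disymbio

Comparative-genomic analysis of **di-symbiotic endosymbiont consortia** — host
systems in which an ancient obligate symbiont (e.g. *Buchnera aphidicola*) is
metabolically complemented by a more recently acquired co-obligate partner
(e.g. *Serratia symbiotica*). The package is aimed at microbial comparative
genomicists studying genome erosion and metabolic complementarity in
host-restricted bacteria.

## What it computes

Given annotated symbiont genomes (GenBank or GFF3 + FASTA) and a reference
protein panel, the pipeline:

1. **Classifies every panel gene** as `INTACT`, `PSEUDOGENE`, or `MISSING` by
   the ortholog-length rule: a CDS is a pseudogene when its length *L* falls
   strictly below 80% of its reference ortholog's length *L_ref*
   (`L / L_ref < 0.8`), when it survives only as ≥ 2 fragments, or when the
   annotation flags it as disrupted. Matching uses optimal local protein
   alignment (BLOSUM62, affine gaps 11/1), with content-based tie-breaking and
   fragment pooling: fragments of one gene are merged and coverage is measured
   on the reference protein, `|∪ intervals| / L_ref`.
2. **Evaluates biosynthetic-pathway completeness** with alternative-enzyme
   logic. A pathway is an ordered list of steps, each a set of alternative
   genes; a step is satisfied iff some alternative is intact in some genome
   (`∧_steps ∨_alts ∨_genomes INTACT`), and a consortium verdict over the
   union of genomes attributes each step to its providers — the signature of
   metabolic complementarity.
3. **Screens virulence factors** at the standard thresholds (≥ 50% amino-acid
   identity, ≥ 80% reference coverage) and derives repertoire verdicts:
   flagellum completeness (`COMPLETE` / `BASAL_BODY_ONLY` / `PARTIAL` /
   `ABSENT`) and siderophore locus completeness (enterobactin,
   yersiniabactin).
4. **Summarizes genome erosion** (size, CDS counts, pseudogene percentage) and
   symbiont **prevalence** with exact Clopper–Pearson binomial intervals.
5. **Simulates degraded genomes** with known ground truth — per-gene deletion,
   truncation, fragmentation, and residue substitution — so every stage is
   benchmarkable end to end without downloads.

## Worked example

Simulate a 200-gene eroding genome, classify it, and score recovery:

```python
from disymbio.simulate import (DegradationSpec, degrade_genome,
                               generate_reference_panel, recovery_report)
from disymbio.gene_status import classify_genome

panel = generate_reference_panel(200, seed=7)
spec = DegradationSpec(p_delete=0.2, p_truncate=0.3, p_fragment=0.1, seed=7)
genome, truth = degrade_genome(panel, spec)
table = classify_genome(genome, panel)
confusion, agreement = recovery_report(table, truth)
print(confusion); print(f"agreement: {agreement:.4f}")
```

prints

```
            INTACT  PSEUDOGENE  MISSING
INTACT          77           0        0
PSEUDOGENE      0           79        0
MISSING         0            0       44
agreement: 1.0000
```

i.e. all 77 untouched genes classify `INTACT`, all 79 truncated/fragmented
genes classify `PSEUDOGENE`, and all 44 deleted genes classify `MISSING`.

The same stages are scriptable from the shell (`disymbio simulate`,
`disymbio classify`, `disymbio pathways`, `disymbio virulome`,
`disymbio stats`), and the numbered drivers under `analysis/` run the four
study analyses — the degradation benchmark, vitamin complementarity over the
curated strain tables, the virulome contrast, and erosion/prevalence
statistics — writing their tables under `results/`. For example
`python analysis/04_erosion_stats.py` prints:

```
SsSm: 2.48 Mb, 2617 CDS, 1258 pseudogenes (48%)
SsPl: 3.15 Mb, 3286 CDS, 1172 pseudogenes (36%)
prevalence: 97/97 = 100.0% (95% CI 96.27–100.00%)
```

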