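# Methods

## The model system and the question

Sap-feeding insects such as aphids depend on bacteriocyte-housed bacterial
symbionts for nutrients missing from phloem sap. In di-symbiotic systems the
ancient obligate symbiont (*Buchnera aphidicola*, genome ~0.45 Mb) has eroded
past self-sufficiency and a younger co-obligate partner (here *Serratia
symbiotica*, 2.5–3.2 Mb, 36–48% pseudogenes) completes the missing
biosynthetic pathways. This package implements the comparative-genomic
reasoning used to establish such complementarity: per-gene functional status,
pathway-level boolean completeness over genome unions, virulence-repertoire
contrasts, and the erosion statistics that date a symbiont's decay.

## Pseudogene classification

A panel gene's status in a genome is decided by the ortholog-length rule:

- **MISSING** — no CDS in the genome is assigned to the gene.
- **INTACT** — exactly one assigned CDS, not flagged as disrupted, whose
  translated length is **at least** 80% of the reference ortholog length.
  The inequality is strict on the pseudogene side: a CDS at exactly 0.8 of
  the reference is intact. The boundary is pinned by a dedicated
  boundary-stress simulation mode that truncates at exactly 80%.
- **PSEUDOGENE** — a single shorter CDS, or ≥ 2 fragments (a gene in pieces
  is disrupted whatever the cumulative span — the longest single fragment
  sets `length_ratio`), or a CDS the annotation itself declares pseudo while
  `trust_declared_pseudo` is on (default on: annotation pipelines detect
  frameshifts and internal stops the length rule cannot; switch it off to
  recompute from length alone).

Assignment is one CDS → at most one gene (its best hit), so paralogs are
never double-counted; a gene reachable only through a CDS whose best hit is
another gene stays MISSING and the CDS is reported as unassigned.

## Alignment

Matching uses optimal local alignment (Bio.Align.PairwiseAligner) with
BLOSUM62 and affine gaps: the first residue of a gap costs 11, each further
residue 1. Exact scores are not meant to reproduce any heuristic search
tool; only the identity/coverage contract matters. Identity is identical
aligned positions over aligned columns (substitution plus internal-gap
columns), recomputed from the traceback rather than taken from the aligner.
Coverage is **reference-relative** — eroded fragments shorten the query, so
the intact reference protein is the stable denominator. Assignment floors
are permissive (identity ≥ 0.3, per-fragment reference coverage ≥ 0.1) so
that short pseudogene fragments remain assignable; both are configurable.
Ties between panel entries break by score, then identity, then gene name —
content-based, so results are invariant under panel order. The test suite
vouches for the alignment layer with an independent pure-Python Gotoh
dynamic program: scores and identities must agree on seeded pairs; coverages
are compared only on homologous pairs, because co-optimal alignments of
unrelated sequences can differ in extent while sharing the optimal score.

An optional reciprocal-best-hit check against the query proteome is not
enabled by default: panel screening is one-directional, and the synthetic
benchmarks show the single-direction assignment is already unambiguous at
the identity levels involved.

## Pathway completeness

`complete ⇔ ∧_steps ∨_alternatives ∨_genomes INTACT`. At step level a
pseudogenized alternative dominates a missing one (a Ψ cell records that the
function was present and decayed, which is evidential). Consortium
evaluation is monotone in the genome set: adding a member can only satisfy
more steps. `unique_providers` (steps with exactly one providing genome) is
the operational definition of complementarity. No partial-pathway fraction
is scored — completeness is qualitative all-steps, matching how these
systems are reasoned about.

The bundled catalog covers riboflavin (with the phosphatase step's
alternatives yigB/ybjI/yigL), biotin (bioC→bioH→bioF→bioA→bioD→bioB), and
the ten host-essential amino acids with standard enterobacterial gene sets
(alternatives encoded where *E. coli* has them, e.g. thrA/metL/lysC,
metE/metH, aroG/aroF/aroH). The catalog is data, not logic, and is fully
overridable via YAML. One documented caveat: phosphatase activity of the
riboflavin phosphatase step may in reality be carried by unidentified
alternative enzymes; an unknown enzyme cannot be encoded, so a consortium
whose only known alternatives are decayed evaluates incomplete (the
S. maydis riboflavin consortium behaves exactly so over the curated tables).

## Virulome screening

Screen thresholds default to ≥ 50% identity and ≥ 80% reference coverage.
Cell semantics: **PRESENT** requires an INTACT classification *and* a hit
passing both thresholds (coverage measured on the merged fragment span);
**PSEUDOGENE** is any gene the assignment floor (≥ 30% identity) finds but
the length/fragment rule calls disrupted; **ABSENT** otherwise — including
an intact distant homolog below the screen thresholds, which is why absence
is threshold-dependent. This makes presence anti-monotone in both
thresholds, a property the suite tests.

Flagellum verdicts use a bundled gene→part map (basal body, hook, filament,
export, regulation; overridable). `COMPLETE` requires every mapped gene
present. `BASAL_BODY_ONLY` requires ≥ 1 basal-body gene present and zero
hook and zero filament genes present; export/regulation genes do not block
the call, since the export ATPase and regulators belong to the surviving
basal apparatus, and decayed basal-body rod genes do not rescue a relic into
`PARTIAL`. This matches the observed relic configuration in SsSm, where
intact flgB/flgH/fliE/fliI/fliM/fliN coexist with pseudogenized rod genes.

## Curated strain tables

`disymbio.strains` transcribes only gene statuses reported verbatim for the
four strains (BaSm, SsSm, BaPl, SsPl): riboflavin and biotin genes, the
flagellar genes named for each strain, the ent/ybt siderophore loci, T5SS
autotransporters and YopJ-family effectors. Unreported rows are not
invented; pathway evaluation over these tables is therefore restricted to
riboflavin and biotin. Re-deriving the tables from sequence requires the
deposited assemblies and annotation pipeline and is outside the test path.

## Erosion statistics

Pseudogene percentage is rounded half-up to an integer
(1258/2617 → 48%, 1172/3286 → 36%); full precision is retained in TSV
output. Genome size reports in Mb at two decimals, half-up, summed over all
replicons including plasmids (3.05 Mb chromosome + 97.8 kb plasmid →
3.15 Mb). Intact CDS counts are always the consistent partition
`n_intact = n_total − n_pseudo`; externally reported intact counts that
differ by one from that arithmetic are not reproduced. Prevalence intervals
are exact Clopper–Pearson from the beta quantile function; 97/97 positive
colonies give 100% with a 95% lower bound of 96.27%.

## The synthetic generator

`generate_reference_panel` draws i.i.d. uniform residues over the 20 amino
acids with lengths uniform in [100, 400] aa — typical bacterial protein
sizes. `degrade_genome` assigns each gene an independent fate: delete
(default p = 0.2), truncate (0.3), fragment (0.1), else intact, emulating a
heavily eroding recently host-restricted genome. Truncation keeps an
N-terminal prefix with fraction uniform in (0.2, 0.6) — bounded away from
the 0.8 decision threshold by a margin of 0.05 enforced at spec validation,
so ground truth is unambiguous. Fragmentation splits the protein into k ∈
[2, 4] contiguous pieces, each at least max(15 aa, 12% of the protein) so a
near-identical fragment always aligns and clears the per-fragment coverage
floor, and at most 70% so no piece can masquerade as intact. Substitutions
are applied per-residue (default 2%). Nucleotide sequence is back-translated
with uniform codon choice under the bacterial genetic code so emitted
GenBank/GFF3 files carry real coordinates and sequence; frameshifts are not
simulated, because the classification rule under test is length-based.

All randomness flows from one integer seed; identical seed + spec gives
byte-identical output files. What the generator does **not** emulate:
phylogenetic substitution structure (BLOSUM-like exchangeabilities,
rate variation), indels, compositional bias, operon structure, annotation
error. Passing benchmarks therefore demonstrate the correctness of the
classification logic and thresholds, not robustness to the full noise
spectrum of real eroded genomes — on real data the declared-pseudo layer
and manual curation carry part of the load.

`simulate_consortium` engineers two genomes from a pathway scenario (each
step's provider gets an intact carrier gene, the partner a truncated or
deleted copy; unused alternatives are deleted from both), yielding systems
complete only in union with known provider attribution. When a gene serves
several steps, later steps' assignments win; the union-completeness
guarantee is unaffected.

## Problem sizes and numerical choices

The standard benchmark is 200 genes (~190 CDSs against a 200-protein
panel), which classifies in well under a minute on one core; the multinomial
calibration checks use 10⁴ genes with short proteins, where only fates
matter. Best-hit search computes score-only alignments for the whole panel
and tracebacks only for contenders within the best passing score.
Degenerate inputs are defined errors: empty sequences, non-amino-acid
characters (`X` allowed; internal stop codons read from nucleotide sources
are masked to `X`), thresholds outside (0, 1], fate probabilities summing
past 1, truncation ranges inside the boundary margin. Status tables carry an
explicit record for every panel gene, so |INTACT| + |PSEUDOGENE| +
|MISSING| equals the panel size by construction.

## Known limitations

- The length rule cannot see frameshifts or internal stops on its own; it
  relies on the annotation's pseudo flags for those (the `trust_declared_pseudo`
  switch makes the dependency explicit).
- Alternative-enzyme sets are only as complete as the catalog; unknown
  analogs make completeness conservative.
- Secretion-system and prophage detection are out of scope; such factors
  enter only as ordinary panel genes with category tags.
- Coverage semantics are reference-relative by design; query-relative
  coverage is computed and reported but plays no role in the default rules.
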