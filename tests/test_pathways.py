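"""Pathway completeness, alternative-enzyme logic, and consortium union."""

import itertools

import numpy as np
import pytest

from disymbio.gene_status import INTACT, MISSING, PSEUDOGENE, StatusTable, classify_genome
from disymbio.pathways import (
    CatalogError,
    Pathway,
    PathwayStep,
    SATISFIED,
    PSEUDOGENIZED,
    STEP_MISSING,
    complementarity_matrix,
    consortium_completeness,
    pathway_completeness,
    step_status,
)
from disymbio.simulate import panel_for_catalog, simulate_consortium


def _table(genome, statuses):
    return StatusTable.from_statuses(genome, statuses)


def _random_instance(rng, n_genomes, n_steps, max_alts):
    steps = []
    gene_id = 0
    for s in range(n_steps):
        k = int(rng.integers(1, max_alts + 1))
        steps.append(PathwayStep(f"s{s}", tuple(f"g{gene_id + i}" for i in range(k))))
        gene_id += k
    pathway = Pathway("p", tuple(steps))
    genes = pathway.gene_names
    tables = [
        _table(f"G{g}", {gene: rng.choice([INTACT, PSEUDOGENE, MISSING]) for gene in genes})
        for g in range(n_genomes)
    ]
    return pathway, tables


def _oracle_complete(pathway, tables):
    # brute-force boolean evaluation: AND over steps of OR over alternatives
    return all(
        any(t.status_of(g) == INTACT for t in tables for g in step.alternatives)
        for step in pathway.steps
    )


class TestStepStatus:
    def test_curated_phosphatase_step(self, catalog, vitamin_tables):
        step = next(s for s in catalog["riboflavin"].steps if s.name == "phosphatase")
        # SsSm alone: yigB/ybjI missing, yigL pseudogenized -> step Ψ
        assert step_status(step, [vitamin_tables["SsSm"]]).value == PSEUDOGENIZED
        # SsPl alone: yigL intact -> satisfied by SsPl
        st = step_status(step, [vitamin_tables["SsPl"]])
        assert st.value == SATISFIED
        assert st.providers == {"SsPl"}

    def test_all_alternatives_missing_everywhere(self):
        step = PathwayStep("s", ("a", "b"))
        tables = [_table("G", {"a": MISSING, "b": MISSING})]
        assert step_status(step, tables).value == STEP_MISSING

    def test_pseudogenized_dominates_missing(self):
        step = PathwayStep("s", ("a", "b"))
        tables = [_table("G", {"a": MISSING, "b": PSEUDOGENE})]
        assert step_status(step, tables).value == PSEUDOGENIZED

    def test_absent_alternative_is_config_error(self):
        step = PathwayStep("s", ("a", "zz"))
        with pytest.raises(CatalogError):
            step_status(step, [_table("G", {"a": INTACT})])


class TestPathwayCompleteness:
    def test_all_intact_is_complete(self):
        pathway = Pathway("p", (PathwayStep("s1", ("a",)), PathwayStep("s2", ("b", "c"))))
        verdict = pathway_completeness(pathway, _table("G", {"a": INTACT, "b": INTACT, "c": MISSING}))
        assert verdict.complete

    def test_curated_riboflavin_columns(self, catalog, vitamin_tables):
        rib = catalog["riboflavin"]
        basm = pathway_completeness(rib, vitamin_tables["BaSm"])
        assert not basm.complete
        assert all(s.value == STEP_MISSING for s in basm.per_step)
        sspl = pathway_completeness(rib, vitamin_tables["SsPl"])
        assert sspl.complete

    def test_matches_boolean_oracle_randomized(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            pathway, tables = _random_instance(
                rng, int(rng.integers(1, 5)), int(rng.integers(1, 11)), 3
            )
            verdict = consortium_completeness(pathway, tables)
            assert verdict.complete == _oracle_complete(pathway, tables)
            one = pathway_completeness(pathway, tables[0])
            assert one.complete == _oracle_complete(pathway, tables[:1])

    def test_matches_boolean_oracle_exhaustively_small(self):
        # every status assignment for 2 steps x 2 alternatives x 2 genomes
        pathway = Pathway("p", (PathwayStep("s0", ("a", "b")), PathwayStep("s1", ("c", "d"))))
        genes = ["a", "b", "c", "d"]
        for combo in itertools.product([INTACT, PSEUDOGENE, MISSING], repeat=8):
            tables = [
                _table("G0", dict(zip(genes, combo[:4]))),
                _table("G1", dict(zip(genes, combo[4:]))),
            ]
            assert consortium_completeness(pathway, tables).complete == _oracle_complete(
                pathway, tables
            )


class TestConsortium:
    def test_curated_biotin_complementarity(self, catalog, vitamin_tables):
        bio = catalog["biotin"]
        sm = consortium_completeness(bio, [vitamin_tables["BaSm"], vitamin_tables["SsSm"]])
        assert sm.complete
        unique = dict(sm.unique_providers)
        # the final steps from 7-keto-8-aminopelargonate come from SsSm alone
        assert {unique[s] for s in ("bioA", "bioD", "bioB")} == {"SsSm"}
        pl = consortium_completeness(bio, [vitamin_tables["BaPl"], vitamin_tables["SsPl"]])
        assert not pl.complete
        failing = {s.name for s, st in zip(bio.steps, pl.per_step) if st.value != SATISFIED}
        assert {"bioA", "bioD"} <= failing

    def test_complete_member_implies_complete_consortium(self, catalog, vitamin_tables):
        rib = catalog["riboflavin"]
        assert pathway_completeness(rib, vitamin_tables["SsPl"]).complete
        verdict = consortium_completeness(rib, [vitamin_tables["BaPl"], vitamin_tables["SsPl"]])
        assert verdict.complete

    def test_union_monotone_in_genome_set(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            pathway, tables = _random_instance(rng, 3, 6, 3)
            base = consortium_completeness(pathway, tables[:2])
            grown = consortium_completeness(pathway, tables)
            for s_base, s_grown in zip(base.per_step, grown.per_step):
                if s_base.value == SATISFIED:
                    assert s_grown.value == SATISFIED
                    assert s_base.providers <= s_grown.providers

    def test_duplicate_table_changes_nothing(self, catalog, vitamin_tables):
        bio = catalog["biotin"]
        tables = [vitamin_tables["BaSm"], vitamin_tables["SsSm"]]
        v1 = consortium_completeness(bio, tables)
        v2 = consortium_completeness(bio, tables + [vitamin_tables["SsSm"]])
        assert v1.complete == v2.complete
        assert [s.value for s in v1.per_step] == [s.value for s in v2.per_step]
        assert [s.providers for s in v1.per_step] == [s.providers for s in v2.per_step]


class TestSimulatedConsortia:
    def test_one_sided_split_complete_via_single_member(self, catalog):
        rib = catalog["riboflavin"]
        panel = panel_for_catalog(rib, seed=41)
        scenario = {s.name: "A" for s in rib.steps}
        ga, gb, _ = simulate_consortium(panel, rib, scenario, seed=41)
        ta, tb = classify_genome(ga, panel), classify_genome(gb, panel)
        assert pathway_completeness(rib, ta).complete
        assert not pathway_completeness(rib, tb).complete
        verdict = consortium_completeness(rib, [ta, tb])
        assert verdict.complete
        assert all(g == "symA" for _, g in verdict.unique_providers)

    def test_alternating_split_complete_only_in_union(self, catalog):
        his = catalog["histidine"]  # steps share no genes, so providers are exact
        panel = panel_for_catalog(his, seed=43)
        scenario = {s.name: ("A" if i % 2 == 0 else "B") for i, s in enumerate(his.steps)}
        ga, gb, providers = simulate_consortium(panel, his, scenario, seed=43)
        ta, tb = classify_genome(ga, panel), classify_genome(gb, panel)
        assert not pathway_completeness(his, ta).complete
        assert not pathway_completeness(his, tb).complete
        verdict = consortium_completeness(his, [ta, tb])
        assert verdict.complete
        assert dict(verdict.unique_providers) == providers

    def test_empty_scenario_rejected(self, catalog):
        rib = catalog["riboflavin"]
        panel = panel_for_catalog(rib, seed=2)
        with pytest.raises(ValueError):
            simulate_consortium(panel, rib, {}, seed=2)


class TestComplementarityMatrix:
    def test_row_order_is_deterministic_catalog_order(self, catalog, vitamin_tables):
        sub = catalog.subset(["riboflavin", "biotin"])
        m1 = complementarity_matrix(sub, list(vitamin_tables.values()))
        m2 = complementarity_matrix(sub, list(vitamin_tables.values()))
        assert m1.equals(m2)
        assert m1["pathway"].iloc[0] == "riboflavin"
        # within a step, genes are listed alphabetically
        phosphatase = m1[m1["step"] == "phosphatase"]
        assert phosphatase["gene"].tolist() == ["ybjI", "yigB", "yigL"]
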