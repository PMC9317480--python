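import pytest

from disymbio import gene_status, pathways, simulate, strains


@pytest.fixture(scope="session")
def small_panel():
    return simulate.generate_reference_panel(20, (80, 200), seed=11)


@pytest.fixture(scope="session")
def benchmark():
    """The seeded 200-gene degradation benchmark, classified once per session."""
    panel = simulate.generate_reference_panel(200, seed=7)
    spec = simulate.DegradationSpec(
        p_delete=0.2, p_truncate=0.3, p_fragment=0.1, seed=7
    )
    genome, truth = simulate.degrade_genome(panel, spec)
    table = gene_status.classify_genome(genome, panel)
    return panel, genome, truth, table


@pytest.fixture(scope="session")
def catalog():
    return pathways.load_default_catalog()


@pytest.fixture(scope="session")
def vitamin_tables():
    return strains.vitamin_status_tables()


@pytest.fixture(scope="session")
def vmaps():
    return strains.virulence_maps()
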