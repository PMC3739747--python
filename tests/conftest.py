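import pytest
from hypothesis import settings

from mitocomp.simulate import DuplicationEvent, SimulationConfig, simulate_clade

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

BALANCED_TREE_4 = "((t1:0.3,t2:0.3):0.2,(t3:0.3,t4:0.3):0.2);"


@pytest.fixture(scope="session")
def clade4():
    """Four-taxon clade on a fixed balanced tree, no duplication events."""
    cfg = SimulationConfig(seed=11, n_taxa=4, tree_newick=BALANCED_TREE_4)
    return simulate_clade(cfg)


@pytest.fixture(scope="session")
def clade_events():
    """Clade carrying both duplication mechanisms: a tandem tRNA-Val
    copy re-anticodoned to tRNA-Ile in t1, and a strand-flipped
    tRNA-Asp copy inserted mid-CR in t2."""
    cfg = SimulationConfig(
        seed=23, n_taxa=4, tree_newick=BALANCED_TREE_4,
        duplication_events=[
            DuplicationEvent(taxon="t1", mode="tandem", source_gene="tRNA-Val",
                             new_name="tRNA-Ile", anticodon_dna="AAT"),
            DuplicationEvent(taxon="t2", mode="cr", source_gene="tRNA-Asp"),
        ])
    return simulate_clade(cfg)


@pytest.fixture(scope="session")
def genomes4(clade4):
    return clade4.genomes
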