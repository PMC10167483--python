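import numpy as np
import pytest

from mechassembly.assembly import AssembledCorpus
from mechassembly.ontology import OntologyGraph
from mechassembly.statements import (
    Agent,
    Evidence,
    Grounding,
    ModCondition,
    Statement,
)
from mechassembly.synthetic import (
    SimulationConfig,
    generate_ontology,
    phosphorylation_chain_fixture,
    simulate_corpus,
)


def make_agent(name, ns="HGNC", ident=None, **kwargs):
    ident = ident if ident is not None else name
    return Agent(name=name, groundings=frozenset([Grounding(ns, ident)]),
                 **kwargs)


def make_evidence(source="reader_a", pmid="1", text=None, source_id=None,
                  **kwargs):
    return Evidence(source_api=source, pmid=pmid, text=text,
                    source_id=source_id, **kwargs)


@pytest.fixture(scope="session")
def kinase_ontology():
    """Small MAP-kinase-style ontology: MAP2K1/MAP2K2 isa MEK, MAPK1/MAPK3
    isa ERK, plus a chemical node with xrefs."""
    onto = OntologyGraph()
    mek = onto.add_node("FPLX", "MEK", "MEK")
    erk = onto.add_node("FPLX", "ERK", "ERK")
    for sym, ident, fam in [("MAP2K1", "6840", mek), ("MAP2K2", "6842", mek),
                            ("MAPK1", "6871", erk), ("MAPK3", "6877", erk)]:
        g = onto.add_node("HGNC", ident, sym)
        onto.add_edge(g, fam, "isa")
        up = onto.add_node("UP", f"UP_{sym}", sym)
        onto.add_edge(g, up, "xref")
        onto.add_edge(up, g, "xref")
    chebi = onto.add_node("CHEBI", "15551", "prostaglandin E2")
    mesh = onto.add_node("MESH", "D015232", "prostaglandin E2")
    onto.add_edge(chebi, mesh, "xref")
    braf = onto.add_node("HGNC", "1097", "BRAF")
    onto.add_edge(braf, onto.add_node("FPLX", "RAF", "RAF"), "isa")
    onto.validate()
    return onto


@pytest.fixture(scope="session")
def chain_fixture():
    return phosphorylation_chain_fixture()


@pytest.fixture(scope="session")
def small_corpus():
    """Assembled five-source synthetic corpus used across test modules."""
    config = SimulationConfig(seed=42, n_mechanisms=300)
    raw, truth = simulate_corpus(config)
    corpus = AssembledCorpus.assemble(raw, truth["ontology"])
    return config, corpus, truth


@pytest.fixture(scope="session")
def single_source_corpus():
    """Single-source corpus at the reference error condition."""
    config = SimulationConfig(
        seed=7, n_mechanisms=1500,
        source_params={"reader_a": {"e_syst": 0.10, "e_rand": 0.35}},
        p_hypothesis=0.0, p_negated=0.0)
    raw, truth = simulate_corpus(config)
    corpus = AssembledCorpus.assemble(raw, truth["ontology"])
    return config, corpus, truth
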