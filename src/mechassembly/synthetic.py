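"""Synthetic corpora, ontologies, curations, and dependency matrices.

Every stage of the assembly pipeline is testable offline against data from
this module.  The corpus generator emulates the statistical structure of a
multi-source literature-extraction corpus: a set of true mechanisms over a
toy gene/family ontology; per-source noisy extractions governed by
systematic and random error rates; long-tailed (power-law) mention counts;
and per-mention specificity degradation (dropped sites, member-to-family
generalization) that produces nontrivial refinement hierarchies.  The
dependency-matrix generator emulates paired perturbation screens with
planted correlated gene pairs.

Systematic errors are modeled as a per-(mechanism, source) coin flip that
corrupts *all* of that source's mentions identically — the generative
story behind a per-source systematic error rate, matching the empirical
signature of a reader that misinterprets the same construction in every
sentence; the corrupted mentions assemble into a distinct, wholly
incorrect Statement.  Random errors are per-mention and independent: the
mention stays attached to its Statement but mis-supports it (the sentence
did not actually assert the mechanism), so a Statement with n mentions
from one source is jointly unsupported with probability
e_syst + (1 - e_syst) e_rand^n, exactly the two-parameter reliability
model.  All randomness derives from the config seed; outputs are
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assembly import AssembledCorpus
from .corpus_stats import sample_discrete_power_law
from .ontology import OntologyGraph
from .statements import (
    Agent,
    CurationRecord,
    Evidence,
    Grounding,
    ModCondition,
    Statement,
    matches_key,
)

__all__ = [
    "SimulationConfig",
    "generate_ontology",
    "simulate_corpus",
    "generate_curation_dataset",
    "generate_dependency_matrices",
    "phosphorylation_chain_fixture",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic corpus.

    Defaults describe a medium-sized multi-reader extraction experiment:
    five sources with distinct error profiles (the first source's
    e_syst=0.10 / e_rand=0.35 profile is the reference condition used in
    parameter-recovery experiments), mention counts following a discrete
    power law with exponent 2.38 (the corpus-scale value), and moderate
    specificity degradation so that generic and specific variants of each
    mechanism coexist.
    """

    seed: int = 0
    n_families: int = 20
    members_per_family: int = 3
    n_mechanisms: int = 300
    source_params: dict = field(default_factory=lambda: {
        "reader_a": {"e_syst": 0.10, "e_rand": 0.35},
        "reader_b": {"e_syst": 0.20, "e_rand": 0.30},
        "reader_c": {"e_syst": 0.05, "e_rand": 0.45},
        "reader_d": {"e_syst": 0.15, "e_rand": 0.25},
        "reader_e": {"e_syst": 0.08, "e_rand": 0.40},
    })
    source_weights: Optional[dict] = None  # uniform if None
    powerlaw_exponent: float = 2.38
    max_mentions: int = 1000
    p_drop_site: float = 0.3
    p_generalize: float = 0.2
    p_hypothesis: float = 0.05
    p_negated: float = 0.02
    keyword_rate_incorrect: float = 0.3
    keyword_rate_correct: float = 0.02
    mean_text_tokens: float = 12.0
    # codependency generator
    n_genes: int = 40
    n_samples: int = 500
    n_planted_pairs: int = 10
    planted_rho: float = 0.5
    noise_sd: float = 1.0
    network_aligned_fraction: float = 1.0

    def __post_init__(self):
        for p in (self.p_drop_site, self.p_generalize, self.p_hypothesis,
                  self.p_negated, self.keyword_rate_incorrect,
                  self.keyword_rate_correct, self.planted_rho,
                  self.network_aligned_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def generate_ontology(config: SimulationConfig) -> OntologyGraph:
    """Toy gene/family ontology: families with isa members and xref
    aliases in a second namespace.  Deterministic given the config."""
    onto = OntologyGraph()
    for f in range(config.n_families):
        fam_name = f"FAM{f}"
        fam = onto.add_node("FPLX", fam_name, fam_name)
        for m in range(config.members_per_family):
            gene_name = f"G{f}_{m}"
            gene = onto.add_node("HGNC", str(f * 1000 + m), gene_name)
            onto.add_edge(gene, fam, "isa")
            # cross-reference alias in a protein namespace
            alias = onto.add_node("UP", f"P{f:03d}{m:02d}", gene_name)
            onto.add_edge(gene, alias, "xref")
            onto.add_edge(alias, gene, "xref")
    onto.validate()
    return onto


def _gene_nodes(onto: OntologyGraph) -> list[str]:
    return sorted(k for k, d in onto.graph.nodes(data=True)
                  if d["namespace"] == "HGNC")


def _agent_for(onto: OntologyGraph, node: str) -> Agent:
    data = onto.graph.nodes[node]
    groundings = {Grounding(data["namespace"], data["identifier"])}
    for xk in onto.xref_closure(node):
        xd = onto.graph.nodes[xk]
        groundings.add(Grounding(xd["namespace"], xd["identifier"]))
    return Agent(name=data["name"], groundings=frozenset(groundings))


_MECH_TYPES = ("Phosphorylation", "Activation", "Inhibition", "Complex",
               "IncreaseAmount", "DecreaseAmount")
_MECH_WEIGHTS = (0.35, 0.2, 0.15, 0.15, 0.1, 0.05)
_RESIDUES = ("S", "T", "Y")


@dataclass
class TrueMechanism:
    stmt_type: str
    subj_node: Optional[str]
    obj_node: str
    residue: Optional[str]
    position: Optional[str]


def _draw_mechanisms(config: SimulationConfig, onto: OntologyGraph,
                     rng: np.random.Generator) -> list[TrueMechanism]:
    genes = _gene_nodes(onto)
    mechanisms = []
    seen = set()
    while len(mechanisms) < config.n_mechanisms:
        typ = rng.choice(_MECH_TYPES, p=_MECH_WEIGHTS)
        subj, obj = rng.choice(len(genes), size=2, replace=False)
        residue = position = None
        if typ == "Phosphorylation":
            residue = str(rng.choice(_RESIDUES))
            position = str(int(rng.integers(1, 500)))
        mech = TrueMechanism(str(typ), genes[subj], genes[obj], residue,
                             position)
        sig = (mech.stmt_type, mech.subj_node, mech.obj_node, mech.residue,
               mech.position)
        if sig not in seen:
            seen.add(sig)
            mechanisms.append(mech)
    return mechanisms


def _corrupt(mech: TrueMechanism, genes: list[str],
             rng: np.random.Generator) -> TrueMechanism:
    """A wrong extraction: the object entity is swapped for another gene
    (the typical misgrounding failure mode)."""
    choices = [g for g in genes if g not in (mech.obj_node, mech.subj_node)]
    new_obj = choices[int(rng.integers(len(choices)))]
    return dataclasses.replace(mech, obj_node=new_obj)


def _degrade(mech: TrueMechanism, onto: OntologyGraph,
             rng: np.random.Generator, config: SimulationConfig,
             ) -> TrueMechanism:
    """Per-mention specificity degradation: drop the site and/or
    generalize entities to their family parent."""
    out = mech
    if out.residue is not None and rng.random() < config.p_drop_site:
        out = dataclasses.replace(out, residue=None, position=None)
    elif out.position is not None and rng.random() < config.p_drop_site:
        out = dataclasses.replace(out, position=None)
    for attr in ("subj_node", "obj_node"):
        node = getattr(out, attr)
        if node is None:
            continue
        if rng.random() < config.p_generalize:
            parents = sorted(onto.ancestor_closure(node))
            if parents:
                out = dataclasses.replace(out, **{attr: parents[0]})
    return out


def _mech_to_statement(mech: TrueMechanism, onto: OntologyGraph,
                       evidence: list[Evidence]) -> Statement:
    obj = _agent_for(onto, mech.obj_node)
    if mech.stmt_type == "Complex":
        subj = _agent_for(onto, mech.subj_node)
        return Statement("Complex", [subj, obj], evidence=evidence)
    subj = (_agent_for(onto, mech.subj_node)
            if mech.subj_node is not None else None)
    return Statement(mech.stmt_type, [subj, obj], residue=mech.residue,
                     position=mech.position, evidence=evidence)


def _make_text(rng: np.random.Generator, config: SimulationConfig,
               correct: bool) -> str:
    n_tokens = max(3, int(rng.poisson(config.mean_text_tokens)))
    tokens = [f"w{int(rng.integers(1000))}" for _ in range(n_tokens)]
    rate = (config.keyword_rate_correct if correct
            else config.keyword_rate_incorrect)
    if rng.random() < rate:
        tokens[int(rng.integers(n_tokens))] = "promoter"
    return " ".join(tokens)


def simulate_corpus(config: SimulationConfig,
                    onto: Optional[OntologyGraph] = None,
                    ) -> tuple[list[Statement], dict]:
    """Simulate raw per-mention Statements with ground-truth labels.

    For each true mechanism a power-law mention count is drawn and each
    mention is assigned a source.  With probability e_syst the source
    extracts the mechanism wrongly in a fixed, repeated way (all that
    source's mentions share one corrupted variant statement); otherwise
    each mention independently mis-supports the mechanism's own statement
    with probability e_rand.  Mentions are then independently degraded in
    specificity, creating duplicate and refinement structure.  Every
    Evidence carries its ground-truth correctness in
    ``annotations["correct"]``.

    Returns (raw statements — one per mention — and a ground-truth dict
    with the mechanism list and per-mechanism mention counts).
    """
    rng = np.random.default_rng(config.seed)
    if onto is None:
        onto = generate_ontology(config)
    genes = _gene_nodes(onto)
    mechanisms = _draw_mechanisms(config, onto, rng)
    sources = sorted(config.source_params)
    weights = (np.array([config.source_weights[s] for s in sources])
               if config.source_weights else
               np.ones(len(sources)))
    weights = weights / weights.sum()
    mention_counts = sample_discrete_power_law(
        len(mechanisms), config.powerlaw_exponent, rng,
        xmax=config.max_mentions)

    raw: list[Statement] = []
    truth_rows = []
    ev_counter = 0
    for mech_idx, (mech, n_mentions) in enumerate(
            zip(mechanisms, mention_counts)):
        # one systematic-corruption coin flip and fixed variant per source
        syst_variant: dict[str, Optional[TrueMechanism]] = {}
        for src in sources:
            if rng.random() < config.source_params[src]["e_syst"]:
                syst_variant[src] = _corrupt(mech, genes, rng)
            else:
                syst_variant[src] = None
        for _ in range(int(n_mentions)):
            src = sources[int(rng.choice(len(sources), p=weights))]
            params = config.source_params[src]
            if syst_variant[src] is not None:
                extracted, correct = syst_variant[src], False
            else:
                # random error: the mention stays with the mechanism's own
                # statement but mis-supports it
                extracted = mech
                correct = rng.random() >= params["e_rand"]
            extracted = _degrade(extracted, onto, rng, config)
            ev_counter += 1
            epistemics = {}
            if rng.random() < config.p_hypothesis:
                epistemics["hypothesis"] = True
            if rng.random() < config.p_negated:
                epistemics["negated"] = True
            ev = Evidence(
                source_api=src,
                pmid=str(100000 + int(rng.integers(2000))),
                text=_make_text(rng, config, correct),
                source_id=f"ev{ev_counter}",
                epistemics=epistemics,
                annotations={"correct": bool(correct),
                             "mechanism": mech_idx},
            )
            raw.append(_mech_to_statement(extracted, onto, [ev]))
        truth_rows.append({"mechanism": mech_idx,
                           "stmt_type": mech.stmt_type,
                           "n_mentions": int(n_mentions)})
    truth = {"mechanisms": mechanisms,
             "mention_counts": mention_counts,
             "table": pd.DataFrame(truth_rows),
             "ontology": onto}
    return raw, truth


def ground_truth_curations(corpus: AssembledCorpus,
                           curator: str = "oracle",
                           ) -> list[CurationRecord]:
    """Curation records read off the generator's ground-truth labels."""
    records = []
    for key, stmt in corpus.statements.items():
        for ev in stmt.evidence:
            label = ("correct" if ev.annotations.get("correct", False)
                     else "incorrect")
            records.append(CurationRecord(statement_key=key,
                                          evidence_key=ev.identity_key(),
                                          label=label, curator=curator))
    return records


def generate_curation_dataset(corpus: AssembledCorpus, source: str,
                              strata: Sequence[int] = range(1, 11),
                              per_stratum: int = 10,
                              seed: int = 0) -> list[CurationRecord]:
    """Stratified curation sample: Statements drawn with replacement per
    (source, mention-count) stratum, labels taken from ground truth."""
    rng = np.random.default_rng(seed)
    by_count: dict[int, list[str]] = {k: [] for k in strata}
    for key in corpus.statements:
        k = corpus.evidence_counts(key).direct.get(source, 0)
        if k in by_count:
            by_count[k].append(key)
    records = []
    for k, population in by_count.items():
        if not population:
            continue
        sampled = rng.choice(sorted(population), size=per_stratum,
                             replace=True)
        for key in sampled:
            stmt = corpus.statements[str(key)]
            for ev in stmt.evidence:
                if ev.source_api != source:
                    continue
                label = ("correct" if ev.annotations.get("correct", False)
                         else "incorrect")
                records.append(CurationRecord(
                    statement_key=str(key), evidence_key=ev.identity_key(),
                    label=label, curator="oracle"))
    return records


def generate_dependency_matrices(config: SimulationConfig,
                                 network_edges: Optional[Sequence[tuple]] =
                                 None,
                                 ) -> tuple[pd.DataFrame, pd.DataFrame,
                                            list[tuple[str, str]]]:
    """Two replicate gene-effect matrices with planted correlated pairs.

    Planted pairs share a latent effect profile with correlation
    ``planted_rho`` (within each replicate); all other genes are
    independent noise.  When network edges are supplied, a configured
    fraction of planted pairs is aligned with them (so the network prior
    can explain the codependencies); replicates use independent noise and
    independent latents.
    """
    rng = np.random.default_rng(config.seed + 7)
    genes = [f"GENE{i}" for i in range(config.n_genes)]
    planted: list[tuple[str, str]] = []
    used: set[str] = set()
    if network_edges:
        n_aligned = int(round(config.n_planted_pairs
                              * config.network_aligned_fraction))
        for u, v in network_edges:
            if len(planted) >= n_aligned:
                break
            if u in genes and v in genes and u not in used and v not in used:
                planted.append((u, v))
                used.update((u, v))
    free = [g for g in genes if g not in used]
    rng.shuffle(free)
    while len(planted) < config.n_planted_pairs and len(free) >= 2:
        planted.append((free.pop(), free.pop()))

    rho = config.planted_rho
    samples = [f"CL{j}" for j in range(config.n_samples)]
    mats = []
    for _ in range(2):
        data = rng.normal(0.0, config.noise_sd,
                          size=(config.n_genes, config.n_samples))
        frame = pd.DataFrame(data, index=genes, columns=samples)
        for a, b in planted:
            latent = rng.normal(0.0, 1.0, config.n_samples)
            for g in (a, b):
                noise = rng.normal(0.0, 1.0, config.n_samples)
                frame.loc[g] = config.noise_sd * (
                    np.sqrt(rho) * latent + np.sqrt(1 - rho) * noise)
        mats.append(frame)
    return mats[0], mats[1], planted


# ---------------------------------------------------------------------------
# Hand-built refinement-ladder fixture
# ---------------------------------------------------------------------------

def phosphorylation_chain_fixture() -> tuple[dict[str, Statement],
                                             OntologyGraph]:
    """Nine phosphorylation Statements forming a single refinement ladder.

    Re-encodes, over a toy ontology, a kinase/substrate hierarchy in which
    the same mechanism is described at nine levels of specificity — from
    "the substrate family is phosphorylated" down to "a doubly
    phosphorylated specific kinase phosphorylates the specific substrate
    on a named site".  The refinement graph over these Statements has a
    longest path of eight edges, and exactly one Statement (the most
    specific) is top-level.
    """
    onto = OntologyGraph()
    kin_fam = onto.add_node("FPLX", "RSK", "RSK")
    kin_sub = onto.add_node("FPLX", "P90RSK", "P90RSK")
    kin = onto.add_node("HGNC", "10430", "RPS6KA1")
    sub_fam = onto.add_node("FPLX", "CREB", "CREB")
    sub = onto.add_node("HGNC", "1187", "CREB1")
    onto.add_edge(kin_sub, kin_fam, "isa")
    onto.add_edge(kin, kin_sub, "isa")
    onto.add_edge(sub, sub_fam, "isa")
    onto.validate()

    def agent(node, mods=()):
        data = onto.graph.nodes[node]
        return Agent(name=data["name"],
                     groundings=frozenset(
                         [Grounding(data["namespace"], data["identifier"])]),
                     mods=tuple(mods))

    def ev(i):
        return [Evidence(source_api="reader_a", pmid=str(i),
                         source_id=f"fx{i}")]

    p = ModCondition("phosphorylation", "S", "221")
    p2 = ModCondition("phosphorylation", "T", "573")
    ladder = [
        Statement("Phosphorylation", [None, agent(sub_fam)],
                  evidence=ev(1)),
        Statement("Phosphorylation", [None, agent(sub)], evidence=ev(2)),
        Statement("Phosphorylation", [None, agent(sub)], residue="S",
                  evidence=ev(3)),
        Statement("Phosphorylation", [None, agent(sub)], residue="S",
                  position="133", evidence=ev(4)),
        Statement("Phosphorylation", [agent(kin_fam), agent(sub)],
                  residue="S", position="133", evidence=ev(5)),
        Statement("Phosphorylation", [agent(kin_sub), agent(sub)],
                  residue="S", position="133", evidence=ev(6)),
        Statement("Phosphorylation", [agent(kin), agent(sub)],
                  residue="S", position="133", evidence=ev(7)),
        Statement("Phosphorylation", [agent(kin, [p]), agent(sub)],
                  residue="S", position="133", evidence=ev(8)),
        Statement("Phosphorylation", [agent(kin, [p, p2]), agent(sub)],
                  residue="S", position="133", evidence=ev(9)),
    ]
    return {matches_key(s): s for s in ladder}, onto
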