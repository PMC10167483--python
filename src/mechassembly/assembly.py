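"""Statement assembly: duplicate combination and refinement hierarchies.

After normalization, raw Statements are grouped by equivalence key and
collapsed into unique Statements with merged evidence.  Unique Statements
are then organized into a refinement graph: a directed acyclic graph whose
edges point from more specific to less specific Statements.  A Statement
refines another when it carries all of its information plus additional
specificity — a more specific entity (gene vs. family), an explicit
modification site, an extra bound condition, and so on.

The refinement graph supports two downstream uses: filtering an assembled
corpus to its most specific ("top-level") Statements, and pooling evidence
downward — the *extended* evidence of a Statement is the union of its own
evidence and that of every Statement refining it, recursively.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .ontology import OntologyGraph
from .statements import (
    Agent,
    DEFAULT_NAMESPACE_PRIORITY,
    Evidence,
    Statement,
    canonical_grounding,
    matches_key,
)

logger = logging.getLogger(__name__)

__all__ = [
    "combine_duplicates",
    "refines",
    "build_refinement_graph",
    "build_refinement_graph_bruteforce",
    "extended_evidence",
    "filter_top_level",
    "flatten_to_network",
    "SourceEvidenceCounts",
    "AssembledCorpus",
]

# Element-level comparison outcomes.  EQUAL and REFINES compose into
# statement-level refinement; a single GENERALIZES or INCOMPARABLE element
# blocks it (if one element is more specific but another less specific,
# there is no refinement relationship at the statement level).
EQUAL = "equal"
REFINES = "refines"
GENERALIZES = "generalizes"
INCOMPARABLE = "incomparable"


def combine_duplicates(
    stmts: Iterable[Statement],
    namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
) -> dict[str, Statement]:
    """Group Statements by equivalence key and merge their evidence.

    Returns a mapping of equivalence key to a single representative
    Statement per key whose evidence is the concatenation of the group's
    evidence, deduplicated by evidence identity key.  Idempotent.
    """
    groups: dict[str, Statement] = {}
    seen_ev: dict[str, set] = {}
    for stmt in stmts:
        key = matches_key(stmt, namespace_priority)
        if key not in groups:
            rep = Statement(stmt_type=stmt.stmt_type,
                            agents=list(stmt.agents),
                            residue=stmt.residue, position=stmt.position,
                            evidence=[], belief=None)
            groups[key] = rep
            seen_ev[key] = set()
        rep = groups[key]
        for ev in stmt.evidence:
            ik = ev.identity_key()
            if ik not in seen_ev[key]:
                seen_ev[key].add(ik)
                rep.evidence.append(ev)
    return groups


# ---------------------------------------------------------------------------
# Element-level refinement comparisons
# ---------------------------------------------------------------------------

def _invert(rel: str) -> str:
    if rel == REFINES:
        return GENERALIZES
    if rel == GENERALIZES:
        return REFINES
    return rel


def _merge(rels: Iterable[str]) -> str:
    out = EQUAL
    for rel in rels:
        if rel == INCOMPARABLE:
            return INCOMPARABLE
        if rel == EQUAL:
            continue
        if out == EQUAL:
            out = rel
        elif out != rel:
            # mixing refines and generalizes across elements
            return INCOMPARABLE
    return out


def _compare_entities(a: Agent, b: Agent, onto: OntologyGraph,
                      priority: Sequence[str]) -> str:
    ca = canonical_grounding(a, priority)
    cb = canonical_grounding(b, priority)
    if ca == cb:
        return EQUAL
    if onto.entity_refines(ca, cb):
        return REFINES
    if onto.entity_refines(cb, ca):
        return GENERALIZES
    return INCOMPARABLE


def _mod_covers(specific, generic) -> bool:
    """Does a specific ModCondition carry all information of a generic one?"""
    return (specific.mod_type == generic.mod_type
            and specific.is_modified == generic.is_modified
            and (generic.residue is None or generic.residue == specific.residue)
            and (generic.position is None
                 or generic.position == specific.position))


def _covers_injective(a_items, b_items, covers) -> bool:
    """Greedy injective matching: every item of b covered by a distinct
    item of a."""
    if len(b_items) > len(a_items):
        return False
    available = list(a_items)
    for b in b_items:
        for i, a in enumerate(available):
            if covers(a, b):
                available.pop(i)
                break
        else:
            return False
    return True


def _compare_collections(a_items, b_items, covers, keyfn) -> str:
    if sorted(map(keyfn, a_items)) == sorted(map(keyfn, b_items)):
        return EQUAL
    a_covers_b = _covers_injective(a_items, b_items, covers)
    b_covers_a = _covers_injective(b_items, a_items, covers)
    if a_covers_b and not b_covers_a:
        return REFINES
    if b_covers_a and not a_covers_b:
        return GENERALIZES
    return INCOMPARABLE


def _compare_optional(a_val, b_val) -> str:
    """Optional scalar with no internal hierarchy: present refines absent."""
    if a_val == b_val:
        return EQUAL
    if b_val is None:
        return REFINES
    if a_val is None:
        return GENERALIZES
    return INCOMPARABLE


def _compare_agents(a: Optional[Agent], b: Optional[Agent],
                    onto: OntologyGraph, priority: Sequence[str]) -> str:
    if a is None and b is None:
        return EQUAL
    if b is None:
        # an unspecified slot is the least specific element
        return REFINES
    if a is None:
        return GENERALIZES
    rels = [_compare_entities(a, b, onto, priority)]
    rels.append(_compare_collections(
        a.mods, b.mods, _mod_covers, lambda m: m.key()))
    rels.append(_compare_collections(
        a.mutations, b.mutations, lambda x, y: x == y, lambda m: m.key()))
    # Activity and location have no hierarchy here: equal or present-vs-absent.
    if a.activity == b.activity:
        rels.append(EQUAL)
    elif b.activity is None:
        rels.append(REFINES)
    elif a.activity is None:
        rels.append(GENERALIZES)
    else:
        rels.append(INCOMPARABLE)
    rels.append(_compare_optional(a.location, b.location))

    # Bound conditions compare recursively through the entity hierarchy
    # (bound-to-member refines bound-to-family).
    def bc_covers(bca, bcb):
        return (bca.is_bound == bcb.is_bound
                and _compare_entities(bca.agent, bcb.agent, onto, priority)
                in (EQUAL, REFINES))

    def bc_key(bc):
        return (canonical_grounding(bc.agent, priority), bc.is_bound)

    rels.append(_compare_collections(a.bound_conditions, b.bound_conditions,
                                     bc_covers, bc_key))
    return _merge(rels)


def _compare_unordered(a_agents, b_agents, onto, priority) -> str:
    """Relation between unordered member lists (Complex) via backtracking
    over member bijections."""
    if len(a_agents) != len(b_agents):
        return INCOMPARABLE

    def exists_mapping(xs, ys, allowed):
        # is there a bijection xs->ys with pairwise relation in `allowed`?
        if not xs:
            return True
        x = xs[0]
        for i, y in enumerate(ys):
            if _compare_agents(x, y, onto, priority) in allowed:
                if exists_mapping(xs[1:], ys[:i] + ys[i + 1:], allowed):
                    return True
        return False

    a_l, b_l = list(a_agents), list(b_agents)
    eq = exists_mapping(a_l, b_l, (EQUAL,))
    if eq:
        return EQUAL
    if exists_mapping(a_l, b_l, (EQUAL, REFINES)):
        return REFINES
    if exists_mapping(b_l, a_l, (EQUAL, REFINES)):
        return GENERALIZES
    return INCOMPARABLE


def refines(a: Statement, b: Statement, onto: OntologyGraph,
            namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
            ) -> bool:
    """True iff Statement ``a`` strictly refines Statement ``b``.

    Requires equal statement types; every element of ``a`` (agents by slot,
    agent states, residue/position) must be equal to or refine the
    corresponding element of ``b``, with at least one element strictly
    refining, and no element of ``b`` strictly refining its counterpart in
    ``a``.  Strict: a Statement never refines itself.
    """
    if a.stmt_type != b.stmt_type:
        return False
    rels = []
    if a.is_unordered:
        rels.append(_compare_unordered(a.agents, b.agents, onto,
                                       namespace_priority))
    else:
        for ag_a, ag_b in zip(a.agents, b.agents):
            rels.append(_compare_agents(ag_a, ag_b, onto, namespace_priority))
    rels.append(_compare_optional(a.residue, b.residue))
    rels.append(_compare_optional(a.position, b.position))
    return _merge(rels) == REFINES


# ---------------------------------------------------------------------------
# Refinement graph
# ---------------------------------------------------------------------------

def _slot_closure_ids(agent: Optional[Agent], onto: OntologyGraph,
                      priority: Sequence[str]) -> set:
    """Canonical ids that a less-specific statement may hold at this slot:
    the agent's own id, its entity ancestors, and the unspecified marker."""
    if agent is None:
        return {None}
    cid = canonical_grounding(agent, priority)
    return {cid} | onto.ancestor_closure(cid) | {None}


def build_refinement_graph(
    unique_stmts: dict[str, Statement],
    onto: OntologyGraph,
    namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
) -> nx.DiGraph:
    """Directed refinement graph over unique Statements.

    Nodes are equivalence keys; an edge (a, b) means Statement a refines
    Statement b.  Candidate pairs are generated from an index keyed by
    (statement type, slot, canonical entity id), so that only Statements
    sharing compatible entities in every slot are compared — near-linear
    in the number of matching pairs rather than quadratic in corpus size.
    Unordered (Complex) Statements are compared within their type group.
    """
    graph = nx.DiGraph()
    graph.add_nodes_from(unique_stmts)

    # index[(stmt_type, slot, canonical_id_or_None)] -> statement keys
    index: dict[tuple, set[str]] = {}
    unordered_groups: dict[tuple, list[str]] = {}
    for key, stmt in unique_stmts.items():
        if stmt.is_unordered:
            unordered_groups.setdefault(
                (stmt.stmt_type, len(stmt.agents)), []).append(key)
            continue
        for slot, agent in enumerate(stmt.agents):
            cid = (None if agent is None
                   else canonical_grounding(agent, namespace_priority))
            index.setdefault((stmt.stmt_type, slot, cid), set()).add(key)

    for key, stmt in unique_stmts.items():
        if stmt.is_unordered:
            continue
        candidates: Optional[set[str]] = None
        for slot, agent in enumerate(stmt.agents):
            ids = _slot_closure_ids(agent, onto, namespace_priority)
            slot_cands: set[str] = set()
            for cid in ids:
                slot_cands |= index.get((stmt.stmt_type, slot, cid), set())
            candidates = (slot_cands if candidates is None
                          else candidates & slot_cands)
            if not candidates:
                break
        for other in candidates or ():
            if other != key and refines(stmt, unique_stmts[other], onto,
                                        namespace_priority):
                graph.add_edge(key, other)

    for _, keys in unordered_groups.items():
        for ka, kb in itertools.permutations(keys, 2):
            if refines(unique_stmts[ka], unique_stmts[kb], onto,
                       namespace_priority):
                graph.add_edge(ka, kb)

    if not nx.is_directed_acyclic_graph(graph):
        raise RuntimeError("refinement graph contains a cycle; the entity "
                           "ontology is inconsistent")
    return graph


def build_refinement_graph_bruteforce(
    unique_stmts: dict[str, Statement],
    onto: OntologyGraph,
    namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
) -> nx.DiGraph:
    """All-pairs O(n^2) reference construction (oracle for testing)."""
    graph = nx.DiGraph()
    graph.add_nodes_from(unique_stmts)
    for ka, kb in itertools.permutations(unique_stmts, 2):
        if refines(unique_stmts[ka], unique_stmts[kb], onto,
                   namespace_priority):
            graph.add_edge(ka, kb)
    return graph


# ---------------------------------------------------------------------------
# Extended evidence and corpus container
# ---------------------------------------------------------------------------

@dataclass
class SourceEvidenceCounts:
    """Per-source mention counts for one Statement.

    ``direct`` counts the Statement's own evidence; ``extended`` pools in
    evidence from every Statement refining it (componentwise >= direct).
    PMID counts are unique publications per scope.
    """

    direct: dict[str, int] = field(default_factory=dict)
    extended: dict[str, int] = field(default_factory=dict)
    direct_pmids: int = 0
    extended_pmids: int = 0

    def total(self, scope: str = "direct") -> int:
        return sum(getattr(self, scope).values())


def _count_by_source(evs: Iterable[Evidence]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for ev in evs:
        counts[ev.source_api] = counts.get(ev.source_api, 0) + 1
    return counts


def extended_evidence(stmt_key: str, unique_stmts: dict[str, Statement],
                      refinement_graph: nx.DiGraph) -> list[Evidence]:
    """Union of a Statement's own evidence with that of all Statements
    refining it (transitively), deduplicated by evidence identity."""
    pool: dict[tuple, Evidence] = {}
    stack = [stmt_key]
    visited = set()
    while stack:
        key = stack.pop()
        if key in visited:
            continue
        visited.add(key)
        for ev in unique_stmts[key].evidence:
            pool.setdefault(ev.identity_key(), ev)
        stack.extend(refinement_graph.predecessors(key))
    return list(pool.values())


class AssembledCorpus:
    """Unique Statements, their refinement graph, and evidence counts."""

    def __init__(self, unique_stmts: dict[str, Statement],
                 refinement_graph: nx.DiGraph,
                 ontology: Optional[OntologyGraph] = None,
                 namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY):
        self.statements = unique_stmts
        self.refinement_graph = refinement_graph
        self.ontology = ontology
        self.namespace_priority = tuple(namespace_priority)
        self._extended_cache: Optional[dict[str, list[Evidence]]] = None

    @classmethod
    def assemble(cls, stmts: Iterable[Statement], ontology: OntologyGraph,
                 namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
                 ) -> "AssembledCorpus":
        unique = combine_duplicates(stmts, namespace_priority)
        graph = build_refinement_graph(unique, ontology, namespace_priority)
        return cls(unique, graph, ontology, namespace_priority)

    def __len__(self) -> int:
        return len(self.statements)

    def _extended(self) -> dict[str, list[Evidence]]:
        # One reverse-topological pass: evidence pools flow from specific
        # Statements (graph sources) to the generic ones they refine.
        if self._extended_cache is None:
            pools: dict[str, dict[tuple, Evidence]] = {}
            for key in nx.topological_sort(self.refinement_graph):
                pool: dict[tuple, Evidence] = {}
                for ev in self.statements[key].evidence:
                    pool.setdefault(ev.identity_key(), ev)
                for pred in self.refinement_graph.predecessors(key):
                    pool.update(pools[pred])
                pools[key] = pool
            self._extended_cache = {k: list(v.values())
                                    for k, v in pools.items()}
        return self._extended_cache

    def evidence_counts(self, key: str) -> SourceEvidenceCounts:
        direct_evs = self.statements[key].evidence
        ext_evs = self._extended()[key]
        return SourceEvidenceCounts(
            direct=_count_by_source(direct_evs),
            extended=_count_by_source(ext_evs),
            direct_pmids=len({ev.pmid for ev in direct_evs
                              if ev.pmid is not None}),
            extended_pmids=len({ev.pmid for ev in ext_evs
                                if ev.pmid is not None}),
        )

    def extended_evidence(self, key: str) -> list[Evidence]:
        return list(self._extended()[key])

    def top_level_keys(self) -> list[str]:
        """Keys of Statements not refined by any other (most specific)."""
        return [k for k in self.statements
                if self.refinement_graph.in_degree(k) == 0]


def filter_top_level(unique_stmts: dict[str, Statement],
                     refinement_graph: nx.DiGraph) -> dict[str, Statement]:
    """Keep only Statements with no incoming refinement edges."""
    return {k: s for k, s in unique_stmts.items()
            if refinement_graph.in_degree(k) == 0}


def flatten_to_network(unique_stmts: dict[str, Statement],
                       beliefs: Optional[dict[str, float]] = None,
                       ) -> list[dict]:
    """Flatten Statements to a directed typed edge list.

    One edge per (subject name, object name, statement type); Statements of
    the same type between the same endpoints (e.g. at different levels of
    site specificity) are merged, summing evidence counts and keeping the
    maximum belief.  Complex members yield a symmetric pair of directed
    edges flagged undirected for every unordered member pair.
    """
    edges: dict[tuple, dict] = {}

    def add(u: str, v: str, typ: str, n_ev: int, belief: Optional[float],
            sources: set[str], undirected: bool):
        key = (u, v, typ)
        entry = edges.setdefault(key, {
            "subject": u, "object": v, "type": typ, "n_evidence": 0,
            "belief": None, "sources": set(), "undirected": undirected})
        entry["n_evidence"] += n_ev
        entry["sources"] |= sources
        if belief is not None:
            entry["belief"] = (belief if entry["belief"] is None
                               else max(entry["belief"], belief))

    for key, stmt in unique_stmts.items():
        belief = (beliefs or {}).get(key, stmt.belief)
        n_ev = len(stmt.evidence)
        sources = {ev.source_api for ev in stmt.evidence}
        if stmt.is_unordered:
            for a, b in itertools.combinations(stmt.agents, 2):
                add(a.name, b.name, stmt.stmt_type, n_ev, belief, sources,
                    True)
                add(b.name, a.name, stmt.stmt_type, n_ev, belief, sources,
                    True)
        else:
            named = [a for a in stmt.agents if a is not None]
            if len(named) < 2:
                continue  # single-agent statements carry no edge
            subj, obj = stmt.agents[0], stmt.agents[-1]
            if subj is None or obj is None:
                continue
            add(subj.name, obj.name, stmt.stmt_type, n_ev, belief, sources,
                False)
    out = []
    for entry in edges.values():
        entry["sources"] = sorted(entry["sources"])
        out.append(entry)
    return out
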