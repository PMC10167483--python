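"""Entity ontology graph: grounding standardization and entity hierarchies.

The ontology is a directed graph whose nodes are (namespace, identifier)
entries with a standard name, connected by three edge types:

- ``xref``: the two nodes (usually in different namespaces) denote the same
  entity; traversing directed xref paths yields all equivalent identifiers.
- ``isa``: the source is one of the set of entities the target represents
  (gene -> family).
- ``partof``: the source is a component of the complex the target represents.

isa/partof edges drive entity-level refinement: a gene-level Agent refines
a family-level Agent whose node is reachable via these edges.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from .statements import (
    Agent,
    DEFAULT_NAMESPACE_PRIORITY,
    Grounding,
    canonical_grounding,
)

__all__ = [
    "OntologyGraph",
    "GroundingMap",
    "load_ontology_tsv",
    "load_grounding_map_tsv",
    "standardize_grounding",
    "standardize_agent",
    "apply_grounding_overrides",
]

_HIERARCHY_RELS = ("isa", "partof")


class OntologyGraph:
    """Typed ontology graph over namespaced entity nodes.

    Nodes are keyed ``"NS:ID"`` and carry ``namespace``, ``identifier``
    and ``name`` attributes.  The isa/partof subgraph must be acyclic.
    """

    def __init__(self, refinement_rels: Sequence[str] = _HIERARCHY_RELS):
        self.graph = nx.DiGraph()
        # Which relations participate in entity refinement; the default is
        # both isa and partof, configurable down to isa only.
        self.refinement_rels = tuple(refinement_rels)

    def add_node(self, namespace: str, identifier: str, name: str) -> str:
        key = f"{namespace}:{identifier}"
        self.graph.add_node(key, namespace=namespace, identifier=identifier,
                            name=name)
        return key

    def add_edge(self, src: str, dst: str, rel: str) -> None:
        if rel not in ("isa", "partof", "xref"):
            raise ValueError(f"unknown ontology relation {rel!r}")
        if rel == "xref":
            src_ns = self.graph.nodes[src]["namespace"]
            dst_ns = self.graph.nodes[dst]["namespace"]
            if src_ns == dst_ns:
                raise ValueError(
                    f"xref edge {src} -> {dst} connects nodes with the same "
                    f"namespace {src_ns}")
        self.graph.add_edge(src, dst, rel=rel)

    def validate(self) -> None:
        """Check invariants: acyclic hierarchy, named nodes."""
        hier = self._subgraph(self.refinement_rels)
        if not nx.is_directed_acyclic_graph(hier):
            raise ValueError("isa/partof subgraph contains a cycle")
        for node, data in self.graph.nodes(data=True):
            if not data.get("name"):
                raise ValueError(f"ontology node {node} has no name")

    def _subgraph(self, rels: Sequence[str]) -> nx.DiGraph:
        return self.graph.edge_subgraph(
            [(u, v) for u, v, r in self.graph.edges(data="rel") if r in rels]
        ) if self.graph.edges else nx.DiGraph()

    def __contains__(self, key: str) -> bool:
        return key in self.graph

    def name_of(self, key: str) -> Optional[str]:
        if key in self.graph:
            return self.graph.nodes[key]["name"]
        return None

    def node_by_name(self, name: str) -> Optional[str]:
        for key, data in self.graph.nodes(data=True):
            if data.get("name") == name:
                return key
        return None

    # -- traversals ---------------------------------------------------------

    def xref_closure(self, key: str) -> set[str]:
        """All nodes reachable from ``key`` via directed xref paths.

        Namespace collisions among reached nodes are deduplicated by
        keeping the first identifier reached in breadth-first order.
        """
        if key not in self.graph:
            return set()
        seen_ns = {self.graph.nodes[key]["namespace"]}
        out: set[str] = set()
        visited = {key}
        queue = deque([key])
        while queue:
            node = queue.popleft()
            for _, nbr, rel in self.graph.out_edges(node, data="rel"):
                if rel != "xref" or nbr in visited:
                    continue
                visited.add(nbr)
                ns = self.graph.nodes[nbr]["namespace"]
                if ns not in seen_ns:
                    seen_ns.add(ns)
                    out.add(nbr)
                queue.append(nbr)
        return out

    def ancestor_closure(self, key: str) -> set[str]:
        """All nodes reachable via directed isa/partof paths, excluding self."""
        if key not in self.graph:
            return set()
        out: set[str] = set()
        stack = [key]
        while stack:
            node = stack.pop()
            for _, nbr, rel in self.graph.out_edges(node, data="rel"):
                if rel in self.refinement_rels and nbr not in out:
                    out.add(nbr)
                    stack.append(nbr)
        return out

    def entity_refines(self, a: str, b: str) -> bool:
        """True iff canonical grounding ``a`` equals or specializes ``b``.

        Reflexive on equality; otherwise requires ``b`` to lie in the
        isa/partof ancestor closure of ``a`` (direction matters).
        """
        if a == b:
            return True
        return b in self.ancestor_closure(a)


def load_ontology_tsv(path_or_lines,
                      refinement_rels: Sequence[str] = _HIERARCHY_RELS,
                      ) -> OntologyGraph:
    """Load an ontology from a TSV edge list.

    Columns: src_ns, src_id, src_name, rel, dst_ns, dst_id, dst_name.
    """
    if isinstance(path_or_lines, str):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    onto = OntologyGraph(refinement_rels=refinement_rels)
    for i, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 7:
            raise ValueError(f"ontology TSV line {i}: expected 7 fields, "
                             f"got {len(fields)}")
        src_ns, src_id, src_name, rel, dst_ns, dst_id, dst_name = fields
        src = onto.add_node(src_ns, src_id, src_name)
        dst = onto.add_node(dst_ns, dst_id, dst_name)
        onto.add_edge(src, dst, rel)
    onto.validate()
    return onto


def standardize_grounding(
    groundings: Iterable[Grounding],
    onto: OntologyGraph,
    namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
) -> tuple[frozenset[Grounding], Optional[str]]:
    """Extend groundings with their xref closures and pick a standard name.

    Returns the input groundings plus all identifiers reachable via directed
    xref paths from any of them, and the name of the node chosen canonical
    under the namespace priority.  Groundings absent from the graph pass
    through unchanged (no error) and contribute no name.

    Idempotent: the xref closure of a closure adds nothing new.
    """
    expanded: set[Grounding] = set(groundings)
    for g in list(expanded):
        for key in onto.xref_closure(str(g)):
            data = onto.graph.nodes[key]
            expanded.add(Grounding(data["namespace"], data["identifier"]))
    probe = Agent(name="", groundings=frozenset(expanded))
    canonical = canonical_grounding(probe, namespace_priority)
    name = onto.name_of(canonical)
    return frozenset(expanded), name


def standardize_agent(
    agent: Agent,
    onto: OntologyGraph,
    namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
) -> Agent:
    """Return a copy of ``agent`` with standardized groundings and name."""
    groundings, name = standardize_grounding(agent.groundings, onto,
                                             namespace_priority)
    bound = tuple(
        type(bc)(agent=standardize_agent(bc.agent, onto, namespace_priority),
                 is_bound=bc.is_bound)
        for bc in agent.bound_conditions)
    return Agent(name=name or agent.name, groundings=groundings,
                 mods=agent.mods, mutations=agent.mutations,
                 activity=agent.activity, bound_conditions=bound,
                 location=agent.location)


@dataclass
class GroundingMap:
    """Table-driven grounding overrides keyed by raw entity text.

    Maps a raw text span either to an explicit grounding or to
    ``None`` (meaning: force the entity to be ungrounded).  This is the
    package's only disambiguation mechanism; a context-based predictor can
    be plugged in by subclassing and overriding :meth:`lookup`.
    """

    entries: dict[str, Optional[Grounding]]

    def lookup(self, raw_text: str) -> tuple[bool, Optional[Grounding]]:
        if raw_text in self.entries:
            return True, self.entries[raw_text]
        return False, None


def load_grounding_map_tsv(path_or_lines) -> GroundingMap:
    """Load override table: columns raw_text, namespace, identifier.

    A row whose namespace column is the literal ``ungrounded`` empties the
    agent's groundings.
    """
    if isinstance(path_or_lines, str):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    entries: dict[str, Optional[Grounding]] = {}
    for i, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 2 and fields[1] == "ungrounded":
            entries[fields[0]] = None
        elif len(fields) == 3:
            if not fields[1]:
                raise ValueError(f"grounding map line {i}: empty namespace")
            entries[fields[0]] = Grounding(fields[1], fields[2])
        else:
            raise ValueError(f"grounding map line {i}: expected 2 or 3 "
                             f"fields, got {len(fields)}")
    return GroundingMap(entries)


def apply_grounding_overrides(
    agent: Agent,
    raw_text: Optional[str],
    gmap: GroundingMap,
    onto: OntologyGraph,
    namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
) -> Agent:
    """Apply the override table to one agent, then standardize.

    If ``raw_text`` has an entry, the agent's groundings are replaced by the
    mapped grounding (or emptied for an explicit "ungrounded" row); the
    agent then goes through ontology standardization either way.
    """
    found, mapped = (gmap.lookup(raw_text) if raw_text is not None
                     else (False, None))
    if found:
        groundings = frozenset() if mapped is None else frozenset([mapped])
        agent = Agent(name=agent.name, groundings=groundings,
                      mods=agent.mods, mutations=agent.mutations,
                      activity=agent.activity,
                      bound_conditions=agent.bound_conditions,
                      location=agent.location)
    return standardize_agent(agent, onto, namespace_priority)
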