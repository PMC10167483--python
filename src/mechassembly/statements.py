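"""Domain model for mechanistic Statements.

A Statement is a typed, normalized assertion about a molecular mechanism
(e.g. a phosphorylation, a complex formation, an activation) extracted from
literature or a curated database.  Each Statement takes one or more Agent
arguments (biological entities with groundings and molecular state) and
carries a list of Evidence objects recording where each supporting mention
came from.

Two Statements are *duplicates* when they assert the same mechanism at the
same level of detail; duplicates are detected by comparing canonical
equivalence keys (:func:`matches_key`) rather than by pairwise comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Grounding",
    "ModCondition",
    "MutCondition",
    "ActivityCondition",
    "BoundCondition",
    "Agent",
    "Evidence",
    "Statement",
    "CurationRecord",
    "InvalidStatementError",
    "DEFAULT_NAMESPACE_PRIORITY",
    "MODIFICATION_TYPES",
    "STATEMENT_TYPES",
    "register_statement_type",
    "matches_key",
    "agent_key",
    "canonical_grounding",
    "to_json",
    "from_json",
    "stmt_to_dict",
    "stmt_from_dict",
    "render_english",
    "resolve_curations",
]

#: Priority order used to pick a single canonical grounding for an Agent.
#: Families (FPLX) out-rank member-level namespaces so that family-level
#: Agents canonicalize stably; a plain text name is the final fallback.
DEFAULT_NAMESPACE_PRIORITY: tuple[str, ...] = (
    "FPLX", "HGNC", "UP", "CHEBI", "GO", "MESH",
)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Modification statement types (take an optional residue/position argument).
MODIFICATION_TYPES: set[str] = {
    "Phosphorylation", "Dephosphorylation",
    "Ubiquitination", "Deubiquitination",
    "Acetylation", "Deacetylation",
    "Methylation", "Demethylation",
    "Sumoylation", "Hydroxylation", "Glycosylation",
}

#: Registry of statement types -> number of agent slots (None = variable,
#: at least two; used by Complex).  Extensible via register_statement_type.
STATEMENT_TYPES: dict[str, Optional[int]] = {
    **{t: 2 for t in MODIFICATION_TYPES},
    "Activation": 2,
    "Inhibition": 2,
    "IncreaseAmount": 2,
    "DecreaseAmount": 2,
    "Complex": None,
    "ActiveForm": 1,
}


def register_statement_type(name: str, arity: Optional[int],
                            is_modification: bool = False) -> None:
    """Register an additional Statement type with the given agent arity."""
    STATEMENT_TYPES[name] = arity
    if is_modification:
        MODIFICATION_TYPES.add(name)


class InvalidStatementError(ValueError):
    """Raised when Statement content or JSON violates the schema.

    The ``field`` attribute names the offending field.
    """

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True, order=True)
class Grounding:
    """A (namespace, identifier) pair grounding an entity, e.g. HGNC:6840."""

    namespace: str
    identifier: str

    def __post_init__(self):
        if not self.namespace:
            raise InvalidStatementError("namespace", "must be non-empty")

    def __str__(self) -> str:
        return f"{self.namespace}:{self.identifier}"


@dataclass(frozen=True)
class ModCondition:
    """A post-translational modification state on an Agent."""

    mod_type: str
    residue: Optional[str] = None
    position: Optional[str] = None
    is_modified: bool = True

    def __post_init__(self):
        if self.residue is not None and self.residue not in AMINO_ACIDS:
            raise InvalidStatementError(
                "residue", f"{self.residue!r} is not a one-letter amino acid")
        if self.position is not None:
            if not (self.position.isdigit() and int(self.position) > 0):
                raise InvalidStatementError(
                    "position",
                    f"{self.position!r} does not parse as a positive integer")

    def key(self) -> tuple:
        return (self.mod_type, self.residue or "", self.position or "",
                self.is_modified)


@dataclass(frozen=True, order=True)
class MutCondition:
    """An amino-acid substitution, e.g. V600E."""

    from_residue: str
    position: str
    to_residue: str

    def key(self) -> tuple:
        return (self.from_residue, self.position, self.to_residue)


@dataclass(frozen=True)
class ActivityCondition:
    """A molecular activity state (e.g. kinase activity, active/inactive)."""

    activity_type: str
    is_active: bool = True

    def key(self) -> tuple:
        return (self.activity_type, self.is_active)


@dataclass(frozen=True)
class BoundCondition:
    """An Agent bound (or explicitly not bound) to another Agent.

    Bound agents nest at most one level: an Agent inside a BoundCondition
    must itself carry no bound conditions.
    """

    agent: "Agent"
    is_bound: bool = True


@dataclass
class Agent:
    """A biological entity participating in a Statement.

    An Agent with an empty grounding set is *ungrounded*: only its display
    name identifies it, which is unreliable and is filtered out early in
    assembly pipelines.
    """

    name: str
    groundings: frozenset[Grounding] = frozenset()
    mods: tuple[ModCondition, ...] = ()
    mutations: tuple[MutCondition, ...] = ()
    activity: Optional[ActivityCondition] = None
    bound_conditions: tuple[BoundCondition, ...] = ()
    location: Optional[str] = None

    def __post_init__(self):
        self.groundings = frozenset(self.groundings)
        self.mods = tuple(self.mods)
        self.mutations = tuple(self.mutations)
        self.bound_conditions = tuple(self.bound_conditions)
        namespaces = [g.namespace for g in self.groundings]
        if len(set(namespaces)) != len(namespaces):
            # (namespace, identifier) pairs are unique by frozenset; repeated
            # namespaces with different identifiers are allowed only after
            # ontology standardization dedupes them, so just log here.
            logger.debug("Agent %s has repeated namespaces in grounding",
                         self.name)
        for bc in self.bound_conditions:
            if bc.agent.bound_conditions:
                raise InvalidStatementError(
                    "bound_conditions", "bound Agents cannot themselves "
                    "carry bound conditions (max one level of nesting)")

    @property
    def is_grounded(self) -> bool:
        return bool(self.groundings)


def canonical_grounding(
    agent: Agent,
    namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
) -> str:
    """Pick a single canonical grounding string for an Agent.

    The first namespace in the priority order that the Agent is grounded in
    wins; any remaining namespaces are tried in sorted order; an ungrounded
    Agent falls back to its display name with a TEXT pseudo-namespace.
    """
    by_ns: dict[str, list[str]] = {}
    for g in agent.groundings:
        by_ns.setdefault(g.namespace, []).append(g.identifier)
    for ns in namespace_priority:
        if ns in by_ns:
            return f"{ns}:{sorted(by_ns[ns])[0]}"
    for ns in sorted(by_ns):
        return f"{ns}:{sorted(by_ns[ns])[0]}"
    return f"TEXT:{agent.name}"


def agent_key(agent: Optional[Agent],
              namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
              ) -> str:
    """Canonical state-inclusive key for one agent slot.

    An unspecified (absent) slot participates in keys as the fixed token
    ``~`` so that e.g. "CREB1 is phosphorylated" (no enzyme) has a stable
    key distinct from any enzyme-specified variant.
    """
    if agent is None:
        return "~"
    parts = [canonical_grounding(agent, namespace_priority)]
    if agent.mods:
        parts.append("mods=" + ";".join(
            ",".join(map(str, m.key())) for m in sorted(
                agent.mods, key=lambda m: m.key())))
    if agent.mutations:
        parts.append("muts=" + ";".join(
            ",".join(m.key()) for m in sorted(agent.mutations)))
    if agent.activity is not None:
        parts.append("act=" + ",".join(map(str, agent.activity.key())))
    if agent.bound_conditions:
        bc_keys = sorted(
            (canonical_grounding(bc.agent, namespace_priority),
             bc.is_bound) for bc in agent.bound_conditions)
        parts.append("bound=" + ";".join(f"{g},{b}" for g, b in bc_keys))
    if agent.location is not None:
        parts.append("loc=" + agent.location)
    return "(" + "|".join(parts) + ")"


@dataclass(frozen=True)
class Evidence:
    """One supporting mention: a sentence read by one system from one paper,
    or one database entry."""

    source_api: str
    pmid: Optional[str] = None
    text: Optional[str] = None
    source_id: Optional[str] = None
    epistemics: Mapping[str, bool] = field(default_factory=dict)
    annotations: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not self.source_api:
            raise InvalidStatementError("source_api", "must be non-empty")

    def identity_key(self) -> tuple:
        """Identity for evidence deduplication.

        Identical sentences extracted by *different* readers remain distinct
        because source_api participates in the key.
        """
        return (self.source_api, self.pmid, self.text, self.source_id)


@dataclass
class Statement:
    """A typed mechanistic assertion with role-ordered Agent slots.

    ``agents`` is ordered subject-then-object for binary types; Complex
    holds an unordered member list (order is ignored by equivalence keys
    and refinement).  ``residue``/``position`` apply to modification types
    only.
    """

    stmt_type: str
    agents: list[Optional[Agent]]
    residue: Optional[str] = None
    position: Optional[str] = None
    evidence: list[Evidence] = field(default_factory=list)
    belief: Optional[float] = None

    def __post_init__(self):
        if self.stmt_type not in STATEMENT_TYPES:
            raise InvalidStatementError(
                "type", f"unknown statement type {self.stmt_type!r}")
        arity = STATEMENT_TYPES[self.stmt_type]
        if arity is None:
            if len(self.agents) < 2:
                raise InvalidStatementError(
                    "agents", f"{self.stmt_type} requires at least 2 members")
            if any(a is None for a in self.agents):
                raise InvalidStatementError(
                    "agents", "Complex members cannot be unspecified")
        elif len(self.agents) != arity:
            raise InvalidStatementError(
                "agents",
                f"{self.stmt_type} takes {arity} agents, got {len(self.agents)}")
        if self.residue is not None or self.position is not None:
            if self.stmt_type not in MODIFICATION_TYPES:
                raise InvalidStatementError(
                    "residue", f"{self.stmt_type} takes no residue/position")
        if self.residue is not None and self.residue not in AMINO_ACIDS:
            raise InvalidStatementError(
                "residue", f"{self.residue!r} is not a one-letter amino acid")
        if self.position is not None and not (
                self.position.isdigit() and int(self.position) > 0):
            raise InvalidStatementError(
                "position", f"{self.position!r} is not a positive integer")
        if self.belief is not None and not (0.0 <= self.belief <= 1.0):
            raise InvalidStatementError("belief", "must lie in [0, 1]")

    @property
    def is_unordered(self) -> bool:
        return STATEMENT_TYPES[self.stmt_type] is None


def matches_key(stmt: Statement,
                namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
                ) -> str:
    """Canonical equivalence key: equal keys <=> duplicate Statements.

    The key covers the statement type, each agent's canonical grounding and
    full state, and all remaining statement arguments; it never includes
    evidence, so permuting or extending evidence leaves it unchanged.
    Complex member order does not affect the key.
    """
    keys = [agent_key(a, namespace_priority) for a in stmt.agents]
    if stmt.is_unordered:
        keys = sorted(keys)
    key = f"{stmt.stmt_type}{''.join(keys)}"
    if stmt.stmt_type in MODIFICATION_TYPES:
        key += f"@{stmt.residue or ''},{stmt.position or ''}"
    return key


# ---------------------------------------------------------------------------
# JSON serialization (db_refs-style grounding maps, evidence list)
# ---------------------------------------------------------------------------

def _agent_to_dict(agent: Optional[Agent]) -> Optional[dict]:
    if agent is None:
        return None
    d: dict = {
        "name": agent.name,
        "db_refs": {g.namespace: g.identifier for g in
                    sorted(agent.groundings)},
    }
    if agent.mods:
        d["mods"] = [{"mod_type": m.mod_type, "residue": m.residue,
                      "position": m.position, "is_modified": m.is_modified}
                     for m in agent.mods]
    if agent.mutations:
        d["mutations"] = [{"residue_from": m.from_residue,
                           "position": m.position,
                           "residue_to": m.to_residue}
                          for m in agent.mutations]
    if agent.activity is not None:
        d["activity"] = {"activity_type": agent.activity.activity_type,
                         "is_active": agent.activity.is_active}
    if agent.bound_conditions:
        d["bound_conditions"] = [
            {"agent": _agent_to_dict(bc.agent), "is_bound": bc.is_bound}
            for bc in agent.bound_conditions]
    if agent.location is not None:
        d["location"] = agent.location
    return d


def _agent_from_dict(d: Optional[dict]) -> Optional[Agent]:
    if d is None:
        return None
    if "name" not in d:
        raise InvalidStatementError("name", "agent is missing its name")
    groundings = frozenset(
        Grounding(ns, str(ident)) for ns, ident in d.get("db_refs", {}).items())
    mods = tuple(
        ModCondition(m["mod_type"], m.get("residue"), m.get("position"),
                     m.get("is_modified", True))
        for m in d.get("mods", []))
    mutations = tuple(
        MutCondition(m["residue_from"], m["position"], m["residue_to"])
        for m in d.get("mutations", []))
    activity = None
    if d.get("activity") is not None:
        activity = ActivityCondition(d["activity"]["activity_type"],
                                     d["activity"].get("is_active", True))
    bound = tuple(
        BoundCondition(_agent_from_dict(bc["agent"]), bc.get("is_bound", True))
        for bc in d.get("bound_conditions", []))
    return Agent(name=d["name"], groundings=groundings, mods=mods,
                 mutations=mutations, activity=activity,
                 bound_conditions=bound, location=d.get("location"))


def _evidence_to_dict(ev: Evidence) -> dict:
    d: dict = {"source_api": ev.source_api}
    if ev.pmid is not None:
        d["pmid"] = ev.pmid
    if ev.text is not None:
        d["text"] = ev.text
    if ev.source_id is not None:
        d["source_id"] = ev.source_id
    if ev.epistemics:
        d["epistemics"] = dict(ev.epistemics)
    if ev.annotations:
        d["annotations"] = dict(ev.annotations)
    return d


def _evidence_from_dict(d: dict) -> Evidence:
    if "source_api" not in d:
        raise InvalidStatementError("source_api",
                                    "evidence is missing its source_api")
    return Evidence(source_api=d["source_api"], pmid=d.get("pmid"),
                    text=d.get("text"), source_id=d.get("source_id"),
                    epistemics=dict(d.get("epistemics", {})),
                    annotations=dict(d.get("annotations", {})))


def stmt_to_dict(stmt: Statement) -> dict:
    d: dict = {
        "type": stmt.stmt_type,
        "agents": [_agent_to_dict(a) for a in stmt.agents],
        "evidence": [_evidence_to_dict(ev) for ev in stmt.evidence],
    }
    if stmt.residue is not None:
        d["residue"] = stmt.residue
    if stmt.position is not None:
        d["position"] = stmt.position
    if stmt.belief is not None:
        d["belief"] = stmt.belief
    return d


def stmt_from_dict(d: dict) -> Statement:
    if "type" not in d:
        raise InvalidStatementError("type", "statement is missing its type")
    if "agents" not in d:
        raise InvalidStatementError("agents",
                                    "statement is missing its agents list")
    return Statement(
        stmt_type=d["type"],
        agents=[_agent_from_dict(a) for a in d["agents"]],
        residue=d.get("residue"),
        position=d.get("position"),
        evidence=[_evidence_from_dict(e) for e in d.get("evidence", [])],
        belief=d.get("belief"),
    )


def to_json(stmts: Iterable[Statement], indent: Optional[int] = None) -> str:
    """Serialize Statements to a JSON array; round-trips losslessly."""
    return json.dumps([stmt_to_dict(s) for s in stmts], indent=indent)


def from_json(text: str) -> list[Statement]:
    data = json.loads(text)
    if not isinstance(data, list):
        raise InvalidStatementError("statements",
                                    "top-level JSON must be a list")
    return [stmt_from_dict(d) for d in data]


# ---------------------------------------------------------------------------
# English rendering
# ---------------------------------------------------------------------------

_VERBS = {
    "Phosphorylation": ("phosphorylates", "is phosphorylated"),
    "Dephosphorylation": ("dephosphorylates", "is dephosphorylated"),
    "Ubiquitination": ("ubiquitinates", "is ubiquitinated"),
    "Deubiquitination": ("deubiquitinates", "is deubiquitinated"),
    "Acetylation": ("acetylates", "is acetylated"),
    "Deacetylation": ("deacetylates", "is deacetylated"),
    "Methylation": ("methylates", "is methylated"),
    "Demethylation": ("demethylates", "is demethylated"),
    "Sumoylation": ("sumoylates", "is sumoylated"),
    "Hydroxylation": ("hydroxylates", "is hydroxylated"),
    "Glycosylation": ("glycosylates", "is glycosylated"),
    "Activation": ("activates", "is activated"),
    "Inhibition": ("inhibits", "is inhibited"),
    "IncreaseAmount": ("increases the amount of", None),
    "DecreaseAmount": ("decreases the amount of", None),
}


def render_english(stmt: Statement) -> str:
    """Deterministic human-readable sentence for a Statement."""
    if stmt.stmt_type == "Complex":
        names = [a.name for a in stmt.agents]
        return f"{names[0]} binds {' and '.join(names[1:])}"
    if stmt.stmt_type == "ActiveForm":
        return f"{stmt.agents[0].name} is active"
    site = ""
    if stmt.residue and stmt.position:
        site = f" on {stmt.residue}{stmt.position}"
    elif stmt.residue:
        site = f" on {stmt.residue}"
    elif stmt.position:
        site = f" at position {stmt.position}"
    subj, obj = stmt.agents
    active, passive = _VERBS[stmt.stmt_type]
    if subj is None:
        if passive is None:
            return f"the amount of {obj.name} changes{site}"
        return f"{obj.name} {passive}{site}"
    return f"{subj.name} {active} {obj.name}{site}"


# ---------------------------------------------------------------------------
# Curation records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurationRecord:
    """A curator's correct/incorrect label for one evidence of one Statement."""

    statement_key: str
    evidence_key: tuple
    label: str  # "correct" | "incorrect"
    curator: str = ""

    def __post_init__(self):
        if self.label not in ("correct", "incorrect"):
            raise InvalidStatementError("label",
                                        "must be 'correct' or 'incorrect'")


def resolve_curations(records: Iterable[CurationRecord]
                      ) -> dict[tuple[str, tuple], str]:
    """Resolve multi-curator labels to one label per (statement, evidence).

    Conflicts resolve to "correct" if any curator marked the evidence
    correct, mirroring the at-least-one-correct statement-level rule;
    conflicts are logged.
    """
    resolved: dict[tuple[str, tuple], set[str]] = {}
    for rec in records:
        resolved.setdefault((rec.statement_key, rec.evidence_key),
                            set()).add(rec.label)
    out = {}
    for key, labels in resolved.items():
        if len(labels) > 1:
            logger.info("conflicting curations for %s resolved to 'correct'",
                        key)
        out[key] = "correct" if "correct" in labels else "incorrect"
    return out
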