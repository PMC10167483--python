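"""Configurable normalization/filter pipeline over raw Statement lists.

Each stage takes a Statement list and returns a (possibly smaller) list
plus an accounting row; stages are composed in a configured order by
:func:`run_pipeline`.  Filters are idempotent and never mutate surviving
Statements, with the exception of the grounding-mapping and site-mapping
stages, whose job is normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from . import assembly
from .ontology import GroundingMap, OntologyGraph, apply_grounding_overrides
from .statements import (
    Agent,
    DEFAULT_NAMESPACE_PRIORITY,
    Statement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SiteMap",
    "load_site_map_tsv",
    "filter_no_hypothesis",
    "filter_grounded_only",
    "filter_genes_only",
    "filter_human_only",
    "map_grounding",
    "map_and_filter_sites",
    "run_pipeline",
    "PipelineResult",
    "DEFAULT_STAGE_ORDER",
    "PipelineConfigError",
]

GENE_NAMESPACES = ("HGNC", "UP", "FPLX")


class PipelineConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Site map (pluggable stand-in for full reference-sequence validation)
# ---------------------------------------------------------------------------

@dataclass
class SiteMap:
    """Verdict table for claimed modification sites.

    Keys are (protein canonical id, residue, position); verdicts are
    ``("valid",)``, ``("mapped", residue, position)`` or ``("invalid",)``.
    Sites with no entry are treated as valid (permissive default, logged).
    """

    entries: dict[tuple[str, str, str], tuple] = field(default_factory=dict)

    def lookup(self, protein: str, residue: Optional[str],
               position: Optional[str]) -> tuple:
        if residue is None and position is None:
            return ("valid",)
        verdict = self.entries.get((protein, residue or "", position or ""))
        if verdict is None:
            logger.debug("site map has no entry for %s %s%s; treating as "
                         "valid", protein, residue, position)
            return ("valid",)
        return verdict


def load_site_map_tsv(path_or_lines) -> SiteMap:
    """Columns: protein_id, residue, position, verdict[, mapped_residue,
    mapped_position].  Verdict is valid/mapped/invalid."""
    if isinstance(path_or_lines, str):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    entries: dict[tuple[str, str, str], tuple] = {}
    for i, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"site map line {i}: expected >= 4 fields")
        protein, residue, position, verdict = fields[:4]
        if verdict == "mapped":
            if len(fields) != 6:
                raise ValueError(f"site map line {i}: mapped rows need "
                                 f"mapped_residue and mapped_position")
            entries[(protein, residue, position)] = ("mapped", fields[4],
                                                     fields[5])
        elif verdict in ("valid", "invalid"):
            entries[(protein, residue, position)] = (verdict,)
        else:
            raise ValueError(f"site map line {i}: unknown verdict "
                             f"{verdict!r}")
    return SiteMap(entries)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_no_hypothesis(stmts: Iterable[Statement],
                         filter_hypothesis: bool = True,
                         filter_negated: bool = True) -> list[Statement]:
    """Drop hypothesis/negated evidence; drop Statements left evidence-free.

    Mentions phrased as hypotheses ("we tested whether A phosphorylates B")
    and negative assertions ("A does not bind B") are flagged by extraction
    sources in evidence epistemics; both flags are honored and individually
    switchable.
    """
    out = []
    for stmt in stmts:
        kept = [ev for ev in stmt.evidence
                if not ((filter_hypothesis
                         and ev.epistemics.get("hypothesis", False))
                        or (filter_negated
                            and ev.epistemics.get("negated", False)))]
        if not kept:
            continue
        if len(kept) == len(stmt.evidence):
            out.append(stmt)
        else:
            out.append(Statement(stmt_type=stmt.stmt_type,
                                 agents=list(stmt.agents),
                                 residue=stmt.residue,
                                 position=stmt.position,
                                 evidence=kept, belief=stmt.belief))
    return out


def _top_level_agents(stmt: Statement) -> list[Agent]:
    return [a for a in stmt.agents if a is not None]


def filter_grounded_only(stmts: Iterable[Statement]) -> list[Statement]:
    """Remove Statements in which any specified agent is ungrounded.

    Unspecified (absent) slots — e.g. the missing enzyme in "CREB is
    phosphorylated" — do not count as ungrounded.
    """
    return [s for s in stmts
            if all(a.is_grounded for a in _top_level_agents(s))]


def filter_genes_only(stmts: Iterable[Statement],
                      namespaces: Sequence[str] = GENE_NAMESPACES,
                      ) -> list[Statement]:
    """Keep Statements whose agents all represent genes, proteins, or their
    families/complexes (grounded in HGNC, UniProt or FamPlex)."""
    def is_gene(agent: Agent) -> bool:
        return any(g.namespace in namespaces for g in agent.groundings)
    return [s for s in stmts if all(is_gene(a) for a in _top_level_agents(s))]


def filter_human_only(stmts: Iterable[Statement],
                      human_gene_set: set[str]) -> list[Statement]:
    """Remove Statements containing agents grounded to non-human genes.

    ``human_gene_set`` holds "NS:ID" strings of human gene identifiers
    (HGNC/UP).  Agents grounded only at the family/complex level (FPLX)
    pass: the analysis keeps genes *and their families*.
    """
    def is_human(agent: Agent) -> bool:
        gene_level = [g for g in agent.groundings
                      if g.namespace in ("HGNC", "UP")]
        if not gene_level:
            return True  # family/complex-level agent
        return any(str(g) in human_gene_set for g in gene_level)
    return [s for s in stmts if all(is_human(a) for a in _top_level_agents(s))]


def map_grounding(stmts: Iterable[Statement], onto: OntologyGraph,
                  gmap: Optional[GroundingMap] = None,
                  namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
                  ) -> list[Statement]:
    """Apply grounding overrides (by raw text) and ontology standardization
    to every agent.  The raw entity text is taken from the evidence-level
    ``agent_texts`` annotation when present, keyed by slot index."""
    gmap = gmap or GroundingMap({})
    out = []
    for stmt in stmts:
        texts = {}
        for ev in stmt.evidence:
            texts.update(ev.annotations.get("agent_texts", {}))
        new_agents = []
        for slot, agent in enumerate(stmt.agents):
            if agent is None:
                new_agents.append(None)
                continue
            raw = texts.get(slot, texts.get(str(slot), agent.name))
            new_agents.append(apply_grounding_overrides(
                agent, raw, gmap, onto, namespace_priority))
        out.append(Statement(stmt_type=stmt.stmt_type, agents=new_agents,
                             residue=stmt.residue, position=stmt.position,
                             evidence=stmt.evidence, belief=stmt.belief))
    return out


def map_and_filter_sites(stmts: Iterable[Statement], site_map: SiteMap,
                         namespace_priority: Sequence[str] =
                         DEFAULT_NAMESPACE_PRIORITY,
                         ) -> tuple[list[Statement], dict]:
    """Normalize claimed modification sites and drop invalid ones.

    For each modification Statement the substrate's claimed residue and
    position are looked up: valid sites pass unchanged, mapped sites have
    residue/position overwritten, invalid sites remove the Statement.
    Agent-level modification conditions are treated the same way.  Returns
    the filtered list and a report with the proportion removed.
    """
    from .statements import (MODIFICATION_TYPES, ModCondition,
                             canonical_grounding)
    out = []
    n_site_bearing = 0
    n_invalid = 0
    for stmt in stmts:
        stmt_out = stmt
        invalid = False
        has_site = False
        if (stmt.stmt_type in MODIFICATION_TYPES
                and (stmt.residue or stmt.position)):
            has_site = True
            substrate = stmt.agents[-1]
            protein = (canonical_grounding(substrate, namespace_priority)
                       if substrate is not None else "")
            verdict = site_map.lookup(protein, stmt.residue, stmt.position)
            if verdict[0] == "invalid":
                invalid = True
            elif verdict[0] == "mapped":
                stmt_out = Statement(stmt_type=stmt.stmt_type,
                                     agents=list(stmt.agents),
                                     residue=verdict[1], position=verdict[2],
                                     evidence=stmt.evidence,
                                     belief=stmt.belief)
        if not invalid:
            new_agents = []
            changed = False
            for agent in stmt_out.agents:
                if agent is None or not any(
                        m.residue or m.position for m in agent.mods):
                    new_agents.append(agent)
                    continue
                has_site = True
                protein = canonical_grounding(agent, namespace_priority)
                new_mods = []
                for mod in agent.mods:
                    verdict = site_map.lookup(protein, mod.residue,
                                              mod.position)
                    if verdict[0] == "invalid":
                        invalid = True
                        break
                    if verdict[0] == "mapped":
                        new_mods.append(ModCondition(mod.mod_type, verdict[1],
                                                     verdict[2],
                                                     mod.is_modified))
                        changed = True
                    else:
                        new_mods.append(mod)
                if invalid:
                    break
                new_agents.append(Agent(name=agent.name,
                                        groundings=agent.groundings,
                                        mods=tuple(new_mods),
                                        mutations=agent.mutations,
                                        activity=agent.activity,
                                        bound_conditions=agent.bound_conditions,
                                        location=agent.location))
            if not invalid and changed:
                stmt_out = Statement(stmt_type=stmt_out.stmt_type,
                                     agents=new_agents,
                                     residue=stmt_out.residue,
                                     position=stmt_out.position,
                                     evidence=stmt_out.evidence,
                                     belief=stmt_out.belief)
        if has_site:
            n_site_bearing += 1
        if invalid:
            n_invalid += 1
        else:
            out.append(stmt_out)
    report = {"n_site_bearing": n_site_bearing, "n_invalid": n_invalid,
              "proportion_removed": (n_invalid / n_site_bearing
                                     if n_site_bearing else 0.0)}
    return out, report


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

DEFAULT_STAGE_ORDER = [
    "filter_no_hypothesis",
    "map_grounding",
    "filter_grounded_only",
    "filter_genes_only",
    "filter_human_only",
    "map_sites",
    "combine_duplicates",
    "build_refinements",
]


@dataclass
class PipelineResult:
    statements: list[Statement]
    stages: list[dict]
    unique_statements: Optional[dict[str, Statement]] = None
    refinement_graph: Optional[object] = None
    site_report: Optional[dict] = None

    def report_table(self):
        import pandas as pd
        return pd.DataFrame(self.stages)


def run_pipeline(stmts: Sequence[Statement],
                 stages: Optional[Sequence] = None, *,
                 ontology: Optional[OntologyGraph] = None,
                 grounding_map: Optional[GroundingMap] = None,
                 site_map: Optional[SiteMap] = None,
                 human_genes: Optional[set[str]] = None,
                 namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
                 ) -> PipelineResult:
    """Apply a configured ordered list of stages with per-stage accounting.

    ``stages`` is a list of stage names or ``{"stage": name, **params}``
    descriptors; defaults to the full standard order.  Each report row
    satisfies n_in = n_out + n_removed.
    """
    if stages is None:
        stages = list(DEFAULT_STAGE_ORDER)
    current = list(stmts)
    result = PipelineResult(statements=current, stages=[])
    for descriptor in stages:
        if isinstance(descriptor, str):
            name, params = descriptor, {}
        else:
            descriptor = dict(descriptor)
            name = descriptor.pop("stage", None)
            if name is None:
                raise PipelineConfigError("stage descriptor missing 'stage'")
            params = descriptor
        n_in = len(current)
        if name == "filter_no_hypothesis":
            current = filter_no_hypothesis(current, **params)
        elif name == "map_grounding":
            if ontology is None:
                raise PipelineConfigError("map_grounding requires an ontology")
            current = map_grounding(current, ontology, grounding_map,
                                    namespace_priority, **params)
        elif name == "filter_grounded_only":
            current = filter_grounded_only(current, **params)
        elif name == "filter_genes_only":
            current = filter_genes_only(current, **params)
        elif name == "filter_human_only":
            if human_genes is None:
                raise PipelineConfigError(
                    "filter_human_only requires a human gene set")
            current = filter_human_only(current, human_genes, **params)
        elif name == "map_sites":
            current, site_report = map_and_filter_sites(
                current, site_map or SiteMap(), namespace_priority, **params)
            result.site_report = site_report
        elif name == "combine_duplicates":
            unique = assembly.combine_duplicates(current, namespace_priority)
            result.unique_statements = unique
            current = list(unique.values())
        elif name == "build_refinements":
            if ontology is None:
                raise PipelineConfigError(
                    "build_refinements requires an ontology")
            if result.unique_statements is None:
                unique = assembly.combine_duplicates(current,
                                                     namespace_priority)
                result.unique_statements = unique
                current = list(unique.values())
            result.refinement_graph = assembly.build_refinement_graph(
                result.unique_statements, ontology, namespace_priority)
        else:
            raise PipelineConfigError(f"unknown pipeline stage {name!r}")
        n_out = len(current)
        result.stages.append({"stage": name, "n_in": n_in, "n_out": n_out,
                              "n_removed": n_in - n_out})
        logger.info("stage %s: %d -> %d", name, n_in, n_out)
    result.statements = current
    return result
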