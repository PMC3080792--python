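"""Recursive category-tree mining over the ontology DAG.

Starting from the general categories (direct children of a namespace root),
nodes are expanded into their sub-terms when the expansion policy fires:
by default any node with a positive Z-score is expanded, significantly
enriched nodes always are, and an explicit force-expand list lets callers
descend into depleted branches (an enriched grandchild can hide under a
depleted parent). The report singles out "actual enriched" terms — enriched
terms none of whose visited descendants is itself enriched, i.e. the
terminal enriched refinement along each mining path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Literal

from membranome.enrichment import (
    DEFAULT_Z_THRESHOLD,
    EnrichmentResult,
    enrich_terms,
)
from membranome.ontology import (
    AnnotationTable,
    OntologyDAG,
    OntologyTerm,
    general_categories,
)

logger = logging.getLogger(__name__)

ExpansionReason = Literal["significant_parent", "forced_by_policy", "forced_by_user"]


@dataclass
class MiningPolicy:
    """Controls traversal.

    expand_positive_z: expand any node with z > 0 (enriched nodes are always
    expanded regardless).
    min_A: categories with fewer universe proteins are flagged low-support.
    force_expand: term ids expanded no matter their score.
    """

    z_threshold: float = DEFAULT_Z_THRESHOLD
    expand_positive_z: bool = True
    max_depth: int = 10
    min_A: int = 2
    force_expand: frozenset[str] = frozenset()
    variance: Literal["hypergeometric", "binomial"] = "hypergeometric"


@dataclass
class MiningNode:
    term_id: str
    result: EnrichmentResult
    depth: int
    expanded: bool = False
    expansion_reason: ExpansionReason | None = None
    low_support: bool = False
    children: list["MiningNode"] = field(default_factory=list)

    def walk(self) -> Iterable["MiningNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class MiningReport:
    roots: list[MiningNode]
    actual_enriched: list[str]
    custom_categories: list[str] = field(default_factory=list)
    namespace: str = ""
    stats: dict[str, int] = field(default_factory=dict)

    def nodes(self) -> Iterable[MiningNode]:
        for root in self.roots:
            yield from root.walk()


def add_custom_category(
    name: str,
    protein_ids: Iterable[str],
    dag: OntologyDAG,
    table: AnnotationTable,
    namespace: str = "biological_process",
    term_id: str | None = None,
) -> tuple[OntologyDAG, AnnotationTable, str]:
    """Inject a curated category as a new general category.

    Creates a term attached as a child of the namespace root and annotates
    the listed universe proteins to it; it then behaves like any ontology
    term in enrichment and mining. Unknown protein ids are dropped with a
    warning. Returns updated copies of the DAG and table plus the new term
    id.
    """
    proteins = set(protein_ids)
    if not proteins:
        raise ValueError("custom category needs at least one protein")
    if term_id is None:
        slug = "".join(c if c.isalnum() else "-" for c in name.strip().lower())
        term_id = f"CUSTOM:{slug}"
    if term_id in dag:
        raise ValueError(f"term id {term_id!r} already present in DAG")
    roots = dag.roots
    if namespace not in roots:
        raise ValueError(f"no root for namespace {namespace!r}")
    root_id = roots[namespace]

    known = proteins & table.proteins
    unknown = proteins - known
    if unknown:
        logger.warning(
            "custom category %r: dropping %d unknown protein ids", name, len(unknown)
        )
    if not known:
        raise ValueError(f"custom category {name!r} has no proteins in the universe")

    new_terms = [
        OntologyTerm(
            term_id=t.term_id,
            name=t.name,
            namespace=t.namespace,
            parent_ids=dict(t.parent_ids),
            obsolete=t.obsolete,
        )
        for t in (dag[tid] for tid in dag.terms(include_obsolete=True))
    ]
    new_terms.append(
        OntologyTerm(term_id=term_id, name=name, namespace=namespace,
                     parent_ids={root_id: "is_a"})
    )
    new_dag = OntologyDAG(new_terms)

    new_assignments = {p: set(ts) for p, ts in table.assignments.items()}
    for protein in known:
        new_assignments[protein].add(term_id)
        if table.propagated:
            new_assignments[protein].add(root_id)
    new_table = AnnotationTable(assignments=new_assignments, propagated=table.propagated)
    return new_dag, new_table, term_id


def mine(
    dag: OntologyDAG,
    table: AnnotationTable,
    membranome: Iterable[str],
    policy: MiningPolicy | None = None,
    namespace: str = "biological_process",
) -> MiningReport:
    """Expand general categories and collect the actual enriched terms.

    Traversal is depth-first in identifier order; multi-parent terms may be
    visited once per path but are deduplicated in ``actual_enriched``.
    """
    policy = policy or MiningPolicy()
    missing = sorted(t for t in policy.force_expand if t not in dag)
    if missing:
        raise ValueError(f"force-expand terms absent from DAG: {missing}")

    generals = general_categories(dag, namespace)
    score_cache: dict[str, EnrichmentResult] = {}
    stats: dict[str, int] = {}

    def score(term_ids: list[str]) -> list[EnrichmentResult]:
        todo = [t for t in term_ids if t not in score_cache]
        if todo:
            results, run_stats = enrich_terms(
                membranome, table, todo,
                z_threshold=policy.z_threshold, variance=policy.variance,
            )
            stats.update(run_stats)
            for res in results:
                score_cache[res.term_id] = res
        return [score_cache[t] for t in term_ids]

    visited_enriched: set[str] = set()
    nodes_visited = 0

    def build(term_id: str, depth: int) -> MiningNode:
        nonlocal nodes_visited
        nodes_visited += 1
        result = score([term_id])[0]
        node = MiningNode(
            term_id=term_id,
            result=result,
            depth=depth,
            low_support=result.counts.A < policy.min_A,
        )
        if result.direction == "enriched":
            visited_enriched.add(term_id)
        if depth >= policy.max_depth:
            return node
        reason: ExpansionReason | None = None
        if term_id in policy.force_expand:
            reason = "forced_by_user"
        elif result.direction == "enriched":
            reason = "significant_parent"
        elif policy.expand_positive_z and result.z > 0:
            reason = "forced_by_policy"
        kids = dag.children(term_id)
        if reason is not None and kids:
            node.expanded = True
            node.expansion_reason = reason
            score(kids)  # batch the whole sibling set
            node.children = [build(kid, depth + 1) for kid in kids]
        return node

    roots = [build(tid, 0) for tid in generals]

    # actual enriched: enriched with no enriched term among visited descendants
    def subtree_enriched_terms(node: MiningNode) -> set[str]:
        terms: set[str] = set()
        for child in node.children:
            terms |= subtree_enriched_terms(child)
            if child.result.direction == "enriched":
                terms.add(child.term_id)
        return terms

    actual: set[str] = set()
    for root in roots:
        for node in root.walk():
            if node.result.direction != "enriched":
                continue
            below = subtree_enriched_terms(node)
            if not (below - {node.term_id}):
                actual.add(node.term_id)
    # a term enriched-and-terminal on one path but with an enriched visited
    # descendant on another path is not terminal overall
    confirmed = []
    for tid in sorted(actual):
        desc = dag.descendants(tid)
        if not (desc & visited_enriched):
            confirmed.append(tid)

    custom = [t for t in generals if dag[t].namespace == "custom" or t.startswith("CUSTOM:")]
    stats["nodes_visited"] = nodes_visited
    return MiningReport(
        roots=roots,
        actual_enriched=confirmed,
        custom_categories=custom,
        namespace=namespace,
        stats=stats,
    )


# ---------------------------------------------------------------------------
# rendering


def render_report(
    report: MiningReport,
    dag: OntologyDAG,
    format: Literal["tsv", "tree", "json"] = "tsv",
) -> str:
    """Render a mining report as a TSV table, indented tree, or JSON.

    Output is deterministic: traversal order only, full float precision.
    """
    if format == "tsv":
        lines = ["term_id\tname\tdepth\ta\tn\tA\tN\tz\tdirection\texpansion_reason\tactual_enriched\tlow_support"]
        actual = set(report.actual_enriched)
        for node in report.nodes():
            c = node.result.counts
            lines.append(
                "\t".join(
                    [
                        node.term_id,
                        dag[node.term_id].name if node.term_id in dag else "",
                        str(node.depth),
                        str(c.a),
                        str(c.n),
                        str(c.A),
                        str(c.N),
                        repr(node.result.z),
                        node.result.direction,
                        node.expansion_reason or "",
                        "yes" if node.term_id in actual else "",
                        "yes" if node.low_support else "",
                    ]
                )
            )
        return "\n".join(lines) + "\n"
    if format == "tree":
        lines = []
        for root in report.roots:
            for node in root.walk():
                marker = {"enriched": "+", "depleted": "-", "neutral": " "}[
                    node.result.direction
                ]
                lines.append(
                    f"{'  ' * node.depth}{marker} {node.term_id} "
                    f"(z={node.result.z:.2f}, a={node.result.counts.a}, "
                    f"A={node.result.counts.A})"
                )
        return "\n".join(lines) + "\n"
    if format == "json":
        def encode(node: MiningNode) -> dict:
            c = node.result.counts
            return {
                "term_id": node.term_id,
                "depth": node.depth,
                "a": c.a,
                "n": c.n,
                "A": c.A,
                "N": c.N,
                "z": node.result.z,
                "p_right": node.result.p_hyper_right,
                "p_left": node.result.p_hyper_left,
                "direction": node.result.direction,
                "expanded": node.expanded,
                "expansion_reason": node.expansion_reason,
                "children": [encode(k) for k in node.children],
            }

        payload = {
            "namespace": report.namespace,
            "actual_enriched": report.actual_enriched,
            "custom_categories": report.custom_categories,
            "stats": report.stats,
            "roots": [encode(r) for r in report.roots],
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"
    raise ValueError(f"unknown format {format!r}")


def write_report(report: MiningReport, dag: OntologyDAG, stream: IO[str],
                 format: Literal["tsv", "tree", "json"] = "tsv") -> None:
    stream.write(render_report(report, dag, format=format))
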