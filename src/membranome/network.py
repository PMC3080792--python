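"""Protein-interaction network construction, merging and scoring.

Graphs are simple undirected graphs (no self-loops, no duplicate edges)
over molecule ids, carried on :class:`networkx.Graph`. Nodes may hold a
quantitative ratio-class overlay (enriched red / depleted green / absent
white), a molecule class, and function labels. Network strength is
summarized by the edge/node ratio and by a score equal to -log10 of the
right-tailed Fisher exact (hypergeometric) probability of observing at
least the focus-molecule count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx

from membranome.enrichment import CategoryCount, hypergeom_tail
from membranome.quant import INFINITE, UNDEFINED, ProteinQuantRecord, classify_record

logger = logging.getLogger(__name__)


@dataclass
class InteractionGraph:
    """Simple undirected molecule graph with per-node attributes."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    provenance: set[str] = field(default_factory=set)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def degree(self, node: str) -> int:
        return self.graph.degree[node]


@dataclass(frozen=True)
class NetworkScore:
    focus_count: int
    network_size: int
    eligible_total: int
    universe_total: int
    p_right: float
    score: float  # -log10(p_right)


def build_graph(
    edge_records: Iterable[tuple[str, str] | tuple[str, str, bool] | tuple[str, str, bool, str]],
    node_attributes: Mapping[str, Mapping[str, object]] | None = None,
    provenance: str | None = None,
) -> InteractionGraph:
    """Build a deduplicated simple graph from edge records.

    Each record is (source, target) optionally followed by a directed flag
    (carried as an edge attribute, ignored by the statistics) and a
    provenance label. Self-loops are dropped with a warning. Node attributes
    (molecule_class, function_labels, ...) are joined by id; attributes for
    ids not in any edge create isolated nodes.
    """
    g = nx.Graph()
    prov: set[str] = {provenance} if provenance else set()
    for record in edge_records:
        source, target = record[0], record[1]
        directed = bool(record[2]) if len(record) > 2 else False
        edge_prov = record[3] if len(record) > 3 else provenance
        if source == target:
            logger.warning("dropping self-loop on %r", source)
            continue
        if g.has_edge(source, target):
            if directed:
                g.edges[source, target]["directed"] = True
            continue
        g.add_edge(source, target, directed=directed, provenance=edge_prov)
        if edge_prov:
            prov.add(edge_prov)
    if node_attributes:
        for node, attrs in node_attributes.items():
            if node not in g:
                g.add_node(node)
            g.nodes[node].update(attrs)
    return InteractionGraph(graph=g, provenance=prov)


def merge(graphs: Sequence[InteractionGraph]) -> InteractionGraph:
    """Union of node and edge sets; first-seen node attributes win.

    Attribute conflicts on shared nodes are logged, not raised.
    """
    if not graphs:
        raise ValueError("merge needs at least one graph")
    merged = nx.Graph()
    prov: set[str] = set()
    for ig in graphs:
        prov |= ig.provenance
        for node, attrs in ig.graph.nodes(data=True):
            if node in merged:
                for key, val in attrs.items():
                    old = merged.nodes[node].get(key)
                    if old is not None and old != val:
                        logger.warning(
                            "attribute conflict on node %r key %r: keeping %r, ignoring %r",
                            node, key, old, val,
                        )
                    elif old is None:
                        merged.nodes[node][key] = val
            else:
                merged.add_node(node, **attrs)
        for u, v, attrs in ig.graph.edges(data=True):
            if not merged.has_edge(u, v):
                merged.add_edge(u, v, **attrs)
    return InteractionGraph(graph=merged, provenance=prov)


def edge_node_ratio(graph: InteractionGraph) -> float:
    """|E| / |V|, the network-cohesion summary."""
    if graph.n_nodes == 0:
        raise ValueError("edge/node ratio undefined for an empty graph")
    return graph.n_edges / graph.n_nodes


def isolated_and_missing(
    graph: InteractionGraph, input_set: Iterable[str]
) -> dict[str, object]:
    """Input molecules with no interactions, and inputs absent from the graph."""
    inputs = set(input_set)
    if not inputs:
        raise ValueError("input set must be nonempty")
    isolated = sorted(
        n for n in inputs if n in graph.graph and graph.graph.degree[n] == 0
    )
    missing = sorted(n for n in inputs if n not in graph.graph)
    return {
        "isolated_count": len(isolated),
        "missing_count": len(missing),
        "isolated": isolated,
        "missing": missing,
    }


def network_score(
    focus_count: int, network_size: int, eligible_total: int, universe_total: int
) -> NetworkScore:
    """-log10 of the right-tailed hypergeometric probability.

    Drawing ``network_size`` molecules from a universe of ``universe_total``
    containing ``eligible_total`` eligible input molecules, the score grows
    with the number of input molecules actually found in the network
    (``focus_count``).
    """
    counts = CategoryCount(
        term_id="network",
        a=focus_count,
        n=network_size,
        A=eligible_total,
        N=universe_total,
    )
    p_right = hypergeom_tail(counts, "right")
    score = 0.0 if p_right >= 1.0 else -math.log10(p_right)
    return NetworkScore(
        focus_count=focus_count,
        network_size=network_size,
        eligible_total=eligible_total,
        universe_total=universe_total,
        p_right=p_right,
        score=score,
    )


def overlay_quant(
    graph: InteractionGraph, quant_records: Sequence[ProteinQuantRecord]
) -> InteractionGraph:
    """Color nodes by quantitative class (in place; returns the graph).

    ratio_class: enriched_red (P/H > 1 or membrane-only), depleted_green
    (P/H < 1), absent_white (not quantified). intensity = |log2(ratio)| for
    finite ratios, +inf for membrane-only detections.
    """
    by_id = {rec.protein_id: rec for rec in quant_records}
    for node in graph.graph.nodes:
        rec = by_id.get(node)
        if rec is None or rec.ratio_PH is UNDEFINED:
            graph.graph.nodes[node]["ratio_class"] = "absent_white"
            graph.graph.nodes[node]["intensity"] = 0.0
            continue
        cls = classify_record(rec)
        if cls == "PM_only":
            graph.graph.nodes[node]["ratio_class"] = "enriched_red"
            graph.graph.nodes[node]["intensity"] = math.inf
        elif cls == "PM_enriched":
            graph.graph.nodes[node]["ratio_class"] = "enriched_red"
            graph.graph.nodes[node]["intensity"] = abs(math.log2(rec.ratio_PH))
        elif cls == "depleted":
            graph.graph.nodes[node]["ratio_class"] = "depleted_green"
            graph.graph.nodes[node]["intensity"] = abs(math.log2(rec.ratio_PH))
        else:  # ratio exactly 1
            graph.graph.nodes[node]["ratio_class"] = "absent_white"
            graph.graph.nodes[node]["intensity"] = 0.0
    return graph


def extract_subnetwork(
    graph: InteractionGraph,
    function_label: str | None = None,
    node_list: Iterable[str] | None = None,
    augment: Iterable[str] | None = None,
) -> InteractionGraph:
    """Induced subgraph on nodes carrying a function label or listed by id.

    ``augment`` adds extra molecule ids (the manually imported ones); they
    appear isolated unless the induced edge set connects them. Only direct
    interactions between retained nodes survive — no inferred paths.
    """
    if function_label is None and node_list is None:
        raise ValueError("need a function label or an explicit node list")
    keep: set[str] = set(node_list) if node_list is not None else set()
    if function_label is not None:
        for node, attrs in graph.graph.nodes(data=True):
            labels = attrs.get("function_labels") or ()
            if function_label in labels:
                keep.add(node)
    keep &= set(graph.graph.nodes)
    if not keep and not augment:
        raise ValueError("no nodes match the requested label or list")
    sub = nx.Graph(graph.graph.subgraph(keep))
    for extra in augment or ():
        if extra not in sub:
            sub.add_node(extra)
    return InteractionGraph(graph=sub, provenance=set(graph.provenance))


# ---------------------------------------------------------------------------
# I/O


def read_edge_tsv(stream: IO[str] | str) -> list[tuple[str, str, bool, str]]:
    """Edge TSV: source_id, target_id, optional directed flag, provenance."""
    lines = stream.splitlines() if isinstance(stream, str) else stream.read().splitlines()
    header: list[str] | None = None
    records: list[tuple[str, str, bool, str]] = []
    for raw in lines:
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = [f.strip() for f in raw.rstrip("\n").split("\t")]
        if header is None:
            header = fields
            if header[:2] != ["source_id", "target_id"]:
                raise ValueError("edge table must start with source_id, target_id")
            continue
        row = dict(zip(header, fields))
        records.append(
            (
                row["source_id"],
                row["target_id"],
                row.get("directed", "").lower() in {"1", "true", "yes"},
                row.get("provenance", ""),
            )
        )
    if header is None:
        raise ValueError("empty edge table")
    return records


def write_edge_tsv(graph: InteractionGraph, stream: IO[str]) -> None:
    stream.write("source_id\ttarget_id\tdirected\tprovenance\n")
    for u, v in graph.edges():
        attrs = graph.graph.edges[u, v]
        stream.write(
            f"{u}\t{v}\t{'true' if attrs.get('directed') else 'false'}"
            f"\t{attrs.get('provenance') or ''}\n"
        )


def write_graphml(graph: InteractionGraph, path: str) -> None:
    export = nx.Graph()
    for node, attrs in graph.graph.nodes(data=True):
        clean = {
            k: v for k, v in attrs.items()
            if isinstance(v, (str, int, float, bool)) and v == v and v not in (math.inf, -math.inf)
        }
        if "function_labels" in attrs and attrs["function_labels"]:
            clean["function_labels"] = ";".join(sorted(attrs["function_labels"]))
        export.add_node(node, **clean)
    for u, v, attrs in graph.graph.edges(data=True):
        export.add_edge(u, v, directed=bool(attrs.get("directed")),
                        provenance=str(attrs.get("provenance") or ""))
    nx.write_graphml(export, path)
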