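"""Seeded generators for ontologies, annotation universes, membranomes with
planted enrichment, quant tables, and modular interaction graphs.

Every generator draws from its own RNG stream derived from the master seed
by a stable label, so adding a generator never perturbs existing outputs,
and a fixed seed yields byte-identical artifacts. Ground truth (planted
odds, membrane membership, true enrichment factors, module labels) is
recorded for every generated entity so recovery can be measured.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from membranome.network import InteractionGraph, build_graph
from membranome.ontology import (
    AnnotationTable,
    OntologyDAG,
    OntologyTerm,
    propagate,
)
from membranome.quant import ProteinQuantRecord

NAMESPACE = "biological_process"
ROOT_ID = "SYN:ROOT"


def _rng(seed: int, label: str) -> np.random.Generator:
    """Independent stream per (seed, label); stable across runs and versions."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class QuantConfig:
    membrane_fraction: float = 0.5
    log2_enrichment_mean: float = 2.0
    log2_enrichment_sd: float = 0.5
    abundance_lognormal_mean: float = 4.0  # of ln(abundance)
    abundance_lognormal_sd: float = 1.5
    dropout_H: float = 0.0  # probability sin_H is zeroed -> INFINITE ratio


@dataclass
class GraphConfig:
    module_sizes: tuple[int, ...] = (20, 20, 20)
    p_within: float = 0.3
    p_between: float = 0.02


@dataclass
class SyntheticConfig:
    seed: int = 0
    N: int = 3000
    n: int = 300
    dag_depth: int = 3
    dag_branching: int = 4
    multi_parent_fraction: float = 0.0
    term_annotation_density: float = 0.02
    term_density_overrides: dict[str, float] = field(default_factory=dict)
    planted_terms: dict[str, float] = field(default_factory=dict)  # term -> odds
    quant: QuantConfig = field(default_factory=QuantConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)

    def __post_init__(self) -> None:
        for name, p in [
            ("term_annotation_density", self.term_annotation_density),
            ("multi_parent_fraction", self.multi_parent_fraction),
            ("quant.membrane_fraction", self.quant.membrane_fraction),
            ("quant.dropout_H", self.quant.dropout_H),
            ("graph.p_within", self.graph.p_within),
            ("graph.p_between", self.graph.p_between),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if any(odds <= 0 for odds in self.planted_terms.values()):
            raise ValueError("planted odds must be positive")


@dataclass
class GroundTruth:
    planted_odds: dict[str, float] = field(default_factory=dict)
    realized_A: dict[str, int] = field(default_factory=dict)
    membrane_true: dict[str, bool] = field(default_factory=dict)
    log2_enrichment: dict[str, float] = field(default_factory=dict)
    module_of: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_odds": self.planted_odds,
                "realized_A": self.realized_A,
                "membrane_true": self.membrane_true,
                "log2_enrichment": self.log2_enrichment,
                "module_of": self.module_of,
            },
            indent=2,
            sort_keys=True,
        ) + "\n"


def term_id(level: int, index: int) -> str:
    return ROOT_ID if level == 0 else f"SYN:L{level}N{index:05d}"


def protein_id(index: int) -> str:
    return f"PROT{index:06d}"


def generate_ontology(config: SyntheticConfig) -> OntologyDAG:
    """Rooted DAG with the configured depth and branching.

    Level k holds branching**k terms; with ``multi_parent_fraction`` > 0,
    terms at level >= 2 may gain one extra parent from the level above
    (keeping the graph acyclic).
    """
    if config.dag_depth < 1 or config.dag_branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = _rng(config.seed, "ontology")
    terms = [OntologyTerm(term_id=ROOT_ID, name="root", namespace=NAMESPACE)]
    prev_level = [ROOT_ID]
    for level in range(1, config.dag_depth + 1):
        count = config.dag_branching ** level
        this_level = []
        for idx in range(count):
            tid = term_id(level, idx)
            primary = prev_level[idx // config.dag_branching]
            parents = {primary: "is_a"}
            if (
                level >= 2
                and len(prev_level) > 1
                and rng.random() < config.multi_parent_fraction
            ):
                extra = prev_level[int(rng.integers(len(prev_level)))]
                if extra != primary:
                    parents[extra] = "is_a"
            terms.append(
                OntologyTerm(
                    term_id=tid,
                    name=f"synthetic term level {level} index {idx}",
                    namespace=NAMESPACE,
                    parent_ids=parents,
                )
            )
            this_level.append(tid)
        prev_level = this_level
    return OntologyDAG(terms)


def leaf_terms(dag: OntologyDAG) -> list[str]:
    return sorted(t for t in dag.terms() if not dag.children(t))


def generate_universe(
    config: SyntheticConfig, dag: OntologyDAG
) -> tuple[AnnotationTable, GroundTruth]:
    """N proteins annotated leaf-by-leaf at the configured density, propagated.

    Every protein is annotated at least to the root, so the universe size is
    exactly N and A(root) = N. Realized per-term counts go into the truth.
    """
    rng = _rng(config.seed, "universe")
    proteins = [protein_id(i) for i in range(config.N)]
    assignments: dict[str, set[str]] = {p: {ROOT_ID} for p in proteins}
    for leaf in leaf_terms(dag):
        density = config.term_density_overrides.get(leaf, config.term_annotation_density)
        hits = np.flatnonzero(rng.random(config.N) < density)
        for i in hits:
            assignments[proteins[i]].add(leaf)
    table = propagate(AnnotationTable(assignments=assignments), dag)
    truth = GroundTruth(
        planted_odds=dict(config.planted_terms),
        realized_A=table.term_counts(),
    )
    return table, truth


def generate_membranome(
    config: SyntheticConfig, universe: AnnotationTable, truth: GroundTruth
) -> list[str]:
    """Weighted sample without replacement of n proteins from the universe.

    A protein's weight is the product of the planted odds of the terms it
    carries; with all odds 1 the sample is uniform. Uses exponential-key
    (Efraimidis-Spirakis) sampling for a fully vectorized deterministic draw.
    """
    if config.n > universe.universe_size:
        raise ValueError(f"n={config.n} exceeds universe size {universe.universe_size}")
    rng = _rng(config.seed, "membranome")
    proteins = sorted(universe.proteins)
    weights = np.ones(len(proteins))
    if truth.planted_odds:
        for i, p in enumerate(proteins):
            w = 1.0
            for tid, odds in truth.planted_odds.items():
                if tid in universe.assignments[p]:
                    w *= odds
            weights[i] = w
    keys = rng.exponential(size=len(proteins)) / weights
    chosen = np.argsort(keys, kind="stable")[: config.n]
    return sorted(proteins[i] for i in chosen)


def generate_quant(
    config: SyntheticConfig, membranome: Sequence[str], truth: GroundTruth
) -> list[ProteinQuantRecord]:
    """Quant table with lognormal abundances and planted P/H enrichment.

    Membrane-true proteins get log2(P/H) ~ Normal(mean, sd); the rest get
    Normal(0, sd). H-dropout zeroes sin_H, producing membrane-only
    (infinite-ratio) rows. True membership and enrichment are recorded in
    the truth.
    """
    if not membranome:
        raise ValueError("membranome must be nonempty")
    rng = _rng(config.seed, "quant")
    qc = config.quant
    proteins = sorted(membranome)
    m = len(proteins)
    is_membrane = rng.random(m) < qc.membrane_fraction
    abundance = np.exp(
        rng.normal(qc.abundance_lognormal_mean, qc.abundance_lognormal_sd, size=m)
    )
    sin_p = np.exp(rng.normal(0.0, 1.0, size=m))
    log2_e = np.where(
        is_membrane,
        rng.normal(qc.log2_enrichment_mean, qc.log2_enrichment_sd, size=m),
        rng.normal(0.0, qc.log2_enrichment_sd, size=m),
    )
    sin_h = sin_p / np.exp2(log2_e)
    dropout = rng.random(m) < qc.dropout_H
    sin_h = np.where(dropout, 0.0, sin_h)
    records = []
    for i, p in enumerate(proteins):
        truth.membrane_true[p] = bool(is_membrane[i])
        truth.log2_enrichment[p] = float(log2_e[i])
        records.append(
            ProteinQuantRecord(
                protein_id=p,
                accession=f"ACC_{p}",
                description=f"synthetic protein {p}",
                abundance_P=float(abundance[i]),
                sin_P=float(sin_p[i]),
                sin_H=float(sin_h[i]),
                locations_raw="plasma membrane" if is_membrane[i] else "cytoplasm",
            )
        )
    return records


def generate_interactome(
    config: SyntheticConfig, truth: GroundTruth
) -> InteractionGraph:
    """Stochastic-block-model interaction graph with recorded module labels.

    Within-module pairs connect with probability p_within, between-module
    pairs with p_between. Inverted structure (p_within < p_between) is
    allowed for null tests but warned about.
    """
    gc = config.graph
    if gc.p_within < gc.p_between:
        import warnings

        warnings.warn(
            "p_within < p_between: inverted module structure",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = _rng(config.seed, "interactome")
    nodes: list[str] = []
    module_of: dict[str, str] = {}
    for mod_idx, size in enumerate(gc.module_sizes):
        label = f"module{mod_idx}"
        for j in range(size):
            node = f"NODE{len(nodes):05d}"
            nodes.append(node)
            module_of[node] = label
    edges: list[tuple[str, str]] = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            same = module_of[nodes[i]] == module_of[nodes[j]]
            p = gc.p_within if same else gc.p_between
            if rng.random() < p:
                edges.append((nodes[i], nodes[j]))
    truth.module_of.update(module_of)
    graph = build_graph(
        edges,
        node_attributes={
            node: {"module": module_of[node], "function_labels": (module_of[node],)}
            for node in nodes
        },
        provenance="synthetic",
    )
    return graph


def annotation_tsv(table: AnnotationTable) -> str:
    """Serialize an annotation table in the dialect parse_annotations reads."""
    lines = ["protein_id\tterm_id"]
    for protein in sorted(table.assignments):
        for tid in sorted(table.assignments[protein]):
            lines.append(f"{protein}\t{tid}")
    return "\n".join(lines) + "\n"
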