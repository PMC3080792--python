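"""End-to-end run orchestration: parse -> propagate -> enrich -> mine ->
quant -> network -> report, from a single declarative config.

All outputs are plain text (TSV/JSON), written deterministically so a rerun
with identical inputs is byte-identical; the manifest records config echo
and sha256 checksums of every input and output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import membranome
from membranome.enrichment import DEFAULT_Z_THRESHOLD
from membranome.mining import MiningPolicy, add_custom_category, mine, render_report
from membranome.network import (
    build_graph,
    edge_node_ratio,
    isolated_and_missing,
    merge,
    overlay_quant,
    read_edge_tsv,
)
from membranome.ontology import general_categories, parse_annotations, parse_obo, propagate
from membranome.quant import location_summary, read_quant_tsv
from membranome.reporting import round1

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    obo_path: Path
    annotations_path: Path
    membranome_path: Path
    quant_path: Path | None = None
    edge_paths: tuple[Path, ...] = ()
    out_dir: Path = Path("membranome_out")
    namespace: str = "biological_process"
    z_threshold: float = DEFAULT_Z_THRESHOLD
    min_A: int = 2
    max_depth: int = 10
    expand_positive_z: bool = True
    force_expand: tuple[str, ...] = ()
    variance: str = "hypergeometric"
    custom_categories: dict[str, tuple[str, ...]] = field(default_factory=dict)
    propagate_part_of: bool = True

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        def p(key: str) -> Path | None:
            return base / raw[key] if raw.get(key) else None

        return cls(
            obo_path=base / raw["obo"],
            annotations_path=base / raw["annotations"],
            membranome_path=base / raw["membranome"],
            quant_path=p("quant"),
            edge_paths=tuple(base / e for e in raw.get("edges", [])),
            out_dir=Path(raw.get("out_dir", "membranome_out")),
            namespace=raw.get("namespace", "biological_process"),
            z_threshold=float(raw.get("z_threshold", DEFAULT_Z_THRESHOLD)),
            min_A=int(raw.get("min_A", 2)),
            max_depth=int(raw.get("max_depth", 10)),
            expand_positive_z=bool(raw.get("expand_positive_z", True)),
            force_expand=tuple(raw.get("force_expand", [])),
            variance=raw.get("variance", "hypergeometric"),
            custom_categories={
                name: tuple(ids) for name, ids in raw.get("custom_categories", {}).items()
            },
            propagate_part_of=bool(raw.get("propagate_part_of", True)),
        )


def validate(config: RunConfig) -> list[str]:
    """Collect all config problems without executing anything."""
    problems: list[str] = []
    for label, path in [
        ("obo", config.obo_path),
        ("annotations", config.annotations_path),
        ("membranome", config.membranome_path),
        ("quant", config.quant_path),
        *[("edges", e) for e in config.edge_paths],
    ]:
        if path is not None and not Path(path).is_file():
            problems.append(f"{label} file not found: {path}")
    if config.z_threshold <= 0:
        problems.append("threshold must be positive")
    if config.min_A < 0:
        problems.append("min_A must be nonnegative")
    if config.max_depth < 1:
        problems.append("max_depth must be at least 1")
    if config.variance not in ("hypergeometric", "binomial"):
        problems.append(f"unknown variance convention: {config.variance}")
    if not problems and config.force_expand:
        try:
            dag = parse_obo(Path(config.obo_path).read_text(encoding="utf-8"))
            for tid in config.force_expand:
                if tid not in dag:
                    problems.append(f"force-expand term not in DAG: {tid}")
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            problems.append(f"cannot parse OBO for force-expand check: {exc}")
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_protein_list(path: Path) -> list[str]:
    proteins = []
    for line in path.read_text(encoding="utf-8").splitlines():
        token = line.split("#", 1)[0].strip()
        if token and token != "protein_id":
            proteins.append(token.split("\t")[0])
    return proteins


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the whole pipeline; returns a name -> path map of artifacts."""
    problems = validate(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    t0 = time.monotonic()

    # parse + propagate
    dag = parse_obo(Path(config.obo_path).read_text(encoding="utf-8"),
                    keep_part_of=config.propagate_part_of)
    table, parse_report = parse_annotations(
        Path(config.annotations_path).read_text(encoding="utf-8"), dag
    )
    relations = frozenset({"is_a", "part_of"}) if config.propagate_part_of else frozenset({"is_a"})
    table = propagate(table, dag, relations=relations)
    membrane_proteins = read_protein_list(Path(config.membranome_path))
    logger.info("parsed %d terms, N=%d, membranome=%d [%.1fs]",
                len(dag), table.universe_size, len(membrane_proteins),
                time.monotonic() - t0)

    # custom categories
    custom_ids = []
    for name, protein_ids in sorted(config.custom_categories.items()):
        dag, table, tid = add_custom_category(name, protein_ids, dag, table,
                                              namespace=config.namespace)
        custom_ids.append(tid)

    parse_path = out / "parse_report.json"
    parse_path.write_text(json.dumps(parse_report, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
    artifacts["parse_report"] = parse_path

    # mining (includes enrichment of every visited node)
    policy = MiningPolicy(
        z_threshold=config.z_threshold,
        expand_positive_z=config.expand_positive_z,
        max_depth=config.max_depth,
        min_A=config.min_A,
        force_expand=frozenset(config.force_expand),
        variance=config.variance,  # type: ignore[arg-type]
    )
    report = mine(dag, table, membrane_proteins, policy, namespace=config.namespace)
    mining_tsv = out / "mining_report.tsv"
    mining_tsv.write_text(render_report(report, dag, format="tsv"), encoding="utf-8")
    artifacts["mining_report"] = mining_tsv
    tree_path = out / "mining_tree.txt"
    tree_path.write_text(render_report(report, dag, format="tree"), encoding="utf-8")
    artifacts["mining_tree"] = tree_path
    mining_json = out / "mining_report.json"
    mining_json.write_text(render_report(report, dag, format="json"), encoding="utf-8")
    artifacts["mining_json"] = mining_json
    logger.info("mined %d general categories, %d actual enriched [%.1fs]",
                len(general_categories(dag, config.namespace)),
                len(report.actual_enriched), time.monotonic() - t0)

    # quant
    quant_records = None
    if config.quant_path is not None:
        quant_records = read_quant_tsv(Path(config.quant_path).read_text(encoding="utf-8"))
        summary = location_summary(quant_records)
        quant_path = out / "quant_summary.json"
        quant_path.write_text(summary.to_json(), encoding="utf-8")
        artifacts["quant_summary"] = quant_path

    # network
    if config.edge_paths:
        graphs = [
            build_graph(read_edge_tsv(Path(p).read_text(encoding="utf-8")),
                        provenance=Path(p).name)
            for p in config.edge_paths
        ]
        network = merge(graphs)
        if quant_records is not None:
            network = overlay_quant(network, quant_records)
        ratio = edge_node_ratio(network)
        iso = isolated_and_missing(network, membrane_proteins)
        net_report = {
            "n_nodes": network.n_nodes,
            "n_edges": network.n_edges,
            "edge_node_ratio": ratio,
            "edge_node_ratio_rounded": round1(ratio),
            "isolated_count": iso["isolated_count"],
            "missing_count": iso["missing_count"],
            "provenance": sorted(network.provenance),
        }
        net_path = out / "network_report.json"
        net_path.write_text(json.dumps(net_report, indent=2, sort_keys=True) + "\n",
                            encoding="utf-8")
        artifacts["network_report"] = net_path

    # manifest
    manifest = {
        "package_version": membranome.__version__,
        "config": {
            "namespace": config.namespace,
            "z_threshold": config.z_threshold,
            "min_A": config.min_A,
            "max_depth": config.max_depth,
            "expand_positive_z": config.expand_positive_z,
            "force_expand": sorted(config.force_expand),
            "variance": config.variance,
            "custom_categories": sorted(config.custom_categories),
            "propagate_part_of": config.propagate_part_of,
        },
        "inputs": {
            str(Path(p).name): _sha256(Path(p))
            for p in [config.obo_path, config.annotations_path, config.membranome_path,
                      config.quant_path, *config.edge_paths]
            if p is not None
        },
        "outputs": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                             encoding="utf-8")
    artifacts["manifest"] = manifest_path
    logger.info("run complete: %d artifacts [%.1fs]", len(artifacts),
                time.monotonic() - t0)
    return artifacts
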