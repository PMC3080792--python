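"""Ontology DAG store and protein->term annotation universe.

Parses a subset of OBO 1.2/1.4 ([Term] stanzas with id, name, namespace,
is_a, relationship: part_of, is_obsolete), holds the category hierarchy as a
rooted DAG per namespace, and manages annotation tables including true-path
propagation (a protein annotated to a term is annotated to every ancestor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component", "custom")


class OntologyError(ValueError):
    """Raised on malformed or inconsistent ontology input."""


@dataclass
class OntologyTerm:
    """One category term.

    ``parent_ids`` maps parent term id -> relation tag (``"is_a"`` or
    ``"part_of"``). Obsolete terms carry no edges and are excluded from
    enrichment.
    """

    term_id: str
    name: str = ""
    namespace: str = "biological_process"
    parent_ids: dict[str, str] = field(default_factory=dict)
    obsolete: bool = False


class OntologyDAG:
    """A rooted directed acyclic graph of :class:`OntologyTerm`.

    Each namespace present has exactly one root (a non-obsolete term with no
    parents). Acyclicity is verified at construction via topological sort.
    """

    def __init__(self, terms: Iterable[OntologyTerm]):
        self._terms: dict[str, OntologyTerm] = {}
        for term in terms:
            if term.term_id in self._terms:
                raise OntologyError(f"duplicate term id {term.term_id!r}")
            self._terms[term.term_id] = term
        self._children: dict[str, list[str]] = {tid: [] for tid in self._terms}
        for term in self._terms.values():
            for pid in term.parent_ids:
                if pid not in self._terms:
                    raise OntologyError(
                        f"term {term.term_id!r} references unknown parent {pid!r}"
                    )
                if self._terms[pid].obsolete or term.obsolete:
                    raise OntologyError(
                        f"edge {term.term_id!r} -> {pid!r} touches an obsolete term"
                    )
                self._children[pid].append(term.term_id)
        for kids in self._children.values():
            kids.sort()
        self._verify_acyclic()
        self._roots: dict[str, str] = {}
        for term in self._terms.values():
            if term.obsolete or term.parent_ids:
                continue
            if term.namespace in self._roots:
                raise OntologyError(
                    f"namespace {term.namespace!r} has multiple roots: "
                    f"{self._roots[term.namespace]!r} and {term.term_id!r}"
                )
            self._roots[term.namespace] = term.term_id

    # -- container protocol -------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._terms))

    def __getitem__(self, term_id: str) -> OntologyTerm:
        return self._terms[term_id]

    # -- queries ------------------------------------------------------------

    @property
    def roots(self) -> Mapping[str, str]:
        """Mapping namespace -> root term id."""
        return dict(self._roots)

    def terms(self, include_obsolete: bool = False) -> list[str]:
        return sorted(
            tid
            for tid, t in self._terms.items()
            if include_obsolete or not t.obsolete
        )

    def children(self, term_id: str) -> list[str]:
        return list(self._children[term_id])

    def parents(self, term_id: str, relations: frozenset[str] | None = None) -> list[str]:
        term = self._terms[term_id]
        if relations is None:
            return sorted(term.parent_ids)
        return sorted(p for p, rel in term.parent_ids.items() if rel in relations)

    def ancestors(
        self, term_id: str, relations: frozenset[str] | None = None
    ) -> set[str]:
        """All terms reachable upward from ``term_id`` (excluding itself)."""
        seen: set[str] = set()
        stack = self.parents(term_id, relations)
        while stack:
            tid = stack.pop()
            if tid in seen:
                continue
            seen.add(tid)
            stack.extend(self.parents(tid, relations))
        return seen

    def descendants(self, term_id: str) -> set[str]:
        seen: set[str] = set()
        stack = list(self._children[term_id])
        while stack:
            tid = stack.pop()
            if tid in seen:
                continue
            seen.add(tid)
            stack.extend(self._children[tid])
        return seen

    def edges(self) -> set[tuple[str, str, str]]:
        """Set of (child, parent, relation) triples."""
        return {
            (t.term_id, pid, rel)
            for t in self._terms.values()
            for pid, rel in t.parent_ids.items()
        }

    def topological_order(self) -> list[str]:
        """Parents before children; raises if a cycle exists."""
        return self._verify_acyclic()

    def _verify_acyclic(self) -> list[str]:
        indeg = {tid: len(t.parent_ids) for tid, t in self._terms.items()}
        ready = sorted(tid for tid, d in indeg.items() if d == 0)
        order: list[str] = []
        while ready:
            tid = ready.pop()
            order.append(tid)
            for kid in self._children[tid]:
                indeg[kid] -= 1
                if indeg[kid] == 0:
                    ready.append(kid)
            ready.sort()
        if len(order) != len(self._terms):
            cyclic = sorted(tid for tid, d in indeg.items() if d > 0)
            raise OntologyError(f"cycle detected among terms {cyclic}")
        return order


@dataclass
class AnnotationTable:
    """Protein -> term assignments plus the universe size N.

    ``propagated`` marks whether the true-path closure has been applied.
    """

    assignments: dict[str, set[str]]
    propagated: bool = False

    @property
    def universe_size(self) -> int:
        return len(self.assignments)

    @property
    def proteins(self) -> set[str]:
        return set(self.assignments)

    def term_count(self, term_id: str) -> int:
        """A(t): number of universe proteins annotated to ``term_id``."""
        return sum(1 for terms in self.assignments.values() if term_id in terms)

    def term_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for terms in self.assignments.values():
            for tid in terms:
                counts[tid] = counts.get(tid, 0) + 1
        return counts

    def annotated_to(self, term_id: str) -> set[str]:
        return {p for p, terms in self.assignments.items() if term_id in terms}


# ---------------------------------------------------------------------------
# OBO I/O


def parse_obo(stream: IO[str] | str, keep_part_of: bool = True) -> OntologyDAG:
    """Parse OBO text into an :class:`OntologyDAG`.

    Accepts a file-like object or a string of OBO content. ``is_a`` edges are
    always captured; ``relationship: part_of`` edges are captured unless
    ``keep_part_of`` is false. Obsolete terms are retained in the DAG but
    stripped of edges and excluded from enrichment-eligible term lists.

    Raises :class:`OntologyError` on cycles or dangling parent references.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    terms: list[OntologyTerm] = []
    cur: OntologyTerm | None = None
    in_term = False
    for raw in lines:
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if cur is not None:
                terms.append(cur)
                cur = None
            in_term = line == "[Term]"
            if in_term:
                cur = OntologyTerm(term_id="")
            continue
        if not in_term or cur is None:
            continue
        key, _, value = line.partition(":")
        value = value.strip()
        key = key.strip()
        if key == "id":
            cur.term_id = value
        elif key == "name":
            cur.name = value
        elif key == "namespace":
            cur.namespace = value
        elif key == "is_a":
            cur.parent_ids[value] = "is_a"
        elif key == "relationship":
            rel, _, target = value.partition(" ")
            if rel == "part_of" and keep_part_of:
                cur.parent_ids[target.strip()] = "part_of"
        elif key == "is_obsolete":
            cur.obsolete = value.lower() == "true"
    if cur is not None:
        terms.append(cur)

    for term in terms:
        if not term.term_id:
            raise OntologyError("[Term] stanza without an id")
        if term.obsolete:
            term.parent_ids = {}
    return OntologyDAG(terms)


def write_obo(dag: OntologyDAG, stream: IO[str]) -> None:
    """Serialize a DAG back to OBO text (stable, identifier-sorted)."""
    stream.write("format-version: 1.2\n")
    for tid in dag.terms(include_obsolete=True):
        term = dag[tid]
        stream.write("\n[Term]\n")
        stream.write(f"id: {term.term_id}\n")
        stream.write(f"name: {term.name}\n")
        stream.write(f"namespace: {term.namespace}\n")
        for pid in sorted(term.parent_ids):
            rel = term.parent_ids[pid]
            if rel == "is_a":
                stream.write(f"is_a: {pid}\n")
            else:
                stream.write(f"relationship: {rel} {pid}\n")
        if term.obsolete:
            stream.write("is_obsolete: true\n")


# ---------------------------------------------------------------------------
# Annotations


def parse_annotations(
    stream: IO[str] | str, dag: OntologyDAG
) -> tuple[AnnotationTable, dict[str, int]]:
    """Parse tabular protein->term records against a DAG.

    Expects a TSV with a header row naming at least ``protein_id`` and
    ``term_id`` columns; ``#`` comment lines are skipped. Records whose term
    is absent from the DAG (or obsolete) are dropped and counted. Returns the
    un-propagated table and a parse report::

        {records_in, records_kept, records_dropped_unknown_term,
         records_malformed, N}
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    header: list[str] | None = None
    assignments: dict[str, set[str]] = {}
    records_in = kept = dropped = malformed = 0
    for idx, raw in enumerate(lines):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            if "protein_id" not in header or "term_id" not in header:
                raise OntologyError(
                    "annotation table must have 'protein_id' and 'term_id' columns"
                )
            p_col = header.index("protein_id")
            t_col = header.index("term_id")
            continue
        records_in += 1
        if len(fields) <= max(p_col, t_col):
            malformed += 1
            logger.warning("skipping malformed annotation row %d: %r", idx + 1, raw)
            continue
        protein_id = fields[p_col].strip()
        term_id = fields[t_col].strip()
        if not protein_id or not term_id:
            malformed += 1
            logger.warning("skipping malformed annotation row %d: %r", idx + 1, raw)
            continue
        if term_id not in dag or dag[term_id].obsolete:
            dropped += 1
            continue
        assignments.setdefault(protein_id, set()).add(term_id)
        kept += 1
    if header is None or records_in == 0:
        raise OntologyError("empty annotation table")
    report = {
        "records_in": records_in,
        "records_kept": kept,
        "records_dropped_unknown_term": dropped,
        "records_malformed": malformed,
        "N": len(assignments),
    }
    return AnnotationTable(assignments=assignments, propagated=False), report


def propagate(
    table: AnnotationTable,
    dag: OntologyDAG,
    relations: frozenset[str] = frozenset({"is_a", "part_of"}),
) -> AnnotationTable:
    """Apply the true-path rule: close every protein's term set under ancestry.

    Returns a new table with ``propagated=True``. ``relations`` controls which
    edge types are traversed (default: both ``is_a`` and ``part_of``).
    """
    if table.propagated:
        raise ValueError("table already propagated")
    # memoized ancestor closure per term
    closure: dict[str, set[str]] = {}

    def anc(tid: str) -> set[str]:
        if tid not in closure:
            closure[tid] = dag.ancestors(tid, relations)
        return closure[tid]

    new_assignments: dict[str, set[str]] = {}
    for protein, terms in table.assignments.items():
        full = set(terms)
        for tid in terms:
            full |= anc(tid)
        new_assignments[protein] = full
    return AnnotationTable(assignments=new_assignments, propagated=True)


def general_categories(dag: OntologyDAG, namespace: str) -> list[str]:
    """Direct children of the namespace root, identifier-sorted.

    These are the top-level "general categories" that seed tree mining.
    """
    roots = dag.roots
    if namespace not in roots:
        raise OntologyError(f"no root for namespace {namespace!r}")
    return dag.children(roots[namespace])
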