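import io
import textwrap

import pytest

from membranome.ontology import AnnotationTable, parse_annotations, parse_obo, propagate

MINIMAL_OBO = textwrap.dedent(
    """\
    format-version: 1.2

    [Term]
    id: T:0
    name: root
    namespace: biological_process

    [Term]
    id: T:1
    name: child
    namespace: biological_process
    is_a: T:0

    [Term]
    id: T:2
    name: grandchild
    namespace: biological_process
    is_a: T:1
    """
)

# root with four general categories; T:B1 has an enriched-able grandchild
CHAIN_OBO = textwrap.dedent(
    """\
    format-version: 1.2

    [Term]
    id: R:0
    name: root
    namespace: biological_process

    [Term]
    id: G:A
    name: general A
    namespace: biological_process
    is_a: R:0

    [Term]
    id: G:B
    name: general B
    namespace: biological_process
    is_a: R:0

    [Term]
    id: B:mid
    name: mid under B
    namespace: biological_process
    is_a: G:B

    [Term]
    id: B:leaf
    name: leaf under mid
    namespace: biological_process
    is_a: B:mid
    """
)


@pytest.fixture
def minimal_dag():
    return parse_obo(MINIMAL_OBO)


@pytest.fixture
def chain_dag():
    return parse_obo(CHAIN_OBO)


def make_table(assignments: dict[str, set[str]], dag, propagated: bool = True):
    table = AnnotationTable(assignments={p: set(ts) for p, ts in assignments.items()})
    return propagate(table, dag) if propagated else table


@pytest.fixture
def annotation_text():
    return textwrap.dedent(
        """\
        protein_id\tterm_id
        p1\tT:2
        p2\tT:1
        p3\tT:0
        p4\tT:2
        p5\tT:1
        """
    )
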