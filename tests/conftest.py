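import io
import logging

import pandas as pd
import pytest

from mbco import (
    FixtureSpec,
    GeneSCPTable,
    Taxonomy,
    benchmark_study,
    generate_taxonomy,
    infer_all_edges,
    populate,
    simulate_counts,
)
from mbco.ontology import SCPNode

logging.getLogger("mbco").setLevel(logging.ERROR)


@pytest.fixture
def small_tax() -> Taxonomy:
    """Hand-built 3-level taxonomy: 1 root, 2 areas, 2 families of 2-3 SCPs."""
    nodes = [
        SCPNode("R", "Whole cell", 0, None),
        SCPNode("A1", "Area one", 1, "R", frozenset({"signaling"})),
        SCPNode("A2", "Area two", 1, "R"),
        SCPNode("P1", "Family one", 2, "A1"),
        SCPNode("P2", "Family two", 2, "A2"),
        SCPNode("X", "Process X", 3, "P1"),
        SCPNode("Y", "Process Y", 3, "P1"),
        SCPNode("Z", "Process Z", 3, "P2"),
        SCPNode("W", "Process W", 3, "P2"),
        SCPNode("X4", "Detail X4", 4, "X"),
    ]
    return Taxonomy(nodes)


@pytest.fixture
def tiny_table() -> GeneSCPTable:
    rows = [
        {"gene": "GA", "scp_id": "X", "rank": 1, "p_children_set": 1e-5},
        {"gene": "GB", "scp_id": "X", "rank": 2, "p_children_set": 1e-2},
        {"gene": "GA", "scp_id": "Y", "rank": 1, "p_children_set": 1e-3},
    ]
    return GeneSCPTable(pd.DataFrame(rows))


@pytest.fixture
def small_study():
    """A compact simulated study (2x6 families, 120 genes) for pipeline tests."""
    spec = FixtureSpec(
        seed=11, n_level1=2, children_per_node={1: 2, 2: 3, 3: 1}, n_genes=120,
        abstracts_per_scp=150,
    )
    tax, truth = generate_taxonomy(spec)
    counts = simulate_counts(truth, spec, tax)
    return spec, tax, truth, counts


# -- session-scoped benchmark shared by the expensive recovery tests ---------


@pytest.fixture(scope="session")
def bench():
    """The standard recovery benchmark (4/16/64 taxonomy, 800 genes, seed 1)."""
    return benchmark_study(seed=1)


@pytest.fixture(scope="session")
def bench_population(bench):
    spec, tax, truth, counts, labels = bench
    return populate(counts, tax, None)


@pytest.fixture(scope="session")
def bench_edges(bench):
    spec, tax, truth, counts, labels = bench
    return infer_all_edges(counts, tax, labels)


def taxonomy_tsv(rows) -> io.StringIO:
    """Build an in-memory taxonomy TSV from (scp_id, name, level, parent) rows."""
    buf = io.StringIO()
    buf.write("scp_id\tname\tlevel\tparent_id\tclass_tags\n")
    for r in rows:
        tags = r[4] if len(r) > 4 else ""
        parent = "" if r[3] is None else r[3]
        buf.write(f"{r[0]}\t{r[1]}\t{r[2]}\t{parent}\t{tags}\n")
    buf.seek(0)
    return buf
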