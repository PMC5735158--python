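"""Standard and dynamic (unit-merging) gene-set enrichment analysis.

Standard enrichment is the usual one-sided Fisher exact test of an
experimental gene list against each SCP's gene set.  Dynamic enrichment
extends the tested collection with context-specific *SCP units*: merged gene
sets of two or three level-3 SCPs that (i) are connected among the strongest
inferred SCP-SCP relationships and (ii) each contain at least one perturbed
gene.  Units let whole-cell functions that straddle the annotated taxonomy
surface as a single top-ranked entry; the level-3 SCPs among the top results
are then linked by *all* inferred relationships and the largest connected
component is reported as the context network.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .edges import CompetitionEdge, top_fraction, undirected_scores
from .ontology import GeneSCPTable, Taxonomy

__all__ = [
    "SCPUnit",
    "EnrichmentResult",
    "standard_enrichment",
    "build_units",
    "dynamic_enrichment",
    "extract_context_network",
]

log = logging.getLogger("mbco")


@dataclass(frozen=True)
class SCPUnit:
    """A merged gene set of 2-3 edge-connected level-3 SCPs."""

    member_scps: frozenset
    gene_set: frozenset
    unit_name: str

    def __post_init__(self):
        if not 2 <= len(self.member_scps) <= 3:
            raise ValueError("units contain 2 or 3 member SCPs")


@dataclass(frozen=True)
class EnrichmentResult:
    target: object  # scp_id (str) or SCPUnit
    p: float
    overlap_genes: frozenset
    rank: int

    @property
    def member_scps(self) -> frozenset:
        if isinstance(self.target, SCPUnit):
            return self.target.member_scps
        return frozenset((self.target,))

    @property
    def name(self) -> str:
        return self.target.unit_name if isinstance(self.target, SCPUnit) else self.target


def _sort_key(name: str):
    return name


def standard_enrichment(
    query_genes: set[str],
    gene_sets: Mapping[object, set],
    universe: set[str],
    top_k: int | None = None,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """One-sided Fisher enrichment of a query list against gene sets.

    ``gene_sets`` maps a key (SCP id, unit, ...) to its gene set; every set
    must be contained in ``universe``.  Results are sorted by ascending p
    (ties by name) and ranked 1..N; ``top_k`` truncates the output.  With
    ``bh_correct`` p-values are Benjamini-Hochberg adjusted before ranking
    (off by default: ranking raw p-values is the conventional usage here).
    """
    if not query_genes:
        raise ValueError("query gene list is empty")
    query = set(query_genes) & set(universe)
    if not query:
        raise ValueError("query genes are disjoint from the universe")
    n_u = len(universe)
    n_q = len(query)
    keys, pvals, overlaps = [], [], []
    for key, genes in gene_sets.items():
        gs = set(genes) & set(universe)
        ov = query & gs
        # one-sided upper tail: P(overlap >= observed) under hypergeometric
        p = float(hypergeom.sf(len(ov) - 1, n_u, len(gs), n_q))
        keys.append(key)
        pvals.append(min(p, 1.0))
        overlaps.append(frozenset(ov))
    if bh_correct and pvals:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for i in range(m - 1, -1, -1):
            idx = order[i]
            running = min(running, pvals[idx] * m / (i + 1))
            adj[idx] = running
        pvals = list(adj)
    named = sorted(
        zip(keys, pvals, overlaps),
        key=lambda t: (t[1], t[0].unit_name if isinstance(t[0], SCPUnit) else str(t[0])),
    )
    results = [
        EnrichmentResult(target=k, p=p, overlap_genes=ov, rank=i + 1)
        for i, (k, p, ov) in enumerate(named)
    ]
    return results[:top_k] if top_k else results


def build_units(
    perturbed: set[str],
    level3_sets: Mapping[str, set],
    edges_topq: Iterable[CompetitionEdge],
    max_size: int = 3,
) -> list[SCPUnit]:
    """All 2- and 3-SCP units connected in the selected edge subgraph.

    Candidates are the level-3 SCPs containing at least one perturbed gene
    (required of *every* unit member).  Units are every connected pair and
    every connected triple — any connected subgraph on three candidates, so
    a chain A-B, B-C yields A+B, B+C and A+B+C, and a triangle additionally
    yields A+C.  Output is sorted by name and independent of edge order.
    """
    candidates = {s for s, genes in level3_sets.items() if set(genes) & perturbed}
    graph = nx.Graph()
    graph.add_nodes_from(candidates)
    for pair in undirected_scores(edges_topq):
        a, b = sorted(pair)
        if a in candidates and b in candidates:
            graph.add_edge(a, b)
    units: list[SCPUnit] = []

    def _mk(members: tuple[str, ...]) -> SCPUnit:
        name = " + ".join(sorted(members))
        genes = frozenset(itertools.chain.from_iterable(level3_sets[m] for m in members))
        return SCPUnit(frozenset(members), genes, name)

    for a, b in graph.edges:
        units.append(_mk((a, b)))
    if max_size >= 3:
        for trio in itertools.combinations(sorted(candidates), 3):
            sub = graph.subgraph(trio)
            if sub.number_of_edges() >= 2 and nx.is_connected(sub):
                units.append(_mk(trio))
    units.sort(key=lambda u: u.unit_name)
    return units


def dynamic_enrichment(
    query_genes: set[str],
    ontology_table: GeneSCPTable,
    tax: Taxonomy,
    edges: list[CompetitionEdge],
    q: float = 0.25,
    max_size: int = 3,
    top_k: int | None = 5,
    universe: set[str] | None = None,
    exclude_tag: str | None = "signaling",
) -> list[EnrichmentResult]:
    """Fisher enrichment over level-3 SCPs plus context-specific SCP units.

    Units are built from the top fraction ``q`` of inferred edges
    (signaling-signaling pairs excluded) restricted to SCPs containing a
    perturbed gene.  With ``q=0`` this is exactly standard enrichment.  The
    universe defaults to all genes annotated at level 3.
    """
    level3_sets = ontology_table.gene_sets(tax, 3)
    if universe is None:
        universe = set().union(*level3_sets.values()) if level3_sets else set()
    topq = top_fraction(edges, q, tax, exclude_tag)
    perturbed = set(query_genes) & universe
    units = build_units(perturbed, level3_sets, topq, max_size)
    collection: dict[object, set] = dict(level3_sets)
    for u in units:
        collection[u] = set(u.gene_set)
    log.info("dynamic enrichment: %d SCPs + %d units", len(level3_sets), len(units))
    return standard_enrichment(query_genes, collection, universe, top_k=top_k)


def extract_context_network(
    top_results: list[EnrichmentResult],
    all_edges: list[CompetitionEdge],
    tax: Taxonomy,
    exclude_tag: str | None = "signaling",
) -> nx.Graph:
    """Largest connected component of the top-ranked level-3 SCPs.

    All level-3 SCPs appearing in the top results (singletons or unit
    members) are connected using *all* inferred edges (signaling-signaling
    still excluded).  The largest component wins; ties break toward the
    component holding the best-ranked result.  Member SCPs are decorated
    with their annotated level-2 parents and level-1 grandparents (node
    attribute ``role``: member / parent / grandparent).
    """
    if not top_results:
        raise ValueError("no top results to build a network from")
    scps: set[str] = set()
    best_rank: dict[str, int] = {}
    for res in top_results:
        for s in res.member_scps:
            scps.add(s)
            best_rank[s] = min(best_rank.get(s, 10**9), res.rank)
    graph = nx.Graph()
    graph.add_nodes_from(scps)
    pair_scores = undirected_scores(top_fraction(all_edges, 1.0, tax, exclude_tag))
    for pair, score in pair_scores.items():
        a, b = sorted(pair)
        if a in scps and b in scps:
            graph.add_edge(a, b, score=score)
    components = sorted(
        nx.connected_components(graph),
        key=lambda comp: (-len(comp), min(best_rank[s] for s in comp), min(comp)),
    )
    keep = components[0]
    net = graph.subgraph(keep).copy()
    nx.set_node_attributes(net, {s: "member" for s in net.nodes}, "role")
    nx.set_node_attributes(net, {s: tax.node(s).name for s in net.nodes}, "name")
    for s in sorted(keep):
        parent = tax.ancestor_at_level(s, 2)
        gparent = tax.ancestor_at_level(s, 1)
        for anc, role in ((parent, "parent"), (gparent, "grandparent")):
            if anc is None:
                continue
            if anc not in net:
                net.add_node(anc, role=role, name=tax.node(anc).name)
            net.add_edge(anc, s, kind="taxonomy")
    return net
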