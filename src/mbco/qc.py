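"""Internal-consistency analyses of a populated ontology.

If the taxonomy's vertical parent-child annotations reflect real biology, the
level-2 and level-3 SCPs — which are populated independently of each other —
should end up with overlapping gene sets.  These analyses quantify that:

* what fraction of each level-3 SCP's genes also appear in its annotated
  level-2 parent (computed on a table built *without* upward propagation,
  which would trivialize the question);
* whether the annotated parent is also the level-2 SCP sharing the most
  genes with the child;
* what fraction of a parent's genes is covered by the union of its children
  (computed *with* propagation);
* how that coverage decays when children are removed and the level is
  repopulated (mutual exclusivity of the children's sub-functions).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import CountMatrix
from .ontology import GeneSCPTable, OntologyError, Taxonomy
from .population import PopulationConfig, ValidationLabelSet, populate_level, rank_genes

__all__ = [
    "OverlapReport",
    "child_parent_overlap",
    "best_matching_parent",
    "parent_coverage_by_children",
    "sequential_child_removal",
]

log = logging.getLogger("mbco")


@dataclass
class OverlapReport:
    """Per-child percentage of genes shared with the annotated parent."""

    per_child: pd.Series  # index: level-3 scp_id, values: percent in [0, 100]
    mean: float
    sd: float
    median: float


def _require_unpropagated(table: GeneSCPTable) -> None:
    if (table.df["origin"] == "propagated").any():
        raise OntologyError(
            "analysis requires a table built without upward propagation "
            "(origin='propagated' rows present)"
        )


def child_parent_overlap(table: GeneSCPTable, tax: Taxonomy) -> OverlapReport:
    """Percent of each level-3 SCP's genes found in its level-2 parent."""
    _require_unpropagated(table)
    sets3 = table.gene_sets(tax, 3)
    sets2 = table.gene_sets(tax, 2)
    rows = {}
    for scp, genes in sorted(sets3.items()):
        if not genes:
            continue
        parent = tax.parent(scp)
        pg = sets2.get(parent, set())
        rows[scp] = 100.0 * len(genes & pg) / len(genes)
    per_child = pd.Series(rows, dtype=float)
    if per_child.empty:
        raise OntologyError("no populated level-3 SCPs")
    return OverlapReport(
        per_child=per_child,
        mean=float(per_child.mean()),
        sd=float(per_child.std(ddof=1)) if len(per_child) > 1 else 0.0,
        median=float(per_child.median()),
    )


def best_matching_parent(
    table: GeneSCPTable, tax: Taxonomy
) -> tuple[pd.Series, dict[str, int]]:
    """Classify each level-3 SCP by its best-matching level-2 SCP.

    The best match is the level-2 SCP sharing the most genes with the child.
    ``matched``: the unique best match is the annotated parent; ``tied``:
    several level-2 SCPs attain the maximum and the annotated parent is among
    them; ``mismatched``: the annotated parent does not attain the maximum.
    Children with no genes are excluded (logged).
    """
    _require_unpropagated(table)
    sets3 = table.gene_sets(tax, 3)
    sets2 = table.gene_sets(tax, 2)
    classification = {}
    skipped = 0
    for scp, genes in sorted(sets3.items()):
        if not genes:
            skipped += 1
            continue
        shared = {l2: len(genes & g2) for l2, g2 in sets2.items()}
        if not shared:
            skipped += 1
            continue
        best = max(shared.values())
        winners = {l2 for l2, n in shared.items() if n == best}
        parent = tax.parent(scp)
        if parent in winners:
            classification[scp] = "matched" if len(winners) == 1 else "tied"
        else:
            classification[scp] = "mismatched"
    if skipped:
        log.info("best_matching_parent: %d children without genes excluded", skipped)
    ser = pd.Series(classification, dtype=object)
    counts = {k: int((ser == k).sum()) for k in ("matched", "tied", "mismatched")}
    return ser, counts


def parent_coverage_by_children(
    table: GeneSCPTable, tax: Taxonomy, parent_level: int = 2
) -> tuple[pd.Series, float]:
    """Percent of each parent's genes found in the union of its children.

    Meant for a table built *with* propagation (the published analysis
    includes the propagation step); works on any table.
    """
    sets_parent = table.gene_sets(tax, parent_level)
    sets_child = table.gene_sets(tax, parent_level + 1)
    rows = {}
    for parent, pgenes in sorted(sets_parent.items()):
        if not pgenes:
            continue
        union: set[str] = set()
        for child in tax.children(parent):
            union |= sets_child.get(child, set())
        rows[parent] = 100.0 * len(pgenes & union) / len(pgenes)
    per_parent = pd.Series(rows, dtype=float)
    if per_parent.empty:
        raise OntologyError(f"no populated level-{parent_level} SCPs")
    return per_parent, float(per_parent.mean())


def sequential_child_removal(
    parent_id: str,
    counts: CountMatrix,
    tax: Taxonomy,
    labels: ValidationLabelSet | None,
    cfg: PopulationConfig | None = None,
    parent_genes: set[str] | None = None,
    max_enumerate: int = 12,
    n_samples: int = 256,
    seed: int = 0,
) -> dict[frozenset, int]:
    """Overlap of parent genes with remaining children after child removal.

    For every subset of the parent's level-3 children (all subsets when the
    family has at most ``max_enumerate`` children, otherwise a seeded uniform
    sample of ``n_samples`` subsets), the whole level-3 layer is repopulated
    without the removed children (manual validation skipped) and the overlap
    ``|parent_genes ∩ union(remaining children genes)|`` is recorded.

    ``parent_genes`` defaults to the level-2 parent's gene set from a
    baseline population run with propagation (parents are not repopulated).
    """
    cfg = cfg or PopulationConfig()
    children = sorted(tax.children(parent_id))
    if not children:
        raise OntologyError(f"{parent_id!r} has no children")
    if {tax.level(c) for c in children} != {3}:
        raise OntologyError(f"{parent_id!r} is not a level-2 parent of level-3 children")
    if parent_genes is None:
        from .population import populate

        baseline = populate(counts, tax, labels, cfg, propagate=True)
        parent_genes = baseline.genes_of(parent_id)

    if len(children) <= max_enumerate:
        subsets = [
            frozenset(c)
            for r in range(len(children) + 1)
            for c in itertools.combinations(children, r)
        ]
    else:
        rng = np.random.default_rng(seed)
        subsets = [frozenset()]
        for _ in range(n_samples):
            mask = rng.random(len(children)) < 0.5
            subsets.append(frozenset(c for c, m in zip(children, mask) if m))
        subsets = list(dict.fromkeys(subsets))

    out: dict[frozenset, int] = {}
    for removed in subsets:
        tbl = populate_level(
            counts, tax, cfg, level=3, labels=labels,
            exclude=removed, label_policy="none",
        )
        tbl = rank_genes(tbl)
        remaining = set(children) - removed
        union: set[str] = set()
        sub = tbl[tbl["scp_id"].isin(remaining)]
        union = set(sub["gene"])
        out[removed] = len(parent_genes & union)
    return out
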