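"""Leave-one-out inference of weighted relationships between level-3 SCPs.

SCPs of the same level compete for genes during population: the enrichment
rounds assign a gene to the SCP(s) where its literature support is most
selective.  How strongly two SCPs compete measures how related they are.  To
quantify it, one level-3 SCP at a time is removed and the level-3 layer is
repopulated; for every remaining SCP we sum how far the removed SCP's
(validated) member genes move *up* in its ranking — a gene newly entering a
remaining SCP of previous size N counts as moving from rank N+1 — and
normalize the sum by the SCP's size before removal.  Non-zero scores become
directed edges removed→remaining; for network use the two directions are
collapsed to their maximum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .corpus import CountMatrix
from .ontology import OntologyError, Taxonomy
from .population import PopulationConfig, ValidationLabelSet, populate_level, rank_genes

__all__ = [
    "CompetitionEdge",
    "repopulate_without",
    "score_competition",
    "infer_all_edges",
    "top_fraction",
    "undirected_scores",
    "save_edges",
    "load_edges",
]

log = logging.getLogger("mbco")


@dataclass(frozen=True)
class CompetitionEdge:
    removed_scp: str
    remaining_scp: str
    score: float
    contributing_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.removed_scp == self.remaining_scp:
            raise ValueError("self-edges are not allowed")
        if self.score <= 0:
            raise ValueError("emitted edges must have positive score")


def repopulate_without(
    scp_id: str | None,
    counts: CountMatrix,
    tax: Taxonomy,
    labels: ValidationLabelSet | None,
    cfg: PopulationConfig | None = None,
) -> pd.DataFrame:
    """Repopulate the level-3 layer without one SCP (or none, for baseline).

    Label handling is restricted for these runs: misinterpreted-term (M)
    removals, the sibling (S) count penalty and true-positive protection
    apply, but false positives are *kept* (their removal reflects curation of
    the full ontology, not the competition being measured).  The baseline
    ("reference") table is computed with exactly the same criteria so the two
    are comparable.
    """
    cfg = cfg or PopulationConfig()
    if scp_id is not None and tax.level(scp_id) != 3:
        raise OntologyError(f"{scp_id!r} is not a level-3 SCP")
    exclude = () if scp_id is None else (scp_id,)
    policy = "loo" if labels is not None and len(labels) else "none"
    tbl = populate_level(
        counts, tax, cfg, level=3, labels=labels, exclude=exclude, label_policy=policy
    )
    return rank_genes(tbl)


def _rank_maps(df: pd.DataFrame) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for scp, grp in df.groupby("scp_id"):
        out[scp] = dict(zip(grp["gene"], grp["rank"].astype(int)))
    return out


def score_competition(
    removed_scp: str,
    baseline: pd.DataFrame,
    alternative: pd.DataFrame,
    members: set[str],
) -> list[CompetitionEdge]:
    """Score how strongly each remaining SCP absorbed the removed SCP's genes.

    ``members`` are the (manually validated) member genes of the removed SCP.
    For remaining SCP r of baseline size N: a member gene found at rank k in
    the repopulated r contributes max(0, rank_before - k), where rank_before
    is its baseline rank in r, or N+1 if it is a new member.  The edge score
    is the contribution sum divided by N; zero-score edges are dropped, and
    SCPs empty in the baseline are skipped (no size to normalize by).
    """
    base_ranks = _rank_maps(baseline[baseline["scp_id"] != removed_scp])
    alt_ranks = _rank_maps(alternative)
    edges = []
    for scp, aranks in sorted(alt_ranks.items()):
        if scp == removed_scp:
            continue
        branks = base_ranks.get(scp, {})
        n_before = len(branks)
        if n_before == 0:
            continue
        total = 0.0
        contrib = set()
        for g in sorted(members):
            k = aranks.get(g)
            if k is None:
                continue
            rank_before = branks.get(g, n_before + 1)
            delta = max(0, rank_before - k)
            if delta > 0:
                total += delta
                contrib.add(g)
        if total > 0:
            edges.append(
                CompetitionEdge(removed_scp, scp, total / n_before, frozenset(contrib))
            )
    return edges


def infer_all_edges(
    counts: CountMatrix,
    tax: Taxonomy,
    labels: ValidationLabelSet | None,
    cfg: PopulationConfig | None = None,
    scps: Iterable[str] | None = None,
) -> list[CompetitionEdge]:
    """Leave-one-out edge inference over every level-3 SCP.

    Members of a left-out SCP are its T-validated genes when labels are
    given, otherwise its baseline gene set.  Deterministic.
    """
    cfg = cfg or PopulationConfig()
    baseline = repopulate_without(None, counts, tax, labels, cfg)
    level3 = sorted(tax.level_members(3) if scps is None else set(scps))
    edges: list[CompetitionEdge] = []
    for scp in level3:
        baseline_genes = set(baseline.loc[baseline["scp_id"] == scp, "gene"])
        if labels is not None and len(labels):
            members = {g for (g, s), lab in labels.items() if s == scp and lab == "T"}
        else:
            members = baseline_genes
        if not members:
            continue
        alt = repopulate_without(scp, counts, tax, labels, cfg)
        edges.extend(score_competition(scp, baseline, alt, members))
    log.info("leave-one-out inference: %d directed edges", len(edges))
    return edges


def undirected_scores(edges: Iterable[CompetitionEdge]) -> dict[frozenset, float]:
    """Collapse directed edges to undirected pair scores (max of directions)."""
    out: dict[frozenset, float] = {}
    for e in edges:
        key = frozenset((e.removed_scp, e.remaining_scp))
        out[key] = max(out.get(key, 0.0), e.score)
    return out


def top_fraction(
    edges: list[CompetitionEdge],
    q: float,
    tax: Taxonomy | None = None,
    exclude_tag: str | None = "signaling",
) -> list[CompetitionEdge]:
    """Keep the strongest fraction ``q`` of edges.

    Edges whose two endpoints both carry the excluded class tag (by default
    ``signaling``: relationships between signaling SCPs mostly reflect shared
    genes, not functional coupling) are dropped before ranking.  The top
    ceil(q*N) edges are kept; ties at the cutoff score are all included.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    pool = list(edges)
    if tax is not None and exclude_tag is not None:
        pool = [
            e
            for e in pool
            if not (
                exclude_tag in tax.tags(e.removed_scp)
                and exclude_tag in tax.tags(e.remaining_scp)
            )
        ]
    if q == 0 or not pool:
        return []
    pool.sort(key=lambda e: (-e.score, e.removed_scp, e.remaining_scp))
    k = math.ceil(q * len(pool))
    cutoff = pool[k - 1].score
    return [e for e in pool if e.score >= cutoff]


def save_edges(edges: Iterable[CompetitionEdge], dest, meta=None) -> None:
    from .ontology import _write_tsv

    rows = [
        {
            "removed_scp": e.removed_scp,
            "remaining_scp": e.remaining_scp,
            "score": e.score,
            "contributing_genes": ";".join(sorted(e.contributing_genes)),
        }
        for e in edges
    ]
    df = pd.DataFrame(rows, columns=["removed_scp", "remaining_scp", "score", "contributing_genes"])
    _write_tsv(df, dest, meta)


def load_edges(source) -> list[CompetitionEdge]:
    df = pd.read_csv(source, sep="\t", comment="#", dtype={"removed_scp": str, "remaining_scp": str},
                     keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        genes = frozenset(g for g in str(r.contributing_genes).split(";") if g)
        out.append(CompetitionEdge(r.removed_scp, r.remaining_scp, float(r.score), genes))
    return out
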