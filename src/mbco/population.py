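"""Population of SCPs with genes by two-stage competitive Fisher enrichment.

The pipeline turns raw per-SCP abstract counts into a curated association
table in five steps:

1. abstract-count thresholds per level (a gene needs at least 4/3/2/1
   supporting abstracts for a level-1/2/3/4 SCP);
2. manual-validation adjustments: associations flagged as misinterpreted
   dictionary terms (M) are removed, counts of associations flagged as
   belonging to a sibling SCP (S) are cut to 34% of their value;
3. for levels 2 and 3: per-SCP normalization of counts to a fixed total
   (3000 for levels 1-2, 1000 for levels 3-4) followed by a one-sided Fisher
   enrichment of every gene against all SCPs of the same level, then a second
   round against the sibling SCPs only ("children set"); after each round a
   gene keeps only the SCPs above the largest gap in its sorted -log10
   p-value profile.  Associations previously validated true (T) are never
   removed.  Levels 1 and 4 replace the same-level round by inheritance
   (level-1 candidates must appear in a level-2 child or level-3 grandchild;
   level-4 candidates must appear in the level-3 parent);
4. associations validated false (F) are removed;
5. every level-3 gene is propagated to its level-2 parent and level-1
   grandparent, every level-2 gene to its level-1 parent.

Finally genes are ranked within each SCP (ascending children-set p-value,
ties broken by descending adjusted count, then symbol).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .corpus import CountMatrix
from .ontology import GeneSCPTable, OntologyError, Taxonomy

__all__ = [
    "PopulationConfig",
    "ValidationLabelSet",
    "apply_abstract_minimum",
    "apply_validation_adjustments",
    "normalize_scp_counts",
    "fisher_upper_tail",
    "gene_pvalues",
    "largest_gap_filter",
    "enrich_and_filter",
    "inherit_filter",
    "remove_false_positives",
    "propagate_upward",
    "rank_genes",
    "populate",
    "populate_level",
]

log = logging.getLogger("mbco")


@dataclass(frozen=True)
class PopulationConfig:
    """Tunable parameters of the population pipeline.

    ``min_abstracts_by_level``: minimum supporting abstracts per level.
    ``norm_total_by_level``: per-SCP normalization target of summed counts.
    ``sibling_penalty_factor``: fraction of the count retained for
    associations validated as belonging to a sibling SCP (a 66% reduction).
    """

    min_abstracts_by_level: Mapping[int, int] = field(
        default_factory=lambda: {1: 4, 2: 3, 3: 2, 4: 1}
    )
    norm_total_by_level: Mapping[int, float] = field(
        default_factory=lambda: {1: 3000.0, 2: 3000.0, 3: 1000.0, 4: 1000.0}
    )
    sibling_penalty_factor: float = 0.34

    def __post_init__(self):
        if not 0 < self.sibling_penalty_factor < 1:
            raise ValueError("sibling_penalty_factor must lie in (0, 1)")
        if any(v <= 0 for v in self.norm_total_by_level.values()):
            raise ValueError("normalization totals must be positive")

    @classmethod
    def from_mapping(cls, obj: Mapping) -> "PopulationConfig":
        kwargs = {}
        if "min_abstracts_by_level" in obj:
            kwargs["min_abstracts_by_level"] = {
                int(k): int(v) for k, v in obj["min_abstracts_by_level"].items()
            }
        if "norm_total_by_level" in obj:
            kwargs["norm_total_by_level"] = {
                int(k): float(v) for k, v in obj["norm_total_by_level"].items()
            }
        if "sibling_penalty_factor" in obj:
            kwargs["sibling_penalty_factor"] = float(obj["sibling_penalty_factor"])
        return cls(**kwargs)


class ValidationLabelSet:
    """Manual validation verdicts per (gene, SCP) pair.

    Labels: T (true positive), F (false positive), M (misinterpreted
    dictionary term), S (belongs to a sibling SCP).
    """

    VALID = ("T", "F", "M", "S")

    def __init__(self, labels: Mapping[tuple, str] | None = None):
        self._labels: dict[tuple[str, str], str] = {}
        for (gene, scp), lab in (labels or {}).items():
            if lab not in self.VALID:
                raise ValueError(f"invalid label {lab!r} for ({gene}, {scp})")
            self._labels[(gene, scp)] = lab

    def __len__(self):
        return len(self._labels)

    def get(self, gene: str, scp_id: str) -> str | None:
        return self._labels.get((gene, scp_id))

    def pairs_with(self, label: str) -> set[tuple[str, str]]:
        return {k for k, v in self._labels.items() if v == label}

    def items(self):
        return self._labels.items()

    def label_series(self, df: pd.DataFrame) -> pd.Series:
        """Vector of labels aligned to rows of a (gene, scp_id) frame."""
        keys = list(zip(df["gene"], df["scp_id"]))
        return pd.Series([self._labels.get(k, "unlabeled") for k in keys], index=df.index)

    @classmethod
    def load(cls, source) -> "ValidationLabelSet":
        df = pd.read_csv(source, sep="\t", comment="#", dtype=str, keep_default_na=False)
        return cls({(r.gene, r.scp_id): r.label for r in df.itertuples(index=False)})

    def save(self, dest) -> None:
        from .ontology import _write_tsv

        rows = [
            {"gene": g, "scp_id": s, "label": lab}
            for (g, s), lab in sorted(self._labels.items())
        ]
        _write_tsv(pd.DataFrame(rows, columns=["gene", "scp_id", "label"]), dest)


# ---------------------------------------------------------------------------
# steps 1-2: thresholds and validation adjustments
# ---------------------------------------------------------------------------


def apply_abstract_minimum(
    counts: CountMatrix, tax: Taxonomy, cfg: PopulationConfig
) -> CountMatrix:
    """Drop (gene, SCP) pairs below the per-level minimum abstract count."""
    df = counts.counts
    if df.empty:
        return counts.copy()
    unknown = set(df["scp_id"]) - set(tax.nodes)
    if unknown:
        raise OntologyError(f"counts reference SCPs missing from taxonomy: {sorted(unknown)[:5]}")
    levels = df["scp_id"].map(lambda s: tax.level(s))
    thresholds = levels.map(lambda l: cfg.min_abstracts_by_level.get(l, 1))
    kept = df[df["count"] >= thresholds]
    log.info("abstract minimum: %d of %d pairs kept", len(kept), len(df))
    return CountMatrix(kept.reset_index(drop=True), dict(counts.scp_totals))


def apply_validation_adjustments(
    counts: CountMatrix, labels: ValidationLabelSet, cfg: PopulationConfig
) -> CountMatrix:
    """Remove M-labeled pairs; scale S-labeled counts by the sibling penalty."""
    df = counts.counts.copy()
    if df.empty or len(labels) == 0:
        return CountMatrix(df, dict(counts.scp_totals))
    lab = labels.label_series(df)
    known_pairs = set(zip(df["gene"], df["scp_id"]))
    unknown = [k for k, _ in labels.items() if k not in known_pairs]
    if unknown:
        log.warning("%d validation labels refer to absent pairs (ignored)", len(unknown))
    n_m = int((lab == "M").sum())
    df = df[lab != "M"].copy()
    lab = lab[lab != "M"]
    s_mask = lab == "S"
    df.loc[s_mask, "count"] = df.loc[s_mask, "count"] * cfg.sibling_penalty_factor
    log.info("validation adjustments: removed %d M pairs, penalized %d S pairs",
             n_m, int(s_mask.sum()))
    return CountMatrix(df.reset_index(drop=True), dict(counts.scp_totals))


# ---------------------------------------------------------------------------
# step 3 machinery: normalization, Fisher test, largest-gap cutoff
# ---------------------------------------------------------------------------


def normalize_scp_counts(
    counts: CountMatrix, tax: Taxonomy, cfg: PopulationConfig, scps: Iterable[str] | None = None
) -> CountMatrix:
    """Scale each SCP's counts so they sum to the level's normalization target.

    SCPs whose counts sum to zero are flagged empty (their rows dropped) and
    excluded from enrichment.
    """
    df = counts.counts.copy()
    if scps is not None:
        df = df[df["scp_id"].isin(set(scps))]
    if df.empty:
        return CountMatrix(df.reset_index(drop=True), dict(counts.scp_totals))
    targets = df["scp_id"].map(lambda s: cfg.norm_total_by_level[tax.level(s)])
    sums = df.groupby("scp_id")["count"].transform("sum")
    zero = sums <= 0
    if zero.any():
        log.warning("normalization: %d SCPs with zero total excluded",
                    df.loc[zero, "scp_id"].nunique())
        df, targets, sums = df[~zero], targets[~zero], sums[~zero]
    df = df.assign(count=df["count"] * targets / sums)
    return CountMatrix(df.reset_index(drop=True), dict(counts.scp_totals))


def fisher_upper_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided upper-tail Fisher probability P(X >= a) for a 2x2 table.

    The table rows are (gene, not-gene) article counts and the columns
    (SCP set, background set); the tail asks how likely a count of ``a`` or
    higher is under the hypergeometric null with the observed margins.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency entries must be non-negative")
    n = a + b + c + d
    if n <= 0:
        raise ValueError("degenerate table: grand total must be positive")
    return float(hypergeom.sf(a - 1, n, a + c, a + b))


def _fisher_sf_vec(a: np.ndarray, n_total: np.ndarray, k_gene: np.ndarray,
                   n_scp: np.ndarray) -> np.ndarray:
    return hypergeom.sf(a - 1, n_total, k_gene, n_scp)


def _pvalues_for_background(
    df: pd.DataFrame, target: float, n_background: int
) -> pd.Series:
    """Fisher upper-tail p per (gene, scp) row within one background set.

    ``df`` holds normalized counts of every pair in the background; the SCP
    total is the normalization target and the background grand total is
    ``n_background * target``.  Normalized counts are rounded to integers
    immediately before testing.
    """
    t_int = int(round(target))
    a = np.rint(df["count"].to_numpy()).astype(np.int64)
    a = np.minimum(a, t_int)
    gene_tot = df.groupby("gene")["count"].transform("sum").to_numpy()
    c = np.rint(gene_tot - df["count"].to_numpy()).astype(np.int64)
    n_total = n_background * t_int
    k_gene = a + c
    p = _fisher_sf_vec(a, np.full_like(a, n_total), k_gene, np.full_like(a, t_int))
    # sf can underflow to exactly 0; p-values live in (0, 1]
    return pd.Series(np.clip(p, 1e-320, 1.0), index=df.index)


def gene_pvalues(
    counts: CountMatrix,
    tax: Taxonomy,
    background: str,
    scope_id=None,
    cfg: PopulationConfig | None = None,
) -> pd.DataFrame:
    """Per-(gene, SCP) enrichment p-values against a background set.

    ``background`` is ``"same_level"`` (scope_id = the level; background =
    all SCPs of that level present in the counts) or ``"children_set"``
    (scope_id = a parent SCP; background = its children).  Counts must
    already be normalized for the scope.
    """
    cfg = cfg or PopulationConfig()
    if background == "same_level":
        scps = tax.level_members(int(scope_id))
        level = int(scope_id)
    elif background == "children_set":
        scps = tax.children(scope_id)
        levels = {tax.level(s) for s in scps}
        if len(levels) != 1:
            raise OntologyError(f"children of {scope_id!r} span levels {levels}")
        level = levels.pop()
    else:
        raise ValueError(f"unknown background kind {background!r}")
    df = counts.counts[counts.counts["scp_id"].isin(scps)].copy()
    n_bg = df["scp_id"].nunique()
    if background == "same_level" and n_bg < 2:
        raise OntologyError(
            "same-level background requires more than one populated SCP"
        )
    if df.empty:
        return pd.DataFrame(columns=["gene", "scp_id", "p"])
    target = cfg.norm_total_by_level[level]
    p = _pvalues_for_background(df, target, n_bg)
    return pd.DataFrame({"gene": df["gene"], "scp_id": df["scp_id"], "p": p}).reset_index(
        drop=True
    )


def largest_gap_filter(values: list[tuple]) -> set:
    """Keep the SCPs above the largest gap of a gene's -log10(p) profile.

    ``values`` are (scp, neglog_p) pairs for one gene across one background.
    The profile is sorted descending; the largest difference between adjacent
    values is the cutoff and everything below it is dropped.  Ties between
    equal positive gaps resolve to the gap closest to the top (keeping the
    fewest, most selective associations).  A single value, or an all-equal
    profile (no informative gap), is kept in full.
    """
    vals = list(values)
    if not vals:
        raise ValueError("largest_gap_filter: empty input")
    for _, v in vals:
        if not np.isfinite(v):
            raise ValueError("largest_gap_filter: non-finite value")
    if len(vals) == 1:
        return {vals[0][0]}
    vals.sort(key=lambda t: (-t[1], t[0]))
    gaps = [vals[i][1] - vals[i + 1][1] for i in range(len(vals) - 1)]
    best = max(gaps)
    if best <= 0:
        return {s for s, _ in vals}
    cut = gaps.index(best)
    return {s for s, _ in vals[: cut + 1]}


def _gap_keep_mask(pdf: pd.DataFrame) -> pd.Series:
    """Vectorized largest-gap filter over a (gene, scp_id, p) frame.

    Groups rows by gene, sorts each group's -log10(p) descending and keeps
    rows at or above the topmost largest positive gap.  Returns a boolean
    mask aligned to ``pdf``'s index.
    """
    with np.errstate(divide="ignore"):
        neglog = -np.log10(np.clip(pdf["p"].to_numpy(), 1e-320, 1.0))
    work = pdf.assign(_nl=neglog).sort_values(
        ["gene", "_nl", "scp_id"], ascending=[True, False, True]
    )
    g = work.groupby("gene", sort=False)
    gap = work["_nl"] - g["_nl"].shift(-1)  # NaN on each group's last row
    maxgap = gap.groupby(work["gene"], sort=False).transform("max")
    is_cut = (gap == maxgap) & (maxgap > 0)
    cum = is_cut.groupby(work["gene"], sort=False).cumsum()
    keep_sorted = (cum == 0) | ((cum == 1) & is_cut)
    return keep_sorted.reindex(pdf.index)


def enrich_and_filter(
    counts: CountMatrix,
    tax: Taxonomy,
    background: str,
    scope_id,
    labels: ValidationLabelSet | None = None,
    cfg: PopulationConfig | None = None,
    protect_true: bool = True,
) -> tuple[CountMatrix, pd.DataFrame]:
    """One enrichment round: p-values plus largest-gap removal of pairs.

    Returns the filtered counts (restricted to the background SCPs) and a
    frame (gene, scp_id, p, reinstated) for the surviving pairs.  Pairs
    manually validated T are never removed; if the gap filter would drop
    them they survive flagged ``reinstated``.
    """
    cfg = cfg or PopulationConfig()
    pdf = gene_pvalues(counts, tax, background, scope_id, cfg)
    if pdf.empty:
        empty_counts = pd.DataFrame(columns=["gene", "scp_id", "count"])
        empty_p = pd.DataFrame(columns=["gene", "scp_id", "p", "reinstated"])
        return CountMatrix(empty_counts, dict(counts.scp_totals)), empty_p
    keep = _gap_keep_mask(pdf)
    reinstated = pd.Series(False, index=pdf.index)
    if protect_true and labels is not None and len(labels):
        lab = labels.label_series(pdf)
        t_mask = lab == "T"
        reinstated = t_mask & ~keep
        keep = keep | t_mask
    out_p = pdf[keep].assign(reinstated=reinstated[keep]).reset_index(drop=True)
    kept_pairs = set(zip(out_p["gene"], out_p["scp_id"]))
    cdf = counts.counts
    in_scope = cdf["scp_id"].isin(set(pdf["scp_id"]))
    mask = [
        (g, s) in kept_pairs
        for g, s in zip(cdf["gene"], cdf["scp_id"])
    ]
    filtered = cdf[pd.Series(mask, index=cdf.index) & in_scope]
    log.info("enrichment (%s, %s): %d of %d pairs kept (%d reinstated)",
             background, scope_id, len(filtered), int(in_scope.sum()),
             int(reinstated.sum()))
    return CountMatrix(filtered.reset_index(drop=True), dict(counts.scp_totals)), out_p


# ---------------------------------------------------------------------------
# inheritance (step 2b), F removal (d), propagation (step 5), ranking
# ---------------------------------------------------------------------------


def inherit_filter(
    candidates: CountMatrix, populated: pd.DataFrame, tax: Taxonomy, level: int
) -> CountMatrix:
    """Replace same-level enrichment for levels 1 and 4 by inheritance.

    Level-1 candidates must appear in at least one level-2 child or level-3
    grandchild; level-4 candidates must appear in their level-3 parent.
    ``populated`` is the validated association frame for levels 2-3 (columns
    gene, scp_id).
    """
    if level not in (1, 4):
        raise ValueError("inherit_filter applies to levels 1 and 4 only")
    if populated.empty or not {2, 3} & {tax.level(s) for s in populated["scp_id"].unique()}:
        raise OntologyError("inherit_filter called before levels 2-3 were populated")
    genes_by_scp: dict[str, set[str]] = {
        scp: set(grp["gene"]) for scp, grp in populated.groupby("scp_id")
    }
    df = candidates.counts
    df = df[df["scp_id"].map(lambda s: tax.level(s) == level).astype(bool)]
    keep_rows = []
    for row in df.itertuples(index=True):
        scp = row.scp_id
        if level == 1:
            pool: set[str] = set()
            for child in tax.children(scp):
                pool |= genes_by_scp.get(child, set())
                for gchild in tax.children(child):
                    pool |= genes_by_scp.get(gchild, set())
        else:
            pool = genes_by_scp.get(tax.parent(scp), set())
        if row.gene in pool:
            keep_rows.append(row.Index)
    out = df.loc[keep_rows]
    log.info("inheritance (level %d): %d of %d candidates kept", level, len(out), len(df))
    return CountMatrix(out.reset_index(drop=True), dict(candidates.scp_totals))


def remove_false_positives(df: pd.DataFrame, labels: ValidationLabelSet) -> pd.DataFrame:
    """Drop rows validated F; only true positives remain in the final table."""
    if df.empty or len(labels) == 0:
        return df
    lab = labels.label_series(df[["gene", "scp_id"]])
    out = df[lab != "F"]
    log.info("false-positive removal: dropped %d pairs", len(df) - len(out))
    return out.reset_index(drop=True)


def propagate_upward(df: pd.DataFrame, tax: Taxonomy) -> pd.DataFrame:
    """Add level-3 genes to their level-2 parent and level-1 grandparent, and
    level-2 genes to their level-1 parent (origin ``propagated``)."""
    df = df.reset_index(drop=True)
    have: set[tuple[str, str]] = set(zip(df["gene"], df["scp_id"]))
    new_rows: list[dict] = []

    def _add(gene: str, scp: str | None):
        if scp is None or tax.level(scp) < 1:
            return
        if (gene, scp) not in have:
            have.add((gene, scp))
            new_rows.append(
                {
                    "gene": gene,
                    "scp_id": scp,
                    "raw_count": np.nan,
                    "adjusted_count": np.nan,
                    "norm_count": np.nan,
                    "p_same_level": np.nan,
                    "p_children_set": np.nan,
                    "rank": np.nan,
                    "label": "unlabeled",
                    "origin": "propagated",
                }
            )

    lv = df["scp_id"].map(lambda s: tax.level(s))
    for row in df[lv == 3].itertuples(index=False):
        parent = tax.parent(row.scp_id)
        _add(row.gene, parent)
        if parent is not None:
            _add(row.gene, tax.parent(parent))
    # include freshly added level-2 rows when lifting level 2 -> level 1
    lvl2_rows = [r for r in new_rows if tax.level(r["scp_id"]) == 2]
    for row in df[lv == 2].itertuples(index=False):
        _add(row.gene, tax.parent(row.scp_id))
    for r in lvl2_rows:
        _add(r["gene"], tax.parent(r["scp_id"]))
    if new_rows:
        df = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
    return df


def rank_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Rank genes 1..N within each SCP.

    Key: ascending children-set p-value (missing last), then descending
    adjusted count, then gene symbol.
    """
    df = df.copy()
    if "adjusted_count" not in df.columns:
        df["adjusted_count"] = np.nan
    order = df.assign(
        _p=df["p_children_set"].fillna(np.inf),
        _c=-df["adjusted_count"].fillna(-np.inf),
    ).sort_values(["scp_id", "_p", "_c", "gene"], kind="mergesort")
    ranks = order.groupby("scp_id").cumcount() + 1
    df.loc[order.index, "rank"] = ranks
    df["rank"] = df["rank"].astype(int)
    return df.sort_values(["scp_id", "rank"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _assemble(
    counts: CountMatrix,
    raw: pd.DataFrame,
    adjusted: pd.DataFrame,
    p_same: pd.DataFrame | None,
    p_child: pd.DataFrame,
    origin_default: str,
) -> pd.DataFrame:
    """Join surviving pairs with their counts and p-values into table rows."""
    key = ["gene", "scp_id"]
    out = counts.counts.rename(columns={"count": "norm_count"}).copy()
    out = out.merge(raw.rename(columns={"count": "raw_count"}), on=key, how="left")
    out = out.merge(adjusted.rename(columns={"count": "adjusted_count"}), on=key, how="left")
    if p_same is not None:
        out = out.merge(
            p_same.rename(columns={"p": "p_same_level"})[key + ["p_same_level"]],
            on=key, how="left",
        )
    else:
        out["p_same_level"] = np.nan
    out = out.merge(
        p_child.rename(columns={"p": "p_children_set"})[key + ["p_children_set", "reinstated"]],
        on=key, how="left",
    )
    out["origin"] = np.where(out["reinstated"].fillna(False), "reinstated", origin_default)
    return out.drop(columns=["reinstated"])


def _children_set_round(
    counts: CountMatrix,
    tax: Taxonomy,
    level: int,
    labels: ValidationLabelSet | None,
    cfg: PopulationConfig,
    protect_true: bool,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Children-set enrichment for every family with members at ``level``."""
    parents = sorted(
        {tax.parent(s) for s in counts.counts["scp_id"].unique() if tax.level(s) == level}
    )
    kept_frames, p_frames = [], []
    for parent in parents:
        fam = tax.children(parent)
        sub = CountMatrix(
            counts.counts[counts.counts["scp_id"].isin(fam)], counts.scp_totals
        )
        if sub.counts.empty:
            continue
        filt, pdf = enrich_and_filter(
            sub, tax, "children_set", parent, labels, cfg, protect_true
        )
        kept_frames.append(filt.counts)
        p_frames.append(pdf)
    kept = pd.concat(kept_frames, ignore_index=True) if kept_frames else counts.counts.iloc[0:0]
    ps = (
        pd.concat(p_frames, ignore_index=True)
        if p_frames
        else pd.DataFrame(columns=["gene", "scp_id", "p", "reinstated"])
    )
    return CountMatrix(kept, dict(counts.scp_totals)), ps


def populate_level(
    counts: CountMatrix,
    tax: Taxonomy,
    cfg: PopulationConfig,
    level: int,
    labels: ValidationLabelSet | None = None,
    exclude: Iterable[str] = (),
    label_policy: str = "full",
) -> pd.DataFrame:
    """Populate a single level through both enrichment rounds.

    ``label_policy``: ``"full"`` applies M removal, the S penalty, T
    protection and F removal; ``"loo"`` (leave-one-out repopulation) applies
    all adjustments except F removal; ``"none"`` ignores labels entirely.
    ``exclude`` drops SCPs from the level before anything is computed.
    """
    if label_policy not in ("full", "loo", "none"):
        raise ValueError(f"unknown label policy {label_policy!r}")
    use_labels = labels if (labels is not None and label_policy != "none") else None
    exclude = set(exclude)
    scps = tax.level_members(level) - exclude
    df = counts.counts
    df = df[df["scp_id"].isin(scps)]
    raw = df.copy()
    work = CountMatrix(df, dict(counts.scp_totals))
    work = apply_abstract_minimum(work, tax, cfg)
    if use_labels is not None:
        work = apply_validation_adjustments(work, use_labels, cfg)
    adjusted = work.counts.copy()
    work = normalize_scp_counts(work, tax, cfg)
    p_same = None
    if level in (2, 3):
        work, p_same = enrich_and_filter(
            work, tax, "same_level", level, use_labels, cfg,
            protect_true=use_labels is not None,
        )
        work = normalize_scp_counts(work, tax, cfg)
    work, p_child = _children_set_round(
        work, tax, level, use_labels, cfg, protect_true=use_labels is not None
    )
    table = _assemble(
        work, raw, adjusted, p_same, p_child,
        origin_default="enriched" if level in (2, 3) else "inherited",
    )
    if use_labels is not None:
        table["label"] = use_labels.label_series(table[["gene", "scp_id"]])
        if label_policy == "full":
            table = remove_false_positives(table, use_labels)
    else:
        table["label"] = "unlabeled"
    return table


def populate(
    counts: CountMatrix,
    tax: Taxonomy,
    labels: ValidationLabelSet | None = None,
    cfg: PopulationConfig | None = None,
    label_policy: str = "full",
    exclude: Iterable[str] = (),
    propagate: bool = True,
) -> GeneSCPTable:
    """Run the full population pipeline and return the association table.

    Deterministic given inputs.  ``propagate=False`` stops before step 5
    (needed for the parent-child consistency analyses, which compare parent
    and child gene sets before children genes are lifted into parents).
    """
    cfg = cfg or PopulationConfig()
    labels = labels or ValidationLabelSet()
    exclude = set(exclude)

    frames = []
    for level in (2, 3):
        frames.append(
            populate_level(counts, tax, cfg, level, labels, exclude, label_policy)
        )
    t23 = pd.concat(frames, ignore_index=True)

    # levels 1 and 4: inheritance from the validated levels 2-3, then the
    # children-set round
    frames14 = []
    for level in (1, 4):
        scps = tax.level_members(level) - exclude
        df = counts.counts
        df = df[df["scp_id"].isin(scps)]
        if df.empty:
            continue
        raw = df.copy()
        work = CountMatrix(df, dict(counts.scp_totals))
        work = apply_abstract_minimum(work, tax, cfg)
        use_labels = labels if label_policy != "none" else None
        if use_labels is not None:
            work = apply_validation_adjustments(work, use_labels, cfg)
        work = inherit_filter(work, t23[["gene", "scp_id"]], tax, level)
        if work.counts.empty:
            continue
        adjusted = work.counts.copy()
        work = normalize_scp_counts(work, tax, cfg)
        work, p_child = _children_set_round(
            work, tax, level, use_labels, cfg, protect_true=use_labels is not None
        )
        tbl = _assemble(work, raw, adjusted, None, p_child, origin_default="inherited")
        if use_labels is not None:
            tbl["label"] = use_labels.label_series(tbl[["gene", "scp_id"]])
        else:
            tbl["label"] = "unlabeled"
        frames14.append(tbl)
    table = pd.concat([t23, *frames14], ignore_index=True)
    if label_policy == "full":
        table = remove_false_positives(table, labels)
    if propagate:
        table = propagate_upward(table, tax)
    table = rank_genes(table)
    return GeneSCPTable(table)
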