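"""Co-expression validation of the populated ontology.

Genes acting in the same sub-cellular process tend to be co-expressed across
tissues.  Given a gene x tissue median-expression matrix (GCT or plain TSV),
we compute the Pearson correlation of every gene pair, split the pairs into
those sharing at least one SCP of a chosen level versus those sharing none
(only pairs where *both* genes are annotated at that level are considered),
and compare the two correlation distributions with a two-sided two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .ontology import GeneSCPTable, Taxonomy

__all__ = [
    "load_gct",
    "load_expression_tsv",
    "pairwise_pearson",
    "partition_pairs",
    "ks_two_sample",
    "histogram_frame",
]

log = logging.getLogger("mbco")


def _collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Duplicate gene symbols collapse to the row with the highest median."""
    if df.index.is_unique:
        return df
    med = df.median(axis=1)
    order = np.argsort(-med.to_numpy(), kind="stable")
    df = df.iloc[order]
    return df[~df.index.duplicated(keep="first")]


def load_gct(source) -> pd.DataFrame:
    """Read a GCT file (version line, dims line, Name/Description + samples).

    Returns a gene x tissue frame indexed by gene symbol (the Description
    column when present, else Name), duplicates collapsed to the row with the
    highest median expression.
    """
    path = Path(source)
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if not version.startswith("#1."):
            raise ValueError(f"not a GCT file (version line {version!r})")
        fh.readline()  # dimensions line, unused
        df = pd.read_csv(fh, sep="\t")
    sym_col = "Description" if "Description" in df.columns else "Name"
    data = df.drop(columns=[c for c in ("Name", "Description") if c in df.columns])
    data.index = df[sym_col].astype(str)
    data = data.apply(pd.to_numeric, errors="coerce").dropna(axis=0)
    return _collapse_duplicates(data)


def load_expression_tsv(source) -> pd.DataFrame:
    """Plain TSV expression matrix: first column gene, remaining tissues."""
    df = pd.read_csv(source, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    df = df.apply(pd.to_numeric, errors="coerce").dropna(axis=0)
    return _collapse_duplicates(df)


def pairwise_pearson(
    expr: pd.DataFrame, gene_subset: set[str] | None = None
) -> dict[frozenset, float]:
    """Pearson r for every unordered pair of (usable) genes.

    Zero-variance genes are excluded (logged); fewer than 2 usable genes or
    fewer than 3 tissues is an error.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 tissues for correlation")
    if gene_subset is not None:
        expr = expr.loc[expr.index.intersection(sorted(gene_subset))]
    values = expr.to_numpy(dtype=float)
    stds = values.std(axis=1)
    usable = stds > 0
    if (~usable).any():
        log.info("pairwise_pearson: %d zero-variance genes excluded", int((~usable).sum()))
    expr = expr.iloc[usable]
    if expr.shape[0] < 2:
        raise ValueError("fewer than 2 usable genes")
    corr = np.corrcoef(expr.to_numpy(dtype=float))
    genes = list(expr.index)
    out: dict[frozenset, float] = {}
    for i, j in combinations(range(len(genes)), 2):
        out[frozenset((genes[i], genes[j]))] = float(corr[i, j])
    return out


def partition_pairs(
    pairs: dict[frozenset, float],
    table: GeneSCPTable,
    tax: Taxonomy,
    level: int,
) -> tuple[dict[frozenset, float], dict[frozenset, float]]:
    """Split correlations into shared-SCP and non-shared groups.

    Only pairs where both genes are annotated to at least one SCP of the
    level are considered; among those, a pair is *shared* when the genes
    have at least one common SCP of that level.
    """
    sets = table.gene_sets(tax, level)
    scps_of: dict[str, set[str]] = {}
    for scp, genes in sets.items():
        for g in genes:
            scps_of.setdefault(g, set()).add(scp)
    shared: dict[frozenset, float] = {}
    nonshared: dict[frozenset, float] = {}
    for pair, r in pairs.items():
        g1, g2 = sorted(pair)
        s1, s2 = scps_of.get(g1), scps_of.get(g2)
        if not s1 or not s2:
            continue
        (shared if s1 & s2 else nonshared)[pair] = r
    return shared, nonshared


def ks_two_sample(g1, g2) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test: (D, p)."""
    g1 = np.asarray(list(g1), dtype=float)
    g2 = np.asarray(list(g2), dtype=float)
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both samples must be non-empty")
    res = ks_2samp(g1, g2, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def histogram_frame(
    shared: dict[frozenset, float],
    nonshared: dict[frozenset, float],
    bins: int = 40,
) -> pd.DataFrame:
    """Histogram data with both groups normalized to 100 (percent of pairs)."""
    edges = np.linspace(-1, 1, bins + 1)
    h1, _ = np.histogram(list(shared.values()), bins=edges)
    h2, _ = np.histogram(list(nonshared.values()), bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "shared_pct": 100.0 * h1 / max(h1.sum(), 1),
            "nonshared_pct": 100.0 * h2 / max(h2.sum(), 1),
        }
    )
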