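"""Dictionary-based gene recognition in SCP-specific abstract sets.

Each SCP of the ontology has its own literature set (titles + abstracts
retrieved by an SCP-specific query).  A term dictionary maps free-text terms
(symbols, synonyms, complex and family names) to biological entities in eight
classes; terms of the non-gene classes exist chiefly to *suppress* identical
gene terms so that, e.g., an abbreviation for a measurement technique is not
counted as a gene mention.

Counting is per document: a gene is counted once per abstract no matter how
often it is mentioned, and the per-(gene, SCP) count is the number of distinct
documents in that SCP's set mentioning the gene at least once.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "ENTITY_CLASSES",
    "GENE_CLASS",
    "DictionaryEntry",
    "AbstractRecord",
    "TokenMatcher",
    "CountMatrix",
    "compile_matcher",
    "count_gene_mentions",
    "load_dictionary",
    "load_abstracts_jsonl",
    "load_abstracts_medline",
]

ENTITY_CLASSES = (
    "genes and proteins",
    "protein domains",
    "metabolites",
    "diseases",
    "drugs",
    "sub-cellular structures",
    "sub-cellular processes",
    "confounding terms",
)
GENE_CLASS = "genes and proteins"

# tokens: alphanumeric runs, keeping internal hyphens (gene symbols embed both)
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*")


@dataclass(frozen=True)
class DictionaryEntry:
    term: str
    entity_id: str
    entity_class: str

    def __post_init__(self):
        if not self.term:
            raise ValueError("dictionary term must be non-empty")
        if self.entity_class not in ENTITY_CLASSES:
            raise ValueError(
                f"unknown entity class {self.entity_class!r}; expected one of {ENTITY_CLASSES}"
            )


@dataclass(frozen=True)
class AbstractRecord:
    doc_id: str
    scp_id: str
    text: str  # title + abstract concatenation


@dataclass
class CountMatrix:
    """Long-form gene x SCP abstract counts plus per-SCP abstract totals.

    ``counts`` has columns (gene, scp_id, count); counts start life as
    integers but become fractional after validation adjustments downstream.
    """

    counts: pd.DataFrame
    scp_totals: dict = field(default_factory=dict)

    def __post_init__(self):
        cols = ["gene", "scp_id", "count"]
        if list(self.counts.columns[:3]) != cols:
            self.counts = self.counts[cols]
        self.counts = self.counts.reset_index(drop=True)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), dict(self.scp_totals))

    def pivot(self) -> pd.DataFrame:
        return self.counts.pivot_table(
            index="gene", columns="scp_id", values="count", fill_value=0.0, aggfunc="sum"
        )

    @classmethod
    def load(cls, counts_source, totals_source=None) -> "CountMatrix":
        df = pd.read_csv(counts_source, sep="\t", comment="#",
                         dtype={"gene": str, "scp_id": str})
        totals = {}
        if totals_source is not None:
            t = pd.read_csv(totals_source, sep="\t", comment="#", dtype={"scp_id": str})
            totals = dict(zip(t["scp_id"], t["n_abstracts"].astype(int)))
        return cls(df, totals)

    def save(self, counts_dest, totals_dest=None) -> None:
        from .ontology import _write_tsv

        _write_tsv(self.counts, counts_dest)
        if totals_dest is not None:
            t = pd.DataFrame(
                sorted(self.scp_totals.items()), columns=["scp_id", "n_abstracts"]
            )
            _write_tsv(t, totals_dest)


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


class TokenMatcher:
    """Exact, whole-token, case-insensitive multi-term matcher.

    Matching walks the token sequence left to right; at every position the
    longest dictionary term starting there wins and the scan resumes after
    it.  If a matched term belongs to any non-gene entity class, its gene
    interpretations are suppressed (a confounding abbreviation, a process or
    a metabolite name beats an identical gene synonym).

    ``stop_terms`` lists all-lowercase common-word synonyms that are only
    trusted when the text does not spell them as an ordinary lowercase word
    (i.e. "MET" counts, "met" does not).
    """

    def __init__(self, entries: Iterable[DictionaryEntry], stop_terms: Iterable[str] = ()):
        entries = list(entries)
        if not entries:
            raise ValueError("empty dictionary")
        seen: set[tuple[str, str, str]] = set()
        self._by_key: dict[tuple[str, ...], list[DictionaryEntry]] = {}
        self.max_len = 1
        for e in entries:
            # a term may map to several genes (ambiguous synonym); exact
            # duplicates of one mapping are rejected
            dedup = (e.term.lower(), e.entity_class, e.entity_id)
            if dedup in seen:
                raise ValueError(f"duplicate dictionary entry: {dedup}")
            seen.add(dedup)
            key = tuple(t.lower() for t in tokenize(e.term))
            if not key:
                raise ValueError(f"term tokenizes to nothing: {e.term!r}")
            self._by_key.setdefault(key, []).append(e)
            self.max_len = max(self.max_len, len(key))
        self.stop_terms = {s.lower() for s in stop_terms}

    def gene_hits(self, text: str) -> set[str]:
        """Distinct gene entity ids mentioned in ``text``."""
        toks = tokenize(text)
        low = [t.lower() for t in toks]
        hits: set[str] = set()
        i = 0
        n = len(toks)
        while i < n:
            matched_len = 0
            matched: list[DictionaryEntry] | None = None
            for L in range(min(self.max_len, n - i), 0, -1):
                key = tuple(low[i : i + L])
                entries = self._by_key.get(key)
                if entries is not None:
                    matched, matched_len = entries, L
                    break
            if matched is None:
                i += 1
                continue
            surface = " ".join(toks[i : i + matched_len])
            nongene = any(e.entity_class != GENE_CLASS for e in matched)
            lowercase_common = (
                surface.lower() in self.stop_terms and surface == surface.lower()
            )
            if not nongene and not lowercase_common:
                hits.update(e.entity_id for e in matched if e.entity_class == GENE_CLASS)
            i += matched_len
        return hits


def compile_matcher(
    entries: Iterable[DictionaryEntry], stop_terms: Iterable[str] = ()
) -> TokenMatcher:
    return TokenMatcher(entries, stop_terms)


def count_gene_mentions(
    abstracts: Iterable[AbstractRecord], matcher: TokenMatcher
) -> CountMatrix:
    """Count, per (gene, SCP), the distinct documents mentioning the gene.

    A document appearing in several SCP sets is counted independently in each
    (the same article can support several processes).  Mention multiplicity
    within one document is irrelevant.
    """
    per_pair_docs: dict[tuple[str, str], set[str]] = {}
    scp_docs: dict[str, set[str]] = {}
    seen_records: set[tuple[str, str]] = set()
    for rec in abstracts:
        rkey = (rec.doc_id, rec.scp_id)
        if rkey in seen_records:
            raise ValueError(f"duplicate (doc_id, scp_id) record: {rkey}")
        seen_records.add(rkey)
        scp_docs.setdefault(rec.scp_id, set()).add(rec.doc_id)
        for gene in matcher.gene_hits(rec.text):
            per_pair_docs.setdefault((gene, rec.scp_id), set()).add(rec.doc_id)
    rows = [
        {"gene": g, "scp_id": s, "count": len(docs)}
        for (g, s), docs in sorted(per_pair_docs.items())
    ]
    counts = pd.DataFrame(rows, columns=["gene", "scp_id", "count"])
    totals = {s: len(d) for s, d in scp_docs.items()}
    return CountMatrix(counts, totals)


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def load_dictionary(source) -> list[DictionaryEntry]:
    """Dictionary TSV with columns term, entity_id, entity_class."""
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return [
        DictionaryEntry(term=r.term, entity_id=r.entity_id, entity_class=r.entity_class)
        for r in df.itertuples(index=False)
    ]


def load_abstracts_jsonl(source) -> list[AbstractRecord]:
    """JSON-lines abstract sets: objects with doc_id, scp_id, title, abstract."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    out = []
    for line in lines:
        if not line.strip():
            continue
        obj = json.loads(line)
        text = " ".join(x for x in (obj.get("title", ""), obj.get("abstract", "")) if x)
        out.append(AbstractRecord(str(obj["doc_id"]), str(obj["scp_id"]), text))
    return out


def load_abstracts_medline(source, scp_id: str) -> list[AbstractRecord]:
    """MEDLINE-format abstract file for one SCP (PMID/TI/AB fields).

    Uses Biopython's Medline parser when available; the records carry the
    given ``scp_id``.
    """
    from Bio import Medline  # optional dependency, only for this loader

    if hasattr(source, "read"):
        handle = source
        records = list(Medline.parse(handle))
    else:
        with open(source, encoding="utf-8") as handle:
            records = list(Medline.parse(handle))
    out = []
    for rec in records:
        doc_id = rec.get("PMID", "")
        text = " ".join(x for x in (rec.get("TI", ""), rec.get("AB", "")) if x)
        if doc_id:
            out.append(AbstractRecord(str(doc_id), scp_id, text))
    return out
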