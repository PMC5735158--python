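"""Data model and I/O for the sub-cellular-process (SCP) taxonomy.

The ontology is a tree of SCPs spanning five levels: a single level-0 root
("the whole cell"), level-1 SCPs describing broad functional areas (chapters),
down to level-4 SCPs describing the most detailed sub-functions.  Genes are
attached to SCPs in a :class:`GeneSCPTable`, which records the literature
evidence (abstract counts), the enrichment p-values from the population
pipeline, the within-SCP rank and the manual-validation provenance of every
association.

File dialects are deliberately plain: UTF-8 TSV with a header for the taxonomy
and the association table (lines starting with ``#`` are provenance comments
and are skipped on load), and standard GMT for gene-set export.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SCPNode",
    "Taxonomy",
    "GeneSCPTable",
    "OntologyError",
    "load_taxonomy",
    "save_taxonomy",
    "query_relatives",
    "export_gmt",
    "parse_gmt",
    "load_associations",
    "save_associations",
]

VALID_LABELS = ("T", "F", "M", "S", "unlabeled")
VALID_ORIGINS = ("enriched", "inherited", "propagated", "reinstated")

ASSOC_COLUMNS = [
    "gene",
    "scp_id",
    "raw_count",
    "adjusted_count",
    "norm_count",
    "p_same_level",
    "p_children_set",
    "rank",
    "label",
    "origin",
]


class OntologyError(ValueError):
    """Raised on any structural violation of the taxonomy or association table."""


@dataclass(frozen=True)
class SCPNode:
    """One sub-cellular process: a node of the taxonomy tree."""

    scp_id: str
    name: str
    level: int
    parent_id: str | None
    class_tags: frozenset = field(default_factory=frozenset)


class Taxonomy:
    """Validated SCP tree with derived children / level indices.

    Invariants enforced on construction:

    * exactly one root with level 0 and no parent;
    * every other node's parent exists and sits exactly one level above;
    * node identifiers are unique.
    """

    def __init__(self, nodes: Iterable[SCPNode]):
        nodes = list(nodes)
        self.nodes: dict[str, SCPNode] = {}
        errors: list[str] = []
        for n in nodes:
            if n.scp_id in self.nodes:
                errors.append(f"duplicate id: {n.scp_id!r}")
            self.nodes[n.scp_id] = n
        roots = [n for n in nodes if n.parent_id is None]
        if len(roots) != 1:
            errors.append(
                f"expected exactly one root (level 0, no parent), found {len(roots)}"
            )
        for n in nodes:
            if n.parent_id is None:
                if n.level != 0:
                    errors.append(f"{n.scp_id!r}: root must have level 0, has {n.level}")
                continue
            parent = self.nodes.get(n.parent_id)
            if parent is None:
                errors.append(f"{n.scp_id!r}: missing parent {n.parent_id!r}")
            elif parent.level != n.level - 1:
                errors.append(
                    f"{n.scp_id!r}: level mismatch (level {n.level}, "
                    f"parent {n.parent_id!r} has level {parent.level})"
                )
        if errors:
            raise OntologyError("; ".join(errors))
        self._children: dict[str, list[str]] = {sid: [] for sid in self.nodes}
        for n in nodes:
            if n.parent_id is not None:
                self._children[n.parent_id].append(n.scp_id)
        for sid in self._children:
            self._children[sid].sort()
        self._levels: dict[int, list[str]] = {}
        for n in nodes:
            self._levels.setdefault(n.level, []).append(n.scp_id)
        for lvl in self._levels:
            self._levels[lvl].sort()
        self.root = roots[0].scp_id

    # -- basic queries ------------------------------------------------------

    def __contains__(self, scp_id: str) -> bool:
        return scp_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, scp_id: str) -> SCPNode:
        try:
            return self.nodes[scp_id]
        except KeyError:
            raise OntologyError(f"unknown SCP id: {scp_id!r}") from None

    def level(self, scp_id: str) -> int:
        return self.node(scp_id).level

    def parent(self, scp_id: str) -> str | None:
        return self.node(scp_id).parent_id

    def children(self, scp_id: str) -> set[str]:
        self.node(scp_id)
        return set(self._children[scp_id])

    def grandchildren(self, scp_id: str) -> set[str]:
        out: set[str] = set()
        for c in self.children(scp_id):
            out |= self.children(c)
        return out

    def siblings(self, scp_id: str) -> set[str]:
        """All SCPs sharing the node's parent, excluding the node itself."""
        n = self.node(scp_id)
        if n.parent_id is None:
            return set()
        return self.children(n.parent_id) - {scp_id}

    def children_set(self, scp_id: str) -> set[str]:
        """The node together with its siblings (all children of its parent)."""
        return self.siblings(scp_id) | {scp_id}

    def level_members(self, level: int) -> set[str]:
        return set(self._levels.get(level, []))

    def level_counts(self) -> dict[int, int]:
        return {lvl: len(ids) for lvl, ids in sorted(self._levels.items())}

    def ancestors(self, scp_id: str) -> list[str]:
        """Ancestor chain from the parent up to the root."""
        out = []
        cur = self.node(scp_id).parent_id
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent_id
        return out

    def ancestor_at_level(self, scp_id: str, level: int) -> str | None:
        if self.level(scp_id) == level:
            return scp_id
        for a in self.ancestors(scp_id):
            if self.nodes[a].level == level:
                return a
        return None

    def tags(self, scp_id: str) -> frozenset:
        """Effective class tags: the node's own plus its level-1 ancestor's.

        Functional class membership (e.g. ``signaling``, used for edge
        exclusion) is typically annotated on the level-1 branch and inherited
        by the whole subtree unless a node overrides it with its own tags.
        """
        n = self.node(scp_id)
        l1 = self.ancestor_at_level(scp_id, 1)
        inherited = self.nodes[l1].class_tags if l1 is not None else frozenset()
        return n.class_tags | inherited

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scp_id": n.scp_id,
                "name": n.name,
                "level": n.level,
                "parent_id": "" if n.parent_id is None else n.parent_id,
                "class_tags": ";".join(sorted(n.class_tags)),
            }
            for n in sorted(self.nodes.values(), key=lambda n: (n.level, n.scp_id))
        ]
        return pd.DataFrame(rows, columns=["scp_id", "name", "level", "parent_id", "class_tags"])


def load_taxonomy(source) -> Taxonomy:
    """Read a taxonomy TSV (scp_id, name, level, parent_id, class_tags).

    ``source`` may be a path, an open text stream, or a DataFrame with the
    same columns.  All tree invariants are checked; violations raise
    :class:`OntologyError` naming the offending rows.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"scp_id", "name", "level", "parent_id"}
    missing = required - set(df.columns)
    if missing:
        raise OntologyError(f"taxonomy table missing columns: {sorted(missing)}")
    if "class_tags" not in df.columns:
        df["class_tags"] = ""
    nodes = []
    for row in df.itertuples(index=False):
        tags = frozenset(t for t in str(row.class_tags).split(";") if t)
        parent = str(row.parent_id) if str(row.parent_id) != "" else None
        nodes.append(
            SCPNode(
                scp_id=str(row.scp_id),
                name=str(row.name),
                level=int(row.level),
                parent_id=parent,
                class_tags=tags,
            )
        )
    return Taxonomy(nodes)


def save_taxonomy(tax: Taxonomy, dest, meta: Mapping[str, str] | None = None) -> None:
    _write_tsv(tax.to_frame(), dest, meta)


_RELATIONS = ("parent", "children", "siblings", "grandchildren", "level_members")


def query_relatives(tax: Taxonomy, scp_id: str, relation: str) -> set[str]:
    """Return the requested relative set of an SCP.

    ``relation`` is one of ``parent``, ``children``, ``siblings``,
    ``grandchildren`` or ``level_members`` (all SCPs of the node's level,
    excluding the node).
    """
    if relation not in _RELATIONS:
        raise OntologyError(f"unknown relation {relation!r}; expected one of {_RELATIONS}")
    n = tax.node(scp_id)
    if relation == "parent":
        return set() if n.parent_id is None else {n.parent_id}
    if relation == "children":
        return tax.children(scp_id)
    if relation == "siblings":
        return tax.siblings(scp_id)
    if relation == "grandchildren":
        return tax.grandchildren(scp_id)
    return tax.level_members(n.level) - {scp_id}


# ---------------------------------------------------------------------------
# Gene-SCP association table
# ---------------------------------------------------------------------------


class GeneSCPTable:
    """The populated ontology: one row per (gene, SCP) association.

    Columns: gene, scp_id, raw_count, adjusted_count, norm_count,
    p_same_level, p_children_set, rank, label, origin.  Gene symbols are
    case-preserved but treated case-insensitively for uniqueness.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        for col in ASSOC_COLUMNS:
            if col not in df.columns:
                if col in ("label",):
                    df[col] = "unlabeled"
                elif col in ("origin",):
                    df[col] = "enriched"
                else:
                    df[col] = float("nan")
        self.df = df[ASSOC_COLUMNS].reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.df
        key = df["gene"].str.upper() + "\t" + df["scp_id"].astype(str)
        dup = key[key.duplicated()]
        if len(dup):
            raise OntologyError(
                f"duplicate (gene, scp) pairs: {sorted(set(dup))[:5]}"
            )
        bad_label = set(df["label"]) - set(VALID_LABELS)
        if bad_label:
            raise OntologyError(f"malformed labels: {sorted(bad_label)}")
        bad_origin = set(df["origin"]) - set(VALID_ORIGINS)
        if bad_origin:
            raise OntologyError(f"malformed origins: {sorted(bad_origin)}")
        ranked = df.dropna(subset=["rank"])
        for scp, grp in ranked.groupby("scp_id"):
            ranks = sorted(int(r) for r in grp["rank"])
            if ranks != list(range(1, len(ranks) + 1)):
                raise OntologyError(f"SCP {scp!r}: ranks not gapless 1..N: {ranks[:10]}")
        for col in ("p_same_level", "p_children_set"):
            vals = df[col].dropna()
            if len(vals) and ((vals <= 0) | (vals > 1)).any():
                raise OntologyError(f"{col}: probabilities must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSCPTable):
            return NotImplemented
        a = self.df.sort_values(["scp_id", "gene"]).reset_index(drop=True)
        b = other.df.sort_values(["scp_id", "gene"]).reset_index(drop=True)
        return a.equals(b)

    def genes_of(self, scp_id: str) -> set[str]:
        return set(self.df.loc[self.df["scp_id"] == scp_id, "gene"])

    def gene_sets(self, tax: Taxonomy, level: int) -> dict[str, set[str]]:
        """Gene sets of every populated SCP at the given level."""
        sub = self.df[self.df["scp_id"].map(lambda s: tax.level(s) == level).astype(bool)]
        return {scp: set(g["gene"]) for scp, g in sub.groupby("scp_id")}

    def ranks_of(self, scp_id: str) -> dict[str, int]:
        sub = self.df[(self.df["scp_id"] == scp_id) & self.df["rank"].notna()]
        return {g: int(r) for g, r in zip(sub["gene"], sub["rank"])}


def load_associations(source) -> GeneSCPTable:
    """Load an association TSV; uniqueness and rank invariants re-checked."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", comment="#", dtype={"gene": str, "scp_id": str},
                         keep_default_na=False, na_values=[""])
    if "gene" not in df.columns or "scp_id" not in df.columns:
        raise OntologyError("association table requires at least gene and scp_id columns")
    if "label" in df.columns:
        df["label"] = df["label"].fillna("unlabeled")
    if "origin" in df.columns:
        df["origin"] = df["origin"].fillna("enriched")
    return GeneSCPTable(df)


def save_associations(table: GeneSCPTable, dest, meta: Mapping[str, str] | None = None) -> None:
    _write_tsv(table.df, dest, meta)


# ---------------------------------------------------------------------------
# GMT export
# ---------------------------------------------------------------------------


def export_gmt(table: GeneSCPTable, tax: Taxonomy, level: int, dest) -> None:
    """Write one GMT line per populated SCP of ``level``.

    Line format: ``name<TAB>scp_id<TAB>gene1<TAB>gene2...``, genes ordered by
    their within-SCP rank (unranked genes follow, alphabetically).
    """
    if level not in (1, 2, 3, 4):
        raise OntologyError(f"level must be 1-4, got {level}")
    df = table.df[table.df["scp_id"].map(lambda s: tax.level(s) == level).astype(bool)]
    if df.empty:
        raise OntologyError(f"no populated SCPs at level {level}")
    lines = []
    for scp in sorted(df["scp_id"].unique()):
        grp = df[df["scp_id"] == scp]
        order = grp.assign(_r=grp["rank"].fillna(float("inf"))).sort_values(["_r", "gene"])
        genes = list(order["gene"])
        lines.append("\t".join([tax.node(scp).name, scp, *genes]))
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text, encoding="utf-8")


def parse_gmt(source) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT stream into ``{description: (name, [genes in order])}``.

    Keyed by the description field (the SCP id in our exports) because GMT
    names are free text and need not be unique identifiers.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    out: dict[str, tuple[str, list[str]]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise OntologyError(f"malformed GMT line: {line[:60]!r}")
        name, desc, genes = parts[0], parts[1], parts[2:]
        out[desc] = (name, genes)
    return out


# ---------------------------------------------------------------------------
# shared TSV writer with provenance header
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, dest, meta: Mapping[str, str] | None = None) -> None:
    buf = io.StringIO()
    if meta:
        for k, v in meta.items():
            buf.write(f"# {k}={v}\n")
    df.to_csv(buf, sep="\t", index=False)
    text = buf.getvalue()
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text, encoding="utf-8")
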