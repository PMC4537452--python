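"""Readers and writers for every tabular and graph format the pipeline touches.

Expression tables, pathway documents, interaction tables, identifier maps and
gene-set (GMT) files are all plain UTF-8 tab-separated text; networks are
exchanged as GraphML (attribute complete), SIF (topology + edge kind) or a flat
edge table.  The differential-expression criterion — the fold-change /
p-value rule applied to every measured gene and microRNA — also lives here
because every later stage consumes its verdicts.

Fold changes are signed *linear* folds: up-regulation is a value > 1, and
down-regulation is reported as the negative fold (a halving is −2.0, never
0.5).  Values strictly inside (−1, 1) are therefore malformed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionRecord",
    "CriterionSpec",
    "GENE_CRITERION",
    "MIRNA_CRITERION",
    "PathwayNode",
    "Pathway",
    "PathwayCollection",
    "InteractionRecord",
    "IdMap",
    "evaluate_criterion",
    "classify_expression",
    "read_expression_table",
    "write_expression_table",
    "read_pathway_collection",
    "write_pathway_collection",
    "read_interaction_table",
    "write_interaction_table",
    "read_id_map",
    "write_id_map",
    "read_gmt",
    "write_gmt",
    "write_network",
    "read_network_graphml",
]


class FormatError(ValueError):
    """A file does not conform to its expected layout."""


# ---------------------------------------------------------------------------
# expression records and the DE criterion
# ---------------------------------------------------------------------------

GENE = "gene"
MICRORNA = "microRNA"

UP = "up"
DOWN = "down"
NOT_DE = "not_de"
UNMEASURED = "unmeasured"


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class ExpressionRecord:
    """One measured gene or microRNA: signed linear fold change and p-value."""

    entity_id: str
    fold_change: float | None
    p_value: float | None
    entity_kind: str = GENE

    def __post_init__(self):
        if not _is_missing(self.fold_change) and abs(self.fold_change) < 1.0:
            raise ValueError(
                f"{self.entity_id}: |fold_change| must be >= 1 on the signed "
                f"linear scale, got {self.fold_change}"
            )
        if not _is_missing(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.entity_id}: p_value outside [0, 1]")


@dataclass(frozen=True)
class CriterionSpec:
    """Differential-expression rule: |FC| above a cut-off AND p below a cut-off.

    Both inequalities are strict, so boundary values fail the criterion.
    Defaults follow the usual microarray conventions for genes (1.5-fold) and
    the stricter 2-fold rule applied to microRNAs.
    """

    min_abs_fold: float = 1.5
    max_p: float = 0.05

    def __post_init__(self):
        if not self.min_abs_fold > 1.0:
            raise ValueError("min_abs_fold must exceed 1")
        if not 0.0 < self.max_p < 1.0:
            raise ValueError("max_p must lie strictly inside (0, 1)")


GENE_CRITERION = CriterionSpec(min_abs_fold=1.5, max_p=0.05)
MIRNA_CRITERION = CriterionSpec(min_abs_fold=2.0, max_p=0.05)


def evaluate_criterion(record: ExpressionRecord, spec: CriterionSpec) -> str:
    """Classify one record as ``up``, ``down`` or ``not_de``.

    A record with a missing fold change or p-value is never differentially
    expressed; a warning is logged so silent data loss is visible.
    """
    if _is_missing(record.fold_change) or _is_missing(record.p_value):
        logger.warning(
            "entity %s has missing fold change or p-value; treated as not_de",
            record.entity_id,
        )
        return NOT_DE
    if record.p_value < spec.max_p:
        if record.fold_change > spec.min_abs_fold:
            return UP
        if record.fold_change < -spec.min_abs_fold:
            return DOWN
    return NOT_DE


def classify_expression(table: pd.DataFrame, spec: CriterionSpec) -> pd.Series:
    """Vectorised :func:`evaluate_criterion` over an expression table.

    Returns a Series aligned with ``table`` holding ``up``/``down``/``not_de``.
    """
    fc = pd.to_numeric(table["fold_change"], errors="coerce")
    p = pd.to_numeric(table["p_value"], errors="coerce")
    status = pd.Series(NOT_DE, index=table.index, dtype=object)
    ok = fc.notna() & p.notna() & (p < spec.max_p)
    status[ok & (fc > spec.min_abs_fold)] = UP
    status[ok & (fc < -spec.min_abs_fold)] = DOWN
    return status


_EXPRESSION_COLUMNS = ("id", "fold_change", "p_value")
_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}


def read_expression_table(path, entity_kind: str = GENE) -> pd.DataFrame:
    """Read a tab-separated expression table (columns id, fold_change, p_value).

    Row order and the sign convention are preserved.  Missing numeric values
    (empty or ``NA``) are allowed and carried through as NaN; rows with too few
    fields or unparseable numbers raise :class:`FormatError` naming the line.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _EXPRESSION_COLUMNS if c not in header]
        if missing:
            raise FormatError(
                f"{path.name}: missing required column(s) {', '.join(missing)}"
            )
        idx = {c: header.index(c) for c in _EXPRESSION_COLUMNS}
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(header):
                raise FormatError(f"{path.name}, line {lineno}: expected "
                                  f"{len(header)} fields, got {len(fields)}")
            entity = fields[idx["id"]]
            values = {}
            for col in ("fold_change", "p_value"):
                raw = fields[idx[col]].strip()
                if raw in _MISSING_TOKENS:
                    values[col] = math.nan
                    continue
                try:
                    values[col] = float(raw)
                except ValueError:
                    raise FormatError(
                        f"{path.name}, line {lineno}: unparseable {col} "
                        f"value {raw!r}"
                    ) from None
            # run the record-level invariants (fold scale, p range)
            ExpressionRecord(entity, values["fold_change"], values["p_value"],
                             entity_kind)
            rows.append((entity, values["fold_change"], values["p_value"]))
    df = pd.DataFrame(rows, columns=["entity_id", "fold_change", "p_value"])
    df["entity_kind"] = entity_kind
    return df


def write_expression_table(table: pd.DataFrame, path) -> None:
    out = table[["entity_id", "fold_change", "p_value"]].rename(
        columns={"entity_id": "id"}
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pathway documents
# ---------------------------------------------------------------------------

NODE_GENE_PRODUCT = "gene_product"
NODE_METABOLITE = "metabolite"
NODE_PATHWAY_LINK = "pathway_link"
NODE_GROUP = "group"
NODE_LABEL = "label"

_NODE_TYPES = {
    NODE_GENE_PRODUCT,
    NODE_METABOLITE,
    NODE_PATHWAY_LINK,
    NODE_GROUP,
    NODE_LABEL,
}

CATEGORY_CANCER = "cancer"
CATEGORY_GENERAL = "general"
CATEGORY_OTHER = "other"
_CATEGORIES = {CATEGORY_CANCER, CATEGORY_GENERAL, CATEGORY_OTHER}


@dataclass(frozen=True)
class PathwayNode:
    node_id: str
    label: str = ""
    node_type: str = NODE_GENE_PRODUCT
    xref: tuple[str, str] | None = None
    members: tuple[str, ...] = ()
    unmapped: bool = False

    def __post_init__(self):
        if self.node_type not in _NODE_TYPES:
            raise ValueError(f"unknown node_type {self.node_type!r}")
        if self.node_type == NODE_GROUP and not self.members:
            raise ValueError(f"group node {self.node_id} has no members")


@dataclass(frozen=True)
class Pathway:
    """A typed pathway diagram: nodes, directed edges and group memberships."""

    pathway_id: str
    name: str
    category: str
    nodes: tuple[PathwayNode, ...]
    edges: tuple[tuple[str, str, str], ...]

    def __post_init__(self):
        if self.category not in _CATEGORIES:
            raise ValueError(
                f"{self.pathway_id}: category must be one of {sorted(_CATEGORIES)}"
            )
        self.validate()

    def validate(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"{self.pathway_id}: duplicate node id(s) {dup}")
        known = set(ids)
        for src, tgt, _ in self.edges:
            for endpoint in (src, tgt):
                if endpoint not in known:
                    raise FormatError(
                        f"{self.pathway_id}: edge endpoint {endpoint!r} is not "
                        f"a node of this pathway"
                    )
        for node in self.nodes:
            if node.node_type == NODE_GROUP:
                for m in node.members:
                    if m not in known:
                        raise FormatError(
                            f"{self.pathway_id}: group {node.node_id} references "
                            f"unknown member {m!r}"
                        )

    def gene_xref_ids(self) -> set[str]:
        """Raw xref identifiers of the gene-product nodes (GMT projection)."""
        out = set()
        for n in self.nodes:
            if n.node_type == NODE_GENE_PRODUCT:
                out.add(n.xref[1] if n.xref else n.node_id)
        return out

    def to_document(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "name": self.name,
            "category": self.category,
            "nodes": [
                {
                    "node_id": n.node_id,
                    "label": n.label,
                    "node_type": n.node_type,
                    "xref": list(n.xref) if n.xref else None,
                    "members": list(n.members),
                    "unmapped": n.unmapped,
                }
                for n in self.nodes
            ],
            "edges": [list(e) for e in self.edges],
        }

    @classmethod
    def from_document(cls, doc: Mapping) -> "Pathway":
        nodes = tuple(
            PathwayNode(
                node_id=nd["node_id"],
                label=nd.get("label", ""),
                node_type=nd.get("node_type", NODE_GENE_PRODUCT),
                xref=tuple(nd["xref"]) if nd.get("xref") else None,
                members=tuple(nd.get("members", ())),
                unmapped=bool(nd.get("unmapped", False)),
            )
            for nd in doc["nodes"]
        )
        edges = tuple((e[0], e[1], e[2]) for e in doc["edges"])
        return cls(doc["pathway_id"], doc["name"], doc["category"], nodes, edges)


@dataclass
class PathwayCollection:
    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.values())

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self.pathways[pathway_id]

    def add(self, pathway: Pathway) -> None:
        if pathway.pathway_id in self.pathways:
            raise FormatError(f"duplicate pathway_id {pathway.pathway_id!r}")
        self.pathways[pathway.pathway_id] = pathway

    def gene_sets(self) -> dict[str, set[str]]:
        return {p.pathway_id: p.gene_xref_ids() for p in self}


def read_pathway_collection(directory) -> PathwayCollection:
    """Load every ``*.json`` pathway document in a directory (sorted order)."""
    directory = Path(directory)
    docs = sorted(directory.glob("*.json"))
    if not docs:
        raise FormatError(f"no pathway documents found in {directory}")
    collection = PathwayCollection()
    for doc_path in docs:
        with doc_path.open("r", encoding="utf-8") as fh:
            doc = json.load(fh)
        collection.add(Pathway.from_document(doc))
    return collection


def write_pathway_collection(collection: PathwayCollection, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for pathway in collection:
        out = directory / f"{pathway.pathway_id}.json"
        with out.open("w", encoding="utf-8") as fh:
            json.dump(pathway.to_document(), fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def write_gmt(gene_sets: Mapping[str, tuple[str, Iterable[str]]], path) -> None:
    """Write GMT: one line per set — name, description, then the gene ids."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for name in sorted(gene_sets):
            desc, genes = gene_sets[name]
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    out: dict[str, tuple[str, set[str]]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in out:
                raise FormatError(f"GMT line {lineno}: duplicate set {name!r}")
            out[name] = (desc, set(fields[2:]))
    return out


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

KIND_PPI = "ppi"
KIND_TF = "tf_target"
KIND_MIRNA = "mirna_target"
_INTERACTION_KINDS = {KIND_PPI, KIND_TF, KIND_MIRNA}


@dataclass(frozen=True)
class InteractionRecord:
    source_id: str
    target_id: str
    kind: str
    score: float | None = None
    source_db: str = ""

    def __post_init__(self):
        if self.kind not in _INTERACTION_KINDS:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if self.kind == KIND_PPI:
            if self.score is None:
                raise ValueError("ppi interactions require a score")
            if not 0.0 <= self.score <= 1.0:
                raise ValueError(f"ppi score {self.score} outside [0, 1]")
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError(f"interaction score {self.score} outside [0, 1]")


def read_interaction_table(path, kind: str) -> pd.DataFrame:
    """Read a directed or undirected interaction table.

    PPI tables require a ``score`` column; pairs are canonicalised to
    lexicographic order and duplicates collapse to the maximum score (an
    interaction seen with several confidences is kept at its best one).
    Directed kinds (tf_target, mirna_target) keep their orientation and drop
    exact duplicate rows.
    """
    if kind not in _INTERACTION_KINDS:
        raise ValueError(f"unknown interaction kind {kind!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"source_id": str, "target_id": str})
    for col in ("source_id", "target_id"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col}")
    if kind == KIND_PPI:
        if "score" not in df.columns:
            raise FormatError(f"{path.name}: ppi table requires a score column")
        score = pd.to_numeric(df["score"], errors="raise")
        bad = score[(score < 0) | (score > 1)]
        if len(bad):
            raise FormatError(
                f"{path.name}: ppi score {bad.iloc[0]} outside [0, 1]"
            )
        a = df["source_id"].where(df["source_id"] <= df["target_id"],
                                  df["target_id"])
        b = df["target_id"].where(df["source_id"] <= df["target_id"],
                                  df["source_id"])
        out = pd.DataFrame({"source_id": a, "target_id": b, "score": score})
        out = (
            out.groupby(["source_id", "target_id"], as_index=False)["score"]
            .max()
        )
    else:
        cols = ["source_id", "target_id"]
        if "score" in df.columns:
            cols.append("score")
        out = df[cols].drop_duplicates(subset=["source_id", "target_id"])
        if "score" not in out.columns:
            out = out.assign(score=math.nan)
    out = out.sort_values(["source_id", "target_id"]).reset_index(drop=True)
    out["kind"] = kind
    if kind != KIND_PPI and "source_db" in df.columns:
        out = out.merge(
            df[["source_id", "target_id", "source_db"]].drop_duplicates(
                subset=["source_id", "target_id"]
            ),
            on=["source_id", "target_id"],
            how="left",
        )
    else:
        out["source_db"] = ""
    return out


def write_interaction_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("source_id", "target_id", "score") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# identifier mapping
# ---------------------------------------------------------------------------

@dataclass
class IdMap:
    """Deterministic (database, identifier) → unified-identifier lookup."""

    entries: dict[tuple[str, str], str] = field(default_factory=dict)

    def lookup(self, database: str, identifier: str) -> str | None:
        return self.entries.get((database, identifier))

    def add(self, database: str, identifier: str, unified: str) -> None:
        if not unified:
            raise FormatError("unified identifier must be non-empty")
        key = (database, identifier)
        existing = self.entries.get(key)
        if existing is not None and existing != unified:
            raise FormatError(
                f"conflicting mapping for {key}: {existing!r} vs {unified!r}"
            )
        self.entries[key] = unified

    def __len__(self) -> int:
        return len(self.entries)


def read_id_map(path) -> IdMap:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("database", "identifier", "unified"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col}")
    idmap = IdMap()
    for row in df.itertuples(index=False):
        idmap.add(row.database, row.identifier, row.unified)
    return idmap


def write_id_map(idmap: IdMap, path) -> None:
    rows = sorted(
        (db, ident, unified) for (db, ident), unified in idmap.entries.items()
    )
    pd.DataFrame(rows, columns=["database", "identifier", "unified"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("graphml", "sif", "edge_tsv")

# attributes whose values are sets; encoded as sorted JSON arrays in GraphML
_SET_ATTRS = {"pathway_memberships", "provenance", "members"}


def _encode_value(key: str, value):
    if key in _SET_ATTRS:
        return json.dumps(sorted(value))
    return value


def _decode_value(key: str, value):
    if key in _SET_ATTRS:
        return set(json.loads(value))
    return value


def _as_graph(network) -> nx.MultiDiGraph:
    if isinstance(network, nx.Graph):
        return network
    graph = getattr(network, "graph", None)
    if isinstance(graph, nx.Graph):
        return graph
    raise TypeError(f"cannot interpret {type(network).__name__} as a network")


def _sorted_graph(g: nx.Graph) -> nx.Graph:
    """Rebuild with nodes and edges in sorted order for deterministic output."""
    out = g.__class__()
    for node in sorted(g.nodes):
        attrs = {
            k: _encode_value(k, v)
            for k, v in sorted(g.nodes[node].items())
            if v is not None
        }
        out.add_node(node, **attrs)
    if g.is_multigraph():
        edges = sorted(
            ((u, v, str(k), d) for u, v, k, d in g.edges(keys=True, data=True)),
            key=lambda t: (t[0], t[1], t[2]),
        )
    else:
        edges = sorted(
            ((u, v, None, d) for u, v, d in g.edges(data=True)),
            key=lambda t: (t[0], t[1]),
        )
    for u, v, k, d in edges:
        attrs = {
            key: _encode_value(key, val)
            for key, val in sorted(d.items())
            if val is not None
        }
        if g.is_multigraph():
            out.add_edge(u, v, key=k, **attrs)
        else:
            out.add_edge(u, v, **attrs)
    return out


def write_network(network, path, fmt: str = "graphml") -> None:
    """Write a network deterministically (nodes and edges sorted by id).

    ``graphml`` keeps every node/edge attribute; ``sif`` keeps topology plus
    the edge kind; ``edge_tsv`` is a flat edge table with kind, score and
    provenance columns.
    """
    if fmt not in NETWORK_FORMATS:
        raise ValueError(
            f"unknown network format {fmt!r}; supported: {', '.join(NETWORK_FORMATS)}"
        )
    g = _as_graph(network)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(_sorted_graph(g), path, named_key_ids=True)
        return
    rows = []
    for u, v, d in g.edges(data=True):
        kind = d.get("edge_kind", d.get("kind", "edge"))
        rows.append((u, kind, v, d))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with path.open("w", encoding="utf-8") as fh:
        if fmt == "sif":
            for u, kind, v, _ in rows:
                fh.write(f"{u}\t{kind}\t{v}\n")
        else:
            fh.write("source\tkind\ttarget\tscore\tprovenance\n")
            for u, kind, v, d in rows:
                score = d.get("score")
                prov = ",".join(sorted(d.get("provenance", ())))
                fh.write(
                    f"{u}\t{kind}\t{v}\t"
                    f"{'' if score is None else score}\t{prov}\n"
                )


def read_network_graphml(path) -> nx.MultiDiGraph:
    """Read a GraphML file written by :func:`write_network`, decoding set attrs."""
    g = nx.read_graphml(Path(path), force_multigraph=True)
    out = nx.MultiDiGraph()
    for node, attrs in g.nodes(data=True):
        out.add_node(node, **{k: _decode_value(k, v) for k, v in attrs.items()})
    for u, v, k, d in g.edges(keys=True, data=True):
        out.add_edge(u, v, key=k,
                     **{key: _decode_value(key, val) for key, val in d.items()})
    return out
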