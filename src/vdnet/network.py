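"""Building the integrated pathway network.

Selected pathways are identifier-unified, merged into one graph keyed by the
unified gene identifier, scanned for *linking nodes* (elements shared by two
or more pathways, which stitch the pathways together), and finally extended
with scored protein–protein interactions and transcription-factor→target
interactions so that differentially expressed first neighbours of pathway
genes join the network.

Node identity: gene products live in the plain unified-identifier namespace;
metabolites are prefixed ``met:``; pathway-link nodes ``pw:``; group/complex
nodes are pathway-local (``grp:<pathway>:<node>``) and never unify with genes.
PPI edges are undirected (stored once, endpoints in lexicographic order);
TF→target and microRNA→target edges keep their direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import pandas as pd

from . import io as vio

logger = logging.getLogger(__name__)

__all__ = [
    "IntegratedNetwork",
    "ORIGIN_PATHWAY",
    "ORIGIN_PPI",
    "ORIGIN_TF",
    "ORIGIN_MIRNA",
    "unify_identifiers",
    "merge_pathways",
    "linking_nodes",
    "annotate_expression",
    "extend_network",
    "network_summary",
]

ORIGIN_PATHWAY = "pathway"
ORIGIN_PPI = "ppi_extension"
ORIGIN_TF = "tf_extension"
ORIGIN_MIRNA = "mirna_overlay"

EDGE_PATHWAY = "pathway_edge"


class IntegratedNetwork:
    """A merged multi-pathway graph with typed nodes and provenance-tagged edges.

    Thin wrapper around a :class:`networkx.MultiDiGraph`.  Undirected edge
    kinds (pathway edges without inherent direction are still stored as drawn;
    PPI edges are canonicalised) carry ``directed=False`` and are expanded
    symmetrically by :meth:`undirected`.
    """

    def __init__(self, graph: nx.MultiDiGraph | None = None):
        self.graph = graph if graph is not None else nx.MultiDiGraph()

    # -- container basics ---------------------------------------------------
    def __contains__(self, node_id: str) -> bool:
        return node_id in self.graph

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "IntegratedNetwork":
        g = nx.MultiDiGraph()
        for node, attrs in self.graph.nodes(data=True):
            g.add_node(node, **{k: (set(v) if isinstance(v, set) else v)
                                for k, v in attrs.items()})
        for u, v, k, d in self.graph.edges(keys=True, data=True):
            g.add_edge(u, v, key=k,
                       **{key: (set(val) if isinstance(val, set) else val)
                          for key, val in d.items()})
        return IntegratedNetwork(g)

    def undirected(self) -> nx.Graph:
        """Simple undirected projection, used for connectivity questions."""
        return nx.Graph(self.graph)

    def component_count(self) -> int:
        if self.graph.number_of_nodes() == 0:
            return 0
        return nx.number_connected_components(self.undirected())

    def gene_nodes(self) -> list[str]:
        return [
            n for n, d in self.graph.nodes(data=True)
            if d.get("node_type") == vio.NODE_GENE_PRODUCT
        ]

    # -- node/edge insertion ------------------------------------------------
    def add_pathway_node(self, node_id: str, label: str, node_type: str,
                         pathway_id: str, unmapped: bool = False,
                         members=()) -> None:
        if node_id in self.graph:
            self.graph.nodes[node_id]["pathway_memberships"].add(pathway_id)
            return
        attrs = dict(
            label=label,
            node_type=node_type,
            origin=ORIGIN_PATHWAY,
            pathway_memberships={pathway_id},
            de_status=vio.UNMEASURED,
            unmapped=unmapped,
        )
        if members:
            attrs["members"] = set(members)
        self.graph.add_node(node_id, **attrs)

    def add_extension_node(self, node_id: str, origin: str, de_status: str,
                           label: str = "") -> None:
        if node_id in self.graph:
            return
        self.graph.add_node(
            node_id,
            label=label or node_id,
            node_type=vio.NODE_GENE_PRODUCT,
            origin=origin,
            pathway_memberships=set(),
            de_status=de_status,
            unmapped=False,
        )

    def add_edge(self, u: str, v: str, edge_kind: str, edge_type: str = "",
                 provenance=(), score: float | None = None,
                 directed: bool = True) -> None:
        if not directed and v < u:
            u, v = v, u
        key = f"{edge_kind}:{edge_type}"
        if self.graph.has_edge(u, v, key):
            self.graph[u][v][key]["provenance"].update(provenance)
            if score is not None:
                old = self.graph[u][v][key].get("score")
                self.graph[u][v][key]["score"] = (
                    score if old is None else max(old, score)
                )
            return
        self.graph.add_edge(
            u, v, key=key,
            edge_kind=edge_kind, edge_type=edge_type,
            provenance=set(provenance), score=score, directed=directed,
        )

    # -- serialisation ------------------------------------------------------
    def write(self, path, fmt: str = "graphml") -> None:
        vio.write_network(self.graph, path, fmt)

    @classmethod
    def from_graphml(cls, path) -> "IntegratedNetwork":
        g = vio.read_network_graphml(path)
        for _, attrs in g.nodes(data=True):
            attrs.setdefault("pathway_memberships", set())
        return cls(g)

    def equals(self, other: "IntegratedNetwork") -> bool:
        return nx.utils.graphs_equal(self.graph, other.graph)


# ---------------------------------------------------------------------------
# identifier unification
# ---------------------------------------------------------------------------

def _unified_node_id(node: vio.PathwayNode, pathway_id: str,
                     idmap: vio.IdMap | None) -> tuple[str, bool]:
    """Return (namespaced unified id, unmapped flag) for a pathway node."""
    if node.node_type == vio.NODE_GENE_PRODUCT:
        if node.xref and idmap is not None:
            unified = idmap.lookup(*node.xref)
            if unified is not None:
                return unified, False
        return (node.xref[1] if node.xref else node.node_id), idmap is not None
    if node.node_type == vio.NODE_METABOLITE:
        if node.xref and idmap is not None:
            unified = idmap.lookup(*node.xref)
            if unified is not None:
                return f"met:{unified}", False
        return f"met:{node.xref[1] if node.xref else node.node_id}", idmap is not None
    if node.node_type == vio.NODE_PATHWAY_LINK:
        ref = node.xref[1] if node.xref else (node.label or node.node_id)
        return f"pw:{ref}", False
    if node.node_type == vio.NODE_GROUP:
        return f"grp:{pathway_id}:{node.node_id}", False
    return f"lbl:{pathway_id}:{node.node_id}", False


def unify_identifiers(pathway: vio.Pathway, idmap: vio.IdMap | None) -> vio.Pathway:
    """Rewrite a pathway onto unified identifiers.

    Gene-product and metabolite nodes whose xref resolves through the map take
    the unified id; unresolved nodes keep their original identifier and are
    flagged ``unmapped``.  Nodes of one pathway that unify to the same id are
    collapsed, their edges merged (self-loops produced by collapsing are
    dropped).
    """
    rename: dict[str, str] = {}
    merged: dict[str, vio.PathwayNode] = {}
    for node in pathway.nodes:
        new_id, unmapped = _unified_node_id(node, pathway.pathway_id, idmap)
        rename[node.node_id] = new_id
        if new_id not in merged:
            merged[new_id] = replace(node, node_id=new_id, unmapped=unmapped)

    # rewrite group membership lists onto the new namespace
    final_nodes = []
    for node in merged.values():
        if node.members:
            members = tuple(sorted({rename[m] for m in node.members}))
            node = replace(node, members=members)
        final_nodes.append(node)

    edges = []
    seen = set()
    for src, tgt, etype in pathway.edges:
        edge = (rename[src], rename[tgt], etype)
        if edge[0] == edge[1]:
            continue  # collapse artefact
        if edge not in seen:
            seen.add(edge)
            edges.append(edge)

    return vio.Pathway(
        pathway_id=pathway.pathway_id,
        name=pathway.name,
        category=pathway.category,
        nodes=tuple(final_nodes),
        edges=tuple(edges),
    )


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_pathways(pathways) -> IntegratedNetwork:
    """Union a list of identifier-unified pathways into one network.

    Nodes are keyed by unified id; a node contributed by several pathways
    records all of them in ``pathway_memberships``.  Edges with identical
    endpoints and type collapse to one edge whose provenance lists every
    contributing pathway.
    """
    pathways = list(pathways)
    if not pathways:
        raise ValueError("merge_pathways requires at least one pathway")
    net = IntegratedNetwork()
    for pathway in sorted(pathways, key=lambda p: p.pathway_id):
        for node in pathway.nodes:
            net.add_pathway_node(
                node.node_id, node.label or node.node_id, node.node_type,
                pathway.pathway_id, unmapped=node.unmapped,
                members=node.members,
            )
        for src, tgt, etype in pathway.edges:
            net.add_edge(src, tgt, EDGE_PATHWAY, etype,
                         provenance={pathway.pathway_id}, directed=True)
    return net


def linking_nodes(net: IntegratedNetwork) -> pd.DataFrame:
    """Nodes present in two or more pathways, with their membership counts.

    Sorted by membership count descending, then node id — these are the
    elements that link the merged pathways to each other.
    """
    rows = []
    for node, attrs in net.graph.nodes(data=True):
        memberships = attrs.get("pathway_memberships", set())
        if len(memberships) >= 2:
            rows.append(
                {
                    "node_id": node,
                    "label": attrs.get("label", node),
                    "node_type": attrs.get("node_type", ""),
                    "n_pathways": len(memberships),
                    "pathways": ",".join(sorted(memberships)),
                }
            )
    df = pd.DataFrame(
        rows, columns=["node_id", "label", "node_type", "n_pathways", "pathways"]
    )
    if len(df):
        df = df.sort_values(
            ["n_pathways", "node_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# expression annotation and extension
# ---------------------------------------------------------------------------

def annotate_expression(net: IntegratedNetwork, expression: pd.DataFrame,
                        criterion: vio.CriterionSpec = vio.GENE_CRITERION) -> None:
    """Attach de_status (and fold change / p) to matching gene nodes in place."""
    status = vio.classify_expression(expression, criterion)
    by_gene = {
        g: (s, fc, p)
        for g, s, fc, p in zip(
            expression["entity_id"], status,
            expression["fold_change"], expression["p_value"],
        )
    }
    for node, attrs in net.graph.nodes(data=True):
        if attrs.get("node_type") != vio.NODE_GENE_PRODUCT:
            continue
        hit = by_gene.get(node)
        if hit is None:
            attrs["de_status"] = vio.UNMEASURED
        else:
            attrs["de_status"] = hit[0]
            attrs["fold_change"] = float(hit[1])
            attrs["p_value"] = float(hit[2])


def extend_network(
    net: IntegratedNetwork,
    ppi: pd.DataFrame,
    tf: pd.DataFrame,
    expression: pd.DataFrame,
    criterion: vio.CriterionSpec = vio.GENE_CRITERION,
    score_min: float = 0.4,
) -> IntegratedNetwork:
    """Add differentially expressed first neighbours from PPI and TF tables.

    A new node joins the network iff it is differentially expressed under the
    criterion and interacts with a gene already in the (pre-extension)
    network — through a PPI edge scoring strictly above ``score_min``, or any
    TF→target edge.  PPI candidates are admitted first; TF candidates count as
    TF-origin only if still new.  All qualifying edges whose two endpoints end
    up in the network are added, including interactions among pre-existing
    nodes, so downstream module search can use them.
    """
    out = net.copy()
    status = vio.classify_expression(expression, criterion)
    de_status = {
        g: s for g, s in zip(expression["entity_id"], status) if s != vio.NOT_DE
    }
    base_genes = set(out.gene_nodes())

    def admit(cands: pd.DataFrame, origin: str) -> None:
        for a, b in zip(cands["source_id"], cands["target_id"]):
            for candidate, anchor in ((a, b), (b, a)):
                if candidate in out.graph or anchor not in base_genes:
                    continue
                s = de_status.get(candidate)
                if s is not None:
                    out.add_extension_node(candidate, origin, s)

    strong_ppi = ppi[ppi["score"] > score_min]
    admit(strong_ppi, ORIGIN_PPI)
    admit(tf, ORIGIN_TF)

    present = set(out.graph.nodes)
    for row in strong_ppi.itertuples(index=False):
        if row.source_id in present and row.target_id in present:
            out.add_edge(row.source_id, row.target_id, vio.KIND_PPI,
                         provenance={row.source_db or "ppi"},
                         score=float(row.score), directed=False)
    for row in tf.itertuples(index=False):
        if row.source_id in present and row.target_id in present:
            out.add_edge(row.source_id, row.target_id, vio.KIND_TF,
                         provenance={row.source_db or "tf"}, directed=True)
    annotate_expression(out, expression, criterion)
    return out


def network_summary(
    net: IntegratedNetwork,
    expression: pd.DataFrame | None = None,
    criterion: vio.CriterionSpec = vio.GENE_CRITERION,
) -> dict:
    """Node/edge counts by origin, type and DE status, plus DE coverage.

    DE coverage is the fraction of all differentially expressed genes in the
    expression table that appear as nodes of the network.
    """
    by_origin: dict[str, int] = {}
    by_status: dict[str, int] = {}
    by_type: dict[str, int] = {}
    for _, attrs in net.graph.nodes(data=True):
        by_origin[attrs.get("origin", "?")] = by_origin.get(attrs.get("origin", "?"), 0) + 1
        by_type[attrs.get("node_type", "?")] = by_type.get(attrs.get("node_type", "?"), 0) + 1
        if attrs.get("node_type") == vio.NODE_GENE_PRODUCT:
            s = attrs.get("de_status", vio.UNMEASURED)
            by_status[s] = by_status.get(s, 0) + 1
    summary = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "nodes_by_origin": dict(sorted(by_origin.items())),
        "gene_nodes_by_de_status": dict(sorted(by_status.items())),
        "nodes_by_type": dict(sorted(by_type.items())),
        "n_components": net.component_count(),
    }
    if expression is not None:
        status = vio.classify_expression(expression, criterion)
        de_genes = set(expression.loc[status != vio.NOT_DE, "entity_id"])
        in_net = {g for g in de_genes if g in net.graph}
        if not de_genes:
            logger.warning("expression table has no DE genes; coverage = 0")
            coverage = 0.0
        else:
            coverage = len(in_net) / len(de_genes)
        summary.update(
            n_de_total=len(de_genes),
            n_de_in_network=len(in_net),
            de_coverage=coverage,
        )
    return summary
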