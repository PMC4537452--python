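"""Identifier unification, pathway merging and first-neighbour extension."""

import pandas as pd
import pytest

import vdnet.io as vio
from vdnet.network import (
    IntegratedNetwork,
    ORIGIN_PATHWAY,
    ORIGIN_PPI,
    ORIGIN_TF,
    annotate_expression,
    extend_network,
    linking_nodes,
    merge_pathways,
    network_summary,
    unify_identifiers,
)


def _idmap(entries):
    idmap = vio.IdMap()
    for db, ident, unified in entries:
        idmap.add(db, ident, unified)
    return idmap


def _gene_pathway(pid, genes, category="general", extra_edges=()):
    nodes = tuple(
        vio.PathwayNode(f"n{i}", g, xref=("GENE", g))
        for i, g in enumerate(genes)
    )
    chain = tuple((f"n{i}", f"n{i+1}", "relation") for i in range(len(genes) - 1))
    return vio.Pathway(pid, pid, category, nodes, chain + tuple(extra_edges))


def _identity_map(genes):
    return _idmap([("GENE", g, g) for g in genes])


class TestUnifyIdentifiers:
    def test_mapped_node_takes_unified_id(self):
        pw = vio.Pathway(
            "WP1", "p", "general",
            (vio.PathwayNode("n1", "p53", xref=("Entrez", "7157")),), ()
        )
        out = unify_identifiers(pw, _idmap([("Entrez", "7157", "TP53")]))
        assert out.nodes[0].node_id == "TP53"
        assert not out.nodes[0].unmapped

    def test_unmapped_node_keeps_id_and_flag(self):
        pw = vio.Pathway(
            "WP1", "p", "general",
            (vio.PathwayNode("n1", "x", xref=("Entrez", "999")),), ()
        )
        out = unify_identifiers(pw, _idmap([("Entrez", "7157", "TP53")]))
        assert out.nodes[0].node_id == "999"
        assert out.nodes[0].unmapped

    def test_collapse_merges_edges(self):
        # a 3-node toy where two nodes unify to CDK2: their edges merge
        pw = vio.Pathway(
            "WP1", "p", "general",
            (
                vio.PathwayNode("n1", "cdk2a", xref=("Entrez", "1017")),
                vio.PathwayNode("n2", "cdk2b", xref=("Ensembl", "ENSG123")),
                vio.PathwayNode("n3", "tp53", xref=("Entrez", "7157")),
            ),
            (("n1", "n3", "relation"), ("n3", "n2", "relation")),
        )
        out = unify_identifiers(pw, _idmap([
            ("Entrez", "1017", "CDK2"),
            ("Ensembl", "ENSG123", "CDK2"),
            ("Entrez", "7157", "TP53"),
        ]))
        assert {n.node_id for n in out.nodes} == {"CDK2", "TP53"}
        assert set(out.edges) == {("CDK2", "TP53", "relation"),
                                  ("TP53", "CDK2", "relation")}

    def test_metabolites_prefixed_and_groups_pathway_local(self):
        pw = vio.Pathway(
            "WP1", "p", "general",
            (
                vio.PathwayNode("n1", "g", xref=("GENE", "G1")),
                vio.PathwayNode("m1", "atp", vio.NODE_METABOLITE,
                                xref=("CHEM", "ATP")),
                vio.PathwayNode("g1", "cplx", vio.NODE_GROUP, members=("n1",)),
            ),
            (),
        )
        out = unify_identifiers(pw, _idmap([("GENE", "G1", "G1"),
                                            ("CHEM", "ATP", "ATP")]))
        ids = {n.node_id for n in out.nodes}
        assert ids == {"G1", "met:ATP", "grp:WP1:g1"}
        group = next(n for n in out.nodes if n.node_type == vio.NODE_GROUP)
        assert group.members == ("G1",)


class TestMergePathways:
    def test_shared_node_counts_once(self):
        a = _gene_pathway("WPA", ["G1", "G2", "G3", "G4", "G5"])
        b = _gene_pathway("WPB", ["G5", "G6", "G7", "G8", "G9"])
        idmap = _identity_map([f"G{i}" for i in range(1, 10)])
        net = merge_pathways([unify_identifiers(p, idmap) for p in (a, b)])
        assert net.number_of_nodes() == 9
        assert net.graph.nodes["G5"]["pathway_memberships"] == {"WPA", "WPB"}

    def test_disjoint_pathways_two_components(self):
        a = _gene_pathway("WPA", ["G1", "G2"])
        b = _gene_pathway("WPB", ["G3", "G4"])
        idmap = _identity_map(["G1", "G2", "G3", "G4"])
        net = merge_pathways([unify_identifiers(p, idmap) for p in (a, b)])
        assert net.component_count() == 2

    def test_merge_single_pathway_is_identity(self):
        p = _gene_pathway("WPA", ["G1", "G2", "G3"])
        unified = unify_identifiers(p, _identity_map(["G1", "G2", "G3"]))
        net = merge_pathways([unified])
        assert set(net.graph.nodes) == {n.node_id for n in unified.nodes}
        assert net.number_of_edges() == len(unified.edges)

    def test_merge_idempotent(self):
        pws = [
            _gene_pathway("WPA", ["G1", "G2", "G3"]),
            _gene_pathway("WPB", ["G2", "G4"]),
        ]
        idmap = _identity_map(["G1", "G2", "G3", "G4"])
        unified = [unify_identifiers(p, idmap) for p in pws]
        assert merge_pathways(unified).equals(merge_pathways(unified))

    def test_shared_edge_provenance_union(self):
        a = _gene_pathway("WPA", ["G1", "G2"])
        b = _gene_pathway("WPB", ["G1", "G2"])
        idmap = _identity_map(["G1", "G2"])
        net = merge_pathways([unify_identifiers(p, idmap) for p in (a, b)])
        (_, _, data), = net.graph.edges(data=True)
        assert data["provenance"] == {"WPA", "WPB"}


class TestLinkingNodes:
    def test_counts_and_order(self):
        pws = [_gene_pathway(f"WP{i}", ["HUB", f"G{i}"]) for i in range(5)]
        pws.append(_gene_pathway("WP9", ["G0", "G1"]))
        idmap = _identity_map(["HUB"] + [f"G{i}" for i in range(5)])
        net = merge_pathways([unify_identifiers(p, idmap) for p in pws])
        df = linking_nodes(net)
        assert df.iloc[0]["node_id"] == "HUB"
        assert df.iloc[0]["n_pathways"] == 5
        assert set(df["node_id"]) == {"HUB", "G0", "G1"}

    def test_no_linking_nodes(self):
        net = merge_pathways([
            unify_identifiers(_gene_pathway("WPA", ["G1", "G2"]),
                              _identity_map(["G1", "G2"]))
        ])
        assert len(linking_nodes(net)) == 0


def _expression(rows):
    return pd.DataFrame(rows, columns=["entity_id", "fold_change", "p_value"])


def _base_net():
    p = _gene_pathway("WPA", ["G1", "G2", "G3"])
    return merge_pathways([unify_identifiers(p, _identity_map(["G1", "G2", "G3"]))])


class TestExtendNetwork:
    def _tables(self, ppi_rows, tf_rows=()):
        ppi = pd.DataFrame(ppi_rows,
                           columns=["source_id", "target_id", "score"])
        ppi["kind"] = vio.KIND_PPI
        ppi["source_db"] = "string"
        tf = pd.DataFrame(list(tf_rows) or None,
                          columns=["source_id", "target_id"])
        tf["score"] = float("nan")
        tf["kind"] = vio.KIND_TF
        tf["source_db"] = "encode"
        return ppi, tf

    def test_score_threshold_strict(self):
        expr = _expression([("G1", 1.1, 0.9), ("X1", 2.0, 0.01),
                            ("X2", 2.0, 0.01)])
        ppi, tf = self._tables([("G1", "X1", 0.39), ("G1", "X2", 0.41)])
        out = extend_network(_base_net(), ppi, tf, expr)
        assert "X2" in out.graph and "X1" not in out.graph
        assert out.graph.nodes["X2"]["origin"] == ORIGIN_PPI

    def test_non_de_neighbour_excluded(self):
        expr = _expression([("X1", 1.2, 0.9)])
        ppi, tf = self._tables([("G1", "X1", 0.9)])
        out = extend_network(_base_net(), ppi, tf, expr)
        assert "X1" not in out.graph

    def test_tf_edge_keeps_direction_and_origin(self):
        expr = _expression([("X1", -2.0, 0.01)])
        ppi, tf = self._tables([], [("X1", "G1")])
        out = extend_network(_base_net(), ppi, tf, expr)
        assert out.graph.nodes["X1"]["origin"] == ORIGIN_TF
        assert out.graph.has_edge("X1", "G1")
        assert not out.graph.has_edge("G1", "X1")

    def test_ppi_takes_precedence_over_tf(self):
        expr = _expression([("X1", 2.0, 0.01)])
        ppi, tf = self._tables([("G1", "X1", 0.8)], [("X1", "G2")])
        out = extend_network(_base_net(), ppi, tf, expr)
        assert out.graph.nodes["X1"]["origin"] == ORIGIN_PPI
        # the TF edge among now-present nodes is still added
        assert out.graph.has_edge("X1", "G2")

    def test_extension_is_first_neighbour_only(self):
        # X2 touches only the new node X1, never the original network
        expr = _expression([("X1", 2.0, 0.01), ("X2", 2.0, 0.01)])
        ppi, tf = self._tables([("G1", "X1", 0.9), ("X1", "X2", 0.9)])
        out = extend_network(_base_net(), ppi, tf, expr)
        assert "X1" in out.graph and "X2" not in out.graph

    def test_extension_never_removes_and_components_never_increase(self):
        expr = _expression([("X1", 2.0, 0.01)])
        ppi, tf = self._tables([("G1", "X1", 0.9)])
        base = _base_net()
        out = extend_network(base, ppi, tf, expr)
        assert set(base.graph.nodes) <= set(out.graph.nodes)
        assert out.component_count() <= base.component_count()

    def test_every_extension_node_touches_a_pathway_node(self, bundle):
        from vdnet.pipeline import PipelineConfig, run_pipeline  # noqa: F401

        bundle_dir, _ = bundle
        expr = vio.read_expression_table(bundle_dir / "genes.tsv")
        coll = vio.read_pathway_collection(bundle_dir / "pathways")
        idmap = vio.read_id_map(bundle_dir / "idmap.tsv")
        from vdnet.network import unify_identifiers as unify

        net = merge_pathways([unify(p, idmap) for p in list(coll)[:5]])
        ppi = vio.read_interaction_table(bundle_dir / "ppi.tsv", vio.KIND_PPI)
        tf = vio.read_interaction_table(bundle_dir / "tf.tsv", vio.KIND_TF)
        out = extend_network(net, ppi, tf, expr)
        pathway_nodes = {
            n for n, d in out.graph.nodes(data=True)
            if d["origin"] == ORIGIN_PATHWAY
        }
        und = out.undirected()
        for node, data in out.graph.nodes(data=True):
            if data["origin"] in (ORIGIN_PPI, ORIGIN_TF):
                assert any(nb in pathway_nodes for nb in und.neighbors(node))


class TestNetworkSummary:
    def test_coverage_toy(self):
        net = _base_net()
        expr = _expression([("G1", 2.0, 0.01), ("Z9", -2.0, 0.01)])
        annotate_expression(net, expr)
        summary = network_summary(net, expr)
        assert summary["de_coverage"] == 0.5
        assert summary["n_de_total"] == 2

    def test_no_de_genes_warns_zero(self, caplog):
        net = _base_net()
        expr = _expression([("G1", 1.1, 0.9)])
        with caplog.at_level("WARNING"):
            summary = network_summary(net, expr)
        assert summary["de_coverage"] == 0.0

    def test_empty_network(self):
        summary = network_summary(IntegratedNetwork())
        assert summary["n_nodes"] == 0 and summary["n_components"] == 0

    def test_coverage_monotone_under_extension(self):
        expr = _expression([("G1", 2.0, 0.01), ("X1", 2.0, 0.01)])
        base = _base_net()
        annotate_expression(base, expr)
        ppi = pd.DataFrame([("G1", "X1", 0.9)],
                           columns=["source_id", "target_id", "score"])
        ppi["kind"] = vio.KIND_PPI
        ppi["source_db"] = ""
        tf = pd.DataFrame(columns=["source_id", "target_id", "score", "kind",
                                   "source_db"])
        out = extend_network(base, ppi, tf, expr)
        assert (network_summary(out, expr)["de_coverage"]
                >= network_summary(base, expr)["de_coverage"])
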