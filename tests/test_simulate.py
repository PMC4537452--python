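"""The synthetic-data generator: planted signals, invariants, determinism."""

import json

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import vdnet.io as vio
from vdnet.simulate import (
    ScenarioConfig,
    generate_annotations,
    generate_expression,
    generate_interactome,
    generate_pathway_collection,
    generate_scenario,
    generate_target_linksets,
    load_manifest,
)

GENES = [f"G{i:04d}" for i in range(1, 2001)]


class TestConfig:
    def test_defaults_valid(self):
        ScenarioConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"de_fraction": 0.0},
            {"n_genes": 10, "de_fraction": 0.05},  # fewer than one DE gene
            {"planted_de_enrichment": 0.04},       # below background rate
            {"n_planted_pathways": 99},
            {"n_de_mirnas": 99},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioConfig(**kwargs)


class TestExpression:
    def test_realised_de_fraction_in_band(self):
        cfg = ScenarioConfig(seed=0)
        genes_df, _, _ = generate_expression(cfg)
        frac = (vio.classify_expression(genes_df, vio.GENE_CRITERION)
                != vio.NOT_DE).mean()
        assert 0.04 <= frac <= 0.06

    def test_truth_lists_match_criterion(self):
        cfg = ScenarioConfig(seed=1)
        genes_df, _, truth = generate_expression(cfg)
        status = vio.classify_expression(genes_df, vio.GENE_CRITERION)
        by_gene = dict(zip(genes_df["entity_id"], status))
        assert all(by_gene[g] == vio.UP for g in truth["de_genes_up"])
        assert all(by_gene[g] == vio.DOWN for g in truth["de_genes_down"])

    def test_de_mirnas_pass_mirna_criterion_up(self):
        cfg = ScenarioConfig(seed=2)
        _, mirnas_df, truth = generate_expression(cfg)
        status = vio.classify_expression(mirnas_df, vio.MIRNA_CRITERION)
        by_m = dict(zip(mirnas_df["entity_id"], status))
        assert len(truth["de_mirnas"]) == cfg.n_de_mirnas
        assert all(by_m[m] == vio.UP for m in truth["de_mirnas"])

    def test_seed_determinism(self):
        cfg = ScenarioConfig(seed=3)
        a = generate_expression(cfg)[0]
        b = generate_expression(cfg)[0]
        pd.testing.assert_frame_equal(a, b)


class TestPathways:
    def test_zero_overlap_means_disjoint(self):
        cfg = ScenarioConfig(seed=4, n_pathways=5, pathway_size_range=(5, 10),
                             pathway_overlap=0.0, n_planted_pathways=1)
        coll, _, _ = generate_pathway_collection(cfg, GENES, GENES[:100])
        seen = set()
        for genes in coll.gene_sets().values():
            raw = {g.replace("ALIAS_", "") for g in genes}
            assert not (seen & raw)
            seen |= raw

    def test_planted_pathways_enriched(self):
        cfg = ScenarioConfig(seed=5)
        genes_df, _, truth = generate_expression(cfg)
        de = set(truth["de_genes_up"] + truth["de_genes_down"])
        coll, planted, alias_of = generate_pathway_collection(
            cfg, list(genes_df["entity_id"]), sorted(de)
        )

        def de_frac(pid):
            members = {g.replace("ALIAS_", "")
                       for g in coll[pid].gene_xref_ids()}
            return len(members & de) / len(members)

        planted_frac = np.mean([de_frac(p) for p in planted])
        background_frac = np.mean([
            de_frac(p.pathway_id) for p in coll
            if p.pathway_id not in set(planted)
        ])
        assert planted_frac >= 2 * max(background_frac, 1e-9)

    def test_documents_round_trip(self, tmp_path):
        cfg = ScenarioConfig(seed=6, n_pathways=4, pathway_size_range=(5, 10),
                             n_planted_pathways=1)
        coll, _, _ = generate_pathway_collection(cfg, GENES[:300], GENES[:20])
        vio.write_pathway_collection(coll, tmp_path / "pw")
        loaded = vio.read_pathway_collection(tmp_path / "pw")
        assert len(loaded) == 4
        for p in coll:
            assert loaded[p.pathway_id] == p


class TestInteractome:
    def test_planted_module_connected_above_threshold(self):
        cfg = ScenarioConfig(seed=7)
        module = GENES[10:25]
        ppi, _ = generate_interactome(cfg, GENES, module)
        g = nx.Graph()
        strong = ppi[ppi["score"] > 0.4]
        g.add_edges_from(zip(strong["source_id"], strong["target_id"]))
        assert nx.is_connected(g.subgraph(module))

    def test_mean_degree_near_target(self):
        cfg = ScenarioConfig(seed=8)
        ppi, _ = generate_interactome(cfg, GENES, GENES[:15])
        mean_degree = 2 * len(ppi) / len(GENES)
        assert abs(mean_degree - cfg.ppi_degree_mean) <= 0.25 * cfg.ppi_degree_mean

    def test_scores_in_unit_interval(self):
        cfg = ScenarioConfig(seed=9)
        ppi, _ = generate_interactome(cfg, GENES[:500], GENES[:10])
        assert ppi["score"].between(0, 1).all()


class TestLinksets:
    def test_predicted_much_larger_and_overlap_in_band(self):
        cfg = ScenarioConfig(seed=10)
        de_mirnas = [f"hsa-miR-sim-{i:03d}" for i in (1, 2, 3)]
        val, pred = generate_target_linksets(cfg, GENES, GENES[:200], de_mirnas)
        assert len(pred.interactions) > 3 * len(val.interactions)
        dual = set(val.interactions) & set(pred.interactions)
        ratio = len(dual) / len(val.interactions)
        assert abs(ratio - cfg.linkset_overlap_fraction) \
            <= 0.3 * cfg.linkset_overlap_fraction + 0.02

    def test_every_de_mirna_present(self):
        cfg = ScenarioConfig(seed=11)
        de_mirnas = [f"hsa-miR-sim-{i:03d}" for i in (4, 5)]
        val, pred = generate_target_linksets(cfg, GENES, GENES[:50], de_mirnas)
        regs = val.regulators | pred.regulators
        assert set(de_mirnas) <= regs


class TestAnnotations:
    def test_planted_term_strongly_enriched(self):
        from vdnet.grouping import annotation_universe, enrich_terms

        cfg = ScenarioConfig(seed=12)
        module = GENES[:15]
        terms, planted_id = generate_annotations(cfg, GENES, module)
        universe = annotation_universe(terms)
        query = [g for g in module if g in universe]
        df = enrich_terms(query, terms, universe).set_index("term_id")
        assert df.loc[planted_id, "p"] < 1e-4

    def test_family_structure_visible_in_kappa(self):
        from vdnet.grouping import annotation_universe, kappa_stat

        cfg = ScenarioConfig(seed=13)
        terms, _ = generate_annotations(cfg, GENES, GENES[:15])
        universe = annotation_universe(terms)
        fam0 = [t for t in terms if t.term_name.startswith("family 0")]
        fam1 = [t for t in terms if t.term_name.startswith("family 1")]
        within = kappa_stat(fam0[0].genes, fam0[1].genes, universe).kappa
        across = kappa_stat(fam0[0].genes, fam1[0].genes, universe).kappa
        assert within >= 0.4
        assert across < 0.4

    def test_terms_subset_of_universe(self):
        cfg = ScenarioConfig(seed=14)
        terms, _ = generate_annotations(cfg, GENES, GENES[:15])
        for t in terms:
            assert t.genes <= set(GENES)


class TestScenarioBundle:
    def test_manifest_entities_exist_and_bundle_loads(self, bundle):
        bundle_dir, manifest = bundle
        genes_df = vio.read_expression_table(bundle_dir / "genes.tsv")
        mirnas_df = vio.read_expression_table(bundle_dir / "mirnas.tsv",
                                              vio.MICRORNA)
        coll = vio.read_pathway_collection(bundle_dir / "pathways")
        vio.read_id_map(bundle_dir / "idmap.tsv")
        ppi = vio.read_interaction_table(bundle_dir / "ppi.tsv", vio.KIND_PPI)
        vio.read_interaction_table(bundle_dir / "tf.tsv", vio.KIND_TF)

        gene_ids = set(genes_df["entity_id"])
        assert set(manifest.planted_module) <= gene_ids
        assert set(manifest.de_genes_up) <= gene_ids
        assert set(manifest.planted_pathways) <= set(coll.pathways)
        assert set(manifest.de_mirnas) <= set(mirnas_df["entity_id"])
        assert ppi["score"].between(0, 1).all()

    def test_checksums_verify(self, bundle):
        import hashlib

        bundle_dir, manifest = bundle
        for fname, digest in manifest.checksums.items():
            actual = hashlib.sha256((bundle_dir / fname).read_bytes()).hexdigest()
            assert actual == digest, fname

    def test_manifest_round_trip(self, bundle):
        bundle_dir, manifest = bundle
        loaded = load_manifest(bundle_dir / "manifest.json")
        assert loaded == manifest
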