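"""Synthetic input bundles with planted ground truth.

The generator emulates the statistical structure of a vitamin-D treatment
microarray study — a filtered gene universe of which roughly 5 % is
differentially expressed (split evenly up/down), a handful of strongly
up-regulated microRNAs, a pathway collection with overlapping membership in
which a few pathways are enriched for DE genes, a scored protein interactome
and TF→target table in which one connected DE module is planted, dual-source
microRNA target linksets (predicted much larger than validated), a flat
GO-style term annotation with one term coherent with the planted module, and
a curated regulator target list.  A truth manifest records everything that
was planted so recovery can be scored.

Every operation is deterministic given the scenario seed, and every file is
written through the same formats the readers in :mod:`vdnet.io` expect, so a
generated bundle round-trips cleanly through the whole pipeline.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio

__all__ = [
    "ScenarioConfig",
    "TruthManifest",
    "generate_expression",
    "generate_pathway_collection",
    "generate_interactome",
    "generate_target_linksets",
    "generate_annotations",
    "generate_curated_targets",
    "generate_scenario",
    "load_manifest",
    "paper_scale_config",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic bundle.

    Defaults are a scaled-down rendition of the emulated study: 2000 measured
    genes with 5 % differential expression split evenly between up and down,
    60 overlapping pathways of 20–200 genes of which 8 are planted with a
    three-fold-enriched DE fraction, a scored interactome of mean degree 4
    with Beta(2,2) confidence scores, 30 microRNAs of which 9 are
    differentially expressed, and a planted connected 15-gene module.
    """

    n_genes: int = 2000
    de_fraction: float = 0.05
    up_down_split: float = 0.5
    n_pathways: int = 60
    pathway_size_range: tuple[int, int] = (20, 200)
    pathway_overlap: float = 0.1
    n_planted_pathways: int = 8
    planted_de_enrichment: float = 0.3
    ppi_degree_mean: float = 4.0
    ppi_score_beta: tuple[float, float] = (2.0, 2.0)
    n_tfs: int = 20
    n_terms: int = 100
    n_mirnas: int = 30
    n_de_mirnas: int = 9
    targets_per_mirna_range: tuple[int, int] = (10, 300)
    linkset_overlap_fraction: float = 0.1
    planted_module_size: int = 15
    alias_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_genes, self.n_pathways, self.n_planted_pathways,
                  self.n_tfs, self.n_terms, self.n_mirnas, self.n_de_mirnas,
                  self.planted_module_size)
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        for frac in (self.de_fraction, self.up_down_split,
                     self.linkset_overlap_fraction):
            if not 0.0 < frac < 1.0:
                raise ValueError("fractions must lie strictly inside (0, 1)")
        if not 0.0 <= self.pathway_overlap < 1.0:
            raise ValueError("pathway_overlap must lie in [0, 1)")
        if not self.planted_de_enrichment > self.de_fraction:
            raise ValueError("planted_de_enrichment must exceed de_fraction")
        if self.de_fraction * self.n_genes < 1:
            raise ValueError("infeasible config: fewer than one DE gene")
        if self.n_planted_pathways > self.n_pathways:
            raise ValueError("more planted pathways than pathways")
        if self.n_de_mirnas > self.n_mirnas:
            raise ValueError("more DE microRNAs than microRNAs")


def paper_scale_config(seed: int = 0) -> ScenarioConfig:
    """A study-scale preset (15000 genes, 276 pathways) for stress testing."""
    return ScenarioConfig(n_genes=15_000, n_pathways=276, seed=seed)


@dataclass
class TruthManifest:
    planted_pathways: list[str]
    planted_module: list[str]
    de_genes_up: list[str]
    de_genes_down: list[str]
    de_mirnas: list[str]
    checksums: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def load_manifest(path) -> TruthManifest:
    with Path(path).open("r", encoding="utf-8") as fh:
        return TruthManifest(**json.load(fh))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _mirna_ids(n: int) -> list[str]:
    return [f"hsa-miR-sim-{i:03d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(config: ScenarioConfig, seed: int | None = None):
    """Gene and microRNA expression tables plus the planted DE gene lists.

    DE genes draw |fold| from 1.5 + Exp(1) and p from U(0, 0.045), so both
    criteria pass with margin; non-DE genes fail the criterion through one of
    two escape routes — a sub-threshold fold with a free p, or an
    unconstrained fold with p above 0.05 — keeping the criterion genuinely
    two-dimensional.  DE microRNAs draw folds above 2 (all up-regulated, as
    in the emulated study).  Returns (genes_df, mirnas_df, truth_dict).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = _gene_ids(config.n_genes)
    n_de = int(round(config.de_fraction * config.n_genes))
    de_genes = sorted(rng.choice(genes, size=n_de, replace=False))
    n_up = int(round(config.up_down_split * n_de))
    up_genes = sorted(rng.choice(de_genes, size=n_up, replace=False))
    up_set = set(up_genes)
    down_genes = [g for g in de_genes if g not in up_set]
    de_set = set(de_genes)

    rows = []
    for g in genes:
        if g in de_set:
            fold = 1.5 + rng.exponential(1.0)
            if g not in up_set:
                fold = -fold
            p = rng.uniform(0.0, 0.05 * 0.9)
        elif rng.random() < 0.5:
            # escape route A: sub-threshold fold, any p
            fold = 1.0 + min(rng.exponential(0.2), 0.499)
            if rng.random() < 0.5:
                fold = -fold
            p = rng.uniform(0.0, 1.0)
        else:
            # escape route B: unconstrained fold, non-significant p
            fold = 1.0 + rng.exponential(0.2)
            if rng.random() < 0.5:
                fold = -fold
            p = rng.uniform(0.05, 1.0)
        rows.append((g, round(float(fold), 6), round(float(p), 8)))
    genes_df = pd.DataFrame(rows, columns=["entity_id", "fold_change", "p_value"])
    genes_df["entity_kind"] = vio.GENE

    mirnas = _mirna_ids(config.n_mirnas)
    de_mirnas = sorted(rng.choice(mirnas, size=config.n_de_mirnas, replace=False))
    de_mirna_set = set(de_mirnas)
    mrows = []
    for m in mirnas:
        if m in de_mirna_set:
            fold = 2.0 + rng.exponential(1.0)
            p = rng.uniform(0.0, 0.05 * 0.9)
        elif rng.random() < 0.5:
            fold = 1.0 + min(rng.exponential(0.3), 0.999)
            if rng.random() < 0.5:
                fold = -fold
            p = rng.uniform(0.0, 1.0)
        else:
            fold = 1.0 + rng.exponential(0.3)
            if rng.random() < 0.5:
                fold = -fold
            p = rng.uniform(0.05, 1.0)
        mrows.append((m, round(float(fold), 6), round(float(p), 8)))
    mirnas_df = pd.DataFrame(mrows, columns=["entity_id", "fold_change", "p_value"])
    mirnas_df["entity_kind"] = vio.MICRORNA

    realized = (vio.classify_expression(genes_df, vio.GENE_CRITERION)
                != vio.NOT_DE).mean()
    if abs(realized - config.de_fraction) > 0.2 * config.de_fraction:
        raise RuntimeError(
            f"realised DE fraction {realized:.4f} strays from target "
            f"{config.de_fraction:.4f}"
        )
    truth = {
        "de_genes_up": list(up_genes),
        "de_genes_down": list(down_genes),
        "de_mirnas": list(de_mirnas),
    }
    return genes_df, mirnas_df, truth


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

def _pathway_document(pid, name, category, gene_members, alias_of, rng,
                      other_pathway_ids):
    """Assemble one pathway document from its gene membership."""
    nodes = []
    for i, g in enumerate(gene_members):
        xref = ("SYN", alias_of[g]) if g in alias_of else ("GENE", g)
        nodes.append(vio.PathwayNode(
            node_id=f"n{i:04d}", label=g, node_type=vio.NODE_GENE_PRODUCT,
            xref=xref,
        ))
    n_genes = len(nodes)

    # a few metabolites, one link to another pathway, one group node
    n_met = int(rng.integers(1, 4))
    for j in range(n_met):
        met = f"M{int(rng.integers(1, 200)):03d}"
        nodes.append(vio.PathwayNode(
            node_id=f"m{j:03d}", label=met, node_type=vio.NODE_METABOLITE,
            xref=("CHEM", met),
        ))
    if other_pathway_ids:
        target = other_pathway_ids[int(rng.integers(len(other_pathway_ids)))]
        nodes.append(vio.PathwayNode(
            node_id="pl000", label=target, node_type=vio.NODE_PATHWAY_LINK,
            xref=("WP", target),
        ))
    group_size = int(min(n_genes, rng.integers(2, 5)))
    members = tuple(
        nodes[i].node_id for i in rng.choice(n_genes, group_size, replace=False)
    )
    nodes.append(vio.PathwayNode(
        node_id="grp000", label="complex", node_type=vio.NODE_GROUP,
        members=members,
    ))

    # connected random tree over all nodes plus ~20 % extra edges
    ids = [n.node_id for n in nodes]
    order = list(rng.permutation(len(ids)))
    edges = []
    for pos in range(1, len(order)):
        parent = order[int(rng.integers(pos))]
        edges.append((ids[parent], ids[order[pos]], "relation"))
    n_extra = int(0.2 * len(ids))
    for _ in range(n_extra):
        a, b = rng.choice(len(ids), 2, replace=False)
        edge = (ids[int(a)], ids[int(b)], "relation")
        if edge not in edges and (edge[1], edge[0], "relation") not in edges:
            edges.append(edge)
    return vio.Pathway(pathway_id=pid, name=name, category=category,
                       nodes=tuple(nodes), edges=tuple(edges))


def generate_pathway_collection(config: ScenarioConfig, genes, de_genes,
                                seed: int | None = None):
    """Pathway collection with overlap and planted DE-enriched pathways.

    Shared membership comes from a common gene pool sampled at the configured
    overlap fraction; with overlap 0 the pathways draw disjoint gene sets
    (an error is raised if the universe is too small for that).  Planted
    pathways take ``planted_de_enrichment`` of their genes from the DE list.
    Returns (collection, planted_ids, alias_of).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    genes = list(genes)
    de_genes = list(de_genes)
    de_set = set(de_genes)
    lo, hi = config.pathway_size_range
    if hi > len(genes):
        raise ValueError("gene universe smaller than the maximum pathway size")

    # synonym aliases so identifier unification has real work to do
    aliased = rng.choice(genes, size=int(config.alias_fraction * len(genes)),
                         replace=False)
    alias_of = {g: f"ALIAS_{g}" for g in sorted(aliased)}

    pool_size = max(20, int(0.1 * len(genes)))
    shared_pool = sorted(rng.choice(genes, size=pool_size, replace=False))

    # pathways capture only part of the DE signal: planted pathways draw
    # their DE members from half of the DE list, so the other half is
    # reachable only through the interaction-based extension
    de_pool = sorted(
        str(g) for g in
        rng.choice(de_genes, size=max(1, len(de_genes) // 2), replace=False)
    ) if de_genes else []

    pids = [f"WP{i:03d}" for i in range(1, config.n_pathways + 1)]
    planted = sorted(rng.choice(pids, size=config.n_planted_pathways,
                                replace=False))
    planted_set = set(planted)

    unused = list(rng.permutation(genes))
    collection = vio.PathwayCollection()
    for pid in pids:
        size = int(rng.integers(lo, hi + 1))
        members: list[str] = []
        if config.pathway_overlap > 0:
            n_shared = int(round(config.pathway_overlap * size))
            members += [shared_pool[i] for i in
                        rng.choice(len(shared_pool),
                                   min(n_shared, len(shared_pool)),
                                   replace=False)]
        if pid in planted_set:
            n_de = int(round(config.planted_de_enrichment * size))
            picked = rng.choice(de_pool, size=min(n_de, len(de_pool)),
                                replace=False)
            members += [g for g in picked if g not in members]
        n_rest = size - len(members)
        if config.pathway_overlap == 0:
            if len(unused) < size:
                raise ValueError(
                    "universe too small for disjoint pathways at overlap 0"
                )
            members = [unused.pop() for _ in range(size)]
        else:
            rest_pool = [g for g in genes if g not in set(members)]
            if pid in planted_set:
                rest_pool = [g for g in rest_pool if g not in de_set]
            idx = rng.choice(len(rest_pool), size=max(n_rest, 0), replace=False)
            members += [rest_pool[i] for i in idx]
        category = (vio.CATEGORY_CANCER if rng.random() < 0.4
                    else vio.CATEGORY_GENERAL)
        others = [p for p in pids if p != pid]
        collection.add(_pathway_document(
            pid, f"Synthetic pathway {pid}", category, members, alias_of,
            rng, others,
        ))
    return collection, planted, alias_of


def build_id_map(genes, alias_of) -> vio.IdMap:
    """Identity map for plain gene ids plus the synonym aliases."""
    idmap = vio.IdMap()
    for g in genes:
        idmap.add("GENE", g, g)
    for g, alias in alias_of.items():
        idmap.add("SYN", alias, g)
    return idmap


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

def generate_interactome(config: ScenarioConfig, genes, module_genes,
                         pathway_genes=None, seed: int | None = None):
    """Scored PPI table and TF→target table with a planted connected module.

    The background PPI graph is Erdős–Rényi-like with the configured mean
    degree and Beta-distributed scores.  The planted module genes are wired
    into a connected high-confidence subgraph (spanning tree plus extras,
    scores above the extension threshold) and each is anchored by one strong
    edge to a pathway gene so the module survives first-neighbour extension.
    Returns (ppi_df, tf_df).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    genes = list(genes)
    module_genes = list(module_genes)
    if not set(module_genes) <= set(genes):
        raise ValueError("planted module genes must lie in the gene universe")
    a, b = config.ppi_score_beta

    n_edges = int(round(config.ppi_degree_mean * len(genes) / 2))
    edge_scores: dict[tuple[str, str], float] = {}
    idx = rng.integers(0, len(genes), size=(int(n_edges * 1.3), 2))
    for i, j in idx:
        if len(edge_scores) >= n_edges:
            break
        if i == j:
            continue
        u, v = genes[int(i)], genes[int(j)]
        if u > v:
            u, v = v, u
        if (u, v) not in edge_scores:
            edge_scores[(u, v)] = float(rng.beta(a, b))

    def plant_edge(u, v, lo=0.45):
        # planted edges must clear the extension threshold even if the pair
        # already exists with a low background score
        if u > v:
            u, v = v, u
        score = float(rng.uniform(lo, 0.95))
        edge_scores[(u, v)] = max(edge_scores.get((u, v), 0.0), score)

    # connected module: random spanning tree + ~30 % extra internal edges
    order = list(rng.permutation(len(module_genes)))
    for pos in range(1, len(order)):
        parent = order[int(rng.integers(pos))]
        plant_edge(module_genes[parent], module_genes[order[pos]])
    for _ in range(max(1, int(0.3 * len(module_genes)))):
        i, j = rng.choice(len(module_genes), 2, replace=False)
        plant_edge(module_genes[int(i)], module_genes[int(j)])

    anchors = list(pathway_genes) if pathway_genes else genes
    for g in module_genes:
        anchor = anchors[int(rng.integers(len(anchors)))]
        if anchor != g:
            plant_edge(g, anchor)

    ppi = pd.DataFrame(
        [(u, v, round(s, 4)) for (u, v), s in sorted(edge_scores.items())],
        columns=["source_id", "target_id", "score"],
    )

    tfs = sorted(rng.choice(genes, size=config.n_tfs, replace=False))
    trows = []
    for tf in tfs:
        n_targets = int(rng.integers(10, 51))
        targets = rng.choice(genes, size=n_targets, replace=False)
        trows += [(tf, t) for t in sorted(map(str, targets)) if t != tf]
    tf_df = (pd.DataFrame(trows, columns=["source_id", "target_id"])
             .drop_duplicates().sort_values(["source_id", "target_id"])
             .reset_index(drop=True))
    return ppi, tf_df


# ---------------------------------------------------------------------------
# microRNA linksets
# ---------------------------------------------------------------------------

def generate_target_linksets(config: ScenarioConfig, genes, network_genes,
                             de_mirnas, seed: int | None = None):
    """Validated and predicted linksets (predicted ≈ 8× larger).

    A configured fraction of validated pairs is replicated into the predicted
    set, giving dual-provenance interactions.  Every DE microRNA is
    guaranteed at least one target among ``network_genes``.
    Returns (validated_linkset, predicted_linkset).
    """
    from .overlay import TargetLinkset

    rng = np.random.default_rng((config.seed if seed is None else seed) + 3)
    genes = list(genes)
    network_genes = sorted(network_genes) if network_genes else genes
    mirnas = _mirna_ids(config.n_mirnas)
    lo, hi = config.targets_per_mirna_range
    de_set = set(de_mirnas)

    predicted: set[tuple[str, str]] = set()
    validated: set[tuple[str, str]] = set()
    for m in mirnas:
        n_pred = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        targets = rng.choice(genes, size=min(n_pred, len(genes)), replace=False)
        predicted |= {(m, str(t)) for t in targets}
        n_val = max(1, n_pred // 8)
        n_dual = int(round(config.linkset_overlap_fraction * n_val))
        dual = rng.choice(len(targets), size=min(n_dual, len(targets)),
                          replace=False)
        validated |= {(m, str(targets[i])) for i in dual}
        n_fresh = n_val - len(dual)
        fresh = rng.choice(genes, size=min(max(n_fresh, 0), len(genes)),
                           replace=False)
        validated |= {(m, str(t)) for t in fresh if (m, str(t)) not in predicted}
        if m in de_set:
            anchor = network_genes[int(rng.integers(len(network_genes)))]
            predicted.add((m, anchor))
    return (
        TargetLinkset(name="validated", interactions=tuple(sorted(validated))),
        TargetLinkset(name="predicted", interactions=tuple(sorted(predicted))),
    )


# ---------------------------------------------------------------------------
# annotations and curated targets
# ---------------------------------------------------------------------------

def generate_annotations(config: ScenarioConfig, genes, module_genes,
                         seed: int | None = None):
    """Flat GO-style term annotation with one planted coherent term.

    Term sizes are log-uniform in [10, 200].  Terms come in correlated
    families sharing a gene core (~60 % of each member), so kappa grouping
    has genuine cluster structure; one planted term contains at least 80 % of
    the planted module genes.  Returns (terms, planted_term_id).
    """
    from .grouping import TermAnnotation

    rng = np.random.default_rng((config.seed if seed is None else seed) + 4)
    genes = list(genes)
    module_genes = list(module_genes)

    terms = []
    n_core = max(1, int(math.ceil(0.8 * len(module_genes))))
    planted_genes = set(
        str(g) for g in rng.choice(module_genes, size=n_core, replace=False)
    )
    filler = rng.choice([g for g in genes if g not in planted_genes],
                        size=5, replace=False)
    planted_genes |= {str(g) for g in filler}
    planted_id = "T0000"
    terms.append(TermAnnotation(planted_id, "planted module process",
                                frozenset(planted_genes)))

    n_families = max(1, (config.n_terms - 1) // 10)
    family_sizes = [5] * n_families
    tid = 1
    for fam in range(n_families):
        size = int(np.exp(rng.uniform(np.log(10), np.log(200))))
        core = rng.choice(genes, size=max(2, int(0.6 * size)), replace=False)
        for _ in range(family_sizes[fam]):
            periphery = rng.choice(genes, size=size - len(core) + 1,
                                   replace=False)
            term_genes = frozenset(map(str, core)) | frozenset(map(str, periphery))
            terms.append(TermAnnotation(f"T{tid:04d}",
                                        f"family {fam} process {tid}",
                                        term_genes))
            tid += 1
    while tid < config.n_terms:
        size = int(np.exp(rng.uniform(np.log(10), np.log(200))))
        term_genes = frozenset(
            map(str, rng.choice(genes, size=size, replace=False))
        )
        terms.append(TermAnnotation(f"T{tid:04d}", f"singleton process {tid}",
                                    term_genes))
        tid += 1
    return terms, planted_id


def generate_curated_targets(config: ScenarioConfig, genes, de_genes_up,
                             seed: int | None = None):
    """Curated regulator target list biased toward up-regulated genes."""
    from .overlay import CuratedTargetList

    rng = np.random.default_rng((config.seed if seed is None else seed) + 5)
    n_curated = min(50, len(genes))
    n_up = min(len(de_genes_up), n_curated // 3)
    picked = set(str(g) for g in rng.choice(de_genes_up, size=n_up,
                                            replace=False))
    rest = [g for g in genes if g not in picked]
    picked |= {str(g) for g in rng.choice(rest, size=n_curated - len(picked),
                                          replace=False)}
    entries = tuple(sorted(
        (g, int(rng.integers(1, 8))) for g in picked
    ))
    return CuratedTargetList(regulator="VDR", entries=entries)


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def generate_scenario(config: ScenarioConfig, out_dir) -> TruthManifest:
    """Write a complete input bundle and its truth manifest.

    Files: gene/microRNA expression tables, pathway documents, id map, PPI
    and TF tables, two linksets, a GMT annotation, a curated target list, a
    DE-microRNA list and ``manifest.json`` with per-file checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes_df, mirnas_df, truth = generate_expression(config)
    genes = list(genes_df["entity_id"])
    de_genes = truth["de_genes_up"] + truth["de_genes_down"]

    collection, planted_pw, alias_of = generate_pathway_collection(
        config, genes, de_genes
    )
    idmap = build_id_map(genes, alias_of)

    rng = np.random.default_rng(config.seed + 6)
    module_genes = sorted(
        str(g) for g in rng.choice(
            truth["de_genes_down"],
            size=min(config.planted_module_size, len(truth["de_genes_down"])),
            replace=False,
        )
    )
    # the planted module is a coherent strong signal: its genes get p-values
    # far below the ordinary DE range, so module search has a target
    in_module = genes_df["entity_id"].isin(module_genes)
    genes_df.loc[in_module, "p_value"] = np.round(
        rng.uniform(0.0, 0.001, size=int(in_module.sum())), 8
    )
    pathway_genes = sorted(set().union(*collection.gene_sets().values()))
    pathway_genes = [alias_to_gene(g, alias_of) for g in pathway_genes]
    ppi, tf = generate_interactome(config, genes, module_genes,
                                   pathway_genes=pathway_genes)

    network_like = sorted(set(pathway_genes) | set(module_genes))
    validated, predicted = generate_target_linksets(
        config, genes, network_like, truth["de_mirnas"]
    )
    terms, planted_term = generate_annotations(config, genes, module_genes)
    curated = generate_curated_targets(config, genes, truth["de_genes_up"])

    # --- write everything -------------------------------------------------
    vio.write_expression_table(genes_df, out / "genes.tsv")
    vio.write_expression_table(mirnas_df, out / "mirnas.tsv")
    vio.write_pathway_collection(collection, out / "pathways")
    vio.write_id_map(idmap, out / "idmap.tsv")
    ppi.to_csv(out / "ppi.tsv", sep="\t", index=False)
    tf.to_csv(out / "tf.tsv", sep="\t", index=False)
    for linkset, fname in ((validated, "linkset_validated.tsv"),
                           (predicted, "linkset_predicted.tsv")):
        pd.DataFrame(linkset.interactions,
                     columns=["regulator_id", "gene_id"]).assign(
            linkset_name=linkset.name
        ).to_csv(out / fname, sep="\t", index=False)
    vio.write_gmt(
        {t.term_id: (t.term_name, t.genes) for t in terms},
        out / "annotations.gmt",
    )
    pd.DataFrame(curated.entries, columns=["gene_id", "report_count"]).to_csv(
        out / "curated_targets.tsv", sep="\t", index=False
    )
    (out / "de_mirnas.txt").write_text(
        "".join(m + "\n" for m in truth["de_mirnas"]), encoding="utf-8"
    )

    files = [
        "genes.tsv", "mirnas.tsv", "idmap.tsv", "ppi.tsv", "tf.tsv",
        "linkset_validated.tsv", "linkset_predicted.tsv", "annotations.gmt",
        "curated_targets.tsv", "de_mirnas.txt",
    ] + sorted(f"pathways/{p.name}" for p in (out / "pathways").glob("*.json"))
    manifest = TruthManifest(
        planted_pathways=list(planted_pw),
        planted_module=list(module_genes),
        de_genes_up=truth["de_genes_up"],
        de_genes_down=truth["de_genes_down"],
        de_mirnas=truth["de_mirnas"],
        checksums={f: _sha256(out / f) for f in files},
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def alias_to_gene(identifier: str, alias_of: dict[str, str]) -> str:
    """Undo a synonym alias (generator-side convenience)."""
    if identifier.startswith("ALIAS_"):
        return identifier[len("ALIAS_"):]
    return identifier
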