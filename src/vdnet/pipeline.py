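"""End-to-end orchestration of the six analysis stages.

From one input bundle the pipeline runs: (1) differential-expression
evaluation, (2) pathway over-representation and selection, (3) identifier
unification and pathway merging, (4) first-neighbour extension with PPI and
TF interactions, (5a) active-module search plus term grouping of the top
module, and (5b) the microRNA overlay with the DE-regulator subnetwork and
the curated-target annotation.  Every intermediate is written in a standard
format, and the structured run report plus the generator's truth manifest
support recovery scoring.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

from . import __version__
from . import io as vio
from . import ora as vora
from . import network as vnet
from . import modules as vmod
from . import grouping as vgrp
from . import overlay as vovl
from .simulate import TruthManifest, load_manifest

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "StageError",
    "RecoveryMetrics",
    "run_pipeline",
    "validate_against_truth",
    "load_config",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Input paths plus per-stage parameters for one pipeline run."""

    bundle_dir: str
    out_dir: str
    seed: int = 0
    # stage 1: DE criteria
    gene_min_fold: float = 1.5
    mirna_min_fold: float = 2.0
    max_p: float = 0.05
    # stage 2: ORA
    n_perm: int = 1000
    z_min: float = 1.96
    ora_p_max: float = 0.05
    min_positive: int = 5
    ora_universe: str = "mapped"
    category_filter: str | None = None
    # stage 4: extension
    score_min: float = 0.4
    # stage 5a: modules + grouping
    n_modules: int = 10
    max_k: int = 30
    restarts: int = 20
    overlap_max: float = 0.5
    n_null_samples: int = 500
    module_mode: str = "two_sided"
    kappa_threshold: float = 0.4
    merge_fraction: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_yaml(path)


@dataclass
class RecoveryMetrics:
    """Recovery of planted truth by a pipeline run; all values in [0, 1]."""

    pathway_precision: float
    pathway_recall: float
    module_jaccard: float
    de_coverage_before: float
    de_coverage_after: float
    regulator_completeness: float

    def __post_init__(self):
        for name, value in asdict(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {value}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(report: dict, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            report["timings"][name] = round(time.perf_counter() - self.t0, 4)
            if exc is not None:
                raise StageError(name, exc) from exc
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report dict (also written to report.json)."""
    bundle = Path(config.bundle_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = {
        "genes": bundle / "genes.tsv",
        "mirnas": bundle / "mirnas.tsv",
        "pathways": bundle / "pathways",
        "idmap": bundle / "idmap.tsv",
        "ppi": bundle / "ppi.tsv",
        "tf": bundle / "tf.tsv",
        "linkset_validated": bundle / "linkset_validated.tsv",
        "linkset_predicted": bundle / "linkset_predicted.tsv",
        "annotations": bundle / "annotations.gmt",
        "curated": bundle / "curated_targets.tsv",
        "de_mirnas": bundle / "de_mirnas.txt",
    }
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {
            k: {"path": str(p), "checksum": _sha256(p) if p.is_file() else None}
            for k, p in inputs.items()
        },
        "stages": {},
        "timings": {},
    }

    gene_criterion = vio.CriterionSpec(config.gene_min_fold, config.max_p)
    mirna_criterion = vio.CriterionSpec(config.mirna_min_fold, config.max_p)

    with _stage(report, "expression"):
        genes = vio.read_expression_table(inputs["genes"], vio.GENE)
        mirnas = vio.read_expression_table(inputs["mirnas"], vio.MICRORNA)
        gstatus = vio.classify_expression(genes, gene_criterion)
        mstatus = vio.classify_expression(mirnas, mirna_criterion)
        report["stages"]["expression"] = {
            "n_genes": len(genes),
            "n_de_genes": int((gstatus != vio.NOT_DE).sum()),
            "n_up": int((gstatus == vio.UP).sum()),
            "n_down": int((gstatus == vio.DOWN).sum()),
            "n_mirnas": len(mirnas),
            "n_de_mirnas": int((mstatus != vio.NOT_DE).sum()),
        }

    with _stage(report, "ora"):
        collection = vio.read_pathway_collection(inputs["pathways"])
        idmap = vio.read_id_map(inputs["idmap"])
        results = vora.run_ora(
            collection, genes, gene_criterion,
            n_perm=config.n_perm, seed=config.seed, idmap=idmap,
            universe=config.ora_universe,
        )
        thresholds = vora.SelectionThresholds(
            config.z_min, config.ora_p_max, config.min_positive
        )
        selected = vora.select_pathways(results, thresholds)
        if config.category_filter:
            selected = [s for s in selected
                        if s.category == config.category_filter]
        selected_ids = {s.pathway_id for s in selected}
        vora.write_results(
            [replace(r, selected=r.pathway_id in selected_ids)
             for r in results],
            out / "ora_results.tsv",
        )
        report["stages"]["ora"] = {
            "n_pathways_scored": len(results),
            "n_selected": len(selected),
            "selected": [s.pathway_id for s in selected],
        }

    with _stage(report, "merge"):
        if not selected:
            raise ValueError("no pathway passed the selection rule")
        unified = [
            vnet.unify_identifiers(collection[s.pathway_id], idmap)
            for s in selected
        ]
        net = vnet.merge_pathways(unified)
        vnet.annotate_expression(net, genes, gene_criterion)
        linking = vnet.linking_nodes(net)
        linking.to_csv(out / "linking_nodes.tsv", sep="\t", index=False)
        net.write(out / "merged_network.graphml")
        summary_before = vnet.network_summary(net, genes, gene_criterion)
        report["stages"]["merge"] = {
            "summary": summary_before,
            "n_linking_nodes": len(linking),
        }

    with _stage(report, "extend"):
        ppi = vio.read_interaction_table(inputs["ppi"], vio.KIND_PPI)
        tf = vio.read_interaction_table(inputs["tf"], vio.KIND_TF)
        extended = vnet.extend_network(
            net, ppi, tf, genes, gene_criterion, score_min=config.score_min
        )
        extended.write(out / "extended_network.graphml")
        summary_after = vnet.network_summary(extended, genes, gene_criterion)
        report["stages"]["extend"] = {"summary": summary_after}

    with _stage(report, "modules"):
        p_values = vmod.gene_pvalues_from_expression(genes, config.module_mode)
        params = vmod.SearchParams(
            n_modules=config.n_modules, max_k=config.max_k,
            restarts=config.restarts, overlap_max=config.overlap_max,
            n_null_samples=config.n_null_samples, mode=config.module_mode,
        )
        found = vmod.search_modules(extended, p_values, params,
                                    seed=config.seed)
        with (out / "modules.json").open("w", encoding="utf-8") as fh:
            json.dump(
                [{"genes": list(m.genes), "k": m.k, "z_a": round(m.z_a, 6),
                  "s": round(m.s, 6)} for m in found],
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
        report["stages"]["modules"] = {
            "n_modules": len(found),
            "top_module_size": found[0].k if found else 0,
            "top_module_score": round(found[0].s, 4) if found else None,
            "top_module_genes": list(found[0].genes) if found else [],
        }

    with _stage(report, "grouping"):
        terms = vgrp.read_annotation_gmt(inputs["annotations"])
        universe = vgrp.annotation_universe(terms)
        module_genes = [g for g in found[0].genes if g in universe]
        if not module_genes:
            raise ValueError("top module shares no gene with the annotation")
        enrichment = vgrp.enrich_terms(module_genes, terms, universe)
        kappa_graph = vgrp.build_kappa_graph(
            terms, universe, kappa_threshold=config.kappa_threshold
        )
        groups, unassigned = vgrp.group_terms(
            kappa_graph, enrichment, merge_fraction=config.merge_fraction
        )
        enrichment.to_csv(out / "module_enrichment.tsv", sep="\t", index=False)
        vio.write_network(kappa_graph, out / "kappa_graph.graphml")
        with (out / "term_groups.tsv").open("w", encoding="utf-8") as fh:
            fh.write("group_id\tleading_term\tmembers\n")
            for g in groups:
                fh.write(f"{g.group_id}\t{g.leading_term}\t"
                         f"{','.join(g.members)}\n")
        best_term = enrichment.sort_values(["p", "term_id"]).iloc[0]
        report["stages"]["grouping"] = {
            "n_groups": len(groups),
            "n_unassigned": len(unassigned),
            "best_term": str(best_term["term_id"]),
            "best_term_p": float(best_term["p"]),
        }

    with _stage(report, "overlay"):
        validated = vovl.read_linkset(inputs["linkset_validated"], "validated")
        predicted = vovl.read_linkset(inputs["linkset_predicted"], "predicted")
        overlaid = extended.copy()
        add_report = vovl.add_target_edges(overlaid, [validated, predicted])
        de_mirnas = [
            line.strip()
            for line in Path(inputs["de_mirnas"]).read_text("utf-8").splitlines()
            if line.strip()
        ]
        sub, reg_report = vovl.extract_regulator_subnetwork(
            overlaid, de_mirnas, add_report.linkset_regulators
        )
        sub.write(out / "mirna_subnetwork.graphml")
        overlaid.write(out / "overlaid_network.graphml")
        target_summary = vovl.summarize_regulator_targets(
            sub, overlaid, validated_linksets=("validated",)
        )
        curated = vovl.read_curated_targets(inputs["curated"])
        curated_summary = vovl.overlay_curated_targets(
            overlaid, genes, curated, gene_criterion
        )
        report["stages"]["overlay"] = {
            "mirna_edges_added": add_report.edges_added,
            "mirna_regulators_added": add_report.regulators_added,
            "de_mirnas_found": reg_report["found"],
            "de_mirnas_missing_no_targets": reg_report["missing_no_targets"],
            "de_mirnas_missing_unknown": reg_report["missing_unknown"],
            "target_summary_overall": target_summary["overall"],
            "curated_summary": {
                k: v for k, v in curated_summary.items()
                if k not in ("present", "absent")
            },
        }

    with (out / "report.json").open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def validate_against_truth(report: dict, manifest: TruthManifest | str) -> RecoveryMetrics:
    """Score a run report against the truth manifest of its input bundle.

    Checks that the report consumed the manifest's bundle (checksum match on
    the expression table) and computes pathway precision/recall, the best
    module-vs-planted Jaccard, DE coverage before/after extension and the
    fraction of DE microRNAs recovered in the overlay subnetwork.
    """
    if not isinstance(manifest, TruthManifest):
        manifest = load_manifest(manifest)

    recorded = report["inputs"]["genes"]["checksum"]
    expected = manifest.checksums.get("genes.tsv")
    if expected is not None and recorded != expected:
        raise ValueError("report and manifest refer to different bundles")

    planted = set(manifest.planted_pathways)
    selected = set(report["stages"]["ora"]["selected"])
    precision = len(selected & planted) / len(selected) if selected else 0.0
    recall = len(selected & planted) / len(planted) if planted else 0.0

    module = set(manifest.planted_module)
    top = set(report["stages"]["modules"]["top_module_genes"])
    jaccard = len(top & module) / len(top | module) if (top | module) else 0.0

    before = report["stages"]["merge"]["summary"].get("de_coverage", 0.0)
    after = report["stages"]["extend"]["summary"].get("de_coverage", 0.0)

    found = set(report["stages"]["overlay"]["de_mirnas_found"])
    total = set(manifest.de_mirnas)
    completeness = len(found & total) / len(total) if total else 0.0

    return RecoveryMetrics(
        pathway_precision=precision,
        pathway_recall=recall,
        module_jaccard=jaccard,
        de_coverage_before=before,
        de_coverage_after=after,
        regulator_completeness=completeness,
    )
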