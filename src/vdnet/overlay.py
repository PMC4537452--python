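"""MicroRNA–target overlay and curated-regulator (VDR-style) annotation.

MicroRNA→target interactions come from *linksets* — one table per source
database, typically a small validated set and a much larger predicted set.
Interactions whose target is present in the network are added as directed
``mirna_target`` edges; one edge per (regulator, gene) pair carries the set
of linkset names supporting it, so dual-database support is a property of the
edge rather than a parallel edge.  From the overlaid network the subnetwork
of differentially expressed microRNAs and their targets is extracted and
summarised by target origin (pathway vs interaction extension), expression
status and provenance class.  A curated regulator target list (e.g. the
literature-curated vitamin-D-receptor targets) is overlaid as a node
annotation with its supporting-article count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from . import io as vio
from .network import IntegratedNetwork, ORIGIN_MIRNA, ORIGIN_PATHWAY

logger = logging.getLogger(__name__)

__all__ = [
    "TargetLinkset",
    "CuratedTargetList",
    "read_linkset",
    "read_curated_targets",
    "OverlayReport",
    "add_target_edges",
    "extract_regulator_subnetwork",
    "summarize_regulator_targets",
    "overlay_curated_targets",
]


@dataclass(frozen=True)
class TargetLinkset:
    """Directed regulator→gene interactions from one source database."""

    name: str
    interactions: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if len(set(self.interactions)) != len(self.interactions):
            raise ValueError(f"linkset {self.name} contains duplicate pairs")

    @property
    def regulators(self) -> set[str]:
        return {r for r, _ in self.interactions}


@dataclass(frozen=True)
class CuratedTargetList:
    """A curated regulator target list with per-gene supporting-report counts."""

    regulator: str
    entries: tuple[tuple[str, int], ...]

    def __post_init__(self):
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError("curated target list has duplicate gene ids")
        if any(c < 1 for _, c in self.entries):
            raise ValueError("report_count must be >= 1")


def read_linkset(path, name: str | None = None) -> TargetLinkset:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("regulator_id", "gene_id"):
        if col not in df.columns:
            raise vio.FormatError(f"linkset missing required column {col}")
    if name is None:
        if "linkset_name" in df.columns and len(df):
            name = str(df["linkset_name"].iloc[0])
        else:
            name = "linkset"
    pairs = tuple(
        sorted(set(zip(df["regulator_id"], df["gene_id"])))
    )
    return TargetLinkset(name=name, interactions=pairs)


def read_curated_targets(path, regulator: str = "VDR") -> CuratedTargetList:
    """Read a curated target table (gene_id, report_count).

    Duplicate genes are collapsed to their maximum report count, with a
    warning — curation tables assembled by hand do repeat entries.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "report_count"):
        if col not in df.columns:
            raise vio.FormatError(f"curated target list missing column {col}")
    if df["gene_id"].duplicated().any():
        logger.warning("curated target list has duplicate genes; keeping max count")
        df = df.groupby("gene_id", as_index=False)["report_count"].max()
    entries = tuple(
        sorted((g, int(c)) for g, c in zip(df["gene_id"], df["report_count"]))
    )
    return CuratedTargetList(regulator=regulator, entries=entries)


@dataclass
class OverlayReport:
    regulators_added: int = 0
    edges_added: int = 0
    interactions_skipped: int = 0
    linkset_regulators: set = field(default_factory=set)


def add_target_edges(net: IntegratedNetwork, linksets) -> OverlayReport:
    """Add regulator→gene edges for every interaction whose gene is in-network.

    The regulator node is created on first use; repeated application with the
    same linksets is idempotent (the provenance set simply absorbs the same
    names again).  Interactions whose target gene is absent are skipped and
    counted.
    """
    report = OverlayReport()
    for linkset in linksets:
        report.linkset_regulators |= linkset.regulators
        for regulator, gene in linkset.interactions:
            if gene not in net.graph or regulator == gene:
                report.interactions_skipped += 1
                continue
            if regulator not in net.graph:
                net.graph.add_node(
                    regulator,
                    label=regulator,
                    node_type=vio.NODE_GENE_PRODUCT,
                    is_regulator=True,
                    origin=ORIGIN_MIRNA,
                    pathway_memberships=set(),
                    de_status=vio.UNMEASURED,
                )
                report.regulators_added += 1
            before = net.graph.number_of_edges()
            net.add_edge(regulator, gene, vio.KIND_MIRNA,
                         provenance={linkset.name}, directed=True)
            report.edges_added += net.graph.number_of_edges() - before
    return report


def _mirna_edges(net: IntegratedNetwork):
    for u, v, k, d in net.graph.edges(keys=True, data=True):
        if d.get("edge_kind") == vio.KIND_MIRNA:
            yield u, v, k, d


def extract_regulator_subnetwork(
    net: IntegratedNetwork,
    de_regulators,
    linkset_regulators: set | None = None,
) -> tuple[IntegratedNetwork, dict]:
    """Subnetwork of the DE regulators present in the network and their targets.

    Returns the subnetwork plus a report listing which DE regulators were
    found, which appeared in a linkset but had no in-network target, and
    which were absent from the linksets altogether (when the linkset
    regulator universe is supplied).
    """
    de_regulators = sorted(set(de_regulators))
    if not de_regulators:
        logger.warning("empty DE regulator list; returning empty subnetwork")
    found = [r for r in de_regulators if r in net.graph]
    missing = [r for r in de_regulators if r not in net.graph]
    if linkset_regulators is not None:
        missing_no_targets = [r for r in missing if r in linkset_regulators]
        missing_unknown = [r for r in missing if r not in linkset_regulators]
    else:
        missing_no_targets, missing_unknown = missing, []

    sub = IntegratedNetwork()
    for u, v, k, d in _mirna_edges(net):
        if u not in found:
            continue
        for node in (u, v):
            if node not in sub.graph:
                attrs = net.graph.nodes[node]
                sub.graph.add_node(
                    node, **{key: (set(val) if isinstance(val, set) else val)
                             for key, val in attrs.items()}
                )
        sub.graph.add_edge(u, v, key=k,
                           **{key: (set(val) if isinstance(val, set) else val)
                              for key, val in d.items()})
    report = {
        "found": found,
        "missing_no_targets": missing_no_targets,
        "missing_unknown": missing_unknown,
    }
    return sub, report


def summarize_regulator_targets(
    sub: IntegratedNetwork,
    net: IntegratedNetwork,
    validated_linksets=("validated",),
) -> dict:
    """Per-regulator and overall target counts for a regulator subnetwork.

    Targets are split by origin (pathway vs interaction extension), by
    expression status, and by provenance class: supported only by validated
    linksets, only by predicted ones, or by both.  Genes targeted by two or
    more regulators are reported separately.
    """
    validated = set(validated_linksets)

    def prov_class(provenance: set) -> str:
        has_val = bool(provenance & validated)
        has_pred = bool(provenance - validated)
        if has_val and has_pred:
            return "both"
        return "validated_only" if has_val else "predicted_only"

    per_regulator: dict[str, dict] = {}
    targeted_by: dict[str, set] = {}
    for u, v, _, d in _mirna_edges(sub):
        entry = per_regulator.setdefault(
            u,
            {
                "n_targets": 0,
                "pathway_origin": 0,
                "extension_origin": 0,
                "up": 0, "down": 0, "not_de": 0, "unmeasured": 0,
                "validated_only": 0, "predicted_only": 0, "both": 0,
            },
        )
        target_attrs = net.graph.nodes[v]
        entry["n_targets"] += 1
        origin = target_attrs.get("origin")
        if origin == ORIGIN_PATHWAY:
            entry["pathway_origin"] += 1
        else:
            entry["extension_origin"] += 1
        entry[target_attrs.get("de_status", vio.UNMEASURED)] += 1
        entry[prov_class(d.get("provenance", set()))] += 1
        targeted_by.setdefault(v, set()).add(u)

    multi = sorted(g for g, regs in targeted_by.items() if len(regs) >= 2)
    overall = {
        "n_regulators": len(per_regulator),
        "n_distinct_targets": len(targeted_by),
        "n_target_edges": sum(e["n_targets"] for e in per_regulator.values()),
        "multi_targeted_genes": multi,
    }
    for key in ("pathway_origin", "extension_origin", "up", "down",
                "validated_only", "predicted_only", "both"):
        overall[key] = sum(e[key] for e in per_regulator.values())
    return {"per_regulator": dict(sorted(per_regulator.items())),
            "overall": overall}


def overlay_curated_targets(
    net: IntegratedNetwork,
    expression: pd.DataFrame,
    curated: CuratedTargetList,
    criterion: vio.CriterionSpec = vio.GENE_CRITERION,
    linking_min_pathways: int = 2,
) -> dict:
    """Annotate curated regulator targets on the network and summarise them.

    Matching nodes gain ``curated_target`` (the regulator name) and
    ``curated_report_count`` attributes.  The summary reports how many curated
    targets are up- or down-regulated in the expression data, how many sit in
    pathway-origin versus extension-origin nodes, how many are absent from
    the network, and which present targets are linking nodes (members of two
    or more pathways).
    """
    status = vio.classify_expression(expression, criterion)
    de_of = dict(zip(expression["entity_id"], status))

    present, absent, linking = [], [], []
    by_origin = {"pathway": 0, "extension": 0}
    de_counts = {"up": 0, "down": 0, "not_de": 0, "unmeasured": 0}
    for gene, count in curated.entries:
        if gene in net.graph:
            attrs = net.graph.nodes[gene]
            attrs["curated_target"] = curated.regulator
            attrs["curated_report_count"] = count
            present.append(gene)
            if attrs.get("origin") == ORIGIN_PATHWAY:
                by_origin["pathway"] += 1
            else:
                by_origin["extension"] += 1
            de_counts[de_of.get(gene, vio.UNMEASURED)] += 1
            if len(attrs.get("pathway_memberships", ())) >= linking_min_pathways:
                linking.append(gene)
        else:
            absent.append(gene)
    return {
        "regulator": curated.regulator,
        "n_curated": len(curated.entries),
        "present": sorted(present),
        "absent": sorted(absent),
        "n_present": len(present),
        "n_absent": len(absent),
        "de_counts": de_counts,
        "by_origin": by_origin,
        "linking_targets": sorted(linking),
    }
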