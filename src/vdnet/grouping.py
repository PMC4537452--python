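"""Functional term enrichment and kappa-based term grouping.

Module genes are tested against a flat term→genes annotation (GO-style) with
a right-tailed hypergeometric test, Benjamini–Hochberg adjusted across terms.
Term-to-term similarity is Cohen's kappa computed over the annotation
universe: each term is a binary membership vector over the universe, the 2×2
agreement table of two vectors gives the observed agreement p_o and the
chance agreement p_e, and κ = (p_o − p_e)/(1 − p_e).  Terms whose κ reaches a
threshold are connected in a term graph, and groups are formed by merging
overlapping neighbourhoods — each final group is named by its leading
(most-enriched) term, and terms with no similar partner stay ungrouped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from . import io as vio

logger = logging.getLogger(__name__)

__all__ = [
    "TermAnnotation",
    "KappaResult",
    "TermGroup",
    "read_annotation_gmt",
    "read_annotation_tsv",
    "annotation_universe",
    "enrich_terms",
    "kappa_stat",
    "build_kappa_graph",
    "group_terms",
]


@dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    term_name: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"term {self.term_id} has an empty gene set")


@dataclass(frozen=True)
class KappaResult:
    term_a: str
    term_b: str
    p_o: float
    p_e: float
    kappa: float


@dataclass(frozen=True)
class TermGroup:
    group_id: int
    members: tuple[str, ...]
    leading_term: str


def read_annotation_gmt(path) -> list[TermAnnotation]:
    sets = vio.read_gmt(path)
    return [
        TermAnnotation(term_id=tid, term_name=desc, genes=frozenset(genes))
        for tid, (desc, genes) in sorted(sets.items())
    ]


def read_annotation_tsv(pairs_path, names_path=None) -> list[TermAnnotation]:
    """Two-column term_id/gene_id table, optional term_id/term_name sidecar."""
    pairs = pd.read_csv(pairs_path, sep="\t", dtype=str)
    for col in ("term_id", "gene_id"):
        if col not in pairs.columns:
            raise vio.FormatError(f"annotation table missing column {col}")
    names = {}
    if names_path is not None:
        sidecar = pd.read_csv(names_path, sep="\t", dtype=str)
        names = dict(zip(sidecar["term_id"], sidecar["term_name"]))
    out = []
    for tid, sub in pairs.groupby("term_id", sort=True):
        out.append(
            TermAnnotation(
                term_id=tid,
                term_name=names.get(tid, tid),
                genes=frozenset(sub["gene_id"]),
            )
        )
    return out


def annotation_universe(terms) -> frozenset:
    """All genes annotated to at least one term."""
    out: set = set()
    for t in terms:
        out |= t.genes
    return frozenset(out)


def enrich_terms(query_genes, terms, universe=None) -> pd.DataFrame:
    """Right-tailed hypergeometric enrichment of a query set per term.

    The universe defaults to every annotated gene; the query must be a subset
    of it.  p = P[X >= overlap] with population = |universe|, successes =
    term size (restricted to the universe) and draws = |query|.  Adjusted
    p-values are Benjamini–Hochberg across the tested terms.
    """
    query = set(query_genes)
    if not query:
        raise ValueError("empty query gene set")
    terms = list(terms)
    if universe is None:
        universe = annotation_universe(terms)
    universe = set(universe)
    if not query <= universe:
        missing = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside the universe, e.g. {missing}")
    M = len(universe)
    rows = []
    for t in sorted(terms, key=lambda t: t.term_id):
        term_genes = t.genes & universe
        K = len(term_genes)
        k = len(term_genes & query)
        p = float(hypergeom.sf(k - 1, M, K, len(query)))
        rows.append((t.term_id, t.term_name, K, k, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "term_size",
                                     "overlap", "p"])
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def kappa_stat(genes_a, genes_b, universe) -> KappaResult:
    """Cohen's kappa between two gene sets over a common universe.

    Agreement is tabulated per universe gene (in both / only a / only b /
    neither).  When chance agreement is perfect (both sets are the whole
    universe), kappa is defined as 1.
    """
    universe = set(universe)
    if len(universe) < 2:
        raise ValueError("universe must contain at least two genes")
    a = set(genes_a) & universe
    b = set(genes_b) & universe
    if set(genes_a) - universe or set(genes_b) - universe:
        raise ValueError("gene sets must be subsets of the universe")
    n = len(universe)
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = n - both - only_a - only_b
    p_o = (both + neither) / n
    fa, fb = len(a) / n, len(b) / n
    p_e = fa * fb + (1 - fa) * (1 - fb)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1 - p_e)
    return KappaResult("", "", p_o=p_o, p_e=p_e, kappa=kappa)


def build_kappa_graph(terms, universe=None, kappa_threshold: float = 0.4) -> nx.Graph:
    """Undirected term graph: edge iff pairwise kappa >= threshold.

    Every term appears as a node; edge weights carry the kappa value.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("no terms supplied")
    if universe is None:
        universe = annotation_universe(terms)
    g = nx.Graph()
    for t in terms:
        g.add_node(t.term_id, term_name=t.term_name)
    for i, ta in enumerate(terms):
        for tb in terms[i + 1:]:
            kappa = kappa_stat(ta.genes, tb.genes, universe).kappa
            if kappa >= kappa_threshold:
                g.add_edge(ta.term_id, tb.term_id, weight=kappa)
    return g


def group_terms(
    term_graph: nx.Graph,
    enrichment: pd.DataFrame,
    merge_fraction: float = 0.5,
) -> tuple[list[TermGroup], list[str]]:
    """Merge kappa-neighbourhoods into disjoint named term groups.

    Initial groups are each term together with its kappa neighbours.  Two
    groups merge while they share at least ``merge_fraction`` of the smaller
    group's terms.  The merged groups are then made disjoint: every term joins
    the group to whose members its summed kappa (over term-graph edges) is
    highest, ties to the smaller group id.  Each group is led by its member
    with the smallest raw enrichment p (ties by term id); isolated terms are
    returned separately as unassigned.
    """
    if not 0.0 < merge_fraction <= 1.0:
        raise ValueError("merge_fraction must be in (0, 1]")
    p_raw = dict(zip(enrichment["term_id"], enrichment["p"]))

    terms = sorted(term_graph.nodes)
    unassigned = [t for t in terms if term_graph.degree(t) == 0]
    connected = [t for t in terms if term_graph.degree(t) > 0]

    groups: dict[int, set[str]] = {
        i: {t} | set(term_graph.neighbors(t)) for i, t in enumerate(connected)
    }

    changed = True
    while changed:
        changed = False
        ids = sorted(groups)
        for pos, gi in enumerate(ids):
            for gj in ids[pos + 1:]:
                a, b = groups[gi], groups[gj]
                if len(a & b) >= merge_fraction * min(len(a), len(b)):
                    groups[gi] = a | b
                    del groups[gj]
                    changed = True
                    break
            if changed:
                break

    # disjointify: each term joins the group with the highest summed kappa
    assignment: dict[str, int] = {}
    for term in connected:
        hosting = sorted(gid for gid, members in groups.items() if term in members)
        if len(hosting) == 1:
            assignment[term] = hosting[0]
            continue
        best_gid, best_sum = None, -1.0
        for gid in hosting:
            total = sum(
                term_graph[term][other]["weight"]
                for other in groups[gid]
                if other != term and term_graph.has_edge(term, other)
            )
            if total > best_sum + 1e-12:
                best_gid, best_sum = gid, total
        assignment[term] = best_gid

    final: dict[int, set[str]] = {}
    for term, gid in assignment.items():
        final.setdefault(gid, set()).add(term)

    out = []
    for new_id, gid in enumerate(sorted(final)):
        members = tuple(sorted(final[gid]))
        leading = min(members, key=lambda t: (p_raw.get(t, 1.0), t))
        out.append(TermGroup(group_id=new_id, members=members,
                             leading_term=leading))
    return out, unassigned
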