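"""Pathway over-representation analysis (ORA).

For each pathway the number of criterion-positive (differentially expressed)
genes among its measured genes is standardised against the hypergeometric
expectation, giving the classical MAPPFinder/PathVisio *Z score*

    z = (r − n·R/N) / sqrt( n·(R/N)·(1 − R/N)·(1 − (n−1)/(N−1)) )

where, over the measured universe:

    N — measured genes mapped to the pathway collection,
    R — of those, genes passing the differential-expression criterion,
    n — measured genes in the pathway at hand,
    r — criterion-positive genes in that pathway.

The denominator is exactly the standard deviation of a Hypergeometric(N, R, n)
count, including the finite-population correction (N−n)/(N−1); the score is
therefore the number of hypergeometric standard deviations by which the
observed positive count exceeds chance.

Significance is assessed non-parametrically: the gene-level criterion labels
are permuted uniformly over the measured universe and the Z score recomputed,
with add-one smoothing so the permutation p-value is never zero.  A pathway is
called altered when z exceeds a normal-critical cut-off, the permutation p is
small and the pathway contains a minimum number of positive genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import io as vio

logger = logging.getLogger(__name__)

__all__ = [
    "ZeroVarianceError",
    "ZScoreResult",
    "SelectionThresholds",
    "compute_zscore",
    "permutation_pvalue",
    "run_ora",
    "select_pathways",
    "results_frame",
    "write_results",
    "read_results",
]


class ZeroVarianceError(ValueError):
    """The hypergeometric variance is zero, so the Z score is undefined."""


@dataclass(frozen=True)
class ZScoreResult:
    """Per-pathway ORA counts and scores."""

    pathway_id: str
    N: int
    R: int
    n: int
    r: int
    z: float
    perm_p: float
    selected: bool = False
    name: str = ""
    category: str = ""

    def __post_init__(self):
        if not (0 <= self.r <= self.n <= self.N and self.r <= self.R <= self.N):
            raise ValueError(
                f"{self.pathway_id}: inconsistent counts "
                f"N={self.N} R={self.R} n={self.n} r={self.r}"
            )
        if not 0.0 < self.perm_p <= 1.0:
            raise ValueError(f"{self.pathway_id}: perm_p outside (0, 1]")


@dataclass(frozen=True)
class SelectionThresholds:
    """The altered-pathway rule: z > z_min, perm p < p_max, r >= min_positive."""

    z_min: float = 1.96
    p_max: float = 0.05
    min_positive: int = 5

    def __post_init__(self):
        if self.z_min <= 0 or self.p_max <= 0 or self.min_positive <= 0:
            raise ValueError("all selection thresholds must be positive")


def _hypergeom_moments(N: int, R: int, n: int) -> tuple[float, float]:
    mu = n * R / N
    var = n * (R / N) * (1.0 - R / N) * (1.0 - (n - 1) / (N - 1))
    return mu, var


def compute_zscore(N: int, R: int, n: int, r: int) -> float:
    """Hypergeometric-standardised positive count for one pathway."""
    if not (n >= 1 and N >= 2 and n < N):
        raise ValueError(f"require 1 <= n < N and N >= 2, got n={n}, N={N}")
    if not (0 <= r <= n and 0 <= r <= R <= N):
        raise ValueError(f"inconsistent counts N={N} R={R} n={n} r={r}")
    mu, var = _hypergeom_moments(N, R, n)
    if var <= 0.0:
        raise ZeroVarianceError(
            f"zero variance for N={N}, R={R}, n={n}; Z score undefined"
        )
    return (r - mu) / np.sqrt(var)


def permutation_pvalue(
    member_flags,
    de_flags,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for one pathway.

    The criterion labels are shuffled uniformly over the measured genes
    ``n_perm`` times and the Z score recomputed each time; the p-value uses
    the add-one convention p = (1 + #{z_perm >= z_obs}) / (1 + n_perm), so it
    is never exactly zero.  Degenerate label vectors (no positives, or all
    positive) are permutation invariant and return p = 1.
    """
    member = np.asarray(member_flags, dtype=bool)
    de = np.asarray(de_flags, dtype=bool)
    if member.shape != de.shape or member.ndim != 1 or member.size < 2:
        raise ValueError("flag vectors must be equal-length 1-D with size >= 2")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    N = member.size
    R = int(de.sum())
    n = int(member.sum())
    r = int((member & de).sum())
    if R == 0 or R == N:
        logger.warning("degenerate criterion labels (R=%d of N=%d); p = 1", R, N)
        return 1.0
    if n == 0 or n == N:
        logger.warning("degenerate membership (n=%d of N=%d); p = 1", n, N)
        return 1.0
    rng = np.random.default_rng(seed)
    z_obs = compute_zscore(N, R, n, r)
    perms = rng.permuted(np.tile(de, (n_perm, 1)), axis=1)
    r_perm = perms[:, member].sum(axis=1)
    mu, var = _hypergeom_moments(N, R, n)
    z_perm = (r_perm - mu) / np.sqrt(var)
    exceed = int((z_perm >= z_obs - 1e-12).sum())
    return (1 + exceed) / (1 + n_perm)


def run_ora(
    collection: vio.PathwayCollection,
    expression: pd.DataFrame,
    criterion: vio.CriterionSpec = vio.GENE_CRITERION,
    n_perm: int = 1000,
    seed: int = 0,
    idmap: vio.IdMap | None = None,
    universe: str = "mapped",
) -> list[ZScoreResult]:
    """Score every pathway in a collection against an expression table.

    ``universe`` selects the reference gene universe: ``"mapped"`` (default,
    PathVisio behaviour) restricts N to measured genes that map into at least
    one pathway of the collection; ``"all_measured"`` uses every measured gene.
    Pathways with no measured genes are dropped with a warning; pathways whose
    variance is degenerate under the chosen universe are likewise dropped.
    Results come back sorted by Z descending, ties broken by pathway id.
    """
    if expression.empty:
        raise ValueError("expression table is empty")
    if universe not in ("mapped", "all_measured"):
        raise ValueError("universe must be 'mapped' or 'all_measured'")

    status = vio.classify_expression(expression, criterion)
    de_by_gene = dict(zip(expression["entity_id"], status != vio.NOT_DE))
    measured = list(dict.fromkeys(expression["entity_id"]))

    gene_sets = {}
    for pathway in collection:
        genes = set()
        for raw in pathway.gene_xref_ids():
            unified = None
            if idmap is not None:
                # pathway gene ids may be aliases; resolve through the map
                for db in ("GENE", "SYN"):
                    unified = idmap.lookup(db, raw)
                    if unified is not None:
                        break
            genes.add(unified if unified is not None else raw)
        gene_sets[pathway.pathway_id] = genes

    mapped_anywhere = set().union(*gene_sets.values()) if gene_sets else set()
    if universe == "mapped":
        universe_genes = [g for g in measured if g in mapped_anywhere]
    else:
        universe_genes = measured
    if len(universe_genes) < 2:
        raise ValueError("fewer than two measured genes in the ORA universe")

    index = {g: i for i, g in enumerate(universe_genes)}
    de = np.array([de_by_gene[g] for g in universe_genes], dtype=bool)
    N = len(universe_genes)
    R = int(de.sum())

    rows = []
    membership = []
    for pid in sorted(gene_sets):
        idx = [index[g] for g in gene_sets[pid] if g in index]
        if not idx:
            logger.warning("pathway %s has no measured genes; skipped", pid)
            continue
        member = np.zeros(N, dtype=bool)
        member[idx] = True
        n = len(idx)
        r = int(de[idx].sum())
        try:
            z = compute_zscore(N, R, n, r)
        except ZeroVarianceError:
            logger.warning("pathway %s has degenerate variance; skipped", pid)
            continue
        rows.append((pid, n, r, z))
        membership.append(member)

    if not rows:
        return []

    # one shared set of label permutations scores every pathway, mirroring a
    # data-wide permutation of the criterion labels
    rng = np.random.default_rng(seed)
    if R == 0 or R == N:
        logger.warning("degenerate criterion labels over the universe; p = 1")
        perm_ps = [1.0] * len(rows)
    else:
        M = np.stack(membership).astype(np.float32)
        perms = rng.permuted(np.tile(de, (n_perm, 1)), axis=1)
        r_perm = M @ perms.astype(np.float32).T  # pathways x n_perm
        perm_ps = []
        for i, (pid, n, r, z) in enumerate(rows):
            mu, var = _hypergeom_moments(N, R, n)
            z_perm = (r_perm[i] - mu) / np.sqrt(var)
            exceed = int((z_perm >= z - 1e-6).sum())
            perm_ps.append((1 + exceed) / (1 + n_perm))

    results = []
    for (pid, n, r, z), p in zip(rows, perm_ps):
        pathway = collection[pid]
        results.append(
            ZScoreResult(
                pathway_id=pid, N=N, R=R, n=n, r=r, z=float(z), perm_p=p,
                name=pathway.name, category=pathway.category,
            )
        )
    results.sort(key=lambda res: (-res.z, res.pathway_id))
    return results


def select_pathways(results, thresholds: SelectionThresholds = SelectionThresholds()):
    """Apply the altered-pathway rule.

    Accepts either a list of :class:`ZScoreResult` (returns the selected
    subset, each with ``selected=True``) or a DataFrame with columns ``z``,
    ``perm_p`` and ``r`` (returns the selected rows).
    """
    if isinstance(results, pd.DataFrame):
        mask = (
            (results["z"] > thresholds.z_min)
            & (results["perm_p"] < thresholds.p_max)
            & (results["r"] >= thresholds.min_positive)
        )
        return results[mask]
    if not results:
        raise ValueError("no ORA results to select from")
    return [
        replace(res, selected=True)
        for res in results
        if res.z > thresholds.z_min
        and res.perm_p < thresholds.p_max
        and res.r >= thresholds.min_positive
    ]


def results_frame(results: list[ZScoreResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": res.pathway_id,
                "name": res.name,
                "category": res.category,
                "positive": res.r,
                "measured": res.n,
                "z": res.z,
                "perm_p": res.perm_p,
                "selected": res.selected,
            }
            for res in results
        ]
    )


def write_results(results: list[ZScoreResult], path) -> None:
    results_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
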