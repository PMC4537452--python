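"""Active-module detection: high-scoring connected subnetworks of DE genes.

Each gene gets a significance score z_i = Φ⁻¹(1 − p_i) (the standard-normal
quantile of its p-value, clamped away from 0 and 1).  A candidate module A of
k genes is scored by the Stouffer aggregate

    z_A = Σ_{i∈A} z_i / √k,

which is itself standard normal when the z_i are independent standard
normals.  Because gene scores in real data are neither independent nor
centred, z_A is calibrated against a Monte-Carlo null: μ_k and σ_k are the
mean and standard deviation of z_A over random gene sets of each size k
(connectivity is deliberately not enforced in the null), giving the corrected
score s = (z_A − μ_k)/σ_k.

Search is a seeded greedy expansion: starting from each of the highest-z
genes, repeatedly add the adjacent node that raises s the most, stop when no
single addition helps or the size cap is hit.  A slower simulated-annealing
refinement is available as an option.  Unmeasured nodes enter with p = 1
(z at the lower clamp), so they may be traversed as connectors but always
cost score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from . import io as vio
from .network import IntegratedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "P_CLAMP",
    "gene_z",
    "module_score",
    "NullCalibration",
    "calibrate_null",
    "ActiveModule",
    "SearchParams",
    "gene_pvalues_from_expression",
    "search_modules",
]

P_CLAMP = 1e-10


def gene_z(p):
    """Standard-normal quantile of 1 − p, with p clamped to [1e-10, 1 − 1e-10]."""
    p = np.clip(np.asarray(p, dtype=float), P_CLAMP, 1.0 - P_CLAMP)
    out = norm.isf(p)
    return float(out) if out.ndim == 0 else out


def module_score(z_values) -> float:
    """Stouffer aggregate Σz/√k of a gene set's z scores."""
    z = np.asarray(list(z_values), dtype=float)
    if z.size == 0:
        raise ValueError("module_score requires at least one gene")
    return float(z.sum() / math.sqrt(z.size))


@dataclass(frozen=True)
class NullCalibration:
    """Per-size Monte-Carlo null moments of the Stouffer aggregate."""

    mu: dict[int, float]
    sigma: dict[int, float]
    n_samples: int
    seed: int

    def corrected(self, z_sum: float, k: int) -> float:
        return (z_sum / math.sqrt(k) - self.mu[k]) / self.sigma[k]


def calibrate_null(z_values, k_range, n_samples: int = 500,
                   seed: int = 0) -> NullCalibration:
    """Estimate μ_k, σ_k from random gene sets of each size in ``k_range``.

    Sets are drawn uniformly without replacement from all genes; connectivity
    is not required (the null asks how a size-k *collection* of genes scores,
    not a subnetwork).  Deterministic given the seed.
    """
    z = np.asarray(list(z_values), dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain positive sizes")
    if z.size < ks[-1]:
        raise ValueError("more genes required than the largest module size")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    # one permutation per sample; nested prefixes give every k its uniform draw
    perms = np.argsort(rng.random((n_samples, z.size)), axis=1)
    mu: dict[int, float] = {}
    sigma: dict[int, float] = {}
    for k in ks:
        scores = z[perms[:, :k]].sum(axis=1) / math.sqrt(k)
        m = float(scores.mean())
        s = float(scores.std(ddof=1))
        if s <= 1e-12:
            raise ValueError(
                f"degenerate calibration at k={k}: null score variance is zero"
            )
        mu[k] = m
        sigma[k] = s
    return NullCalibration(mu=mu, sigma=sigma, n_samples=n_samples, seed=seed)


@dataclass(frozen=True)
class ActiveModule:
    """A connected gene set with raw aggregate z_A and calibrated score s."""

    genes: tuple[str, ...]
    z_a: float
    s: float

    @property
    def k(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SearchParams:
    n_modules: int = 10
    max_k: int = 30
    restarts: int = 20
    overlap_max: float = 0.5
    n_null_samples: int = 500
    mode: str = "two_sided"        # or "up_only" / "down_only"
    strategy: str = "greedy"       # or "anneal"
    anneal_t0: float = 1.0
    anneal_decay: float = 0.995
    anneal_steps: int = 10_000

    def __post_init__(self):
        if self.mode not in ("two_sided", "up_only", "down_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.strategy not in ("greedy", "anneal"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def gene_pvalues_from_expression(expression, mode: str = "two_sided") -> dict[str, float]:
    """Per-gene p-values for module search.

    ``two_sided`` uses the reported p directly.  Sign-aware modes convert to a
    one-sided p: in ``down_only`` a down-regulated gene gets p/2 and an
    up-regulated gene 1 − p/2 (and symmetrically for ``up_only``), so modules
    of the requested sign score high while the opposite sign is penalised.
    """
    out: dict[str, float] = {}
    for g, fc, p in zip(expression["entity_id"], expression["fold_change"],
                        expression["p_value"]):
        if p is None or (isinstance(p, float) and math.isnan(p)):
            continue
        if mode == "two_sided":
            out[g] = float(p)
            continue
        if fc is None or (isinstance(fc, float) and math.isnan(fc)):
            out[g] = 0.5
            continue
        matches = fc < 0 if mode == "down_only" else fc > 0
        out[g] = float(p / 2.0 if matches else 1.0 - p / 2.0)
    return out


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def search_modules(
    network: IntegratedNetwork,
    p_values: dict[str, float],
    params: SearchParams = SearchParams(),
    seed: int = 0,
    calibration: NullCalibration | None = None,
) -> list[ActiveModule]:
    """Find up to ``n_modules`` high-scoring connected modules.

    Greedy seed-and-expand from the top-``restarts`` genes by z; candidates
    are deduplicated, ranked by calibrated score, and reported subject to a
    pairwise Jaccard-overlap cap.  Ties during expansion are broken by a
    seeded generator, so runs are reproducible given the seed.
    """
    if network.number_of_edges() == 0:
        raise ValueError("network has no edges; module search is undefined")
    if not p_values:
        raise ValueError("no gene has a measured p-value")

    und = network.undirected()
    nodes = sorted(und.nodes)
    z = {n: gene_z(p_values.get(n, 1.0)) for n in nodes}
    measured_genes = [
        n for n in nodes
        if n in p_values
        and network.graph.nodes[n].get("node_type") == vio.NODE_GENE_PRODUCT
    ]
    if not measured_genes:
        raise ValueError("no measured gene nodes present in the network")

    max_k = min(params.max_k, len(nodes))
    if calibration is None:
        calibration = calibrate_null(
            [z[n] for n in nodes], range(1, max_k + 1),
            n_samples=params.n_null_samples, seed=seed,
        )
    rng = np.random.default_rng(seed + 1)

    seeds = sorted(measured_genes, key=lambda n: (-z[n], n))[: params.restarts]
    candidates: dict[frozenset, ActiveModule] = {}
    for start in seeds:
        module = _grow_greedy(und, z, start, max_k, calibration, rng)
        if params.strategy == "anneal":
            module = _refine_anneal(und, z, module, max_k, calibration, rng,
                                    params)
        key = frozenset(module)
        if key not in candidates:
            z_sum = sum(z[n] for n in module)
            candidates[key] = ActiveModule(
                genes=tuple(sorted(module)),
                z_a=z_sum / math.sqrt(len(module)),
                s=calibration.corrected(z_sum, len(module)),
            )

    ranked = sorted(candidates.values(), key=lambda m: (-m.s, m.genes))
    accepted: list[ActiveModule] = []
    for mod in ranked:
        mset = frozenset(mod.genes)
        if all(_jaccard(mset, frozenset(a.genes)) <= params.overlap_max
               for a in accepted):
            accepted.append(mod)
        if len(accepted) == params.n_modules:
            break
    return accepted


def _grow_greedy(und, z, start, max_k, calibration, rng) -> set[str]:
    module = {start}
    z_sum = z[start]
    s = calibration.corrected(z_sum, 1)
    frontier = set(und.neighbors(start)) - module
    while len(module) < max_k and frontier:
        k_new = len(module) + 1
        best_s = -math.inf
        best: list[str] = []
        for cand in frontier:
            cand_s = calibration.corrected(z_sum + z[cand], k_new)
            if cand_s > best_s + 1e-12:
                best_s, best = cand_s, [cand]
            elif abs(cand_s - best_s) <= 1e-12:
                best.append(cand)
        if best_s <= s:
            break
        pick = sorted(best)[rng.integers(len(best))] if len(best) > 1 else best[0]
        module.add(pick)
        z_sum += z[pick]
        s = best_s
        frontier |= set(und.neighbors(pick))
        frontier -= module
    return module


def _connected_without(und, module: set[str], drop: str) -> bool:
    rest = module - {drop}
    if not rest:
        return False
    seen = set()
    stack = [next(iter(rest))]
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        stack.extend(n for n in und.neighbors(node) if n in rest and n not in seen)
    return seen == rest


def _refine_anneal(und, z, module: set[str], max_k, calibration, rng,
                   params: SearchParams) -> set[str]:
    """Metropolis refinement toggling frontier additions / removable members."""
    module = set(module)
    z_sum = sum(z[n] for n in module)
    s = calibration.corrected(z_sum, len(module))
    best_module, best_s = set(module), s
    temp = params.anneal_t0
    for _ in range(params.anneal_steps):
        grow = rng.random() < 0.5 and len(module) < max_k
        if grow:
            frontier = sorted(
                {n for m in module for n in und.neighbors(m)} - module
            )
            if not frontier:
                grow = False
        if grow:
            pick = frontier[rng.integers(len(frontier))]
            new_sum = z_sum + z[pick]
            new_module = module | {pick}
        else:
            removable = sorted(
                n for n in module if _connected_without(und, module, n)
            )
            if not removable:
                temp *= params.anneal_decay
                continue
            pick = removable[rng.integers(len(removable))]
            new_sum = z_sum - z[pick]
            new_module = module - {pick}
        new_s = calibration.corrected(new_sum, len(new_module))
        if new_s >= s or rng.random() < math.exp((new_s - s) / max(temp, 1e-9)):
            module, z_sum, s = new_module, new_sum, new_s
            if s > best_s:
                best_module, best_s = set(module), s
        temp *= params.anneal_decay
    return best_module
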