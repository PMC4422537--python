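"""Mini core extraction: marker-diversity maximization plus baselines.

The optimizer selects a fixed-size subset of the (core) panel maximizing

    weight_mr * mean pairwise Modified Rogers distance within the subset
  + weight_shannon * pooled-band Shannon information of the subset,

with the Shannon term computed on band frequencies pooled over all loci
and normalized by ln(total band count) so both terms live in [0, 1].
Defaults weight the distance term 0.7 and the Shannon term 0.3.

The search runs several independent greedy replicas (random start,
one-for-one swap proposals, accept when the objective does not decrease)
with periodic restart of the worst replica from the global best.  This is
a deliberately simple stochastic subset search verified against
exhaustive enumeration on small instances; it reimplements the published
objective, not any particular optimizer's internals.

Two baseline strategies used for validation are included: proportional
random sampling from marker-tree clusters and from geographic regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .core import _round_half_up, default_target_clusters, stratified_random_selection
from .distance import Dendrogram, modified_rogers_distance
from .diversity import count_alleles_genotypes
from .model import GermplasmPanel, Selection, resolve_subset


@dataclass
class ObjectiveConfig:
    """Weights, target size and search budget for the mini-core search."""

    weight_mr: float = 0.7
    weight_shannon: float = 0.3
    target_fraction: float = 0.2
    steps: int = 2000
    n_replicas: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.weight_mr < 0 or self.weight_shannon < 0:
            raise ValueError("weights must be nonnegative")
        if abs(self.weight_mr + self.weight_shannon - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if not (0.0 < self.target_fraction < 1.0):
            raise ValueError("target_fraction must be in (0, 1)")
        if self.steps < 0 or self.n_replicas < 1:
            raise ValueError("steps must be >= 0 and n_replicas >= 1")


@dataclass
class OptimizationTrace:
    """Per-step search log; best-so-far objective is non-decreasing."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["step", "replica", "objective", "accepted", "best"]
        )
    )


def _pooled_band_matrix(panel: GermplasmPanel) -> np.ndarray:
    """(n, total_bands) 0/1 matrix, missing loci contributing all-zero blocks."""
    blocks = [np.nan_to_num(panel.band_matrices[l.name]) for l in panel.loci]
    return np.concatenate(blocks, axis=1)


def _pooled_shannon(counts: np.ndarray, norm: float) -> float:
    total = counts.sum()
    if total == 0 or norm <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum() / norm)


def objective(
    panel: GermplasmPanel,
    subset: Selection | Sequence[int],
    cfg: ObjectiveConfig | None = None,
) -> float:
    """Weighted mean-MR + pooled-Shannon objective of a subset."""
    cfg = cfg or ObjectiveConfig()
    cfg.validate()
    idx = resolve_subset(panel, subset)
    if len(idx) < 2:
        raise ValueError("subset must contain at least two accessions")
    D = modified_rogers_distance(panel, subset=idx).values
    k = len(idx)
    mean_mr = D[np.triu_indices(k, 1)].mean()
    B = _pooled_band_matrix(panel)
    counts = B[idx].sum(axis=0)
    norm = np.log(B.shape[1])
    return float(cfg.weight_mr * mean_mr + cfg.weight_shannon * _pooled_shannon(counts, norm))


def build_minicore(
    panel: GermplasmPanel, cfg: ObjectiveConfig | None = None
) -> tuple[Selection, OptimizationTrace]:
    """Stochastic multi-replica subset search for the mini core.

    Returns the best subset of exactly round(target_fraction x n)
    accessions found within the step budget, plus the search trace.
    """
    cfg = cfg or ObjectiveConfig()
    cfg.validate()
    n = len(panel)
    size = max(2, _round_half_up(cfg.target_fraction * n))
    if size >= n:
        raise ValueError("target mini core size is the whole panel")
    rng = np.random.default_rng(cfg.seed)
    D = modified_rogers_distance(panel).values
    B = _pooled_band_matrix(panel)
    norm = np.log(B.shape[1])
    n_pairs = size * (size - 1) / 2

    def full_eval(members: np.ndarray):
        pair_sum = D[np.ix_(members, members)].sum() / 2.0
        counts = B[members].sum(axis=0)
        return pair_sum, counts

    def obj(pair_sum: float, counts: np.ndarray) -> float:
        return float(
            cfg.weight_mr * pair_sum / n_pairs
            + cfg.weight_shannon * _pooled_shannon(counts, norm)
        )

    replicas = []
    best_members: np.ndarray | None = None
    best_obj = -np.inf
    for _ in range(cfg.n_replicas):
        members = rng.choice(n, size=size, replace=False)
        pair_sum, counts = full_eval(members)
        value = obj(pair_sum, counts)
        replicas.append({"members": members, "pair_sum": pair_sum, "counts": counts, "obj": value})
        if value > best_obj:
            best_obj, best_members = value, members.copy()

    if cfg.steps == 0:
        warnings.warn("step budget 0: returning best random initial subset")

    rows = []
    restart_every = max(1, cfg.steps // 10)
    for step in range(cfg.steps):
        r = step % cfg.n_replicas
        state = replicas[r]
        members = state["members"]
        out_pos = rng.integers(size)
        u = members[out_pos]
        in_pool = np.setdiff1d(np.arange(n), members, assume_unique=False)
        v = in_pool[rng.integers(len(in_pool))]
        others = np.delete(members, out_pos)
        new_pair_sum = state["pair_sum"] - D[u, others].sum() + D[v, others].sum()
        new_counts = state["counts"] - B[u] + B[v]
        new_obj = obj(new_pair_sum, new_counts)
        accepted = new_obj >= state["obj"]
        if accepted:
            members[out_pos] = v
            state["pair_sum"] = new_pair_sum
            state["counts"] = new_counts
            state["obj"] = new_obj
            if new_obj > best_obj:
                best_obj = new_obj
                best_members = members.copy()
        rows.append((step, r, state["obj"], accepted, best_obj))
        if (step + 1) % restart_every == 0:
            worst = min(range(cfg.n_replicas), key=lambda i: replicas[i]["obj"])
            members = best_members.copy()
            pair_sum, counts = full_eval(members)
            replicas[worst] = {
                "members": members,
                "pair_sum": pair_sum,
                "counts": counts,
                "obj": obj(pair_sum, counts),
            }

    trace = OptimizationTrace(
        pd.DataFrame(rows, columns=["step", "replica", "objective", "accepted", "best"])
    )
    selection = Selection(
        panel=panel,
        indices=sorted(int(i) for i in best_members),
        method="minicore:optimize",
        seed=cfg.seed,
        fraction=cfg.target_fraction,
        objective=best_obj,
    )
    return selection, trace


def exhaustive_minicore(
    panel: GermplasmPanel, size: int, cfg: ObjectiveConfig | None = None
) -> tuple[list[int], float]:
    """Brute-force optimal subset by full enumeration (small panels only)."""
    cfg = cfg or ObjectiveConfig()
    best: tuple[list[int], float] | None = None
    for combo in combinations(range(len(panel)), size):
        val = objective(panel, list(combo), cfg)
        if best is None or val > best[1]:
            best = (list(combo), val)
    return best


def minicore_by_cluster_sampling(
    panel: GermplasmPanel,
    tree: Dendrogram,
    fraction: float = 0.2,
    seed: int = 0,
    cut_height: float | None = None,
    n_clusters: int | None = None,
) -> Selection:
    """Proportional random sampling from marker-tree clusters.

    Clusters come from cutting the marker UPGMA tree at ``cut_height`` or
    into ``n_clusters`` (default max(2, n/50)); each contributes round
    half-up of fraction x size accessions, minimum one.
    """
    if tree.labels != panel.ids:
        raise ValueError("tree leaves do not match panel accessions")
    if cut_height is not None:
        assignment = tree.cut(height=cut_height)
    else:
        k = min(n_clusters or default_target_clusters(len(panel)), len(panel))
        assignment = tree.cut(k=k)
    sel = stratified_random_selection(
        panel, [str(c) for c in assignment], fraction, seed, "minicore:marker-cluster"
    )
    return sel


def minicore_by_region(
    panel: GermplasmPanel, fraction: float = 0.2, seed: int = 0
) -> Selection:
    """Proportional random sampling from geographic regions only."""
    sel = stratified_random_selection(
        panel, panel.regions, fraction, seed, "minicore:region"
    )
    return sel


@dataclass
class MinicoreComparison:
    """Per-locus allele/genotype retention of several selections."""

    per_locus: pd.DataFrame  # MultiIndex columns (selection, metric)
    means: pd.DataFrame  # rows selections, columns n_alleles / n_genotypes
    mean_differences: pd.DataFrame  # pairwise differences of column means


def compare_minicores(
    panel: GermplasmPanel,
    selections: Sequence[Selection],
    names: Sequence[str] | None = None,
) -> MinicoreComparison:
    """Tabulate allele and genotype counts per locus for each selection."""
    if len(selections) < 2:
        raise ValueError("need at least two selections to compare")
    if names is None:
        names = [s.method for s in selections]
        if len(set(names)) != len(names):
            names = [f"{m}#{i}" for i, m in enumerate(names)]
    blocks = {}
    for name, sel in zip(names, selections):
        rep = count_alleles_genotypes(panel, subset=sel)
        blocks[name] = rep.per_locus[["n_alleles", "n_genotypes"]]
    per_locus = pd.concat(blocks, axis=1)
    means = pd.DataFrame(
        {name: blocks[name].mean() for name in names}
    ).T
    diff_rows = {}
    for a in names:
        for b in names:
            if a < b:
                diff_rows[f"{a} - {b}"] = means.loc[a] - means.loc[b]
    mean_differences = pd.DataFrame(diff_rows).T
    return MinicoreComparison(per_locus=per_locus, means=means, mean_differences=mean_differences)
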