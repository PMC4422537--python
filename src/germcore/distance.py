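"""Pairwise dissimilarities and UPGMA dendrograms.

Three dissimilarities are provided: standardized Euclidean on trait
vectors (phenotype), Jaccard on dominant band profiles, and the Modified
Rogers distance on per-locus allele indicator vectors (genotype).  All
three use pairwise deletion for missing data, rescaled so distances stay
comparable across pairs with unequal coverage.

UPGMA (average linkage) is implemented directly so that ties are broken
deterministically by the lexicographically smallest pair of cluster
labels; the resulting merge table follows the scipy linkage layout, so
scipy's hierarchy utilities (fcluster, cophenet) apply to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier

from .model import GermplasmPanel, Selection, resolve_subset


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative dissimilarity matrix with labelled axes."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValueError("distance matrix contains non-finite values")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("negative dissimilarity")
        self.values = np.maximum(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=[str(l) for l in df.index], values=df.to_numpy(float))


class Dendrogram:
    """Binary UPGMA merge tree in scipy linkage layout.

    ``linkage[i] = [left, right, height, size]`` where heights are the
    average inter-cluster distances at merge time (so the cophenetic
    distance between two leaves equals the merge height of their lowest
    common ancestor) and are non-decreasing from leaves to root.
    """

    def __init__(self, linkage: np.ndarray, labels: Sequence[str]) -> None:
        self.linkage = np.asarray(linkage, dtype=float)
        self.labels = list(labels)
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage shape does not match label count")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def root_height(self) -> float:
        return float(self.linkage[-1, 2])

    def cophenetic(self) -> DistanceMatrix:
        """Leaf-pair distances = merge height of the lowest common ancestor."""
        from scipy.spatial.distance import squareform

        cond = _hier.cophenet(self.linkage)
        return DistanceMatrix(labels=list(self.labels), values=squareform(cond))

    def cut(self, height: float | None = None, k: int | None = None) -> np.ndarray:
        """Flat clusters below ``height`` (or forced into ``k`` clusters).

        Returns integer labels 0..m-1 ordered by each cluster's smallest
        member index, so labelling is deterministic.
        """
        if (height is None) == (k is None):
            raise ValueError("give exactly one of height or k")
        if height is not None:
            if height < 0:
                raise ValueError("cut height must be >= 0")
            raw = _hier.fcluster(self.linkage, t=height, criterion="distance")
        else:
            raw = _hier.fcluster(self.linkage, t=k, criterion="maxclust")
        order: dict[int, int] = {}
        for lab in raw:  # first appearance = smallest member index
            if lab not in order:
                order[lab] = len(order)
        return np.array([order[lab] for lab in raw], dtype=int)

    def to_newick(self) -> str:
        n = self.n_leaves
        heights = np.concatenate([np.zeros(n), self.linkage[:, 2]])

        def render(node: int) -> str:
            if node < n:
                return self.labels[node]
            left, right = int(self.linkage[node - n, 0]), int(self.linkage[node - n, 1])
            parts = []
            for child in (left, right):
                bl = heights[node] - heights[child]
                parts.append(f"{render(child)}:{bl:.10g}")
            return "(" + ",".join(parts) + ")"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * n + 100))
        try:
            return render(2 * n - 2) + ";"
        finally:
            sys.setrecursionlimit(old)


# -- trait distance -------------------------------------------------------


def standardized_euclidean(
    panel: GermplasmPanel,
    descriptors: Sequence[str] | None = None,
    subset: Selection | Sequence[int] | None = None,
) -> DistanceMatrix:
    """Euclidean distance on z-scored traits with pairwise deletion.

    Each descriptor is centred and scaled (sample SD, n-1) over the
    analyzed set; a pair's squared distance over its shared non-missing
    descriptors is rescaled by K/K_obs so pairs with unequal coverage
    remain comparable.
    """
    idx = resolve_subset(panel, subset)
    codes = list(descriptors) if descriptors is not None else panel.descriptor_codes
    raw = panel.traits[codes].to_numpy(float)[idx]
    n, K = raw.shape
    if n < 2:
        raise ValueError("need at least two accessions")
    mean = np.nanmean(raw, axis=0)
    sd = np.nanstd(raw, axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)  # constant trait contributes 0 everywhere
    Z = (raw - mean) / sd
    M = ~np.isnan(Z)
    Z0 = np.where(M, Z, 0.0)
    S = Z0**2
    Mf = M.astype(float)
    cross = Z0 @ Z0.T
    si = S @ Mf.T  # sum over k of z_ik^2 where both i and j observed
    k_obs = Mf @ Mf.T
    if np.any(k_obs[np.triu_indices(n, 1)] == 0):
        i, j = np.argwhere(np.triu(k_obs == 0, 1))[0]
        labels = [panel.ids[t] for t in idx]
        raise ValueError(
            f"accessions {labels[i]!r} and {labels[j]!r} share no observed descriptor"
        )
    sq = si + si.T - 2 * cross
    with np.errstate(invalid="ignore"):
        d = np.sqrt(np.maximum(sq * (K / k_obs), 0.0))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(labels=[panel.ids[t] for t in idx], values=d)


# -- marker distances -----------------------------------------------------


def jaccard_distance(
    panel: GermplasmPanel,
    subset: Selection | Sequence[int] | None = None,
) -> DistanceMatrix:
    """1 - Jaccard similarity over band columns, missing loci deleted pairwise.

    Similarity a/(a+b+c): a = bands present in both, b+c = bands present
    in exactly one, counted over loci scored in both accessions.
    """
    idx = resolve_subset(panel, subset)
    n = len(idx)
    if n < 2:
        raise ValueError("need at least two accessions")
    a = np.zeros((n, n))
    union = np.zeros((n, n))
    co = np.zeros((n, n))
    for locus in panel.loci:
        X = panel.band_matrices[locus.name][idx]
        scored = (~np.isnan(X[:, 0])).astype(float)
        X0 = np.nan_to_num(X)
        shared = X0 @ X0.T
        r = X0.sum(axis=1)
        a += shared
        union += np.outer(r, scored) + np.outer(scored, r) - shared
        co += np.outer(scored, scored)
    off = ~np.eye(n, dtype=bool)
    if np.any(co[off] == 0):
        i, j = np.argwhere((co == 0) & off)[0]
        labels = [panel.ids[t] for t in idx]
        raise ValueError(
            f"accessions {labels[i]!r} and {labels[j]!r} share no scored locus"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, a / np.where(union > 0, union, 1.0), 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(labels=[panel.ids[t] for t in idx], values=d)


def modified_rogers_distance(
    panel: GermplasmPanel,
    subset: Selection | Sequence[int] | None = None,
) -> DistanceMatrix:
    """Modified Rogers distance on per-locus allele indicator vectors.

    MR(i,j) = sqrt( sum_l sum_b (x_ib - x_jb)^2 / (2 m) ) over the m loci
    scored in both accessions; a single-band profile is the unit indicator
    vector, so two fully distinct homozygotes are at distance 1.
    """
    idx = resolve_subset(panel, subset)
    n = len(idx)
    if n < 2:
        raise ValueError("need at least two accessions")
    sq = np.zeros((n, n))
    m_loci = np.zeros((n, n))
    for locus in panel.loci:
        X = panel.band_matrices[locus.name][idx]
        rowsum = np.nansum(X, axis=1)
        scored = (~np.isnan(X[:, 0])) & (rowsum > 0)
        X0 = np.where(scored[:, None], np.nan_to_num(X), 0.0)
        X0 = X0 / np.where(rowsum > 0, rowsum, 1.0)[:, None]
        s2 = (X0**2).sum(axis=1)
        cross = X0 @ X0.T
        pair_sq = s2[:, None] + s2[None, :] - 2 * cross
        mask = np.outer(scored, scored)
        sq += np.where(mask, pair_sq, 0.0)
        m_loci += mask
    off = ~np.eye(n, dtype=bool)
    if np.any(m_loci[off] == 0):
        i, j = np.argwhere((m_loci == 0) & off)[0]
        labels = [panel.ids[t] for t in idx]
        raise ValueError(
            f"accessions {labels[i]!r} and {labels[j]!r} share no scored locus"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(sq / np.where(m_loci > 0, 2 * m_loci, 1.0), 0.0))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(labels=[panel.ids[t] for t in idx], values=d)


# -- UPGMA ----------------------------------------------------------------


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration with lexicographic tie-breaking.

    At each step the pair of clusters with minimal average inter-cluster
    distance is merged at that distance; among tied pairs, the one whose
    (smallest-label, smallest-label) pair sorts lexicographically first
    wins, making the tree independent of input order up to relabelling.
    """
    n = len(dist)
    if n < 2:
        raise ValueError("need at least two leaves")
    D = dist.values.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    cluster_id = list(range(n))  # scipy node id occupying each slot
    sizes = np.ones(n)
    minlab = [dist.labels[i] for i in range(n)]
    active = np.ones(n, dtype=bool)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = np.where(active)[0]
        block = D[np.ix_(sub, sub)]
        m = block.min()
        ties = np.argwhere(np.isclose(block, m, rtol=0, atol=0))
        best = None
        for a, b in ties:
            if a >= b:
                continue
            i, j = sub[a], sub[b]
            key = tuple(sorted((minlab[i], minlab[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        ci, cj = cluster_id[i], cluster_id[j]
        Z[step] = [min(ci, cj), max(ci, cj), m, sizes[i] + sizes[j]]
        # average-linkage update into slot i
        new = (sizes[i] * D[i] + sizes[j] * D[j]) / (sizes[i] + sizes[j])
        D[i, :] = new
        D[:, i] = new
        D[i, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        sizes[i] += sizes[j]
        minlab[i] = min(minlab[i], minlab[j])
        cluster_id[i] = n + step
        active[j] = False
    return Dendrogram(Z, dist.labels)


def cut_tree(tree: Dendrogram, height: float) -> dict[str, int]:
    """Flat clusters below ``height`` as a label -> cluster-index mapping."""
    assignment = tree.cut(height=height)
    return dict(zip(tree.labels, (int(c) for c in assignment)))


# -- group-level dissimilarity --------------------------------------------


def group_dissimilarity(
    panel: GermplasmPanel,
    grouping: Mapping[str, str],
) -> DistanceMatrix:
    """Modified Rogers distance between pooled group allele frequencies.

    ``grouping`` maps accession id to group label; unmapped accessions are
    ignored (useful for trait-class groupings with missing values).  Each
    group is reduced to its per-locus allele frequency vector and the MR
    formula is applied to those vectors over loci scored in both groups.
    """
    from .diversity import allele_frequencies

    groups: dict[str, list[int]] = {}
    for i, acc_id in enumerate(panel.ids):
        if acc_id in grouping:
            groups.setdefault(str(grouping[acc_id]), []).append(i)
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need at least two nonempty groups")
    for lab in labels:
        if not groups[lab]:
            raise ValueError(f"group {lab!r} is empty")
    tables = {lab: allele_frequencies(panel, subset=groups[lab]) for lab in labels}
    g = len(labels)
    d = np.zeros((g, g))
    for a in range(g):
        for b in range(a + 1, g):
            ta, tb = tables[labels[a]], tables[labels[b]]
            sq = 0.0
            m = 0
            for locus in panel.loci:
                if ta.n_scored[locus.name] == 0 or tb.n_scored[locus.name] == 0:
                    continue
                pa = ta.frequencies[locus.name]
                pb = tb.frequencies[locus.name]
                sq += float(np.sum((pa - pb) ** 2))
                m += 1
            if m == 0:
                raise ValueError(
                    f"groups {labels[a]!r} and {labels[b]!r} share no scored locus"
                )
            d[a, b] = d[b, a] = np.sqrt(sq / (2 * m))
    return DistanceMatrix(labels=labels, values=d)
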