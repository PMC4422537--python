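"""Core collection construction.

A core collection is built by geographic stratification (one stratum per
passport region), UPGMA clustering of standardized trait vectors within
each stratum, and proportional random sampling from each cluster: round
half-up of fraction x cluster size, with a minimum of one accession per
nonempty cluster.  A stratum with a single accession is included with
probability ``fraction``.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .distance import standardized_euclidean, upgma
from .model import GermplasmPanel, Selection

if TYPE_CHECKING:  # pragma: no cover
    from .validation import ComparisonReport


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def default_target_clusters(region_size: int) -> int:
    """Default phenotypic cluster count for a stratum: max(2, size/50)."""
    return max(2, _round_half_up(region_size / 50))


def build_core(
    panel: GermplasmPanel,
    fraction: float = 0.2,
    cut_height: float | None = None,
    target_clusters: int | None = None,
    descriptors: Sequence[str] | None = None,
    seed: int = 0,
    exact_size: bool = False,
) -> Selection:
    """Stratify by region, cluster traits within strata, sample per cluster.

    ``cut_height`` cuts each stratum's UPGMA tree at a fixed standardized
    Euclidean distance; ``target_clusters`` forces a cluster count instead
    (default: max(2, stratum_size/50)).  With ``exact_size`` the selection
    is trimmed/padded uniformly at random to exactly
    round(fraction x panel size).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    if len(panel) == 0:
        raise ValueError("empty panel")
    if cut_height is not None and target_clusters is not None:
        raise ValueError("give at most one of cut_height and target_clusters")
    rng = np.random.default_rng(seed)

    regions: dict[str, list[int]] = {}
    for i, region in enumerate(panel.regions):
        regions.setdefault(region, []).append(i)

    selected: list[int] = []
    stratum_counts: dict[str, int] = {}
    for region in sorted(regions):
        members = regions[region]
        if len(members) == 1:
            take = [members[0]] if rng.random() < fraction else []
        else:
            take = _sample_stratum(
                panel, members, fraction, cut_height, target_clusters, descriptors, rng
            )
        stratum_counts[region] = len(take)
        selected.extend(take)

    if exact_size:
        target = _round_half_up(fraction * len(panel))
        selected = _adjust_to_target(selected, target, len(panel), rng)
        stratum_counts = {}  # per-stratum counts no longer exact after adjustment
    selected.sort()
    return Selection(
        panel=panel,
        indices=selected,
        method="core:stratified-cluster",
        seed=seed,
        fraction=fraction,
        stratum_counts=stratum_counts,
    )


def _sample_stratum(
    panel: GermplasmPanel,
    members: list[int],
    fraction: float,
    cut_height: float | None,
    target_clusters: int | None,
    descriptors: Sequence[str] | None,
    rng: np.random.Generator,
) -> list[int]:
    dist = standardized_euclidean(panel, descriptors=descriptors, subset=members)
    tree = upgma(dist)
    if cut_height is not None:
        assignment = tree.cut(height=cut_height)
    else:
        k = min(target_clusters or default_target_clusters(len(members)), len(members))
        assignment = tree.cut(k=k)
    take: list[int] = []
    for cluster in range(assignment.max() + 1):
        cluster_members = [members[j] for j in np.flatnonzero(assignment == cluster)]
        n_take = max(1, _round_half_up(fraction * len(cluster_members)))
        picked = rng.choice(len(cluster_members), size=n_take, replace=False)
        take.extend(cluster_members[j] for j in picked)
    return take


def _adjust_to_target(
    selected: list[int], target: int, n: int, rng: np.random.Generator
) -> list[int]:
    selected = list(selected)
    if len(selected) > target:
        drop = rng.choice(len(selected), size=len(selected) - target, replace=False)
        keep = set(range(len(selected))) - set(drop.tolist())
        selected = [selected[j] for j in sorted(keep)]
    elif len(selected) < target:
        pool = sorted(set(range(n)) - set(selected))
        add = rng.choice(len(pool), size=target - len(selected), replace=False)
        selected.extend(pool[j] for j in add)
    return selected


def stratified_random_selection(
    panel: GermplasmPanel,
    strata: Sequence[str],
    fraction: float,
    seed: int,
    method: str,
) -> Selection:
    """Proportional random sampling from arbitrary stratum labels.

    Shared backend for region-only cores/mini cores and marker-cluster
    sampling: per stratum, round half-up of fraction x size with the
    min-1 rule; singleton strata enter with probability ``fraction``.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if len(strata) != len(panel):
        raise ValueError("one stratum label per accession required")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(strata):
        groups.setdefault(str(s), []).append(i)
    selected: list[int] = []
    stratum_counts: dict[str, int] = {}
    for label in sorted(groups):
        members = groups[label]
        if len(members) == 1 and fraction < 1.0:
            take = [members[0]] if rng.random() < fraction else []
        else:
            n_take = min(len(members), max(1, _round_half_up(fraction * len(members))))
            picked = rng.choice(len(members), size=n_take, replace=False)
            take = [members[j] for j in picked]
        stratum_counts[label] = len(take)
        selected.extend(take)
    selected.sort()
    return Selection(
        panel=panel,
        indices=selected,
        method=method,
        seed=seed,
        fraction=fraction,
        stratum_counts=stratum_counts,
    )


def validate_core_representativeness(
    panel: GermplasmPanel, core: Selection
) -> "ComparisonReport":
    """Compare the core against its source panel (delegates to
    :func:`germcore.validation.compare_collections`)."""
    if len(core) == 0:
        raise ValueError("core selection is empty")
    from .validation import compare_collections

    return compare_collections(panel, core)
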