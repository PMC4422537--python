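"""Statistical comparison of a germplasm subset against its source.

Covers the summary statistics used to judge core/mini-core
representativeness: the Brown-Mood median ("equality") test, a binned
chi-square homogeneity test on shared trait classes, quantile-quantile
comparison with a plugin Kullback-Leibler distance, the Mantel
permutation test between phenotypic and genotypic distance matrices, and
Fisher-z comparison of trait correlation coefficients between subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distance import DistanceMatrix, modified_rogers_distance, standardized_euclidean
from .diversity import reference_bin_edges, summary_stats
from .model import GermplasmPanel, Selection, resolve_subset


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: int | None = None
    degenerate: bool = False


def equality_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Brown-Mood median test of two samples.

    Pools both samples, splits each at the pooled median, and applies the
    chi-square test (1 df, no continuity correction) to the resulting 2x2
    table.  Degenerate inputs (all values equal, or an empty side of the
    split) return p = 1 with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least two non-missing values")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, 1, degenerate=True)
    try:
        res = stats.median_test(x, y, ties="below", correction=False)
    except ValueError:
        return TestResult(0.0, 1.0, 1, degenerate=True)
    stat, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(stat):
        return TestResult(0.0, 1.0, 1, degenerate=True)
    return TestResult(stat, p, 1)


def _pool_sparse_classes(table: np.ndarray) -> np.ndarray:
    """Merge adjacent classes until every expected count is >= 1."""
    table = table.astype(float)
    while table.shape[1] > 1:
        col_tot = table.sum(axis=0)
        expected = np.outer(table.sum(axis=1), col_tot) / table.sum()
        if (expected >= 1.0).all():
            break
        j = int(np.argmin(col_tot))
        neighbor = j + 1 if j + 1 < table.shape[1] else j - 1
        table[:, neighbor] += table[:, j]
        table = np.delete(table, j, axis=1)
    return table


def homogeneity_test(
    x: Sequence[float],
    y: Sequence[float],
    n_classes: int,
    bin_edges: np.ndarray | None = None,
) -> TestResult:
    """Chi-square homogeneity of two samples over shared trait classes.

    Both samples are binned into the same equal-width classes (edges from
    the reference collection, or from the pooled samples when omitted);
    classes with expected count < 1 are pooled into neighbors before the
    2 x k' chi-square test with k'-1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if bin_edges is None:
        pooled = np.concatenate([x, y])
        bin_edges = np.linspace(pooled.min(), pooled.max(), n_classes + 1)
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
        n_classes = len(bin_edges) - 1
    if bin_edges[-1] - bin_edges[0] <= 0:
        return TestResult(0.0, 1.0, 0, degenerate=True)

    def bin_counts(v: np.ndarray) -> np.ndarray:
        b = np.clip(np.digitize(v, bin_edges[1:-1]), 0, n_classes - 1)
        return np.bincount(b, minlength=n_classes)

    table = np.vstack([bin_counts(x), bin_counts(y)])
    occupied = table.sum(axis=0) > 0
    table = table[:, occupied]
    table = _pool_sparse_classes(table)
    if table.shape[1] < 2:
        return TestResult(0.0, 1.0, 0, degenerate=True)
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(stat), float(p), int(df))


@dataclass
class QQResult:
    quantiles_x: np.ndarray
    quantiles_y: np.ndarray
    kl: float


def qq_kl(
    x: Sequence[float],
    y: Sequence[float],
    quantile_step: float = 0.005,
    n_bins: int = 20,
) -> QQResult:
    """Q-Q quantile pairs plus a plugin Kullback-Leibler distance.

    Empirical quantiles of both samples are taken on the interior grid
    {step, 2 step, ..., 1-step} with linear interpolation; the two
    quantile vectors are discretized into shared equal-width bins and
    KL(p||q) = sum p ln(p/q) is computed after symmetric add-one
    smoothing of the bin counts.
    """
    if not (0.0 < quantile_step < 0.5):
        raise ValueError("quantile_step must be in (0, 0.5)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    grid = np.arange(quantile_step, 1.0 - quantile_step / 2, quantile_step)
    qx = np.quantile(x, grid)
    qy = np.quantile(y, grid)
    lo = min(qx.min(), qy.min())
    hi = max(qx.max(), qy.max())
    if hi - lo <= 0:  # both constant: identical binned distributions
        return QQResult(qx, qy, 0.0)
    edges = np.linspace(lo, hi, n_bins + 1)
    cx = np.histogram(qx, bins=edges)[0]
    cy = np.histogram(qy, bins=edges)[0]
    if np.array_equal(cx, cy):
        return QQResult(qx, qy, 0.0)
    p = (cx + 1.0) / (cx.sum() + n_bins)
    q = (cy + 1.0) / (cy.sum() + n_bins)
    kl = float(np.sum(p * np.log(p / q)))
    return QQResult(qx, qy, kl)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    degenerate: bool = False


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel permutation test between two labelled distance matrices.

    r is the Pearson correlation of the upper triangles; significance
    comes from simultaneous row/column permutation of the second matrix,
    with p = (1 + #{r_perm >= r_obs}) / (1 + n_perm) for the one-sided
    (greater) test, or using |r| for the two-sided option.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels and order")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    n = len(d1)
    iu = np.triu_indices(n, 1)
    a = d1.values[iu]
    if a.std() == 0:
        return MantelResult(np.nan, np.nan, n_perm, degenerate=True)
    rng = np.random.default_rng(seed)
    az = (a - a.mean()) / a.std()

    def corr(mat: np.ndarray) -> float:
        b = mat[iu]
        sd = b.std()
        if sd == 0:
            return 0.0
        return float((az * (b - b.mean()) / sd).mean())

    b0 = d2.values[iu]
    if b0.std() == 0:
        return MantelResult(np.nan, np.nan, n_perm, degenerate=True)
    r_obs = corr(d2.values)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(d2.values[np.ix_(perm, perm)])
        if alternative == "greater":
            count += r_p >= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r_obs, float(p), n_perm)


def compare_correlations(
    panel: GermplasmPanel,
    subset_a: Selection | Sequence[int],
    subset_b: Selection | Sequence[int],
) -> pd.DataFrame:
    """Fisher-z test of each trait pair's Pearson r between two subsets.

    z = (z_a - z_b) / sqrt(1/(n_a - 3) + 1/(n_b - 3)) with two-sided
    normal p; |r| = 1 yields an infinite statistic flagged with p = 0.
    """
    idx_a = resolve_subset(panel, subset_a)
    idx_b = resolve_subset(panel, subset_b)
    if len(idx_a) < 4 or len(idx_b) < 4:
        raise ValueError("need at least four accessions per subset")
    codes = panel.descriptor_codes
    ta = panel.traits.iloc[idx_a]
    tb = panel.traits.iloc[idx_b]
    rows = []
    for i, c1 in enumerate(codes):
        for c2 in codes[i + 1 :]:
            pa = ta[[c1, c2]].dropna()
            pb = tb[[c1, c2]].dropna()
            n_a, n_b = len(pa), len(pb)
            if n_a < 4 or n_b < 4:
                continue
            r_a = float(pa[c1].corr(pa[c2]))
            r_b = float(pb[c1].corr(pb[c2]))
            if abs(r_a) >= 1.0 or abs(r_b) >= 1.0:
                z, p = np.inf, 0.0
            else:
                za, zb = np.arctanh(r_a), np.arctanh(r_b)
                se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
                z = (za - zb) / se
                p = 2 * stats.norm.sf(abs(z))
            rows.append(
                {
                    "pair": f"{c1}:{c2}",
                    "r_a": r_a,
                    "r_b": r_b,
                    "n_a": n_a,
                    "n_b": n_b,
                    "z": float(z),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows).set_index("pair")


@dataclass
class ComparisonReport:
    """Full subset-vs-reference comparison in a per-descriptor table layout."""

    per_descriptor: pd.DataFrame
    correlation_comparison: pd.DataFrame
    mantel: MantelResult | None

    @property
    def max_relative_mean_difference(self) -> float:
        """Largest |mean_subset - mean_ref| / mean_ref across descriptors, %."""
        return float(self.per_descriptor["rel_mean_diff_pct"].max())

    def to_csv(self, path) -> None:
        self.per_descriptor.to_csv(path, index_label="descriptor")


def compare_collections(
    panel: GermplasmPanel,
    subset: Selection | Sequence[int],
    reference: Selection | Sequence[int] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    run_mantel: bool = True,
) -> ComparisonReport:
    """Assemble the per-descriptor and global comparison of a subset.

    The reference defaults to the whole panel; class bins and Shannon
    normalization always come from the whole panel so that collections of
    different sizes are compared on one shared class system.  The Mantel
    test correlates the subset's standardized Euclidean (trait) and
    Modified Rogers (marker) distance matrices.
    """
    idx_sub = resolve_subset(panel, subset)
    idx_ref = resolve_subset(panel, reference)
    if len(idx_sub) == 0:
        raise ValueError("subset is empty")
    stats_sub = summary_stats(panel, subset=idx_sub, reference=panel)
    stats_ref = summary_stats(panel, subset=idx_ref, reference=panel)
    rows = []
    for d in panel.descriptors:
        x = panel.traits[d.code].to_numpy(float)[idx_ref]
        y = panel.traits[d.code].to_numpy(float)[idx_sub]
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        edges = reference_bin_edges(panel, d.code, d.n_classes)
        eq = equality_test(x, y)
        hom = homogeneity_test(x, y, d.n_classes, bin_edges=edges)
        qq = qq_kl(x, y)
        mean_ref = stats_ref.per_descriptor.loc[d.code, "mean"]
        mean_sub = stats_sub.per_descriptor.loc[d.code, "mean"]
        rows.append(
            {
                "descriptor": d.code,
                "mean_ref": mean_ref,
                "mean_subset": mean_sub,
                "rel_mean_diff_pct": abs(mean_sub - mean_ref) / abs(mean_ref) * 100
                if mean_ref != 0
                else np.nan,
                "var_ref": stats_ref.per_descriptor.loc[d.code, "variance"],
                "var_subset": stats_sub.per_descriptor.loc[d.code, "variance"],
                "equality_p": eq.p_value,
                "homogeneity_p": hom.p_value,
                "n_classes": d.n_classes,
                "H_prime_ref": stats_ref.per_descriptor.loc[d.code, "H_prime"],
                "H_prime_subset": stats_sub.per_descriptor.loc[d.code, "H_prime"],
                "qq_kl": qq.kl,
            }
        )
    per_descriptor = pd.DataFrame(rows).set_index("descriptor")
    corr_cmp = compare_correlations(panel, idx_ref, idx_sub)
    mantel = None
    if run_mantel and len(idx_sub) >= 3:
        d_trait = standardized_euclidean(panel, subset=idx_sub)
        d_marker = modified_rogers_distance(panel, subset=idx_sub)
        mantel = mantel_test(d_trait, d_marker, n_perm=n_perm, seed=seed)
    return ComparisonReport(
        per_descriptor=per_descriptor,
        correlation_comparison=corr_cmp,
        mantel=mantel,
    )
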