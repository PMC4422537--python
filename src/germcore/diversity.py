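"""Diversity and heterozygosity statistics on traits and SSR band data.

Marker-side indices follow the PopGene conventions on allele (band)
frequencies: Shannon's information index I = -sum p ln p, Nei's expected
heterozygosity (gene diversity) H_T = 1 - sum p^2, and the polymorphism
information content PIC = 1 - sum p^2 - sum_{i<j} 2 p_i^2 p_j^2.  Natural
logarithms throughout.

The trait-side Shannon-Weaver index bins each descriptor into equal-width
classes over a reference collection's range and normalizes by ln(number
of classes), so whole/core/mini-core values are comparable on one shared
class system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GermplasmPanel, Selection, resolve_subset

_FREQ_TOL = 1e-9


@dataclass
class AlleleFrequencyTable:
    """Per-locus relative band frequencies plus how many profiles were scored.

    A locus where no accession was scored keeps an all-zero frequency
    vector and n_scored 0 (flagged empty) rather than NaNs.
    """

    locus_names: list[str]
    band_labels: dict[str, tuple[str, ...]]
    frequencies: dict[str, np.ndarray]
    n_scored: dict[str, int]

    def __post_init__(self) -> None:
        for name in self.locus_names:
            p = np.asarray(self.frequencies[name], dtype=float)
            if np.any(p < 0):
                raise ValueError(f"locus {name}: negative frequency")
            if self.n_scored[name] > 0 and abs(p.sum() - 1.0) > _FREQ_TOL:
                raise ValueError(f"locus {name}: frequencies sum to {p.sum()}")
            self.frequencies[name] = p

    def is_empty(self, locus: str) -> bool:
        return self.n_scored[locus] == 0


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("frequency vector must be 1-D and nonempty")
    if np.any(p < 0):
        raise ValueError("negative frequency")
    if abs(p.sum() - 1.0) > _FREQ_TOL:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return p


def allele_frequencies(
    panel: GermplasmPanel,
    subset: Selection | Sequence[int] | None = None,
) -> AlleleFrequencyTable:
    """Relative band frequencies per locus over the (sub)panel.

    The denominator is the total number of band observations at the locus
    (an accession presenting two bands at a locus contributes two
    observations); accessions missing at a locus are excluded from that
    locus only.
    """
    idx = resolve_subset(panel, subset)
    freqs: dict[str, np.ndarray] = {}
    n_scored: dict[str, int] = {}
    band_labels: dict[str, tuple[str, ...]] = {}
    for locus in panel.loci:
        X = panel.band_matrices[locus.name][idx]
        rowsum = np.nansum(X, axis=1)
        scored = (~np.isnan(X[:, 0])) & (rowsum > 0)
        band_labels[locus.name] = locus.band_labels
        n_scored[locus.name] = int(scored.sum())
        if n_scored[locus.name] == 0:
            freqs[locus.name] = np.zeros(len(locus.band_labels))
            continue
        counts = np.nan_to_num(X[scored]).sum(axis=0)
        freqs[locus.name] = counts / counts.sum()
    return AlleleFrequencyTable(
        locus_names=panel.locus_names,
        band_labels=band_labels,
        frequencies=freqs,
        n_scored=n_scored,
    )


def shannon_information_index(freqs: np.ndarray) -> float:
    """I = -sum_i p_i ln p_i; zero-frequency terms contribute 0."""
    p = _check_freqs(freqs)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def nei_expected_heterozygosity(freqs: np.ndarray) -> float:
    """H_T = 1 - sum_i p_i^2: chance that two random alleles differ."""
    p = _check_freqs(freqs)
    return float(1.0 - (p**2).sum())


def pic(freqs: np.ndarray) -> float:
    """Polymorphism information content, 1 - sum p^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = _check_freqs(freqs)
    p2 = p**2
    cross = ((p2.sum()) ** 2 - (p2**2).sum())  # 2 * sum_{i<j} p_i^2 p_j^2
    return float(1.0 - p2.sum() - cross)


@dataclass
class DiversityReport:
    """Per-locus marker diversity summary table."""

    per_locus: pd.DataFrame  # index locus; columns n_alleles, n_genotypes, I, H_T, PIC
    total_alleles: int
    total_multilocus_genotypes: int
    means: pd.Series
    sds: pd.Series


def count_alleles_genotypes(
    panel: GermplasmPanel,
    subset: Selection | Sequence[int] | None = None,
) -> DiversityReport:
    """Observed allele and genotype counts plus diversity indices per locus.

    A locus genotype is the exact band pattern; accessions missing at a
    locus are excluded from that locus's tally.  The multilocus genotype
    count considers accessions scored at every locus.
    """
    idx = resolve_subset(panel, subset)
    table = allele_frequencies(panel, subset=idx)
    rows = []
    multilocus: dict[int, tuple] = {i: () for i in idx}
    complete = {i: True for i in idx}
    for locus in panel.loci:
        X = panel.band_matrices[locus.name][idx]
        scored = ~np.isnan(X[:, 0])
        patterns = set()
        for r in np.flatnonzero(scored):
            patterns.add(tuple(X[r].astype(int)))
        for pos, i in enumerate(idx):
            if scored[pos]:
                multilocus[i] = multilocus[i] + (tuple(X[pos].astype(int)),)
            else:
                complete[i] = False
        p = table.frequencies[locus.name]
        n_alleles = int((p > 0).sum())
        rows.append(
            {
                "locus": locus.name,
                "n_alleles": n_alleles,
                "n_genotypes": len(patterns),
                "I": shannon_information_index(p) if not table.is_empty(locus.name) else 0.0,
                "H_T": nei_expected_heterozygosity(p) if not table.is_empty(locus.name) else 0.0,
                "PIC": pic(p) if not table.is_empty(locus.name) else 0.0,
            }
        )
    per_locus = pd.DataFrame(rows).set_index("locus")
    distinct = {multilocus[i] for i in idx if complete[i]}
    num = per_locus[["n_alleles", "n_genotypes", "I", "H_T", "PIC"]]
    return DiversityReport(
        per_locus=per_locus,
        total_alleles=int(per_locus["n_alleles"].sum()),
        total_multilocus_genotypes=len(distinct),
        means=num.mean(),
        sds=num.std(ddof=1),
    )


def reference_bin_edges(
    panel: GermplasmPanel, descriptor: str, n_classes: int | None = None
) -> np.ndarray:
    """Equal-width class edges over the reference panel's observed range."""
    d = panel.descriptor(descriptor)
    k = n_classes if n_classes is not None else d.n_classes
    values = panel.traits[descriptor].to_numpy(float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError(f"descriptor {descriptor}: all values missing")
    lo, hi = float(values.min()), float(values.max())
    return np.linspace(lo, hi, k + 1)


def trait_shannon_index(
    panel: GermplasmPanel,
    descriptor: str,
    n_classes: int | None = None,
    bin_edges: np.ndarray | None = None,
    subset: Selection | Sequence[int] | None = None,
) -> float:
    """Shannon-Weaver H' of a binned trait, normalized by ln(n_classes).

    Bin edges default to equal-width classes over the whole panel's range
    so that subset indices are comparable; values outside the reference
    range are clipped into the end classes.
    """
    idx = resolve_subset(panel, subset)
    d = panel.descriptor(descriptor)
    k = n_classes if n_classes is not None else d.n_classes
    if k < 2:
        raise ValueError("n_classes must be >= 2")
    if bin_edges is None:
        bin_edges = reference_bin_edges(panel, descriptor, k)
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
        k = len(bin_edges) - 1
    values = panel.traits[descriptor].to_numpy(float)[idx]
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError(f"descriptor {descriptor}: all values missing in subset")
    if bin_edges[-1] - bin_edges[0] <= 0:
        warnings.warn(f"descriptor {descriptor}: zero-width range, H'=0")
        return 0.0
    bins = np.clip(np.digitize(values, bin_edges[1:-1]), 0, k - 1)
    counts = np.bincount(bins, minlength=k)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(k))


@dataclass
class TraitDiversityReport:
    """Per-descriptor summary table for one collection."""

    per_descriptor: pd.DataFrame  # index code; mean, variance, H_prime, n_classes, n
    correlations: pd.DataFrame  # trait-pair Pearson correlation matrix


def summary_stats(
    panel: GermplasmPanel,
    subset: Selection | Sequence[int] | None = None,
    reference: GermplasmPanel | None = None,
) -> TraitDiversityReport:
    """Per-descriptor mean, sample variance, Shannon-Weaver H', correlations.

    ``reference`` supplies the bin edges for H' (defaults to the panel
    itself); variances use the n-1 denominator and missing values are
    excluded per descriptor.
    """
    idx = resolve_subset(panel, subset)
    ref = reference if reference is not None else panel
    sub = panel.traits.iloc[idx]
    rows = []
    for d in panel.descriptors:
        values = sub[d.code].to_numpy(float)
        values = values[~np.isnan(values)]
        mean = float(values.mean()) if values.size else np.nan
        if values.size >= 2:
            var = float(values.var(ddof=1))
        else:
            var = np.nan  # flagged: variance undefined below two values
        edges = reference_bin_edges(ref, d.code, d.n_classes)
        h = trait_shannon_index(panel, d.code, d.n_classes, bin_edges=edges, subset=idx)
        rows.append(
            {
                "code": d.code,
                "mean": mean,
                "variance": var,
                "H_prime": h,
                "n_classes": d.n_classes,
                "n": values.size,
            }
        )
    per_descriptor = pd.DataFrame(rows).set_index("code")
    correlations = sub.corr(method="pearson")
    return TraitDiversityReport(per_descriptor=per_descriptor, correlations=correlations)
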