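"""Shared data model for germplasm panels.

A panel bundles three views of the same ordered set of accessions:
passport data (country, region stratum), quantitative trait descriptors,
and dominant-scored SSR band profiles grouped by locus.  Bands are scored
presence/absence, so each band is treated as one allele of its locus; a
missing score at a locus is distinct from "band absent" and removes the
accession from that locus only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TraitDescriptor:
    """A quantitative descriptor, e.g. primary leaf length (V040).

    ``n_classes`` is the number of equal-width phenotype classes used when
    the descriptor is binned for Shannon-Weaver diversity and homogeneity
    tests.
    """

    code: str
    label: str = ""
    units: str = ""
    n_classes: int = 10

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"descriptor {self.code}: n_classes must be >= 2")


@dataclass(frozen=True)
class LocusDef:
    """One SSR locus and the ordered band (allele) labels scored at it."""

    name: str
    band_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.band_labels) < 1:
            raise ValueError(f"locus {self.name}: needs at least one band")
        if len(set(self.band_labels)) != len(self.band_labels):
            raise ValueError(f"locus {self.name}: duplicate band labels")


@dataclass(frozen=True)
class Accession:
    """A single genebank entry: passport info, trait values, band profile.

    ``traits`` maps descriptor code to value (missing codes omitted);
    ``bands`` maps locus name to the frozenset of present band labels, or
    ``None`` when the locus was not scored for this accession.
    """

    id: str
    country: str
    region: str
    traits: Mapping[str, float]
    bands: Mapping[str, frozenset | None]


class GermplasmPanel:
    """Ordered collection of accessions with trait and band matrices.

    Internally traits are a float DataFrame (NaN = missing) and bands are,
    per locus, an (n_accessions, n_bands) 0/1 float matrix whose rows are
    NaN when the accession is missing at that locus.  Ordering follows the
    passport table and is stable under round-trips.
    """

    def __init__(
        self,
        ids: Sequence[str],
        countries: Sequence[str],
        regions: Sequence[str],
        descriptors: Sequence[TraitDescriptor],
        loci: Sequence[LocusDef],
        traits: pd.DataFrame,
        band_matrices: Mapping[str, np.ndarray],
    ) -> None:
        ids = list(ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate accession ids: {dupes}")
        if any(not i for i in ids):
            raise ValueError("empty accession id")
        self.ids = ids
        self.countries = list(countries)
        self.regions = list(regions)
        self.descriptors = list(descriptors)
        self.loci = list(loci)
        codes = [d.code for d in self.descriptors]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate descriptor codes")
        self.traits = traits.reindex(index=ids, columns=codes).astype(float)
        self.band_matrices: dict[str, np.ndarray] = {}
        for locus in self.loci:
            m = np.asarray(band_matrices[locus.name], dtype=float)
            if m.shape != (len(ids), len(locus.band_labels)):
                raise ValueError(
                    f"locus {locus.name}: band matrix shape {m.shape} does not "
                    f"match ({len(ids)}, {len(locus.band_labels)})"
                )
            valid = np.isnan(m) | (m == 0.0) | (m == 1.0)
            if not valid.all():
                r, c = np.argwhere(~valid)[0]
                raise ValueError(
                    f"locus {locus.name}: non-binary band value {m[r, c]!r} at "
                    f"accession {ids[r]!r}, band {locus.band_labels[c]!r}"
                )
            # missing is locus-level: any NaN cell blanks the whole row
            row_missing = np.isnan(m).any(axis=1)
            m = m.copy()
            m[row_missing] = np.nan
            self.band_matrices[locus.name] = m

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_accessions(self) -> int:
        return len(self.ids)

    @property
    def descriptor_codes(self) -> list[str]:
        return [d.code for d in self.descriptors]

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def descriptor(self, code: str) -> TraitDescriptor:
        for d in self.descriptors:
            if d.code == code:
                return d
        raise KeyError(code)

    def band_missing_mask(self) -> np.ndarray:
        """(n_accessions, n_loci) boolean matrix, True where locus unscored."""
        cols = [np.isnan(self.band_matrices[l.name][:, 0]) for l in self.loci]
        return np.column_stack(cols)

    def accession(self, index: int) -> Accession:
        traits = {
            c: v
            for c, v in self.traits.iloc[index].items()
            if not np.isnan(v)
        }
        bands: dict[str, frozenset | None] = {}
        for locus in self.loci:
            row = self.band_matrices[locus.name][index]
            if np.isnan(row[0]):
                bands[locus.name] = None
            else:
                bands[locus.name] = frozenset(
                    lab for lab, v in zip(locus.band_labels, row) if v == 1.0
                )
        return Accession(
            id=self.ids[index],
            country=self.countries[index],
            region=self.regions[index],
            traits=traits,
            bands=bands,
        )

    def subset(self, indices: Iterable[int]) -> "GermplasmPanel":
        """New panel restricted to ``indices`` (order preserved as given)."""
        idx = list(indices)
        return GermplasmPanel(
            ids=[self.ids[i] for i in idx],
            countries=[self.countries[i] for i in idx],
            regions=[self.regions[i] for i in idx],
            descriptors=self.descriptors,
            loci=self.loci,
            traits=self.traits.iloc[idx],
            band_matrices={
                name: m[idx] for name, m in self.band_matrices.items()
            },
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GermplasmPanel):
            return NotImplemented
        if (
            self.ids != other.ids
            or self.countries != other.countries
            or self.regions != other.regions
            or self.descriptors != other.descriptors
            or self.loci != other.loci
        ):
            return False
        if not self.traits.equals(other.traits):
            return False
        for name in self.locus_names:
            a, b = self.band_matrices[name], other.band_matrices[name]
            if not np.array_equal(a, b, equal_nan=True):
                return False
        return True


@dataclass
class Selection:
    """An ordered subset of panel indices plus provenance.

    ``stratum_counts`` records how many accessions each stratum (region or
    region/cluster) contributed; ``objective`` is set by the mini-core
    optimizer.
    """

    panel: GermplasmPanel
    indices: list[int]
    method: str
    seed: int | None = None
    fraction: float | None = None
    stratum_counts: dict[str, int] = field(default_factory=dict)
    objective: float | None = None

    def __post_init__(self) -> None:
        n = len(self.panel)
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selection indices must be unique")
        if any(i < 0 or i >= n for i in self.indices):
            raise ValueError("selection index out of panel bounds")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def ids(self) -> list[str]:
        return [self.panel.ids[i] for i in self.indices]

    def to_panel(self) -> GermplasmPanel:
        return self.panel.subset(self.indices)


def resolve_subset(panel: GermplasmPanel, subset: "Selection | Sequence[int] | None") -> list[int]:
    """Normalize an optional selection/index list to a list of indices."""
    if subset is None:
        return list(range(len(panel)))
    if isinstance(subset, Selection):
        if subset.panel is not panel and subset.panel != panel:
            raise ValueError("selection belongs to a different panel")
        return list(subset.indices)
    idx = [int(i) for i in subset]
    if any(i < 0 or i >= len(panel) for i in idx):
        raise ValueError("subset index out of panel bounds")
    return idx
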