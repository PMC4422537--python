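"""Synthetic germplasm panels with known structure.

The generator emulates a multi-region genebank panel of a predominantly
selfing crop: accessions belong to one of a small number of latent
subpopulations, carry quantitative traits drawn from per-subpopulation
normal distributions (truncated at zero where the unit is nonnegative),
and are homozygous at every SSR locus, presenting exactly one band per
locus sampled from their subpopulation's allele frequencies.

Subpopulation allele-frequency separation is governed by ``divergence``,
interpreted as an F_ST-like drift parameter: per locus a shared base
frequency vector p0 is drawn from a flat Dirichlet, and each
subpopulation's frequencies are drawn from Dirichlet(p0 (1-d)/d)
(Balding-Nichols model), so Var(p_s) = d p0 (1-p0) and d = 0 recovers
panmixia.  Region and subpopulation are sampled independently, since
genebank structure is typically not fully aligned with geography.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import GermplasmPanel, LocusDef, TraitDescriptor

#: Default descriptors: the eight standard mungbean quantitative
#: descriptors with their equal-width class counts.
DEFAULT_DESCRIPTORS: tuple[TraitDescriptor, ...] = (
    TraitDescriptor("V040", "primary leaf length", "cm", 11),
    TraitDescriptor("V050", "primary leaf width", "cm", 10),
    TraitDescriptor("V120", "plant height at flowering", "cm", 15),
    TraitDescriptor("V130", "plant height at maturity", "cm", 14),
    TraitDescriptor("V400", "days to 50% flowering", "days", 11),
    TraitDescriptor("V510", "pod length", "cm", 11),
    TraitDescriptor("V700", "seeds per pod", "count", 13),
    TraitDescriptor("V770", "1000 seed weight", "g", 14),
)

#: Default per-descriptor (mean, variance), matching a large cultivated
#: mungbean collection; applied to every subpopulation unless overridden.
DEFAULT_TRAIT_PARAMS: dict[str, tuple[float, float]] = {
    "V040": (4.5, 0.24),
    "V050": (1.7, 0.05),
    "V120": (22.2, 36.89),
    "V130": (40.5, 149.75),
    "V400": (44.2, 14.49),
    "V510": (7.3, 1.01),
    "V700": (11.0, 1.59),
    "V770": (37.5, 87.24),
}

#: Plausible region mix for a world collection of a South-Asian crop.
DEFAULT_REGION_WEIGHTS: dict[str, float] = {
    "South Asia": 0.35,
    "Southeast Asia": 0.25,
    "East Asia": 0.15,
    "Southwest Asia": 0.08,
    "Africa": 0.07,
    "Americas": 0.06,
    "Europe": 0.04,
}

_REGION_COUNTRIES: dict[str, tuple[str, ...]] = {
    "South Asia": ("India", "Pakistan", "Bangladesh", "Sri Lanka"),
    "Southeast Asia": ("Philippines", "Thailand", "Indonesia", "Vietnam"),
    "East Asia": ("Taiwan", "China", "Korea"),
    "Southwest Asia": ("Afghanistan", "Iran", "Turkey"),
    "Africa": ("Ethiopia", "Kenya", "Nigeria"),
    "Americas": ("USA", "Brazil", "Mexico"),
    "Europe": ("France", "Hungary", "Ukraine"),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic panel generator.

    ``trait_params`` maps descriptor code to either a single
    (mean, variance) pair used for every subpopulation or a sequence of
    one pair per subpopulation.  ``divergence`` in [0, 1) is the F_ST-like
    drift of subpopulation allele frequencies away from the shared base.
    """

    n_accessions: int = 1000
    region_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS)
    )
    trait_params: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_PARAMS)
    )
    descriptors: Sequence[TraitDescriptor] = DEFAULT_DESCRIPTORS
    n_loci: int = 20
    alleles_per_locus_range: tuple[int, int] = (3, 13)
    n_subpops: int = 2
    divergence: float = 0.4
    trait_correlation: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_accessions < 1:
            raise ValueError("n_accessions must be positive")
        total = sum(self.region_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region weights sum to {total}, not 1")
        if any(w < 0 for w in self.region_weights.values()):
            raise ValueError("region weights must be nonnegative")
        lo, hi = self.alleles_per_locus_range
        if not (2 <= lo <= hi <= 30):
            raise ValueError("alleles_per_locus_range must lie within [2, 30]")
        if self.n_loci < 1 or self.n_subpops < 1:
            raise ValueError("n_loci and n_subpops must be positive")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")
        for code, params in self.trait_params.items():
            for pair in self._per_subpop(params):
                mean, var = pair
                if var <= 0:
                    raise ValueError(f"descriptor {code}: variance must be > 0")

    def _per_subpop(self, params) -> list[tuple[float, float]]:
        if isinstance(params[0], (int, float)):
            return [tuple(params)] * self.n_subpops
        out = [tuple(p) for p in params]
        if len(out) != self.n_subpops:
            raise ValueError("trait_params per subpopulation must match n_subpops")
        return out


@dataclass
class SimulationTruth:
    """Ground truth of a simulated panel, for recovery tests."""

    subpop_assignment: dict[str, int]
    locus_frequencies: dict[int, dict[str, np.ndarray]]  # subpop -> locus -> freqs


def simulate_panel(cfg: SimulationConfig) -> tuple[GermplasmPanel, SimulationTruth]:
    """Draw a panel and its ground truth; fully reproducible from cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_accessions
    width = max(4, len(str(n)))
    ids = [f"ACC{i + 1:0{width}d}" for i in range(n)]

    region_names = list(cfg.region_weights)
    weights = np.array([cfg.region_weights[r] for r in region_names])
    regions = [region_names[i] for i in rng.choice(len(region_names), size=n, p=weights)]
    countries = [
        _REGION_COUNTRIES.get(r, (r,))[rng.integers(len(_REGION_COUNTRIES.get(r, (r,))))]
        for r in regions
    ]
    subpops = rng.integers(0, cfg.n_subpops, size=n)

    descriptors = [d for d in cfg.descriptors if d.code in cfg.trait_params]
    traits = _draw_traits(cfg, descriptors, subpops, rng)
    traits_df = pd.DataFrame(traits, index=ids, columns=[d.code for d in descriptors])

    lo, hi = cfg.alleles_per_locus_range
    loci: list[LocusDef] = []
    band_matrices: dict[str, np.ndarray] = {}
    locus_freqs: dict[int, dict[str, np.ndarray]] = {s: {} for s in range(cfg.n_subpops)}
    for l in range(cfg.n_loci):
        k = int(rng.integers(lo, hi + 1))
        name = f"L{l + 1:02d}"
        loci.append(LocusDef(name, tuple(f"b{j + 1}" for j in range(k))))
        base = rng.dirichlet(np.ones(k))
        d = cfg.divergence
        for s in range(cfg.n_subpops):
            if d == 0.0:
                locus_freqs[s][name] = base.copy()
            else:
                # Balding-Nichols drift: Dirichlet(p0 (1-d)/d), Var = d p0 (1-p0)
                alpha = np.maximum(base * (1.0 - d) / d, 1e-6)
                locus_freqs[s][name] = rng.dirichlet(alpha)
        m = np.zeros((n, k))
        for s in range(cfg.n_subpops):
            members = np.flatnonzero(subpops == s)
            if members.size:
                draws = rng.choice(k, size=members.size, p=locus_freqs[s][name])
                m[members, draws] = 1.0
        band_matrices[name] = m

    panel = GermplasmPanel(
        ids=ids,
        countries=countries,
        regions=regions,
        descriptors=descriptors,
        loci=loci,
        traits=traits_df,
        band_matrices=band_matrices,
    )
    truth = SimulationTruth(
        subpop_assignment=dict(zip(ids, (int(s) for s in subpops))),
        locus_frequencies=locus_freqs,
    )
    return panel, truth


def _draw_traits(
    cfg: SimulationConfig,
    descriptors: Sequence[TraitDescriptor],
    subpops: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-subpopulation (truncated) normal traits, optionally correlated."""
    n = len(subpops)
    codes = [d.code for d in descriptors]
    out = np.zeros((n, len(codes)))
    corr = cfg.trait_correlation
    for s in range(cfg.n_subpops):
        members = np.flatnonzero(subpops == s)
        if members.size == 0:
            continue
        means = np.array([cfg._per_subpop(cfg.trait_params[c])[s][0] for c in codes])
        sds = np.sqrt(
            [cfg._per_subpop(cfg.trait_params[c])[s][1] for c in codes]
        )
        if corr is None:
            for j, (mu, sd) in enumerate(zip(means, sds)):
                a = (0.0 - mu) / sd  # traits are nonnegative quantities
                out[members, j] = stats.truncnorm.rvs(
                    a, np.inf, loc=mu, scale=sd, size=members.size, random_state=rng
                )
        else:
            z = rng.multivariate_normal(np.zeros(len(codes)), corr, size=members.size)
            out[members] = np.maximum(means + z * sds, 0.0)
    return out


def simulate_band_noise(
    panel: GermplasmPanel, missing_rate: float, seed: int
) -> GermplasmPanel:
    """Copy of the panel with each locus x accession cell independently
    set to missing with probability ``missing_rate``."""
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    new_matrices: dict[str, np.ndarray] = {}
    for locus in panel.loci:
        m = panel.band_matrices[locus.name].copy()
        drop = rng.random(len(panel)) < missing_rate
        m[drop] = np.nan
        new_matrices[locus.name] = m
    return GermplasmPanel(
        ids=panel.ids,
        countries=panel.countries,
        regions=panel.regions,
        descriptors=panel.descriptors,
        loci=panel.loci,
        traits=panel.traits,
        band_matrices=new_matrices,
    )
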