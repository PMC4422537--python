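import numpy as np
import pandas as pd
import pytest

from germcore.model import GermplasmPanel, LocusDef, TraitDescriptor
from germcore.simulate import SimulationConfig, simulate_panel


def make_panel(
    band_profiles: dict[str, list[str | None]],
    traits: dict[str, list[float]] | None = None,
    regions: list[str] | None = None,
    ids: list[str] | None = None,
    n_classes: int = 10,
) -> GermplasmPanel:
    """Hand-build a panel from per-locus band label lists.

    ``band_profiles`` maps locus name to one band label per accession
    (None = locus missing for that accession).  Band labels of each locus
    are the sorted set of labels seen.
    """
    n = len(next(iter(band_profiles.values())))
    ids = ids or [f"A{i + 1}" for i in range(n)]
    regions = regions or ["R1"] * n
    traits = traits if traits is not None else {"T1": list(np.arange(n, dtype=float))}
    descriptors = [TraitDescriptor(code, n_classes=n_classes) for code in traits]
    loci = []
    band_matrices = {}
    for locus, profile in band_profiles.items():
        labels = sorted({b for b in profile if b is not None}) or ["a"]
        loci.append(LocusDef(locus, tuple(labels)))
        m = np.zeros((n, len(labels)))
        for i, b in enumerate(profile):
            if b is None:
                m[i, :] = np.nan
            else:
                m[i, labels.index(b)] = 1.0
        band_matrices[locus] = m
    return GermplasmPanel(
        ids=ids,
        countries=["X"] * n,
        regions=regions,
        descriptors=descriptors,
        loci=loci,
        traits=pd.DataFrame(traits, index=ids, dtype=float),
        band_matrices=band_matrices,
    )


@pytest.fixture(scope="session")
def sim_panel():
    """Small default-structure simulated panel shared across tests."""
    panel, truth = simulate_panel(SimulationConfig(n_accessions=150, seed=11))
    return panel, truth


@pytest.fixture()
def toy_panel():
    """Four accessions, two loci, two traits, two regions."""
    return make_panel(
        band_profiles={
            "L1": ["a", "a", "b", "b"],
            "L2": ["x", "y", "x", "y"],
        },
        traits={"T1": [1.0, 2.0, 3.0, 4.0], "T2": [0.5, 0.5, 1.5, 1.5]},
        regions=["N", "N", "S", "S"],
    )
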