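"""Read and write the panel CSV trio, selections, and Newick trees.

Dialect: UTF-8 comma-separated CSV, "." decimal, empty cell = missing.
The band matrix has one row per accession and one column per band named
``locus:band``; panel order always follows the passport file.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distance import Dendrogram
from .model import GermplasmPanel, LocusDef, Selection, TraitDescriptor


def _check_ids(name: str, ids: Sequence[str]) -> None:
    seen: set[str] = set()
    dupes: list[str] = []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise ValueError(f"{name}: duplicate accession ids: {sorted(set(dupes))}")


def read_panel(
    trait_path: str | Path,
    band_path: str | Path,
    passport_path: str | Path,
    schema: Mapping | None = None,
) -> GermplasmPanel:
    """Load and join the trait, band and passport tables into a panel.

    ``schema`` may carry a ``descriptors`` list of mappings with keys
    code/label/units/n_classes; descriptors absent from the schema default
    to 10 classes.  Loci and band labels are taken from the band-file
    header (columns named ``locus:band``, kept in file order).
    """
    passport = pd.read_csv(passport_path, dtype=str).fillna("")
    traits = pd.read_csv(trait_path, dtype={0: str})
    bands = pd.read_csv(band_path, dtype={0: str})
    for frame, path in ((passport, passport_path), (traits, trait_path), (bands, band_path)):
        if frame.columns[0] != "id":
            raise ValueError(f"{path}: first column must be 'id'")
        _check_ids(str(path), list(frame["id"]))

    ids = list(passport["id"])
    for name, frame in (("trait", traits), ("band", bands)):
        missing = sorted(set(ids) - set(frame["id"]))
        extra = sorted(set(frame["id"]) - set(ids))
        if missing or extra:
            raise ValueError(
                f"{name} file does not match passport ids; "
                f"missing={missing} extra={extra}"
            )

    traits = traits.set_index("id").loc[ids]
    bands = bands.set_index("id").loc[ids]

    schema = dict(schema or {})
    desc_cfg = {d["code"]: d for d in schema.get("descriptors", [])}
    descriptors = [
        TraitDescriptor(
            code=c,
            label=desc_cfg.get(c, {}).get("label", ""),
            units=desc_cfg.get(c, {}).get("units", ""),
            n_classes=int(desc_cfg.get(c, {}).get("n_classes", 10)),
        )
        for c in traits.columns
    ]

    locus_bands: dict[str, list[str]] = {}
    for col in bands.columns:
        if ":" not in col:
            raise ValueError(f"band column {col!r} is not of the form 'locus:band'")
        locus, band = col.split(":", 1)
        locus_bands.setdefault(locus, []).append(band)
    loci = [LocusDef(name, tuple(bl)) for name, bl in locus_bands.items()]

    band_matrices: dict[str, np.ndarray] = {}
    for locus in loci:
        cols = [f"{locus.name}:{b}" for b in locus.band_labels]
        sub = bands[cols]
        m = np.full(sub.shape, np.nan)
        for j, col in enumerate(cols):
            for i, raw in enumerate(sub[col]):
                if pd.isna(raw) or (isinstance(raw, str) and raw.strip() == ""):
                    continue
                val = float(raw)
                if val not in (0.0, 1.0):
                    raise ValueError(
                        f"non-binary band value {raw!r} at accession "
                        f"{ids[i]!r}, column {col!r}"
                    )
                m[i, j] = val
        band_matrices[locus.name] = m

    return GermplasmPanel(
        ids=ids,
        countries=list(passport.get("country", [""] * len(ids))),
        regions=list(passport.get("region", [""] * len(ids))),
        descriptors=descriptors,
        loci=loci,
        traits=traits,
        band_matrices=band_matrices,
    )


def write_panel(
    panel: GermplasmPanel,
    trait_path: str | Path,
    band_path: str | Path,
    passport_path: str | Path,
) -> None:
    """Write the three panel CSVs; a subsequent read round-trips exactly."""
    pd.DataFrame(
        {"id": panel.ids, "country": panel.countries, "region": panel.regions}
    ).to_csv(passport_path, index=False)
    out = panel.traits.copy()
    out.insert(0, "id", panel.ids)
    out.to_csv(trait_path, index=False)

    cols: dict[str, list] = {"id": panel.ids}
    for locus in panel.loci:
        m = panel.band_matrices[locus.name]
        for j, band in enumerate(locus.band_labels):
            col = m[:, j]
            cols[f"{locus.name}:{band}"] = [
                "" if np.isnan(v) else str(int(v)) for v in col
            ]
    pd.DataFrame(cols).to_csv(band_path, index=False)


# -- Newick ---------------------------------------------------------------


def write_newick(tree: Dendrogram, path: str | Path) -> None:
    """Write a merge tree as Newick; branch length = height difference."""
    Path(path).write_text(tree.to_newick(), encoding="utf-8")


# -- Selections -----------------------------------------------------------


def write_selection(sel: Selection, path: str | Path) -> None:
    """CSV of selected ids with a '#'-prefixed provenance header."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# method={sel.method}\n")
        fh.write(f"# seed={sel.seed}\n")
        fh.write(f"# fraction={sel.fraction}\n")
        fh.write(f"# objective={sel.objective}\n")
        writer = csv.writer(fh)
        writer.writerow(["id"])
        for acc_id in sel.ids:
            writer.writerow([acc_id])


def read_selection(panel: GermplasmPanel, path: str | Path) -> Selection:
    """Re-attach a written selection to its panel by accession id."""
    meta: dict[str, str] = {}
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key] = val
            elif line != "id":
                ids.append(line)
    index = {acc_id: i for i, acc_id in enumerate(panel.ids)}
    missing = [i for i in ids if i not in index]
    if missing:
        raise ValueError(f"selection ids not in panel: {missing}")

    def _parse(key: str, cast):
        val = meta.get(key, "None")
        return None if val == "None" else cast(val)

    return Selection(
        panel=panel,
        indices=[index[i] for i in ids],
        method=meta.get("method", "unknown"),
        seed=_parse("seed", int),
        fraction=_parse("fraction", float),
        objective=_parse("objective", float),
    )
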