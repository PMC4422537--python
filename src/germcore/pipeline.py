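"""End-to-end workflow: simulate/load -> core -> mini core -> validation.

Every stochastic stage derives its seed deterministically from the global
seed and the stage name, so adding stages never shifts existing random
streams and identical configurations yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import io as gio
from .core import build_core, validate_core_representativeness
from .distance import (
    jaccard_distance,
    modified_rogers_distance,
    standardized_euclidean,
    upgma,
)
from .diversity import count_alleles_genotypes
from .minicore import (
    ObjectiveConfig,
    build_minicore,
    compare_minicores,
    minicore_by_cluster_sampling,
    minicore_by_region,
)
from .model import GermplasmPanel
from .simulate import SimulationConfig, simulate_panel

log = logging.getLogger("germcore")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-loadable)."""

    seed: int = 0
    simulation: dict[str, Any] = field(default_factory=dict)
    load: dict[str, str] | None = None  # trait/band/passport paths instead of simulate
    core: dict[str, Any] = field(default_factory=dict)  # fraction, cut_height, ...
    minicore: dict[str, Any] = field(default_factory=dict)  # ObjectiveConfig fields
    validation: dict[str, Any] = field(default_factory=dict)  # n_perm
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute the full workflow into ``outdir``; returns the run directory.

    Writes the panel CSV trio, selection CSVs, Newick trees, Table-style
    reports, the optimizer trace, and a JSON-lines manifest recording each
    stage with the checksums of its outputs.  Any stage failure leaves a
    ``.failed`` marker naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    manifest_path = outdir / "manifest.jsonl"
    records: list[dict] = []
    stage = "setup"
    try:
        # -- panel ---------------------------------------------------------
        stage = "panel"
        if cfg.load:
            panel = gio.read_panel(
                cfg.load["traits"], cfg.load["bands"], cfg.load["passport"],
                schema=cfg.load.get("schema"),
            )
            records.append({"stage": stage, "source": "load", "n": len(panel)})
        else:
            sim_cfg = SimulationConfig(
                seed=stage_seed(cfg.seed, "simulate"), **cfg.simulation
            )
            panel, _truth = simulate_panel(sim_cfg)
            records.append(
                {"stage": stage, "source": "simulate", "n": len(panel),
                 "seed": sim_cfg.seed}
            )
        gio.write_panel(
            panel, outdir / "traits.csv", outdir / "bands.csv", outdir / "passport.csv"
        )

        # -- core ----------------------------------------------------------
        stage = "core"
        core_kwargs = dict(cfg.core)
        fraction = core_kwargs.pop("fraction", 0.2)
        core = build_core(
            panel, fraction=fraction, seed=stage_seed(cfg.seed, "core"), **core_kwargs
        )
        gio.write_selection(core, outdir / "core.csv")
        records.append({"stage": stage, "n_selected": len(core), "seed": core.seed})

        stage = "core-validation"
        report = validate_core_representativeness(panel, core)
        report.to_csv(outdir / "core_validation.csv")
        records.append(
            {
                "stage": stage,
                "max_rel_mean_diff_pct": report.max_relative_mean_difference,
                "mantel_r": None if report.mantel is None else report.mantel.r,
                "mantel_p": None if report.mantel is None else report.mantel.p_value,
            }
        )

        # -- dendrograms of the core --------------------------------------
        stage = "dendrograms"
        core_panel = core.to_panel()
        trait_tree = upgma(standardized_euclidean(core_panel))
        gio.write_newick(trait_tree, outdir / "core_traits.nwk")
        marker_tree = upgma(jaccard_distance(core_panel))
        gio.write_newick(marker_tree, outdir / "core_markers.nwk")
        records.append({"stage": stage})

        # -- diversity report ---------------------------------------------
        stage = "diversity"
        div = count_alleles_genotypes(core_panel)
        div.per_locus.to_csv(outdir / "core_diversity.csv", index_label="locus")
        records.append(
            {
                "stage": stage,
                "total_alleles": div.total_alleles,
                "total_multilocus_genotypes": div.total_multilocus_genotypes,
            }
        )

        # -- mini cores ----------------------------------------------------
        stage = "minicore"
        mc_kwargs = dict(cfg.minicore)
        obj_cfg = ObjectiveConfig(seed=stage_seed(cfg.seed, "minicore"), **mc_kwargs)
        mini, trace = build_minicore(core_panel, obj_cfg)
        gio.write_selection(mini, outdir / "minicore_optimizer.csv")
        trace.records.to_csv(outdir / "minicore_trace.csv", index=False)
        mr_tree = upgma(modified_rogers_distance(core_panel))
        mini_cluster = minicore_by_cluster_sampling(
            core_panel, mr_tree, fraction=obj_cfg.target_fraction,
            seed=stage_seed(cfg.seed, "minicore-cluster"),
        )
        gio.write_selection(mini_cluster, outdir / "minicore_cluster.csv")
        mini_region = minicore_by_region(
            core_panel, fraction=obj_cfg.target_fraction,
            seed=stage_seed(cfg.seed, "minicore-region"),
        )
        gio.write_selection(mini_region, outdir / "minicore_region.csv")
        records.append(
            {"stage": stage, "n_selected": len(mini), "objective": mini.objective}
        )

        stage = "minicore-comparison"
        cmp = compare_minicores(
            core_panel,
            [mini, mini_cluster, mini_region],
            names=["optimizer", "marker-cluster", "region"],
        )
        cmp.per_locus.to_csv(outdir / "minicore_comparison.csv")
        cmp.means.to_csv(outdir / "minicore_means.csv")
        records.append(
            {
                "stage": stage,
                "mean_alleles": {k: float(v) for k, v in cmp.means["n_alleles"].items()},
            }
        )
    except Exception as exc:
        (outdir / ".failed").write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    checksums = {
        p.name: _file_sha256(p)
        for p in sorted(outdir.iterdir())
        if p.suffix in (".csv", ".nwk")
    }
    records.append({"stage": "checksums", "files": checksums, "seed": cfg.seed})
    with open(manifest_path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return outdir
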