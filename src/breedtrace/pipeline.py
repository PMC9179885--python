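"""End-to-end pipeline: QC -> frequencies -> delta -> panel selection
-> cohort simulation -> discriminant assignment -> summaries.

Configured from a YAML mapping (see :func:`default_config`), driven by
a single seed, and fully file-based: every stage writes its artifact
as TSV (plus PLINK text for genotypes) into the output directory with
a manifest recording the configuration hash, seed and version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .breed_assignment import (
    ThresholdRule,
    apply_threshold,
    assignment_summary,
    fit_cda,
    predict,
)
from .datatypes import GenotypeDataset
from .genotype_io import read_plink_binary, read_plink_text, write_plink_text
from .hybrid_simulation import CrossingPlan, build_study_populations, paper_crossing_plan
from .panel_selection import (
    SelectionScheme,
    SNPPanel,
    augment_panel,
    build_core_panel,
    default_augmentation_scheme,
    focal_core_scheme,
)
from .popgen_stats import allele_frequencies, classical_mds, delta_table, ibs_matrix
from .quality_control import QCThresholds, apply_qc
from .synthetic_data import SyntheticStudyConfig, generate_study

logger = logging.getLogger("breedtrace")


def default_config(seed: int = 0) -> dict[str, Any]:
    """The study-shaped default configuration (synthetic input)."""
    return {
        "seed": seed,
        "synthetic": {
            "population_sizes": {"NS": 93, "LW": 44, "LR": 37, "DU": 44, "WB": 88},
            "n_snps": 5000,
            "fst": 0.2,
            "missing_rate": 0.015,
        },
        "qc": {
            "min_sample_call_rate": 0.95,
            "min_snp_call_rate": 0.95,
            "hwe_alpha": 0.01,
            "hwe_population": "NS",
        },
        "selection": {
            "core": [
                {"pair": ["NS", "LR"], "count": 3},
                {"pair": ["NS", "LW"], "count": 3},
                {"pair": ["NS", "WB"], "count": 2},
                {"pair": ["NS", "DU"], "count": 1},
            ],
            "mds_guided": {"pairs": [["LR", "LW"]], "count": 3},
            "augmentation": [
                {"pair": ["LR", "LW"], "count": 3},
                {"pair": ["LR", "WB"], "count": 1},
                {"pair": ["LW", "WB"], "count": 1},
                {"pair": ["DU", "WB"], "count": 1},
                {"pair": ["LR", "DU"], "count": 1},
                {"pair": ["LW", "DU"], "count": 1},
            ],
        },
        "crossing": {
            "n_per_cross_training": 20,
            "n_per_cross_validation": 10,
            "n_per_purebred": 40,
        },
        "threshold": {"tau": 0.65, "fallback": "HY"},
        "priors": "proportional",
        "mds": {"dimensions": 2},
    }


def _scheme_from_config(items: list[dict]) -> SelectionScheme:
    return SelectionScheme.of(
        *((tuple(item["pair"]), int(item["count"])) for item in items)
    )


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    raw: dict[str, Any]
    seed: int
    qc: QCThresholds
    hwe_population: str | None
    core_scheme: SelectionScheme
    mds_pairs: list[tuple[str, str]]
    mds_count: int
    augmentation_scheme: SelectionScheme
    threshold: ThresholdRule
    priors: str
    mds_dimensions: int
    synthetic: SyntheticStudyConfig | None = None
    input_paths: dict[str, str] | None = None
    crossing: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict[str, Any]) -> "PipelineConfig":
        has_synthetic = "synthetic" in cfg
        has_input = "input" in cfg
        if has_synthetic == has_input:
            raise ValueError(
                "config must contain exactly one of 'synthetic' or 'input'"
            )
        seed = int(cfg.get("seed", 0))
        qc_cfg = dict(cfg.get("qc", {}))
        hwe_population = qc_cfg.pop("hwe_population", None)
        qc = QCThresholds(**qc_cfg)
        sel = cfg.get("selection", {})
        core = (
            _scheme_from_config(sel["core"])
            if "core" in sel
            else focal_core_scheme()
        )
        mds_sel = sel.get("mds_guided", {"pairs": [], "count": 0})
        aug = (
            _scheme_from_config(sel["augmentation"])
            if "augmentation" in sel
            else default_augmentation_scheme()
        )
        thr_cfg = cfg.get("threshold", {})
        threshold = ThresholdRule(
            tau=float(thr_cfg.get("tau", 0.65)),
            fallback_class=thr_cfg.get("fallback", "HY"),
        )
        synthetic = None
        if has_synthetic:
            syn = dict(cfg["synthetic"])
            syn.setdefault("seed", seed)
            if "population_sizes" in syn:
                syn["population_sizes"] = dict(syn["population_sizes"])
            synthetic = SyntheticStudyConfig(**syn)
        return cls(
            raw=cfg,
            seed=seed,
            qc=qc,
            hwe_population=hwe_population,
            core_scheme=core,
            mds_pairs=[tuple(p) for p in mds_sel.get("pairs", [])],
            mds_count=int(mds_sel.get("count", 0)),
            augmentation_scheme=aug,
            threshold=threshold,
            priors=cfg.get("priors", "proportional"),
            mds_dimensions=int(cfg.get("mds", {}).get("dimensions", 2)),
            synthetic=synthetic,
            input_paths=dict(cfg["input"]) if has_input else None,
            crossing=dict(cfg.get("crossing", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_input(config: PipelineConfig) -> GenotypeDataset:
    if config.synthetic is not None:
        ds, _ = generate_study(config.synthetic)
        return ds
    paths = config.input_paths or {}
    if "ped" in paths:
        return read_plink_text(paths["ped"], paths["map"])
    if "bed" in paths:
        return read_plink_binary(paths["bed"], paths["bim"], paths["fam"])
    raise ValueError("input section needs ped/map or bed/bim/fam paths")


def _crossing_plan(config: PipelineConfig, pops: list[str]) -> CrossingPlan:
    base = paper_crossing_plan(pops, seed=config.seed)
    cx = config.crossing
    return CrossingPlan(
        crossings=base.crossings,
        purebred_pops=base.purebred_pops,
        n_per_cross_training=int(cx.get("n_per_cross_training", 20)),
        n_per_cross_validation=int(cx.get("n_per_cross_validation", 10)),
        n_per_purebred=int(cx.get("n_per_purebred", 40)),
        seed=config.seed,
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute every stage, writing artifacts under ``outdir``.

    Returns a small in-memory summary (panel sizes, per-cohort
    assignment rates) mirroring what is written to disk.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    ds = _load_input(config)
    logger.info("input: %d samples x %d SNPs", ds.n_samples, ds.n_snps)
    write_plink_text(ds, out / "genotypes.ped", out / "genotypes.map")

    ds_qc, qc_report = apply_qc(
        ds, config.qc, hwe_population=config.hwe_population
    )
    qc_report.to_tsv(out / "qc_report.tsv")
    logger.info("qc: %d samples x %d SNPs retained", ds_qc.n_samples, ds_qc.n_snps)

    ibs = ibs_matrix(ds_qc)
    mds = classical_mds(ibs, k=config.mds_dimensions)
    mds.to_tsv(out / "mds_coordinates.tsv")
    logger.info("mds: %d samples embedded in %d dimensions",
                len(mds.sample_ids), mds.coordinates.shape[1])

    aft = allele_frequencies(ds_qc)
    aft.to_tsv(out / "frequencies.tsv")
    all_pairs = {
        tuple(slot.pair)
        for scheme in (config.core_scheme, config.augmentation_scheme)
        for slot in scheme.slots
    } | set(config.mds_pairs)
    for pair in sorted(all_pairs):
        delta_table(aft, *pair).to_csv(
            out / f"delta_{pair[0]}_{pair[1]}.tsv", sep="\t", index=False
        )
    logger.info("frequencies: %d populations x %d SNPs",
                len(aft.populations), len(aft.snp_ids))

    core_panel = build_core_panel(
        aft, config.core_scheme, config.mds_pairs, config.mds_count
    )
    full_panel = augment_panel(core_panel, aft, config.augmentation_scheme)
    core_panel.to_tsv(out / "panel_core.tsv", aft)
    full_panel.to_tsv(out / "panel_full.tsv", aft)
    logger.info("panels: core %d SNPs, augmented %d SNPs",
                len(core_panel), len(full_panel))

    plan = _crossing_plan(config, ds_qc.population_labels)
    summary_rows = []
    results: dict[str, Any] = {
        "panel_sizes": {"core": len(core_panel), "full": len(full_panel)},
        "rates": {},
    }
    for panel_name, panel in (("core", core_panel), ("full", full_panel)):
        pops = build_study_populations(ds_qc, aft, plan, panel)
        pops.summary().to_csv(
            out / f"cohorts_{panel_name}.tsv", sep="\t", index=False
        )
        model_p = fit_cda(pops.ptp, priors=config.priors)
        model_h = fit_cda(pops.htp, priors=config.priors)
        cohorts = {
            "PTP": (model_p, pops.ptp),
            "PVP": (model_p, pops.pvp),
            "HTP": (model_h, pops.htp),
            "HVP": (model_h, pops.hvp),
        }
        for cohort_name, (model, cohort) in cohorts.items():
            if cohort.n_samples == 0:
                continue
            res = apply_threshold(predict(model, cohort), config.threshold)
            res.to_tsv(
                out / f"assignments_{panel_name}_{cohort_name}.tsv",
                truth=cohort.populations,
            )
            summ = assignment_summary(res, cohort.populations)
            summ.to_tsv(out / f"summary_{panel_name}_{cohort_name}.tsv")
            summary_rows.append(
                {
                    "panel": panel_name,
                    "cohort": cohort_name,
                    "n": cohort.n_samples,
                    "rate_cda": summ.overall_rate,
                    "rate_thresholded": summ.overall_rate_thresholded,
                }
            )
            results["rates"][f"{panel_name}_{cohort_name}"] = summ.overall_rate
            logger.info(
                "assignment %s/%s: %.3f correct (%.3f thresholded)",
                panel_name, cohort_name, summ.overall_rate,
                summ.overall_rate_thresholded,
            )

    import pandas as pd

    pd.DataFrame(summary_rows).to_csv(
        out / "assignment_rates.tsv", sep="\t", index=False
    )

    cfg_json = json.dumps(config.raw, sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config.raw,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results
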