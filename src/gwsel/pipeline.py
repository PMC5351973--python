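"""End-to-end orchestration: simulate-or-load, QC, diversity, REML, model
comparison and marker-density curves, with a manifest for reproducibility.

Stage seeds are derived hierarchically from the master seed, so a stage can
be re-run on its own and still reproduce the full-pipeline result.  The
manifest records inputs, seeds, stage status and a SHA-256 checksum of every
output file; two runs with the same config and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .density import backward_elimination, curve_summary
from .evalcv import cross_validate, make_folds
from .io import (ConfigError, MarkerMatrix, PhenotypeTable, impute_and_filter,
                 read_genotypes, read_phenotypes, write_genotypes,
                 write_phenotypes)
from .relmat import classical_mds, compute_grm, compute_ibs_distance
from .simdata import SimConfig, make_study_like_dataset
from .varcomp import fit_experiment, table_of_parameters
from .wgr import METHOD_CODES, METHODS, WGRSpec

logger = logging.getLogger("gwsel")

STAGES = ("simulate", "qc", "diversity", "reml", "compare", "density")
CODE_ORDER = ["BA", "BB", "BC", "BR", "BL", "GB", "RK", "RB"]


@dataclass
class RunConfig:
    """Everything one full analysis needs (flat, config-file friendly)."""

    geno_path: str = None
    pheno_path: str = None
    sim: dict = None                   # SimConfig overrides; None = load inputs
    traits: list = None                # default: every trait in the phenotypes
    methods: list = field(default_factory=lambda: list(METHODS))
    chain: tuple = (500, 1500, 1)      # test profile; study preset overrides
    cv_folds: int = 5
    cv_repeats: int = 1
    density_reps: int = 3
    density_schedule: str = "geometric"
    density_batch_frac: float = 0.02
    qc_maf_min: float = 0.0
    qc_max_missing: float = 1.0
    reml_constrain: bool = True
    stages: list = field(default_factory=lambda: list(STAGES))
    outdir: str = "gwsel_out"
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self):
        has_paths = self.geno_path is not None or self.pheno_path is not None
        if has_paths and self.sim is not None:
            raise ConfigError("give either input paths or sim settings, not both")
        if has_paths and (self.geno_path is None or self.pheno_path is None):
            raise ConfigError("both geno_path and pheno_path are required")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ConfigError(f"unknown methods: {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        if "chain" in d:
            d = dict(d, chain=tuple(d["chain"]))
        return cls(**d)


def study_profile(cfg: RunConfig) -> RunConfig:
    """The full-scale preset: long chains and exact one-at-a-time elimination."""
    cfg.chain = (20000, 40000, 10)
    cfg.density_reps = 50
    cfg.density_schedule = "exact"
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence([int(master), idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def report_comparison(cv_result, trait=None) -> pd.DataFrame:
    """Fig-2-shaped table: one row per method in legend order."""
    summary = cv_result.summary()
    if trait is not None:
        summary = summary[summary["trait"] == trait]
    summary = summary.copy()
    summary["order"] = summary["code"].map(
        {c: i for i, c in enumerate(CODE_ORDER)})
    summary = summary.sort_values("order").drop(columns="order")
    return summary.reset_index(drop=True)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the requested stages; returns the manifest dictionary.

    On a stage failure the earlier outputs are kept, the manifest records the
    failure, and the manifest's ``status`` is ``"failed"`` (the CLI maps this
    to a nonzero exit).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "stages": {},
        "outputs": {},
        "status": "ok",
    }
    outputs: dict[str, Path] = {}

    def record(stage, status, started, error=None):
        manifest["stages"][stage] = {
            "status": status,
            "seconds": round(time.time() - started, 3),
            **({"error": str(error)} if error else {}),
        }

    # ---- inputs (simulate or load) -----------------------------------
    started = time.time()
    try:
        if cfg.sim is not None or cfg.geno_path is None:
            sim_cfg = SimConfig(**(cfg.sim or {}))
            data = make_study_like_dataset(_stage_seed(cfg.seed, "simulate"),
                                           cfg=sim_cfg)
            geno, pheno = data.geno, data.pheno
            if "simulate" in cfg.stages:
                write_genotypes(geno, outdir / "genotypes.tsv")
                write_phenotypes(pheno, outdir / "phenotypes.csv")
                truth = pd.concat(
                    [t.to_dataframe().assign(trait=k) for k, t in data.truth.items()],
                    ignore_index=True)
                truth.to_csv(outdir / "true_genetic_values.csv", index=False)
                outputs.update({
                    "genotypes": outdir / "genotypes.tsv",
                    "phenotypes": outdir / "phenotypes.csv",
                    "true_genetic_values": outdir / "true_genetic_values.csv",
                })
        else:
            fmt = "vcf" if str(cfg.geno_path).endswith((".vcf", ".vcf.gz")) else "delimited"
            geno = read_genotypes(cfg.geno_path, format=fmt)
            pheno = read_phenotypes(cfg.pheno_path)
        record("simulate", "ok" if "simulate" in cfg.stages else "skipped", started)
    except Exception as exc:
        record("simulate", "failed", started, exc)
        manifest["status"] = "failed"
        _write_manifest(manifest, outputs, outdir)
        return manifest

    traits = cfg.traits or pheno.traits
    experiments = sorted(pheno.data["experiment"].unique())

    # ---- QC ----------------------------------------------------------
    started = time.time()
    try:
        geno = impute_and_filter(geno, cfg.qc_maf_min, cfg.qc_max_missing)
        record("qc", "ok" if "qc" in cfg.stages else "skipped", started)
    except Exception as exc:
        record("qc", "failed", started, exc)
        manifest["status"] = "failed"
        _write_manifest(manifest, outputs, outdir)
        return manifest

    # ---- remaining stages, each independently failable ---------------
    def stage(name, fn):
        if name not in cfg.stages:
            manifest["stages"][name] = {"status": "skipped", "seconds": 0.0}
            return
        t0 = time.time()
        try:
            fn()
            record(name, "ok", t0)
        except Exception as exc:
            logger.exception("stage %s failed", name)
            record(name, "failed", t0, exc)
            manifest["status"] = "failed"

    def diversity():
        dist = compute_ibs_distance(geno)
        mds = classical_mds(dist, k=2)
        coords = pd.DataFrame(mds.coordinates, columns=["axis1", "axis2"])
        coords.insert(0, "plant_id", mds.plant_ids)
        coords.to_csv(outdir / "mds_coordinates.csv", index=False)
        outputs["mds_coordinates"] = outdir / "mds_coordinates.csv"

    def reml():
        grm = compute_grm(geno)
        results = {}
        for experiment in experiments:
            for trait in traits:
                results[(experiment, trait)] = fit_experiment(
                    pheno, trait, experiment, grm=grm, use_grm=True,
                    constrain=cfg.reml_constrain)
        table_of_parameters(results).to_csv(
            outdir / "genetic_parameters.csv", index=False)
        outputs["genetic_parameters"] = outdir / "genetic_parameters.csv"

    def compare():
        frames = []
        for t_i, trait in enumerate(traits):
            y = pheno.plant_means(trait, geno.plant_ids).to_numpy()
            plan = make_folds(geno.plant_ids, cfg.cv_folds, cfg.cv_repeats,
                              seed=_stage_seed(cfg.seed, "compare") + t_i)
            specs = [WGRSpec(method=m, chain=cfg.chain,
                             seed=_stage_seed(cfg.seed, "compare") + 100 + t_i)
                     for m in cfg.methods]
            res = cross_validate(geno, y, specs, plan, trait=trait)
            frames.append(report_comparison(res))
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "model_comparison.csv", index=False)
        outputs["model_comparison"] = outdir / "model_comparison.csv"

    def density():
        for t_i, trait in enumerate(traits):
            y = pheno.plant_means(trait, geno.plant_ids).to_numpy()
            curve = backward_elimination(
                geno, y, reps=cfg.density_reps, n_folds=cfg.cv_folds,
                schedule=cfg.density_schedule,
                batch_frac=cfg.density_batch_frac,
                seed=_stage_seed(cfg.seed, "density") + t_i, trait=trait)
            curve.records.to_csv(outdir / f"density_{trait}.csv", index=False)
            outputs[f"density_{trait}"] = outdir / f"density_{trait}.csv"
            summary = curve_summary(curve)
            (outdir / f"density_{trait}_summary.json").write_text(json.dumps(
                {k: v for k, v in summary.items() if k != "table"}, indent=2))
            outputs[f"density_{trait}_summary"] = \
                outdir / f"density_{trait}_summary.json"

    stage("diversity", diversity)
    stage("reml", reml)
    stage("compare", compare)
    stage("density", density)

    _write_manifest(manifest, outputs, outdir)
    return manifest


def _write_manifest(manifest, outputs, outdir: Path):
    for name, path in outputs.items():
        if Path(path).exists():
            manifest["outputs"][name] = {
                "path": str(Path(path).relative_to(outdir)),
                "sha256": _sha256(Path(path)),
                "bytes": Path(path).stat().st_size,
            }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
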