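"""Workflow orchestration: train -> validate -> optimize -> report.

A single global seed fans out to stage seeds by fixed offsets (training:
seed, search: seed + 1000, simulation: seed + 2000) so each stage is
individually reproducible.  Reports are a machine-readable JSON file plus a
human-readable text summary; per-generation GA traces are written as
delimited text for plotting evolution curves.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ann, ga
from .dataset import Dataset, load_reference_dataset, read_trials
from .design import REFERENCE_FACTORS, FactorSpec
from .model import ANNResponseSurface

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "ConfigError", "run_full"]

TRAIN_SEED_OFFSET = 0
GA_SEED_OFFSET = 1000
SIM_SEED_OFFSET = 2000


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; a partial report may have been written."""


@dataclass
class PipelineConfig:
    factors: tuple[FactorSpec, ...] = REFERENCE_FACTORS
    dataset: str = "reference"  # "reference" or a trial-table path
    train: ann.TrainConfig = field(default_factory=ann.TrainConfig)
    ga: ga.GAConfig = field(default_factory=ga.GAConfig)
    outdir: str = "cellopt-out"
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        try:
            factors = REFERENCE_FACTORS
            if "factors" in raw:
                factors = tuple(FactorSpec(**f) for f in raw["factors"])
            train = ann.TrainConfig(**raw.get("train", {}))
            ga_cfg = ga.GAConfig(**raw.get("ga", {}))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc
        return cls(
            factors=factors,
            dataset=raw.get("dataset", "reference"),
            train=train,
            ga=ga_cfg,
            outdir=raw.get("outdir", "cellopt-out"),
            seed=int(raw.get("seed", 0)),
            verbosity=str(raw.get("verbosity", "INFO")),
        )

    def validate(self) -> None:
        if self.dataset != "reference" and not Path(self.dataset).exists():
            raise ConfigError(f"dataset path does not exist: {self.dataset}")


def _load(cfg: PipelineConfig) -> Dataset:
    if cfg.dataset == "reference":
        return load_reference_dataset()
    return read_trials(cfg.dataset, cfg.factors)


def run_full(cfg: PipelineConfig) -> dict:
    """Run the full workflow and write the report bundle to ``cfg.outdir``.

    Returns the machine-readable report as a dict.  Raises
    :class:`PipelineError` on training non-convergence after writing a
    partial report.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = _load(cfg)
    logger.info("dataset: %d training / %d validation trials",
                len(dataset.training), len(dataset.validation))

    train_cfg = dataclasses.replace(cfg.train, seed=cfg.seed + TRAIN_SEED_OFFSET)
    report: dict = {
        "seed": cfg.seed,
        "stage_seeds": {"train": train_cfg.seed, "ga": cfg.seed + GA_SEED_OFFSET},
        "dataset": cfg.dataset,
    }
    surface = ANNResponseSurface(dataset)
    try:
        fit = surface.fit(train_cfg)
    except ann.ConvergenceError as exc:
        logger.error("training did not converge: %s", exc)
        report["training"] = {
            "converged": False,
            "best_mse": exc.best_model.meta.final_mse,
        }
        _write_report(report, outdir)
        raise PipelineError(f"training did not converge: {exc}") from exc

    meta = fit.network.meta
    logger.info("training converged: restart %d, %d epochs, MSE %.2e",
                meta.restart, meta.epochs, meta.final_mse)
    ann.save_model(fit.network, outdir / "model.txt")
    report["training"] = {
        "converged": True,
        "restart": meta.restart,
        "epochs": meta.epochs,
        "final_mse": meta.final_mse,
    }
    report["fitted_values"] = {
        t.label: float(v) for t, v in zip(dataset.training, fit.fittedvalues)
    }
    report["metrics"] = fit.report.to_dict()
    vf = fit.validation_frame()
    report["validation"] = vf.to_dict(orient="records")

    ga_cfg = ga.GAConfig(**{**cfg.ga.__dict__, "seed": cfg.seed + GA_SEED_OFFSET})
    opt = fit.optimize(ga_cfg)
    logger.info("GA: mean of per-run maxima %.2f%%, best %.2f%%",
                opt.mean_of_max, opt.multirun.best_overall_fitness)
    report["optimization"] = opt.multirun.to_dict()
    report["optimum_actual"] = {
        f.name: float(v)
        for f, v in zip(dataset.factors, opt.multirun.best_overall_x_actual)
    }

    _write_traces(opt, outdir / "ga_traces.csv")
    _write_report(report, outdir)
    with open(outdir / "report.txt", "w", encoding="utf-8") as fh:
        fh.write(fit.summary() + "\n\n" + opt.summary() + "\n")
    return report


def _write_report(report: dict, outdir: Path) -> None:
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_traces(opt, path: Path) -> None:
    import pandas as pd

    rows = []
    for r in opt.multirun.runs:
        for gen, (b, a) in enumerate(zip(r.best_per_generation, r.avg_per_generation), 1):
            rows.append({"run_seed": r.seed, "generation": gen, "best": b, "average": a})
    pd.DataFrame(rows).to_csv(path, index=False)
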