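"""Model/Results interface over the network, metrics and search modules.

:class:`ANNResponseSurface` is built from a trial dataset; ``fit()`` trains
the 3-4-1 perceptron and returns :class:`ANNFitResults`, which carries the
trained network, fitted values, fit-quality statistics and the regression
ANOVA, and exposes prediction, validation scoring and the genetic-algorithm
maximization of the fitted surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import ann, ga, metrics
from .dataset import Dataset, _dataset_from_frame, load_reference_dataset
from .design import REFERENCE_FACTORS, coded_to_actual

__all__ = ["ANNResponseSurface", "ANNFitResults", "OptimizationResults"]


class ANNResponseSurface:
    """A feedforward-network response surface for a three-factor experiment.

    Parameters
    ----------
    dataset : Dataset
        Trials with coded/actual settings and measured efficiencies; the
        training trials are the design points, validation trials are held
        out for prediction scoring.
    """

    def __init__(self, dataset: Dataset):
        self.dataset = dataset

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, factors=REFERENCE_FACTORS) -> "ANNResponseSurface":
        """Build from a trial table with columns label, x1_coded, x2_coded,
        x3_coded, efficiency and optionally sd, ann_fitted, role."""
        return cls(_dataset_from_frame(df, factors))

    @classmethod
    def reference(cls) -> "ANNResponseSurface":
        """Build from the packaged 23-trial experimental dataset."""
        return cls(load_reference_dataset())

    def fit(self, cfg: ann.TrainConfig | None = None, seed: int | None = None) -> "ANNFitResults":
        """Train to the MSE goal (with restarts) and return results."""
        cfg = cfg or ann.TrainConfig()
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        network = ann.train(self.dataset, cfg)
        return ANNFitResults(self, network)


class ANNFitResults:
    """Results of fitting the network response surface."""

    def __init__(self, model: ANNResponseSurface, network: ann.NetworkModel):
        self.model = model
        self.network = network
        self.fittedvalues = np.atleast_1d(
            ann.predict(network, model.dataset.actual_matrix("training"))
        )
        y_exp = model.dataset.efficiencies("training")
        self.report = metrics.fit_metrics(y_exp, self.fittedvalues, with_anova=True)

    @property
    def rsquared(self) -> float:
        return self.report.r2_corr

    @property
    def mse(self) -> float:
        return self.network.meta.final_mse if self.network.meta else float("nan")

    def predict(self, x_actual=None, coded=None) -> np.ndarray | float:
        """Efficiency (%) at actual-unit settings, or at coded settings
        mapped through the dataset's factors."""
        if (x_actual is None) == (coded is None):
            raise ValueError("give exactly one of x_actual or coded")
        if coded is not None:
            x_actual = coded_to_actual(np.asarray(coded, dtype=float), self.model.dataset.factors)
        return ann.predict(self.network, x_actual)

    def validation_frame(self) -> pd.DataFrame:
        """Held-out trials with predictions and relative errors (%)."""
        rows = []
        for t in self.model.dataset.validation:
            pred = float(ann.predict(self.network, t.actual))
            rows.append(
                {
                    "label": t.label,
                    "experimental": t.efficiency,
                    "predicted": pred,
                    "rel_error_pct": 100.0 * abs(t.efficiency - pred) / t.efficiency,
                }
            )
        return pd.DataFrame(rows)

    def optimize(self, cfg: ga.GAConfig | None = None, seed: int | None = None) -> "OptimizationResults":
        """Maximize the fitted surface with the binary-coded GA
        (multi-run aggregation over ``cfg.n_runs`` seeds)."""
        cfg = cfg or ga.GAConfig()
        if seed is not None:
            cfg = ga.GAConfig(**{**cfg.__dict__, "seed": seed})
        fitness = lambda coded: float(self.predict(coded=coded))
        summary = ga.multi_run(cfg, fitness, factors=self.model.dataset.factors)
        return OptimizationResults(self, cfg, summary)

    def summary(self) -> str:
        meta = self.network.meta
        lines = [
            "ANN response surface fit (3-4-1 tanh/linear perceptron)",
            "=" * 56,
            f"training trials      {len(self.model.dataset.training):d}",
        ]
        if meta is not None:
            lines += [
                f"seed / restart       {meta.seed} / {meta.restart}",
                f"epochs               {meta.epochs}",
                f"final MSE (scaled)   {meta.final_mse:.3e}  (goal reached: {meta.converged})",
            ]
        lines += ["", self.report.summary()]
        vf = self.validation_frame()
        if len(vf):
            lines += ["", "Held-out validation:", vf.to_string(index=False, float_format=lambda v: f"{v:.2f}")]
        return "\n".join(lines)


class OptimizationResults:
    """Multi-run GA maximization of a fitted response surface."""

    def __init__(self, fit: ANNFitResults, cfg: ga.GAConfig, summary: ga.MultiRunSummary):
        self.fit = fit
        self.cfg = cfg
        self.multirun = summary

    @property
    def best_coded(self) -> np.ndarray:
        return self.multirun.best_overall_x

    @property
    def best_actual(self) -> np.ndarray:
        return self.multirun.best_overall_x_actual

    @property
    def mean_of_max(self) -> float:
        return self.multirun.mean_of_max

    def summary(self) -> str:
        s = self.multirun
        factors = self.fit.model.dataset.factors
        lines = [
            f"GA maximization: {self.cfg.n_runs} runs x {self.cfg.generations} generations "
            f"(pop {self.cfg.pop_size}, pc {self.cfg.crossover_prob}, pm {self.cfg.mutation_prob})",
            "=" * 72,
            f"per-run maxima       {s.max_range[0]:.2f} .. {s.max_range[1]:.2f} %   "
            f"(mean {s.mean_of_max:.2f} %)",
            f"per-run minima       {s.min_range[0]:.2f} .. {s.min_range[1]:.2f} %",
            f"final-gen averages   {s.avg_range[0]:.2f} .. {s.avg_range[1]:.2f} %",
            f"best efficiency      {s.best_overall_fitness:.2f} %",
            "best setting (coded) " + np.array2string(s.best_overall_x, precision=3),
        ]
        for f, v in zip(factors, s.best_overall_x_actual):
            lines.append(f"  {f.name:28s} {v:.2f}")
        return "\n".join(lines)

    def plot_evolution(self, ax=None, run: int = 0):
        """Best/average fitness traces of one run (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self.multirun.runs[run]
        gens = np.arange(1, len(r.best_per_generation) + 1)
        ax.plot(gens, r.best_per_generation, label="best fitness")
        ax.plot(gens, r.avg_per_generation, label="average fitness")
        ax.set_xlabel("generation")
        ax.set_ylabel("immobilization efficiency (%)")
        ax.legend()
        return ax
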