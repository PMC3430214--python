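"""Fit-quality statistics and the regression ANOVA of model adequacy.

Conventions (chosen so the bundled experimental/simulated columns reproduce
their published summary statistics): mean absolute and mean relative error
divide by n; the error variance divides by n - 1 and the RMSE is its square
root.  The ANOVA is a simple linear regression of the model-fitted values
(dependent) on the experimental values (predictor), with 1 model degree of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["FitReport", "AnovaTable", "fit_metrics", "anova_fit"]


@dataclass(frozen=True)
class AnovaTable:
    df_model: int
    df_residual: int
    df_total: int
    ss_model: float
    ss_residual: float
    ss_total: float
    ms_model: float
    ms_residual: float
    f_value: float
    p_value: float
    r2: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def summary(self) -> str:
        lines = [
            f"{'':10s}{'DF':>4s}{'SS':>12s}{'MS':>12s}{'F':>12s}{'p':>12s}{'R2':>9s}",
            f"{'Model':10s}{self.df_model:>4d}{self.ss_model:>12.3f}{self.ms_model:>12.3f}"
            f"{self.f_value:>12.1f}{self.p_value:>12.2e}{self.r2:>9.4f}",
            f"{'Residual':10s}{self.df_residual:>4d}{self.ss_residual:>12.3f}{self.ms_residual:>12.3f}",
            f"{'Total':10s}{self.df_total:>4d}{self.ss_total:>12.3f}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class FitReport:
    """Agreement between experimental and model-fitted responses (all in
    efficiency points / %, except the dimensionless correlation)."""

    mae: float
    mre: float
    rmse: float
    err_variance: float
    r2_corr: float
    anova: AnovaTable | None = None

    def to_dict(self) -> dict:
        d = {
            "mae": self.mae,
            "mre": self.mre,
            "rmse": self.rmse,
            "err_variance": self.err_variance,
            "r2_corr": self.r2_corr,
        }
        if self.anova is not None:
            d["anova"] = self.anova.to_dict()
        return d

    def summary(self) -> str:
        lines = [
            f"MAE            {self.mae:8.4f}",
            f"MRE (%)        {self.mre:8.4f}",
            f"RMSE           {self.rmse:8.4f}",
            f"error variance {self.err_variance:8.4f}",
            f"R^2 (corr)     {self.r2_corr:8.5f}",
        ]
        if self.anova is not None:
            lines += ["", "ANOVA (fit regressed on experiment):", self.anova.summary()]
        return "\n".join(lines)


def _as_vectors(y_exp, y_fit, min_n: int):
    y_exp = np.asarray(y_exp, dtype=float)
    y_fit = np.asarray(y_fit, dtype=float)
    if y_exp.shape != y_fit.shape or y_exp.ndim != 1:
        raise ValueError("y_exp and y_fit must be 1-d vectors of equal length")
    if len(y_exp) < min_n:
        raise ValueError(f"need at least {min_n} points, got {len(y_exp)}")
    return y_exp, y_fit


def fit_metrics(y_exp, y_fit, with_anova: bool = False) -> FitReport:
    """MAE, MRE, RMSE, error variance and squared Pearson correlation.

    Errors are e_k = y_exp,k - y_fit,k.  The relative error divides by the
    experimental value, so any zero experimental value is a domain error.
    """
    y_exp, y_fit = _as_vectors(y_exp, y_fit, 2)
    if np.any(y_exp == 0):
        raise ValueError("relative error undefined: some experimental values are 0")
    e = y_exp - y_fit
    n = len(e)
    mae = float(np.abs(e).mean())
    mre = float(100.0 * np.mean(np.abs(e) / np.abs(y_exp)))
    err_variance = float((e**2).sum() / (n - 1))
    rmse = float(np.sqrt(err_variance))
    if np.allclose(y_exp, y_fit) and np.ptp(y_exp) > 0:
        r2 = 1.0  # identical non-constant vectors
    elif np.ptp(y_exp) == 0 or np.ptp(y_fit) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(y_exp, y_fit)[0, 1] ** 2)
    anova = anova_fit(y_exp, y_fit) if with_anova else None
    return FitReport(mae=mae, mre=mre, rmse=rmse, err_variance=err_variance,
                     r2_corr=r2, anova=anova)


def anova_fit(y_exp, y_fit) -> AnovaTable:
    """Regression ANOVA of the fitted values on the experimental values.

    Decomposes the total sum of squares of the fitted column about its mean
    into the part explained by a straight line in the experimental values
    (1 df) and a residual (n - 2 df); the F ratio is referred to the
    F(1, n-2) upper tail.
    """
    y_exp, y_fit = _as_vectors(y_exp, y_fit, 3)
    n = len(y_exp)
    sxx = float(((y_exp - y_exp.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("degenerate regression: experimental values have zero variance")
    sxy = float(((y_exp - y_exp.mean()) * (y_fit - y_fit.mean())).sum())
    ss_total = float(((y_fit - y_fit.mean()) ** 2).sum())
    ss_model = sxy**2 / sxx
    ss_residual = ss_total - ss_model
    df_model, df_residual, df_total = 1, n - 2, n - 1
    ms_model = ss_model / df_model
    ms_residual = ss_residual / df_residual
    if ms_residual > 0:
        f_value = ms_model / ms_residual
        p_value = float(stats.f.sf(f_value, df_model, df_residual))
    else:
        f_value, p_value = float("inf"), 0.0
    r2 = ss_model / ss_total if ss_total > 0 else float("nan")
    return AnovaTable(
        df_model=df_model, df_residual=df_residual, df_total=df_total,
        ss_model=ss_model, ss_residual=ss_residual, ss_total=ss_total,
        ms_model=ms_model, ms_residual=ms_residual,
        f_value=f_value, p_value=p_value, r2=r2,
    )
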