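"""Trial tables: the bundled experimental dataset, text I/O and the response.

The response variable throughout is the immobilization efficiency in percent:
100 x (glucose released by the immobilized enzyme) / (glucose released by the
free enzyme) on the same substrate.  Efficiencies live on the 0-100 scale
everywhere outside the network; only the scaling module maps them to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .design import REFERENCE_FACTORS, FactorSpec, coded_to_actual

logger = logging.getLogger(__name__)

__all__ = [
    "Trial",
    "Dataset",
    "SchemaError",
    "IntegrityError",
    "load_reference_dataset",
    "read_trials",
    "write_trials",
    "efficiency_from_glucose",
]

#: Hand-summed total of the 20 training efficiencies in the bundled table;
#: used as an integrity check on the packaged fixture.
_TRAINING_EFFICIENCY_SUM = 1274.86

_REQUIRED_COLUMNS = ("label", "x1_coded", "x2_coded", "x3_coded", "efficiency")


class SchemaError(ValueError):
    """A trial table is missing required columns."""


class IntegrityError(RuntimeError):
    """The packaged fixture does not match its recorded checksum."""


@dataclass(frozen=True)
class Trial:
    """One experimental run: factor setting plus measured response.

    ``ann_fitted`` carries the network-simulated efficiency column published
    alongside the bundled dataset; it is input data for the fit-quality
    metrics, not something this package computes.
    """

    label: str
    coded: np.ndarray
    actual: np.ndarray
    efficiency: float
    efficiency_sd: float | None = None
    ann_fitted: float | None = None
    role: str = "training"

    def __post_init__(self) -> None:
        object.__setattr__(self, "coded", np.asarray(self.coded, dtype=float))
        object.__setattr__(self, "actual", np.asarray(self.actual, dtype=float))
        if not 0.0 <= self.efficiency <= 100.0:
            raise ValueError(
                f"trial {self.label!r}: efficiency {self.efficiency} outside [0, 100]"
            )
        if self.role not in ("training", "validation"):
            raise ValueError(f"trial {self.label!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class Dataset:
    """A collection of trials sharing one set of factor specifications."""

    factors: tuple[FactorSpec, ...]
    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "trials", tuple(self.trials))
        labels = [t.label for t in self.trials]
        if len(set(labels)) != len(labels):
            raise ValueError("trial labels must be unique")
        if not any(t.role == "training" for t in self.trials):
            raise ValueError("dataset needs at least one training trial")

    @property
    def training(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if t.role == "training")

    @property
    def validation(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if t.role == "validation")

    def coded_matrix(self, role: str | None = "training") -> np.ndarray:
        trials = self.trials if role is None else tuple(t for t in self.trials if t.role == role)
        return np.array([t.coded for t in trials])

    def actual_matrix(self, role: str | None = "training") -> np.ndarray:
        trials = self.trials if role is None else tuple(t for t in self.trials if t.role == role)
        return np.array([t.actual for t in trials])

    def efficiencies(self, role: str | None = "training") -> np.ndarray:
        trials = self.trials if role is None else tuple(t for t in self.trials if t.role == role)
        return np.array([t.efficiency for t in trials])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "label": t.label,
                    "x1_coded": t.coded[0],
                    "x2_coded": t.coded[1],
                    "x3_coded": t.coded[2],
                    "efficiency": t.efficiency,
                    "sd": np.nan if t.efficiency_sd is None else t.efficiency_sd,
                    "ann_fitted": np.nan if t.ann_fitted is None else t.ann_fitted,
                    "role": t.role,
                }
            )
        return pd.DataFrame(rows)


def _dataset_from_frame(df: pd.DataFrame, factors) -> Dataset:
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table is missing column(s): {', '.join(missing)}")
    trials = []
    for _, row in df.iterrows():
        coded = np.array([row["x1_coded"], row["x2_coded"], row["x3_coded"]], dtype=float)
        eff = float(row["efficiency"])
        if not 0.0 <= eff <= 100.0:
            raise ValueError(f"efficiency {eff} outside [0, 100] (label {row['label']!r})")
        sd = float(row["sd"]) if "sd" in df.columns and pd.notna(row.get("sd")) else None
        ann = (
            float(row["ann_fitted"])
            if "ann_fitted" in df.columns and pd.notna(row.get("ann_fitted"))
            else None
        )
        role = str(row["role"]) if "role" in df.columns and pd.notna(row.get("role")) else "training"
        trials.append(
            Trial(
                label=str(row["label"]),
                coded=coded,
                actual=coded_to_actual(coded, factors),
                efficiency=eff,
                efficiency_sd=sd,
                ann_fitted=ann,
                role=role,
            )
        )
    return Dataset(factors=tuple(factors), trials=tuple(trials))


def load_reference_dataset() -> Dataset:
    """Load the packaged 23-trial experimental table (20 CCD training trials
    plus 3 held-out validation trials).

    Raises
    ------
    IntegrityError
        If the packaged fixture does not reproduce the recorded sum of
        training efficiencies.
    """
    with resources.files("cellopt.data").joinpath("reference_ccd.csv").open("r") as fh:
        df = pd.read_csv(fh, float_precision="round_trip")
    ds = _dataset_from_frame(df, REFERENCE_FACTORS)
    total = ds.efficiencies("training").sum()
    if abs(total - _TRAINING_EFFICIENCY_SUM) > 1e-9:
        raise IntegrityError(
            f"packaged trial table corrupted: training efficiency sum {total!r} "
            f"!= {_TRAINING_EFFICIENCY_SUM!r}"
        )
    return ds


def read_trials(path, factors=REFERENCE_FACTORS) -> Dataset:
    """Read a delimited trial table (comma-separated, UTF-8, '.' decimals).

    Required columns: label, x1_coded, x2_coded, x3_coded, efficiency.
    Optional: sd, ann_fitted, role (training/validation; default training).
    """
    df = pd.read_csv(Path(path), float_precision="round_trip")
    return _dataset_from_frame(df, factors)


def write_trials(dataset: Dataset, path) -> None:
    """Write a trial table; round-trips through :func:`read_trials` losslessly."""
    # default float formatting is the shortest round-trip repr, which the
    # round_trip parser in read_trials recovers exactly
    dataset.to_frame().to_csv(Path(path), index=False)


def efficiency_from_glucose(glucose_immobilized: float, glucose_free: float) -> float:
    """Immobilization efficiency (%) from glucose yields of the immobilized
    and free enzyme preparations."""
    if glucose_free <= 0:
        raise ValueError(f"glucose_free must be > 0, got {glucose_free}")
    if glucose_immobilized < 0:
        raise ValueError(f"glucose_immobilized must be >= 0, got {glucose_immobilized}")
    return 100.0 * glucose_immobilized / glucose_free
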