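"""A 3-4-1 multilayer perceptron trained by back-propagation.

Architecture: three inputs (the scaled factor settings), four hidden units
with hyperbolic-tangent activation, one pure-linear output (the scaled
efficiency).  Biases are included in both layers: without them the network
is an odd function of its inputs and would be pinned to output 0 at the
design centre, which the data contradict.

Training minimises the mean squared error over the scaled training pairs by
full-batch gradient descent with momentum, restarting from fresh random
weights until the configured error goal is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import Dataset
from .scaling import ScalerParams, scale_input, scale_output, unscale_output

__all__ = [
    "NetworkModel",
    "TrainConfig",
    "TrainingMeta",
    "ConvergenceError",
    "ModelFormatError",
    "forward",
    "loss_and_grad",
    "train",
    "predict",
    "save_model",
    "load_model",
]

N_IN, N_HIDDEN = 3, 4


class ConvergenceError(RuntimeError):
    """No restart reached the error goal; carries the best model found."""

    def __init__(self, message: str, best_model: "NetworkModel"):
        super().__init__(message)
        self.best_model = best_model


class ModelFormatError(ValueError):
    """A model file is malformed or incomplete."""


@dataclass(frozen=True)
class TrainConfig:
    """Back-propagation settings.

    ``goal_mse`` is on scaled outputs (response / 100), so 1e-4 corresponds
    to a root-mean-square training error of one efficiency point.
    """

    goal_mse: float = 1e-4
    max_epochs: int = 50_000
    learning_rate: float = 0.05
    momentum: float = 0.9
    max_restarts: int = 10
    seed: int = 0
    init_scale: float = 0.5

    def __post_init__(self) -> None:
        if not self.goal_mse > 0:
            raise ValueError("goal_mse must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass(frozen=True)
class TrainingMeta:
    seed: int
    restart: int
    epochs: int
    final_mse: float
    converged: bool


@dataclass(frozen=True)
class NetworkModel:
    """Weights and biases of the perceptron plus its training-time scaler."""

    w_in: np.ndarray  # (3, 4) input -> hidden
    b_hidden: np.ndarray  # (4,)
    w_out: np.ndarray  # (4,) hidden -> output
    b_out: float
    scaler: ScalerParams
    meta: TrainingMeta | None = None

    def __post_init__(self) -> None:
        w_in = np.asarray(self.w_in, dtype=float)
        b_h = np.asarray(self.b_hidden, dtype=float)
        w_out = np.asarray(self.w_out, dtype=float)
        if w_in.shape != (N_IN, N_HIDDEN) or b_h.shape != (N_HIDDEN,) or w_out.shape != (N_HIDDEN,):
            raise ValueError("weight shapes must be (3,4), (4,), (4,)")
        for arr in (w_in, b_h, w_out):
            if not np.all(np.isfinite(arr)):
                raise ValueError("weights must be finite")
        if not np.isfinite(self.b_out):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "w_in", w_in)
        object.__setattr__(self, "b_hidden", b_h)
        object.__setattr__(self, "w_out", w_out)
        object.__setattr__(self, "b_out", float(self.b_out))


def forward(model: NetworkModel, x_scaled) -> np.ndarray | float:
    """Forward pass on scaled inputs: tanh hidden layer, linear output.

    Accepts a single 3-vector or an (n, 3) batch; returns a scalar or an
    (n,) vector of scaled outputs.
    """
    x = np.asarray(x_scaled, dtype=float)
    single = x.ndim == 1
    z = np.tanh(np.atleast_2d(x) @ model.w_in + model.b_hidden)
    y = z @ model.w_out + model.b_out
    return float(y[0]) if single else y


def _unpack(p: np.ndarray):
    w_in = p[:12].reshape(N_IN, N_HIDDEN)
    b_h = p[12:16]
    w_out = p[16:20]
    b_out = p[20]
    return w_in, b_h, w_out, b_out


def loss_and_grad(params: np.ndarray, x_scaled: np.ndarray, t_scaled: np.ndarray):
    """MSE loss and its analytic back-propagated gradient.

    ``params`` is the flat 21-vector (w_in, b_hidden, w_out, b_out).  The
    gradient is checked against central finite differences in the test
    suite; this function is the single source of truth for training.
    """
    w_in, b_h, w_out, b_out = _unpack(np.asarray(params, dtype=float))
    x = np.atleast_2d(np.asarray(x_scaled, dtype=float))
    t = np.asarray(t_scaled, dtype=float)
    n = len(t)
    z = np.tanh(x @ w_in + b_h)
    y = z @ w_out + b_out
    e = y - t
    loss = float(np.mean(e**2))
    dy = 2.0 * e / n
    g_w_out = z.T @ dy
    g_b_out = dy.sum()
    dz = np.outer(dy, w_out) * (1.0 - z**2)
    g_w_in = x.T @ dz
    g_b_h = dz.sum(axis=0)
    grad = np.concatenate([g_w_in.ravel(), g_b_h, g_w_out, [g_b_out]])
    return loss, grad


def _model_from_params(p: np.ndarray, scaler: ScalerParams, meta: TrainingMeta) -> NetworkModel:
    w_in, b_h, w_out, b_out = _unpack(p)
    return NetworkModel(
        w_in=w_in.copy(), b_hidden=b_h.copy(), w_out=w_out.copy(), b_out=float(b_out),
        scaler=scaler, meta=meta,
    )


def train(data: Dataset, cfg: TrainConfig | None = None) -> NetworkModel:
    """Train on the dataset's training trials until the MSE goal is met.

    Restart ``r`` draws its initial weights from a generator seeded with
    ``cfg.seed + r``; the first restart whose final MSE reaches the goal is
    returned, making the result deterministic given seed, config and data.

    Raises
    ------
    ConvergenceError
        If no restart reaches the goal within the epoch budget.  The best
        model found is attached to the exception.
    """
    cfg = cfg or TrainConfig()
    training = data.training
    if len({tuple(t.coded) for t in training}) < 2:
        raise ValueError("need at least 2 distinct training points")
    scaler = ScalerParams.from_data(data.actual_matrix("training"))
    x = scale_input(data.actual_matrix("training"), scaler)
    t = scale_output(data.efficiencies("training"))

    best_p, best_mse, best_meta = None, np.inf, None
    for r in range(cfg.max_restarts):
        rng = np.random.default_rng(cfg.seed + r)
        p = rng.uniform(-cfg.init_scale, cfg.init_scale, 21)
        v = np.zeros(21)
        mse, _ = loss_and_grad(p, x, t)
        epochs = 0
        for epoch in range(1, cfg.max_epochs + 1):
            mse, g = loss_and_grad(p, x, t)
            if mse <= cfg.goal_mse:
                break
            v = cfg.momentum * v - cfg.learning_rate * g
            p = p + v
            epochs = epoch
        mse, _ = loss_and_grad(p, x, t)
        meta = TrainingMeta(seed=cfg.seed, restart=r, epochs=epochs, final_mse=mse,
                            converged=mse <= cfg.goal_mse)
        if mse <= cfg.goal_mse:
            return _model_from_params(p, scaler, meta)
        if mse < best_mse:
            best_p, best_mse, best_meta = p, mse, meta
    raise ConvergenceError(
        f"no restart reached goal MSE {cfg.goal_mse:g} within {cfg.max_epochs} epochs; "
        f"best MSE achieved {best_mse:.3e}",
        best_model=_model_from_params(best_p, scaler, best_meta),
    )


def predict(model: NetworkModel, x_actual) -> np.ndarray | float:
    """Efficiency in % at an actual-unit setting (or an (n, 3) batch)."""
    return unscale_output(forward(model, scale_input(x_actual, model.scaler)), model.scaler)


# ---------------------------------------------------------------------------
# plain-text model file: one "key = value" per line, full repr precision

def save_model(model: NetworkModel, path) -> None:
    lines = ["format = cellopt-ann-1"]
    for name, arr in (
        ("w_in", model.w_in.ravel()),
        ("b_hidden", model.b_hidden),
        ("w_out", model.w_out),
        ("b_out", [model.b_out]),
        ("x_min", model.scaler.x_min),
        ("x_max", model.scaler.x_max),
        ("y_bounds", [model.scaler.y_min, model.scaler.y_max]),
    ):
        lines.append(f"{name} = " + " ".join(repr(float(v)) for v in arr))
    if model.meta is not None:
        m = model.meta
        lines.append(
            f"meta = {m.seed} {m.restart} {m.epochs} {m.final_mse!r} {int(m.converged)}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> NetworkModel:
    fields: dict[str, list[str]] = {}
    try:
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                fields[key.strip()] = value.split()
        if fields.get("format") != ["cellopt-ann-1"]:
            raise ModelFormatError(f"{path}: not a cellopt ANN model file")
        def vec(key: str, n: int) -> np.ndarray:
            vals = [float(v) for v in fields[key]]
            if len(vals) != n:
                raise ModelFormatError(f"{path}: field {key!r} has {len(vals)} values, expected {n}")
            return np.array(vals)
        meta = None
        if "meta" in fields:
            m = fields["meta"]
            meta = TrainingMeta(seed=int(m[0]), restart=int(m[1]), epochs=int(m[2]),
                                final_mse=float(m[3]), converged=bool(int(m[4])))
        y_lo, y_hi = vec("y_bounds", 2)
        return NetworkModel(
            w_in=vec("w_in", 12).reshape(N_IN, N_HIDDEN),
            b_hidden=vec("b_hidden", 4),
            w_out=vec("w_out", 4),
            b_out=float(vec("b_out", 1)[0]),
            scaler=ScalerParams(x_min=vec("x_min", 3), x_max=vec("x_max", 3),
                                y_min=y_lo, y_max=y_hi),
            meta=meta,
        )
    except ModelFormatError:
        raise
    except (KeyError, ValueError, IndexError) as exc:
        raise ModelFormatError(f"{path}: malformed model file ({exc})") from exc
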