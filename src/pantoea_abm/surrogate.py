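"""Dense-network surrogate of the simulator.

A single feed-forward network maps the seven active inputs (steptime
included) to the three curve summaries ⟨A⟩, ⟨μ⟩, ⟨τ⟩ simultaneously: two
hidden ReLU layers of 30 and 15 nodes and a linear 3-node output, i.e.
7·30+30 + 30·15+15 + 15·3+3 = 753 trainable parameters.  Training minimizes
mean squared error with the Adam optimizer (learning rate 0.01), 300 epochs
in mini-batches of 50, on inputs and outputs min-max scaled to [0, 1]
(scalers fitted on training data only).  The network is evaluated by 3-fold
cross-validated MAE on the normalized scale, then retrained on the full
training split and scored on the held-out test split (normalized MAE plus
per-output R² after inverse-transforming predictions to original scales).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import MinMaxScaler

from .campaign import ACTIVE_INPUT_COLUMNS

__all__ = [
    "SurrogateSpec",
    "MetamodelMetrics",
    "n_trainable_parameters",
    "build_network",
    "minmax_normalize",
    "cross_validate",
    "train_and_evaluate",
    "export_weights",
]


@dataclass(frozen=True)
class SurrogateSpec:
    input_names: tuple[str, ...] = tuple(ACTIVE_INPUT_COLUMNS)
    hidden_sizes: tuple[int, ...] = (30, 15)
    output_names: tuple[str, ...] = ("A", "mu", "tau")
    learning_rate: float = 0.01
    epochs: int = 300
    batch_size: int = 50
    folds: int = 3


def n_trainable_parameters(spec: SurrogateSpec) -> int:
    """Closed-form weight+bias count of the dense network."""
    sizes = (len(spec.input_names), *spec.hidden_sizes, len(spec.output_names))
    return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


def build_network(spec: SurrogateSpec, seed: int = 0) -> MLPRegressor:
    """Configure the dense network (ReLU hidden layers, linear output, MSE
    loss, Adam) with seeded weight initialization and no early stopping."""
    return MLPRegressor(
        hidden_layer_sizes=spec.hidden_sizes,
        activation="relu",
        solver="adam",
        learning_rate_init=spec.learning_rate,
        max_iter=spec.epochs,
        batch_size=spec.batch_size,
        shuffle=True,
        random_state=seed,
        tol=0.0,
        n_iter_no_change=spec.epochs,
    )


def fitted_parameter_count(model: MLPRegressor) -> int:
    return int(
        sum(w.size for w in model.coefs_) + sum(b.size for b in model.intercepts_)
    )


def minmax_normalize(
    train: pd.DataFrame | np.ndarray, test: pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, np.ndarray, MinMaxScaler]:
    """Per-column affine map to [0, 1] using train min/max only; test values
    outside the train range map outside [0, 1] (no clipping)."""
    tr = np.asarray(train, dtype=float)
    te = np.asarray(test, dtype=float)
    if tr.size == 0:
        raise ValueError("training set is empty")
    span = tr.max(axis=0) - tr.min(axis=0)
    if np.any(span == 0):
        names = (
            list(train.columns) if isinstance(train, pd.DataFrame)
            else list(range(tr.shape[1]))
        )
        bad = [str(names[i]) for i in np.flatnonzero(span == 0)]
        raise ValueError(f"constant column(s): {bad}")
    scaler = MinMaxScaler(clip=False).fit(tr)
    return scaler.transform(tr), scaler.transform(te), scaler


def _fit(net: MLPRegressor, X: np.ndarray, Y: np.ndarray) -> MLPRegressor:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(X, Y)
    if not np.isfinite(net.loss_):
        raise RuntimeError("training diverged (non-finite loss)")
    return net


def cross_validate(
    train: pd.DataFrame, spec: SurrogateSpec = SurrogateSpec(), seed: int = 0
) -> tuple[float, float]:
    """3-fold CV: per fold, fit scalers on the fold-train part, train the
    network, and measure MAE on the fold-validation part in normalized
    space.  Returns (mean, SD) of the fold MAEs."""
    X = train[list(spec.input_names)]
    Y = train[list(spec.output_names)]
    maes = []
    for k, (itr, iva) in enumerate(
        KFold(spec.folds, shuffle=True, random_state=seed).split(X)
    ):
        Xtr, Xva, _ = minmax_normalize(X.iloc[itr], X.iloc[iva])
        Ytr, Yva, _ = minmax_normalize(Y.iloc[itr], Y.iloc[iva])
        try:
            net = _fit(build_network(spec, seed), Xtr, Ytr)
        except RuntimeError as err:
            raise RuntimeError(f"fold {k}: {err}") from err
        maes.append(mean_absolute_error(Yva, net.predict(Xva)))
    maes = np.asarray(maes)
    return float(maes.mean()), float(maes.std(ddof=0))


@dataclass
class MetamodelMetrics:
    cv_mae_mean: float
    cv_mae_sd: float
    test_mae: float
    r2_per_output: dict[str, float]
    seed: int
    model: MLPRegressor | None = field(default=None, repr=False)
    predictions: pd.DataFrame | None = field(default=None, repr=False)


def train_and_evaluate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    spec: SurrogateSpec = SurrogateSpec(),
    seed: int = 0,
) -> MetamodelMetrics:
    """Cross-validate on the training split, retrain on all of it with the
    same schedule, and score the held-out test split."""
    cv_mean, cv_sd = cross_validate(train, spec, seed)
    Xtr, Xte, _ = minmax_normalize(
        train[list(spec.input_names)], test[list(spec.input_names)]
    )
    Ytr, Yte, y_scaler = minmax_normalize(
        train[list(spec.output_names)], test[list(spec.output_names)]
    )
    net = _fit(build_network(spec, seed), Xtr, Ytr)
    pred_norm = net.predict(Xte)
    test_mae = float(mean_absolute_error(Yte, pred_norm))
    pred = y_scaler.inverse_transform(pred_norm)
    truth = test[list(spec.output_names)].values
    r2 = {
        name: float(r2_score(truth[:, j], pred[:, j]))
        for j, name in enumerate(spec.output_names)
    }
    pred_df = pd.DataFrame(
        np.column_stack([truth, pred]),
        columns=[f"{n}_true" for n in spec.output_names]
        + [f"{n}_pred" for n in spec.output_names],
    )
    return MetamodelMetrics(cv_mean, cv_sd, test_mae, r2, seed, net, pred_df)


def export_weights(model: MLPRegressor) -> np.ndarray:
    """Flatten weights then biases, layer by layer (portable layout)."""
    parts = [w.ravel() for w in model.coefs_] + [b.ravel() for b in model.intercepts_]
    return np.concatenate(parts)
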