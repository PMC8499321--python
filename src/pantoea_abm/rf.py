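"""Random-forest sensitivity analysis of the campaign dataset.

For each steptime subset and each output (⟨A⟩, ⟨μ⟩, ⟨τ⟩) a random-forest
regressor is tuned by random search with 3-fold cross-validation, evaluated
by test-set R², and interrogated for Gini (impurity) importance — normalized
so the six remaining inputs sum to 100% — and permutation importance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import r2_score
from sklearn.model_selection import RandomizedSearchCV
from sklearn.preprocessing import StandardScaler

from .campaign import ACTIVE_INPUT_COLUMNS, split_by_steptime, train_test_split

__all__ = [
    "ImportanceReport",
    "standardize_features",
    "tune_random_forest",
    "evaluate",
    "importances",
    "run_rf_suite",
    "heatmap_binned_means",
    "HYPERPARAMETER_DISTRIBUTIONS",
]

logger = logging.getLogger(__name__)

OUTPUTS = ("A", "mu", "tau")

#: the six tuned hyperparameter families
HYPERPARAMETER_DISTRIBUTIONS = {
    "n_estimators": list(range(100, 1001, 100)),
    "max_depth": [None, 10, 20, 30, 40, 50],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
    "max_features": [1.0, "sqrt", 0.3333333333333333],
    "bootstrap": [True, False],
}


@dataclass
class ImportanceReport:
    steptime: float
    output_name: str
    r2_test: float
    gini_importance: dict[str, float]
    permutation_importance: dict[str, float]
    best_hyperparameters: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=_jsonable)

    @classmethod
    def from_json(cls, s: str) -> "ImportanceReport":
        return cls(**json.loads(s))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(type(x))


def standardize_features(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, StandardScaler]:
    """Z-score features with mean/SD from the training set only."""
    if train.empty:
        raise ValueError("training set is empty")
    sds = train.std(ddof=0)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance feature(s): {zero}")
    scaler = StandardScaler().fit(train.values)
    return scaler.transform(train.values), scaler.transform(test.values), scaler


def tune_random_forest(
    X_train: np.ndarray,
    y_train: np.ndarray,
    seed: int = 0,
    n_candidates: int = 50,
    min_rows: int = 30,
) -> tuple[RandomForestRegressor, dict]:
    """Random search (3-fold CV, R² scoring) over the six hyperparameter
    families; refits the best candidate on all training rows."""
    if len(X_train) < min_rows:
        raise ValueError(f"need at least {min_rows} training rows")
    search = RandomizedSearchCV(
        RandomForestRegressor(random_state=seed),
        HYPERPARAMETER_DISTRIBUTIONS,
        n_iter=n_candidates,
        scoring="r2",
        cv=3,
        random_state=seed,
        error_score="raise",
    )
    search.fit(X_train, y_train)
    return search.best_estimator_, dict(search.best_params_)


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray) -> float:
    """Test-set coefficient of determination R² = 1 - SS_res/SS_tot."""
    y_test = np.asarray(y_test, dtype=float)
    if np.allclose(y_test, y_test[0]):
        raise ValueError("R^2 undefined: constant true outputs")
    return float(r2_score(y_test, model.predict(X_test)))


def importances(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    feature_names: list[str],
    seed: int = 0,
    n_repeats: int = 10,
) -> tuple[dict[str, float], dict[str, float]]:
    """Gini importances normalized to sum to 1, and permutation importances
    (mean R² drop over ``n_repeats`` seeded shuffles per feature)."""
    gini = np.asarray(model.feature_importances_, dtype=float)
    total = gini.sum()
    gini = gini / total if total > 0 else gini
    perm = permutation_importance(
        model, X_test, y_test, scoring="r2", n_repeats=n_repeats, random_state=seed
    )
    return (
        dict(zip(feature_names, gini.tolist())),
        dict(zip(feature_names, perm.importances_mean.tolist())),
    )


def run_rf_suite(
    dataset: pd.DataFrame,
    seed: int = 0,
    n_candidates: int = 50,
    min_subset_size: int = 30,
    split_ratio: float = 0.7,
) -> list[ImportanceReport]:
    """Tune/evaluate one forest per (steptime subset × output): 12 reports.

    Within each subset the six remaining inputs are the features (steptime
    is constant there and excluded).  Subsets smaller than
    ``min_subset_size`` are skipped with a warning.
    """
    reports: list[ImportanceReport] = []
    features = [c for c in ACTIVE_INPUT_COLUMNS if c != "steptime"]
    for st, sub in split_by_steptime(dataset).items():
        if len(sub) < min_subset_size:
            logger.warning("steptime %.1f: only %d rows, skipped", st, len(sub))
            continue
        train, test = train_test_split(sub, ratio=split_ratio, seed=seed)
        Xtr, Xte, _ = standardize_features(train[features], test[features])
        for out in OUTPUTS:
            model, best = tune_random_forest(
                Xtr,
                train[out].values,
                seed=seed,
                n_candidates=n_candidates,
                # a minimum-size subset leaves split_ratio * 30 training rows
                min_rows=int(split_ratio * min_subset_size),
            )
            r2 = evaluate(model, Xte, test[out].values)
            gini, perm = importances(model, Xte, test[out].values, features, seed=seed)
            reports.append(
                ImportanceReport(
                    steptime=float(st),
                    output_name=out,
                    r2_test=r2,
                    gini_importance=gini,
                    permutation_importance=perm,
                    best_hyperparameters=best,
                    seed=seed,
                )
            )
    return reports


def heatmap_binned_means(
    dataset: pd.DataFrame,
    output: str,
    x_input: str,
    y_input: str,
    bins: int = 20,
) -> pd.DataFrame:
    """Mean of ``output`` on a bins×bins grid over its two top inputs
    (NaN where a bin is empty); rows indexed by y-bin centers."""
    x = dataset[x_input].values
    y = dataset[y_input].values
    z = dataset[output].values
    x_edges = np.linspace(x.min(), x.max(), bins + 1)
    y_edges = np.linspace(y.min(), y.max(), bins + 1)
    xi = np.clip(np.digitize(x, x_edges) - 1, 0, bins - 1)
    yi = np.clip(np.digitize(y, y_edges) - 1, 0, bins - 1)
    sums = np.zeros((bins, bins))
    cnts = np.zeros((bins, bins))
    np.add.at(sums, (yi, xi), z)
    np.add.at(cnts, (yi, xi), 1)
    with np.errstate(invalid="ignore"):
        grid = sums / cnts
    centers = lambda e: (e[:-1] + e[1:]) / 2  # noqa: E731
    return pd.DataFrame(grid, index=centers(y_edges), columns=centers(x_edges))
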