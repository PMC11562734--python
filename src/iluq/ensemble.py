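"""Equal-weight four-model ensemble, evaluation metrics, and interpretation.

The ensemble prediction for a pair is the (by default unweighted) arithmetic
mean of the four best per-representation models' predictions.  By convexity
(Jensen), its squared error never exceeds the mean of the member squared
errors, so ensemble MSE <= mean member MSE on any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from .chem import Conditions, IonPair, PropertyDataset
from .models import ModelSuite, TrainedModel, RU_REPRESENTATIONS

EQUAL_WEIGHTS = (0.25, 0.25, 0.25, 0.25)


def ensemble_predict(
    suite: ModelSuite,
    pairs: list[IonPair],
    conditions: list[Conditions] | None = None,
    weights: tuple[float, float, float, float] = EQUAL_WEIGHTS,
) -> np.ndarray:
    """Weighted mean of the four best-model predictions (default equal weights).

    With equal weights this equals the mean stored in each RU profile.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be 4 values summing to 1")
    members = suite.member_predictions(pairs, conditions)
    return members @ w


@dataclass(frozen=True)
class EvaluationReport:
    """RMSE / MAE / R² on one evaluation set.

    ``r_squared`` is None when the true values have zero variance (the null
    model is undefined there, so no number is reported).
    """

    rmse: float
    mae: float
    r_squared: float | None
    n: int


def evaluate(y_true, y_pred) -> EvaluationReport:
    """Standard regression metrics: RMSE, MAE, R² = 1 - SS_res/SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    if y_true.size < 2:
        raise ValueError("need at least 2 samples to evaluate")
    if not (np.all(np.isfinite(y_true)) and np.all(np.isfinite(y_pred))):
        raise ValueError("evaluation inputs must be finite")
    r2 = float(r2_score(y_true, y_pred)) if np.std(y_true) > 0 else None
    return EvaluationReport(
        rmse=float(np.sqrt(mean_squared_error(y_true, y_pred))),
        mae=float(mean_absolute_error(y_true, y_pred)),
        r_squared=r2,
        n=int(y_true.size),
    )


@dataclass(frozen=True)
class StratumReport:
    """RMSE of the samples whose true value falls in [lo, hi)."""

    lo: float
    hi: float
    n: int
    rmse: float | None   # None marks an empty bin


def stratified_rmse(y_true, y_pred, bin_edges) -> list[StratumReport]:
    """Per-bin RMSE over ranges of the true value.

    Bins are half-open [lo, hi) on ``y_true``, the last bin closed; samples
    outside the covered range are ignored.  An empty bin is reported with
    n=0 and rmse None.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 entries")
    out: list[StratumReport] = []
    for k in range(edges.size - 1):
        lo, hi = edges[k], edges[k + 1]
        if k == edges.size - 2:
            mask = (y_true >= lo) & (y_true <= hi)
        else:
            mask = (y_true >= lo) & (y_true < hi)
        n = int(mask.sum())
        rmse = (
            float(np.sqrt(np.mean((y_true[mask] - y_pred[mask]) ** 2))) if n else None
        )
        out.append(StratumReport(float(lo), float(hi), n, rmse))
    return out


#: Default capacity strata for the CO2-uptake target (mole fraction).
CO2_BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def global_importance(
    model: TrainedModel,
    dataset: PropertyDataset,
    seed: int = 0,
    n_repeats: int = 3,
    top_k: int | None = 8,
) -> list[tuple[int, float]]:
    """Permutation importance of the features of a vector-representation model.

    Importance of feature j is the mean increase in RMSE over ``n_repeats``
    seeded shuffles of column j of the design matrix.  Returns (feature index,
    importance) sorted descending; ``top_k`` trims the report (default 8, the
    usual size of an "atom group" summary).  Constant columns are skipped
    (their importance is exactly 0).
    """
    if model.representation_kind in ("MI", "MG"):
        raise ValueError(
            "global_importance supports vector representations only "
            f"(got {model.representation_kind})"
        )
    if len(dataset) < 20:
        raise ValueError("need at least 20 evaluation records")
    X = model.model.feature_matrix(dataset.pairs, dataset.conditions)
    y = dataset.values
    base = np.sqrt(np.mean((y - model.model.predict_from_features(X)) ** 2))
    rng = np.random.default_rng(seed)
    varying = np.nonzero(X.std(axis=0) > 0)[0]
    importances = np.zeros(X.shape[1])
    for j in varying:
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            rmse = np.sqrt(np.mean((y - model.model.predict_from_features(Xp)) ** 2))
            deltas.append(rmse - base)
        importances[j] = float(np.mean(deltas))
    order = np.argsort(-importances, kind="stable")
    ranked = [(int(j), float(importances[j])) for j in order]
    return ranked[:top_k] if top_k else ranked


def importance_direction(model: TrainedModel, dataset: PropertyDataset,
                         feature_index: int) -> float:
    """Signed correlation between a feature and the model's predictions.

    A positive value means larger feature values push the prediction up.
    Reported as a direction-of-effect heuristic alongside the (unsigned)
    permutation importance.
    """
    X = model.model.feature_matrix(dataset.pairs, dataset.conditions)
    pred = model.model.predict_from_features(X)
    col = X[:, feature_index]
    if col.std() == 0 or pred.std() == 0:
        return 0.0
    return float(np.corrcoef(col, pred)[0, 1])
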