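"""Per-representation QSPR regressors, hyperparameter-variant sets and suites.

One estimator class, :class:`QsprModel`, covers all five representations:

- ``B-MF`` / ``C-MF`` / ``MD`` — gradient-boosted trees (LightGBM) on the
  concatenated per-ion feature vectors, with standardized condition columns
  appended when the property needs them;
- ``MI`` — a convolutional random-features regressor: a seeded bank of random
  convolution filters + ReLU + average pooling produces image features, and a
  ridge head (with condition side-inputs) is trained on top;
- ``MG`` — a message-passing graph regressor: iterated neighborhood
  aggregation over the bond graph, pooled per graph, feeding a
  gradient-boosted head with condition side-inputs.

All models are deterministic given (data, params, seed).
"""

from __future__ import annotations

import hashlib
import json
import pickle
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lightgbm import LGBMRegressor
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .chem import Conditions, IonPair, PropertyDataset, split_dataset
from .features import (
    BinaryFingerprintFeaturizer,
    CountFingerprintFeaturizer,
    DescriptorFeaturizer,
    GraphFeaturizer,
    ImageFeaturizer,
    MoleculeGraph,
    condition_columns,
)

REPRESENTATIONS = ("B-MF", "C-MF", "MD", "MI", "MG")
#: The four representations whose best models define representation
#: uncertainty and the ensemble (the binary fingerprint is a baseline only).
RU_REPRESENTATIONS = ("C-MF", "MD", "MI", "MG")

MIN_TRAIN_RECORDS = 20


class SchemeMismatchError(RuntimeError):
    """Featurizer scheme at prediction time differs from the training scheme."""


@dataclass(frozen=True)
class HyperparameterVariant:
    """A named hyperparameter assignment for one model family."""

    name: str
    params: tuple[tuple[str, object], ...]

    @staticmethod
    def make(name: str, **params) -> "HyperparameterVariant":
        return HyperparameterVariant(name, tuple(sorted(params.items())))

    @property
    def as_dict(self) -> dict:
        return dict(self.params)


def default_variants(representation: str) -> list[HyperparameterVariant]:
    """The default 4-variant hyperparameter grid per representation family."""
    mk = HyperparameterVariant.make
    if representation in ("B-MF", "C-MF", "MD"):
        return [
            mk("gbt-a", num_leaves=31, learning_rate=0.1, n_estimators=200),
            mk("gbt-b", num_leaves=15, learning_rate=0.05, n_estimators=300),
            mk("gbt-c", num_leaves=63, learning_rate=0.1, n_estimators=150),
            mk("gbt-d", num_leaves=31, learning_rate=0.03, n_estimators=400, max_depth=6),
        ]
    if representation == "MI":
        return [
            mk("conv-a", n_filters=8, filter_size=5, pool=8, alpha=1.0),
            mk("conv-b", n_filters=16, filter_size=5, pool=8, alpha=10.0),
            mk("conv-c", n_filters=8, filter_size=7, pool=8, alpha=0.1),
            mk("conv-d", n_filters=4, filter_size=5, pool=16, alpha=1.0),
        ]
    if representation == "MG":
        return [
            mk("mp-a", rounds=2, num_leaves=31, learning_rate=0.1, n_estimators=200),
            mk("mp-b", rounds=3, num_leaves=15, learning_rate=0.05, n_estimators=300),
            mk("mp-c", rounds=1, num_leaves=63, learning_rate=0.1, n_estimators=150),
            mk("mp-d", rounds=2, num_leaves=31, learning_rate=0.03, n_estimators=400),
        ]
    raise ValueError(f"unknown representation {representation!r}")


# --------------------------------------------------------------------------
# representation feature extraction (with a small memo, since a variant set
# featurizes the same pairs four times)

_FEATURE_CACHE: OrderedDict[tuple, object] = OrderedDict()
_FEATURE_CACHE_SIZE = 12


def _cached(key: tuple, compute):
    if key in _FEATURE_CACHE:
        _FEATURE_CACHE.move_to_end(key)
        return _FEATURE_CACHE[key]
    val = compute()
    _FEATURE_CACHE[key] = val
    while len(_FEATURE_CACHE) > _FEATURE_CACHE_SIZE:
        _FEATURE_CACHE.popitem(last=False)
    return val


def _pairs_key(pairs: list[IonPair]) -> str:
    h = hashlib.sha1()
    for p in pairs:
        h.update(p.smiles.encode())
        h.update(b";")
    return h.hexdigest()


def _conv_features(images: np.ndarray, filters: np.ndarray, pool: int) -> np.ndarray:
    """Random convolution + ReLU + non-overlapping average pooling.

    images: (n, H, W, C); filters: (F, k, k).  Returns (n, F * pooled_cells).
    """
    n, H, W, C = images.shape
    k = filters.shape[1]
    gray = images.mean(axis=3)  # collapse channels; depictions are ink maps
    win = np.lib.stride_tricks.sliding_window_view(gray, (k, k), axis=(1, 2))
    # win: (n, H-k+1, W-k+1, k, k)
    resp = np.tensordot(win, filters, axes=([3, 4], [1, 2]))  # (n, h, w, F)
    np.maximum(resp, 0.0, out=resp)
    h, w = resp.shape[1], resp.shape[2]
    ph, pw = h // pool, w // pool
    resp = resp[:, : ph * pool, : pw * pool, :]
    pooled = resp.reshape(n, ph, pool, pw, pool, -1).mean(axis=(2, 4))
    return pooled.reshape(n, -1)


def _graph_features(graphs: list[MoleculeGraph], rounds: int) -> np.ndarray:
    """Neighborhood-aggregation (message-passing) graph features.

    Node states start from the atom feature vectors; each round adds the mean
    of neighbor states.  After every round the node states are pooled
    (sum / mean / max) per graph, separately for cation and anion components,
    and all rounds' pooled vectors plus bond-feature totals are concatenated.
    """
    feats = []
    for g in graphs:
        n, d = g.node_features.shape
        h = g.node_features.astype(float)
        deg = np.ones(n)
        nbr: list[list[int]] = [[] for _ in range(n)]
        for i, j in g.edges:
            nbr[i].append(j)
            nbr[j].append(i)
        pooled = []
        state = h
        for _ in range(rounds + 1):
            for comp in (0, 1):
                mask = g.component_tag == comp
                sub = state[mask] if mask.any() else np.zeros((1, d))
                pooled.extend([sub.sum(axis=0), sub.mean(axis=0), sub.max(axis=0)])
            msg = np.zeros_like(state)
            for i in range(n):
                if nbr[i]:
                    msg[i] = state[nbr[i]].mean(axis=0)
            state = state + msg
        bond_tot = g.edge_features.sum(axis=0)
        feats.append(np.concatenate([np.concatenate(pooled), bond_tot, [g.n_nodes]]))
    return np.stack(feats)


class QsprModel(BaseEstimator, RegressorMixin):
    """A single-representation QSPR regressor for ion pairs.

    Parameters
    ----------
    representation : one of ``B-MF, C-MF, MD, MI, MG``.
    property_name : target property; decides which condition columns are
        appended to the representation features.
    params : hyperparameters of the model family (see :func:`default_variants`).
    seed : controls every stochastic element (boosting, random filters).

    After :meth:`fit`, the fitted head is in ``head_`` and the featurizer
    scheme in ``scheme_tag_``.
    """

    def __init__(self, representation: str = "C-MF", property_name: str = "viscosity",
                 params: dict | None = None, seed: int = 0):
        self.representation = representation
        self.property_name = property_name
        self.params = params
        self.seed = seed

    # -- featurization ----------------------------------------------------
    def _featurizer(self):
        rep = self.representation
        if rep == "B-MF":
            return BinaryFingerprintFeaturizer()
        if rep == "C-MF":
            return CountFingerprintFeaturizer()
        if rep == "MD":
            return DescriptorFeaturizer()
        if rep == "MI":
            return ImageFeaturizer()
        if rep == "MG":
            return GraphFeaturizer()
        raise ValueError(f"unknown representation {rep!r}")

    def _rep_matrix(self, pairs: list[IonPair]) -> np.ndarray:
        """Representation features before condition columns (memoized)."""
        f = self._featurizer()
        p = dict(self.params or {})
        if self.representation == "MI":
            nf = int(p.get("n_filters", 8))
            k = int(p.get("filter_size", 5))
            pool = int(p.get("pool", 8))
            key = ("mi", f.scheme_tag, nf, k, pool, self.seed, _pairs_key(pairs))
            def compute():
                images = f.transform(pairs)
                rng = np.random.default_rng(self.seed)
                filters = rng.standard_normal((nf, k, k)) / k
                return _conv_features(images, filters, pool)
            return _cached(key, compute)
        if self.representation == "MG":
            rounds = int(p.get("rounds", 2))
            key = ("mg", f.scheme_tag, rounds, _pairs_key(pairs))
            return _cached(key, lambda: _graph_features(f.transform(pairs), rounds))
        key = ("vec", f.scheme_tag, _pairs_key(pairs))
        return _cached(key, lambda: f.transform(pairs))

    def feature_matrix(self, pairs: list[IonPair],
                       conditions: list[Conditions] | None = None) -> np.ndarray:
        """The full design matrix the head consumes (features + conditions)."""
        X = self._rep_matrix(pairs)
        cond = condition_columns(self._conditions_or_default(pairs, conditions),
                                 self.property_name)
        if cond.shape[1]:
            X = np.hstack([X, cond])
        return X

    def _conditions_or_default(self, pairs, conditions):
        if conditions is None:
            return [Conditions() for _ in pairs]
        if len(conditions) != len(pairs):
            raise ValueError("conditions list must match pairs list in length")
        return conditions

    @property
    def scheme_tag(self) -> str:
        base = self._featurizer().scheme_tag
        return f"{base}|prop={self.property_name}"

    # -- fitting ----------------------------------------------------------
    def _make_head(self):
        p = dict(self.params or {})
        if self.representation == "MI":
            alpha = float(p.get("alpha", 1.0))
            return make_pipeline(StandardScaler(), Ridge(alpha=alpha))
        gbm_keys = ("num_leaves", "learning_rate", "n_estimators", "max_depth",
                    "min_child_samples", "subsample", "colsample_bytree")
        kwargs = {k: p[k] for k in gbm_keys if k in p}
        return LGBMRegressor(
            random_state=self.seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
            **kwargs,
        )

    def fit(self, pairs: list[IonPair], y, conditions: list[Conditions] | None = None):
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("training targets must be finite")
        X = self.feature_matrix(pairs, conditions)
        self.head_ = self._make_head()
        self.head_.fit(X, y)
        self.scheme_tag_ = self.scheme_tag
        self.n_features_in_ = X.shape[1]
        pred = self.predict_from_features(X)
        if not np.all(np.isfinite(pred)):
            raise RuntimeError("training produced non-finite predictions")
        return self

    def predict_from_features(self, X: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper records synthetic feature names at
            # fit time; plain ndarrays at predict time are fine
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names"
            )
            return np.asarray(self.head_.predict(X), dtype=float)

    def predict(self, pairs: list[IonPair],
                conditions: list[Conditions] | None = None) -> np.ndarray:
        if not pairs:
            return np.empty(0)
        if self.scheme_tag_ != self.scheme_tag:
            raise SchemeMismatchError(
                f"model trained with {self.scheme_tag_!r}, "
                f"configured featurizer is {self.scheme_tag!r}"
            )
        return self.predict_from_features(self.feature_matrix(pairs, conditions))


# --------------------------------------------------------------------------
# trained-model wrapper and training operations

@dataclass
class TrainedModel:
    """A fitted :class:`QsprModel` plus its provenance and training metrics."""

    representation_kind: str
    variant: HyperparameterVariant
    model: QsprModel
    scheme_tag: str
    training_meta: dict

    def predict(self, pairs: list[IonPair],
                conditions: list[Conditions] | None = None,
                expected_scheme: str | None = None,
                override_scheme_check: bool = False) -> np.ndarray:
        """Order-preserving batch prediction; one finite value per valid pair.

        A pair whose stored SMILES fails to featurize yields NaN for that
        item rather than failing the batch.
        """
        if (expected_scheme is not None and expected_scheme != self.scheme_tag
                and not override_scheme_check):
            raise SchemeMismatchError(
                f"expected scheme {expected_scheme!r}, model has {self.scheme_tag!r}"
            )
        if not pairs:
            return np.empty(0)
        conditions = self.model._conditions_or_default(pairs, conditions)
        try:
            return self.model.predict(pairs, conditions)
        except SchemeMismatchError:
            raise
        except Exception:
            out = np.full(len(pairs), np.nan)
            for i, (p, c) in enumerate(zip(pairs, conditions)):
                try:
                    out[i] = self.model.predict([p], [c])[0]
                except SchemeMismatchError:
                    raise
                except Exception:
                    pass  # per-item failure recorded as NaN
            return out


def _train_metrics(y, pred) -> dict:
    return {
        "rmse": float(np.sqrt(mean_squared_error(y, pred))),
        "mae": float(mean_absolute_error(y, pred)),
        "r2": float(r2_score(y, pred)) if np.std(y) > 0 else None,
    }


def train_model(
    train: PropertyDataset,
    representation_kind: str,
    variant: HyperparameterVariant,
    seed: int = 0,
) -> TrainedModel:
    """Train one model on the training split of a property dataset."""
    if len(train) < MIN_TRAIN_RECORDS:
        raise ValueError(
            f"need at least {MIN_TRAIN_RECORDS} training records, got {len(train)}"
        )
    model = QsprModel(
        representation=representation_kind,
        property_name=train.property_name,
        params=variant.as_dict,
        seed=seed,
    )
    model.fit(train.pairs, train.values, train.conditions)
    pred = model.predict(train.pairs, train.conditions)
    meta = {"seed": seed, "n_train": len(train), **_train_metrics(train.values, pred)}
    return TrainedModel(
        representation_kind=representation_kind,
        variant=variant,
        model=model,
        scheme_tag=model.scheme_tag_,
        training_meta=meta,
    )


def train_variant_set(
    train: PropertyDataset,
    representation_kind: str,
    variants: list[HyperparameterVariant],
    seed: int = 0,
) -> list[TrainedModel]:
    """Train the 4 hyperparameter variants that define model uncertainty."""
    if len(variants) != 4:
        raise ValueError(f"a variant set has exactly 4 members, got {len(variants)}")
    names = [v.name for v in variants]
    if len(set(names)) != 4:
        raise ValueError(f"variant names must be unique, got {names}")
    return [train_model(train, representation_kind, v, seed=seed) for v in variants]


@dataclass
class ModelSuite:
    """Per property: the best model per representation plus the 4-variant sets.

    ``best_models`` has exactly the four representations that define
    representation uncertainty; each ``variant_sets`` entry has 4 members.
    """

    property_name: str
    best_models: dict[str, TrainedModel]
    variant_sets: dict[str, list[TrainedModel]]
    seed: int
    selection: dict[str, str] = field(default_factory=dict)
    selection_scores: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(sorted(self.best_models)) != tuple(sorted(RU_REPRESENTATIONS)):
            raise ValueError(
                f"suite must contain best models for exactly {RU_REPRESENTATIONS}"
            )
        for rep, models in self.variant_sets.items():
            if len(models) != 4:
                raise ValueError(f"variant set for {rep} must have 4 members")

    def member_predictions(
        self, pairs: list[IonPair], conditions: list[Conditions] | None = None
    ) -> np.ndarray:
        """(n_pairs, 4) predictions of the best models, RU column order."""
        cols = [
            self.best_models[rep].predict(pairs, conditions)
            for rep in RU_REPRESENTATIONS
        ]
        return np.column_stack(cols) if pairs else np.empty((0, 4))


def train_suite(
    train: PropertyDataset,
    seed: int = 0,
    variant_grids: dict[str, list[HyperparameterVariant]] | None = None,
    validation_fraction: float = 0.2,
) -> ModelSuite:
    """Train the full per-property model suite.

    For each representation the 4 variants are compared on an internal
    validation split of the training set (seeded with the suite seed); the
    lowest-validation-RMSE variant is selected, then all 4 variants are
    retrained on the full training set so the variant set (used for model
    uncertainty) and the best model share the final training data.
    """
    inner_train, inner_val = split_dataset(train, validation_fraction, seed)
    suite_best: dict[str, TrainedModel] = {}
    variant_sets: dict[str, list[TrainedModel]] = {}
    selection: dict[str, str] = {}
    scores_all: dict[str, dict[str, float]] = {}
    for rep in RU_REPRESENTATIONS:
        variants = (variant_grids or {}).get(rep) or default_variants(rep)
        scores: dict[str, float] = {}
        for v in variants:
            try:
                m = train_model(inner_train, rep, v, seed=seed)
            except Exception as exc:
                raise RuntimeError(f"training failed for {rep}/{v.name}") from exc
            val_pred = m.predict(inner_val.pairs, inner_val.conditions)
            scores[v.name] = float(
                np.sqrt(mean_squared_error(inner_val.values, val_pred))
            )
        best_name = min(scores, key=lambda k: (scores[k], k))
        full_set = train_variant_set(train, rep, list(variants), seed=seed)
        variant_sets[rep] = full_set
        suite_best[rep] = next(m for m in full_set if m.variant.name == best_name)
        selection[rep] = best_name
        scores_all[rep] = scores
    return ModelSuite(
        property_name=train.property_name,
        best_models=suite_best,
        variant_sets=variant_sets,
        seed=seed,
        selection=selection,
        selection_scores=scores_all,
    )


def predict(
    model: TrainedModel,
    pairs: list[IonPair],
    conditions: list[Conditions] | None = None,
) -> np.ndarray:
    """Module-level prediction wrapper (order-preserving, NaN per bad item)."""
    return model.predict(pairs, conditions)


# --------------------------------------------------------------------------
# model artifacts

def save_suite(suite: ModelSuite, directory) -> None:
    """Persist a suite as a directory with a manifest and pickled state."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "property_name": suite.property_name,
        "seed": suite.seed,
        "selection": suite.selection,
        "scheme_tags": {r: m.scheme_tag for r, m in suite.best_models.items()},
        "training_meta": {r: m.training_meta for r, m in suite.best_models.items()},
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    with open(d / "suite.pkl", "wb") as fh:
        pickle.dump(suite, fh)


def load_suite(directory, expected_scheme_tags: dict[str, str] | None = None,
               override_scheme_check: bool = False) -> ModelSuite:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    with open(d / "suite.pkl", "rb") as fh:
        suite: ModelSuite = pickle.load(fh)
    if expected_scheme_tags and not override_scheme_check:
        for rep, tag in expected_scheme_tags.items():
            have = manifest["scheme_tags"].get(rep)
            if have != tag:
                raise SchemeMismatchError(
                    f"suite {rep} scheme is {have!r}, expected {tag!r}"
                )
    return suite
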