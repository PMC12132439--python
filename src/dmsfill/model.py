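"""Gradient-boosted regression trees for score imputation.

Training uses LightGBM with up to 1,000 boosting rounds and early stopping
after 50 rounds without validation-RMSE improvement. Cross-validation is
group-aware: all variants of one protein fall into the same fold, so no
protein contributes to both sides of a split.

Hyperparameter search minimizes the mean grouped-fold RMSE over a standard
GBDT box (learning rate, depth, leaves, row/feature subsampling, L1/L2).
The sampler is seeded random search, declared in the trial log; any
sequential model-based optimizer honoring the same interface can replace it.

Determinism contract: with a fixed seed and single-threaded tree
construction, two runs produce identical models and predictions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import lightgbm as lgb
import numpy as np

from .core_io import DMSDataset, DMSRecord, VariantKey, all_substitution_keys
from .features import FeatureMatrix, FeatureSetConfig, assemble_features
from .normalize import positional_mean, james_stein_prior


@dataclass(frozen=True)
class HyperparamSpace:
    """Search box for the tunable LightGBM parameters (log-uniform where noted)."""

    learning_rate: tuple[float, float] = (1e-3, 0.3)  # log
    max_depth: tuple[int, int] = (3, 12)
    num_leaves: tuple[int, int] = (15, 255)
    row_subsample: tuple[float, float] = (0.5, 1.0)
    feature_subsample: tuple[float, float] = (0.5, 1.0)
    l1_penalty: tuple[float, float] = (1e-8, 10.0)  # log
    l2_penalty: tuple[float, float] = (1e-8, 10.0)  # log

    def __post_init__(self) -> None:
        for name in ("learning_rate", "max_depth", "num_leaves", "row_subsample",
                     "feature_subsample", "l1_penalty", "l2_penalty"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")

    def sample(self, rng: np.random.Generator) -> dict:
        def log_u(lo, hi):
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

        return {
            "learning_rate": log_u(*self.learning_rate),
            "max_depth": int(rng.integers(self.max_depth[0], self.max_depth[1] + 1)),
            "num_leaves": int(rng.integers(self.num_leaves[0], self.num_leaves[1] + 1)),
            "bagging_fraction": float(rng.uniform(*self.row_subsample)),
            "feature_fraction": float(rng.uniform(*self.feature_subsample)),
            "lambda_l1": log_u(*self.l1_penalty),
            "lambda_l2": log_u(*self.l2_penalty),
        }


#: Defaults used when no tuning run is requested.
DEFAULT_PARAMS: dict = {
    "learning_rate": 0.05,
    "max_depth": 8,
    "num_leaves": 63,
    "bagging_fraction": 0.9,
    "feature_fraction": 0.9,
    "lambda_l1": 0.0,
    "lambda_l2": 1.0,
}

_FIXED_PARAMS: dict = {
    "objective": "regression",
    "metric": "rmse",
    "bagging_freq": 1,
    "verbosity": -1,
    "deterministic": True,
    "force_row_wise": True,
    "num_threads": 1,
}


@dataclass
class TrainedModel:
    """A fitted boosting ensemble with its training configuration snapshot."""

    booster: lgb.Booster
    feature_names: list[str]
    best_iteration: int
    config: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        payload = {
            "model": self.booster.model_to_string(),
            "feature_names": self.feature_names,
            "best_iteration": self.best_iteration,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        booster = lgb.Booster(model_str=payload["model"])
        return cls(booster, payload["feature_names"], payload["best_iteration"],
                   payload["config"])


# ---------------------------------------------------------------------------
# Group-aware folds
# ---------------------------------------------------------------------------


def grouped_kfold(
    keys: Sequence[VariantKey],
    group_of: Callable[[VariantKey], str] | None = None,
    k: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Assign each key a fold id such that each group lies wholly in one fold.

    Groups are placed greedily, largest first (ties shuffled by seed), onto
    the currently smallest fold, balancing folds by variant count.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if group_of is None:
        group_of = lambda key: key.protein_id
    groups: dict[str, list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(group_of(key), []).append(i)
    if len(groups) < k:
        raise ValueError(
            f"fewer groups ({len(groups)}) than folds ({k})"
        )
    rng = np.random.default_rng(seed)
    names = sorted(groups)
    rng.shuffle(names)
    names.sort(key=lambda g: -len(groups[g]))  # stable: keeps shuffled tie order
    fold_sizes = [0] * k
    assignment = np.empty(len(keys), dtype=int)
    for g in names:
        fold = int(np.argmin(fold_sizes))
        for i in groups[g]:
            assignment[i] = fold
        fold_sizes[fold] += len(groups[g])
    return assignment


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------


def _as_matrix(features: FeatureMatrix) -> np.ndarray:
    return np.asarray(features.values, dtype=float)


def train(
    features: FeatureMatrix,
    targets: Sequence[float],
    params: Mapping | None = None,
    max_rounds: int = 1000,
    patience: int = 50,
    valid_fraction: float = 0.1,
    valid_set: tuple[FeatureMatrix, Sequence[float]] | None = None,
    groups: Sequence[str] | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit a boosted ensemble with early stopping on a validation slice.

    When no explicit validation set is given, a ``valid_fraction`` slice of
    the training rows is held out — group-aware when at least two groups are
    present, a seeded random slice otherwise (per-protein models).
    """
    y = np.asarray(targets, dtype=float)
    X = _as_matrix(features)
    if len(y) != X.shape[0]:
        raise ValueError(f"feature/target length mismatch: {X.shape[0]} vs {len(y)}")
    if np.unique(y[~np.isnan(y)]).size < 2:
        raise ValueError("targets are degenerate (fewer than 2 distinct values)")

    if valid_set is not None:
        X_tr, y_tr = X, y
        X_va = _align_columns(valid_set[0], features.columns)
        y_va = np.asarray(valid_set[1], dtype=float)
    else:
        n = len(y)
        rng = np.random.default_rng(seed)
        if groups is None:
            groups = [k.protein_id for k in features.keys]
        uniq = sorted(set(groups))
        if len(uniq) >= 2:
            order = list(uniq)
            rng.shuffle(order)
            target_n = max(1, int(round(valid_fraction * n)))
            valid_groups: set[str] = set()
            count = 0
            for g in order:
                if count >= target_n or len(valid_groups) == len(uniq) - 1:
                    break
                valid_groups.add(g)
                count += sum(gg == g for gg in groups)
            mask = np.array([g in valid_groups for g in groups])
        else:
            idx = rng.permutation(n)
            n_va = max(1, int(round(valid_fraction * n)))
            mask = np.zeros(n, dtype=bool)
            mask[idx[:n_va]] = True
        X_tr, y_tr = X[~mask], y[~mask]
        X_va, y_va = X[mask], y[mask]

    run_params = dict(DEFAULT_PARAMS)
    if params:
        run_params.update(params)
    run_params.update(_FIXED_PARAMS)
    run_params["seed"] = seed

    dtrain = lgb.Dataset(X_tr, label=y_tr, feature_name=list(features.columns),
                         free_raw_data=True)
    dvalid = dtrain.create_valid(X_va, label=y_va)
    booster = lgb.train(
        run_params,
        dtrain,
        num_boost_round=max_rounds,
        valid_sets=[dvalid],
        callbacks=[lgb.early_stopping(patience, verbose=False)],
    )
    best_it = booster.best_iteration or max_rounds
    snapshot = {
        "params": {k: v for k, v in run_params.items() if k != "seed"},
        "seed": seed,
        "max_rounds": max_rounds,
        "patience": patience,
        "n_train": int(len(y_tr)),
        "n_valid": int(len(y_va)),
    }
    return TrainedModel(booster, list(features.columns), int(best_it), snapshot)


def _align_columns(features: FeatureMatrix, expected: Sequence[str]) -> np.ndarray:
    have = list(features.columns)
    missing = [c for c in expected if c not in have]
    extra = [c for c in have if c not in expected]
    if missing or extra:
        raise ValueError(
            f"feature columns do not match training: missing={missing}, "
            f"unexpected={extra}"
        )
    order = [have.index(c) for c in expected]
    return _as_matrix(features)[:, order]


def predict(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Predict scores; columns are aligned by name, extras/missing are errors."""
    X = _align_columns(features, model.feature_names)
    preds = model.booster.predict(X, num_iteration=model.best_iteration)
    return np.asarray(preds, dtype=float)


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------


@dataclass
class TuneResult:
    best_params: dict
    best_rmse: float
    trials: list[dict]
    sampler: str = "random_search"


def tune(
    features: FeatureMatrix,
    targets: Sequence[float],
    groups: Sequence[str] | None = None,
    space: HyperparamSpace | None = None,
    n_trials: int = 20,
    k: int = 5,
    seed: int = 0,
    max_rounds: int = 1000,
    patience: int = 50,
) -> TuneResult:
    """Sequential search minimizing mean grouped-fold RMSE.

    Each trial trains k group-fold models with early stopping (the fold's
    held-out part doubles as the early-stopping validation set) and records
    the mean fold RMSE; the argmin trial wins. Reproducible given the seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    y = np.asarray(targets, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("targets are degenerate (zero variance)")
    space = space or HyperparamSpace()
    if groups is None:
        groups = [key.protein_id for key in features.keys]
    folds = _kfold_from_groups(list(groups), k, seed)
    rng = np.random.default_rng(seed)
    X = _as_matrix(features)
    trials: list[dict] = []
    for t in range(n_trials):
        params = space.sample(rng)
        fold_rmses = []
        for fold in range(k):
            mask = folds == fold
            fm_tr = FeatureMatrix(
                [key for key, m in zip(features.keys, mask) if not m],
                features.columns, X[~mask])
            fm_te = FeatureMatrix(
                [key for key, m in zip(features.keys, mask) if m],
                features.columns, X[mask])
            model = train(fm_tr, y[~mask], params=params, max_rounds=max_rounds,
                          patience=patience, valid_set=(fm_te, y[mask]), seed=seed)
            pred = predict(model, fm_te)
            fold_rmses.append(float(np.sqrt(np.mean((pred - y[mask]) ** 2))))
        trials.append({"trial": t, "params": params,
                       "mean_fold_rmse": float(np.mean(fold_rmses)),
                       "fold_rmses": fold_rmses})
    best = min(trials, key=lambda tr: tr["mean_fold_rmse"])
    return TuneResult(dict(best["params"]), best["mean_fold_rmse"], trials)


def _kfold_from_groups(groups: list[str], k: int, seed: int) -> np.ndarray:
    """Grouped fold ids for an explicit per-row group list."""
    uniq: dict[str, list[int]] = {}
    for i, g in enumerate(groups):
        uniq.setdefault(g, []).append(i)
    if len(uniq) < k:
        raise ValueError(f"fewer groups ({len(uniq)}) than folds ({k})")
    rng = np.random.default_rng(seed)
    names = sorted(uniq)
    rng.shuffle(names)
    names.sort(key=lambda g: -len(uniq[g]))
    fold_sizes = [0] * k
    assignment = np.empty(len(groups), dtype=int)
    for g in names:
        fold = int(np.argmin(fold_sizes))
        for i in uniq[g]:
            assignment[i] = fold
        fold_sizes[fold] += len(uniq[g])
    return assignment


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def impute(
    dataset: DMSDataset,
    model: TrainedModel,
    config: FeatureSetConfig,
    embeddings=None,
    prior_kind: str = "mean_dms",
    jse_lambda: float = 1.0,
) -> DMSDataset:
    """Fill every unobserved substitution cell with a model prediction.

    Positional priors are computed from the observed records only; observed
    records pass through untouched and imputed records carry
    ``imputed=True`` with the prediction in ``norm_score``.
    """
    observed = {r.key for r in dataset.records}
    missing: list[VariantKey] = []
    for dom in dataset.domains.values():
        if not dom.sequence:
            raise ValueError(f"{dom.protein_id}: sequence required for imputation")
        missing.extend(
            k for k in all_substitution_keys(dom) if k not in observed
        )
    new_records = [r for r in dataset.records]
    if missing:
        priors = None
        if config.needs_priors:
            priors = {}
            if config.mean_dms:
                priors["mean_dms"] = positional_mean(dataset)
            if config.jse_dms:
                priors["jse_dms"] = james_stein_prior(dataset, lam=jse_lambda)
        fm = assemble_features(dataset, config, priors=priors,
                               embeddings=embeddings, keys=missing)
        preds = predict(model, fm)
        for key, pred in zip(missing, preds):
            new_records.append(
                DMSRecord(key, norm_score=float(pred), imputed=True)
            )
    return DMSDataset(domains=dict(dataset.domains), records=new_records)
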