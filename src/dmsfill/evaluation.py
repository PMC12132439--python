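"""Leakage-controlled split strategies, metrics, and evaluation protocols.

Strategies
----------
``leave_protein_out``
    One plan: a seeded fraction of whole proteins held out for testing
    (the "general model" split — protein-granular, default 10% of domains).
``lopo_series``
    One plan per protein, each holding out that protein entirely.
``random_ratio``
    Per-protein variant-granular random split at a requested train ratio,
    rounded to the nearest variant with ties toward training.
``lposo_ratio``
    Per-protein position-granular split: whole positions assigned to train
    or test at the requested ratio.
``loposo_series`` / ``lovaro_series``
    One plan per (protein, position) / per variant; the training side is the
    rest of the same protein (per-protein models).
``snv_split``
    Train on substitutions reachable by a single nucleotide change, test on
    the rest; the SNV indicator itself is dropped from the features in this
    mode, since it would separate train from test by construction.
``family_unique``
    At most one domain per family retained (most observed variants wins,
    ties lexicographic), then a protein-granular split — train and test
    share no family.

Prior leakage policy
--------------------
Positional priors are always computed from training-visible observations.
For protein-granular holdouts the held-out protein has no training-side
observations, so its prior comes from its own observed variants and the
report is flagged ``within_protein_prior`` — the imputation regime, distinct
from zero-shot evaluation, where priors are disabled altogether.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DMSDataset, VariantKey
from .features import (
    FeatureMatrix,
    FeatureSetConfig,
    assemble_features,
    snv_indicator,
)
from .model import DEFAULT_PARAMS, TrainedModel, predict, train
from .normalize import james_stein_prior, positional_mean

#: Strategies whose holdout unit is the whole protein.
PROTEIN_GRANULAR = {"leave_protein_out", "lopo_series", "family_unique"}

_GRANULARITY = {
    "leave_protein_out": "protein",
    "lopo_series": "protein",
    "family_unique": "protein",
    "random_ratio": "variant",
    "lposo_ratio": "position",
    "loposo_series": "position",
    "lovaro_series": "variant",
    "snv_split": "variant",
}


class SplitError(ValueError):
    """Raised for invalid split parameters or leaky plans."""


@dataclass(frozen=True)
class SplitPlan:
    strategy: str
    params: tuple
    train_keys: tuple[VariantKey, ...]
    test_keys: tuple[VariantKey, ...]

    def __post_init__(self) -> None:
        overlap = set(self.train_keys) & set(self.test_keys)
        if overlap:
            raise SplitError(f"train/test overlap on {len(overlap)} keys")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _observed_substitution_keys(dataset: DMSDataset) -> list[VariantKey]:
    return [r.key for r in dataset.substitution_records() if r.has_score()]


def make_split(
    dataset: DMSDataset,
    strategy: str,
    params: Mapping | None = None,
    seed: int = 0,
) -> SplitPlan | list[SplitPlan]:
    """Build one split plan, or a series for the *_series strategies."""
    params = dict(params or {})
    keys = _observed_substitution_keys(dataset)
    by_protein: dict[str, list[VariantKey]] = {}
    for k in keys:
        by_protein.setdefault(k.protein_id, []).append(k)
    rng = np.random.default_rng(seed)

    if strategy == "leave_protein_out":
        ratio = float(params.get("ratio", 0.1))
        _check_ratio(ratio)
        proteins = sorted(by_protein)
        if len(proteins) < 2:
            raise SplitError("leave_protein_out needs >= 2 proteins")
        rng.shuffle(proteins)
        n_test = min(len(proteins) - 1, max(1, _round_half_up(ratio * len(proteins))))
        test_p = set(proteins[:n_test])
        train = [k for k in keys if k.protein_id not in test_p]
        test = [k for k in keys if k.protein_id in test_p]
        return SplitPlan(strategy, (("ratio", ratio), ("seed", seed)),
                         tuple(train), tuple(test))

    if strategy == "lopo_series":
        if len(by_protein) < 2:
            raise SplitError("lopo_series needs >= 2 proteins")
        plans = []
        for pid in sorted(by_protein):
            test = by_protein[pid]
            train = [k for k in keys if k.protein_id != pid]
            plans.append(SplitPlan(strategy, (("held_out", pid),),
                                   tuple(train), tuple(test)))
        return plans

    if strategy == "random_ratio":
        ratio = float(params.get("ratio", 0.8))
        _check_ratio(ratio)
        train, test = [], []
        for pid in sorted(by_protein):
            ks = sorted(by_protein[pid])
            rng.shuffle(ks)
            n_train = min(len(ks) - 1, max(1, _round_half_up(ratio * len(ks))))
            train += ks[:n_train]
            test += ks[n_train:]
        return SplitPlan(strategy, (("ratio", ratio), ("seed", seed)),
                         tuple(train), tuple(test))

    if strategy == "lposo_ratio":
        ratio = float(params.get("ratio", 0.8))
        _check_ratio(ratio)
        train, test = [], []
        for pid in sorted(by_protein):
            positions = sorted({k.position for k in by_protein[pid]})
            rng.shuffle(positions)
            n_train = min(len(positions) - 1,
                          max(1, _round_half_up(ratio * len(positions))))
            train_pos = set(positions[:n_train])
            for k in by_protein[pid]:
                (train if k.position in train_pos else test).append(k)
        return SplitPlan(strategy, (("ratio", ratio), ("seed", seed)),
                         tuple(train), tuple(test))

    if strategy == "loposo_series":
        plans = []
        for pid in sorted(by_protein):
            positions = sorted({k.position for k in by_protein[pid]})
            if len(positions) < 2:
                raise SplitError(f"{pid}: loposo needs >= 2 observed positions")
            for pos in positions:
                test = [k for k in by_protein[pid] if k.position == pos]
                train = [k for k in by_protein[pid] if k.position != pos]
                plans.append(SplitPlan(strategy,
                                       (("protein", pid), ("position", pos)),
                                       tuple(train), tuple(test)))
        return plans

    if strategy == "lovaro_series":
        plans = []
        for pid in sorted(by_protein):
            ks = sorted(by_protein[pid])
            if len(ks) < 2:
                raise SplitError(f"{pid}: lovaro needs >= 2 observed variants")
            for k in ks:
                train = [kk for kk in ks if kk != k]
                plans.append(SplitPlan(strategy,
                                       (("protein", pid), ("variant", k.token())),
                                       tuple(train), (k,)))
        return plans

    if strategy == "snv_split":
        train = [k for k in keys if snv_indicator(k.wt_aa, k.var_aa) == 1]
        test = [k for k in keys if snv_indicator(k.wt_aa, k.var_aa) == 0]
        if not train or not test:
            raise SplitError("snv_split produced an empty side")
        return SplitPlan(strategy, (), tuple(train), tuple(test))

    if strategy == "family_unique":
        ratio = float(params.get("ratio", 0.1))
        _check_ratio(ratio)
        families: dict[str, list[str]] = {}
        for pid, dom in dataset.domains.items():
            if dom.family_id is None:
                raise SplitError(f"{pid}: family_unique requires family_id")
            families.setdefault(dom.family_id, []).append(pid)
        kept: set[str] = set()
        for fam in sorted(families):
            members = sorted(families[fam])
            members.sort(key=lambda p: -len(by_protein.get(p, [])))
            kept.add(members[0])
        proteins = sorted(p for p in kept if p in by_protein)
        if len(proteins) < 2:
            raise SplitError("family_unique leaves fewer than 2 proteins")
        rng.shuffle(proteins)
        n_test = min(len(proteins) - 1, max(1, _round_half_up(ratio * len(proteins))))
        test_p = set(proteins[:n_test])
        kept_set = set(proteins)
        train = [k for k in keys
                 if k.protein_id in kept_set and k.protein_id not in test_p]
        test = [k for k in keys if k.protein_id in test_p]
        return SplitPlan(strategy, (("ratio", ratio), ("seed", seed)),
                         tuple(train), tuple(test))

    raise SplitError(f"unknown split strategy {strategy!r}")


def _check_ratio(ratio: float) -> None:
    if not (0.0 < ratio < 1.0):
        raise SplitError(f"ratio must lie in (0, 1), got {ratio}")


def verify_split(plan: SplitPlan, dataset: DMSDataset) -> None:
    """Independent leakage check at the strategy's declared granularity."""
    train, test = set(plan.train_keys), set(plan.test_keys)
    if train & test:
        raise SplitError("train and test keys overlap")
    all_keys = set(_observed_substitution_keys(dataset))
    if not (train | test) <= all_keys:
        raise SplitError("split references keys outside the dataset")
    gran = _GRANULARITY.get(plan.strategy, "variant")
    if gran == "protein":
        shared = {k.protein_id for k in train} & {k.protein_id for k in test}
        if shared:
            raise SplitError(f"protein leakage across split: {sorted(shared)}")
        if plan.strategy == "family_unique":
            fam = lambda ks: {dataset.domains[k.protein_id].family_id for k in ks}
            shared_fam = fam(train) & fam(test)
            if shared_fam:
                raise SplitError(f"family leakage across split: {sorted(shared_fam)}")
    elif gran == "position":
        tr = {(k.protein_id, k.position) for k in train}
        te = {(k.protein_id, k.position) for k in test}
        if tr & te:
            raise SplitError("position leakage across split")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    rmse: float
    mae: float
    r2: float
    pearson_r: float
    n_train: int = 0
    n_test: int = 0
    strategy: str = ""
    preset: str = ""
    flags: dict = field(default_factory=dict)


def compute_metrics(
    y_true: Sequence[float], y_pred: Sequence[float]
) -> MetricsReport:
    """RMSE, MAE, R-squared and Pearson r between observed and predicted."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size < 1:
        raise ValueError("metrics need at least one observation")
    err = yp - yt
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    flags: dict = {}
    if yt.size < 2 or np.allclose(yt, yt[0]):
        if yt.size >= 2:
            flags["zero_variance_truth"] = True
            warnings.warn("y_true has zero variance; r and R2 undefined")
        r2 = math.nan
        r = math.nan
    else:
        ss_res = float(np.sum(err**2))
        ss_tot = float(np.sum((yt - yt.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        r = float(stats.pearsonr(yt, yp).statistic) if np.std(yp) > 0 else math.nan
        if math.isnan(r):
            flags["constant_predictions"] = True
    return MetricsReport(rmse, mae, r2, r, n_test=int(yt.size), flags=flags)


# ---------------------------------------------------------------------------
# Protocol runner
# ---------------------------------------------------------------------------


def _build_priors(
    dataset: DMSDataset,
    config: FeatureSetConfig,
    scope: Sequence[VariantKey],
    within_protein: bool,
    jse_lambda: float,
):
    if not config.needs_priors:
        return None
    priors = {}
    if config.mean_dms:
        p = positional_mean(dataset, scope=scope, source="train_only")
        p.within_protein = within_protein
        priors["mean_dms"] = p
    if config.jse_dms:
        p = james_stein_prior(dataset, scope=scope, lam=jse_lambda,
                              source="train_only")
        p.within_protein = within_protein
        priors["jse_dms"] = p
    return priors


def run_protocol(
    dataset: DMSDataset,
    strategy: str,
    preset: FeatureSetConfig | str,
    params: Mapping | None = None,
    strategy_params: Mapping | None = None,
    seed: int = 0,
    embeddings=None,
    jse_lambda: float = 1.0,
    max_rounds: int = 1000,
    patience: int = 50,
) -> tuple[list[MetricsReport], pd.DataFrame]:
    """Fit and score a model under one split strategy.

    Returns one report per plan plus a per-variant error table (observed,
    predicted, absolute/squared/percent error) suitable for heatmaps.
    """
    config = (FeatureSetConfig.preset(preset) if isinstance(preset, str)
              else preset)
    preset_tag = preset if isinstance(preset, str) else "custom"
    if strategy == "snv_split" and config.snv:
        config = config.without_snv()
    plans = make_split(dataset, strategy, strategy_params, seed)
    if isinstance(plans, SplitPlan):
        plans = [plans]
    score_of = {r.key: r.norm_score for r in dataset.substitution_records()}
    within_protein = strategy in PROTEIN_GRANULAR

    reports: list[MetricsReport] = []
    rows: list[dict] = []
    for plan in plans:
        verify_split(plan, dataset)
        if not plan.train_keys or not plan.test_keys:
            raise SplitError(f"{strategy}: empty train or test side")
        prior_scope = (
            list(plan.train_keys) + list(plan.test_keys)
            if within_protein
            else list(plan.train_keys)
        )
        priors = _build_priors(dataset, config, prior_scope, within_protein,
                               jse_lambda)
        fm_train = assemble_features(dataset, config, priors=priors,
                                     embeddings=embeddings,
                                     keys=plan.train_keys)
        y_train = np.array([score_of[k] for k in plan.train_keys])
        model = train(fm_train, y_train, params=params, seed=seed,
                      max_rounds=max_rounds, patience=patience)
        fm_test = assemble_features(dataset, config, priors=priors,
                                    embeddings=embeddings,
                                    keys=plan.test_keys)
        y_test = np.array([score_of[k] for k in plan.test_keys])
        y_pred = predict(model, fm_test)
        if y_test.size >= 2:
            report = compute_metrics(y_test, y_pred)
        else:
            err = float(y_pred[0] - y_test[0])
            report = MetricsReport(abs(err), abs(err), math.nan, math.nan)
        report.n_train = len(plan.train_keys)
        report.n_test = len(plan.test_keys)
        report.strategy = strategy
        report.preset = preset_tag
        if within_protein and config.needs_priors:
            report.flags["within_protein_prior"] = True
        reports.append(report)
        for k, yt, yp in zip(plan.test_keys, y_test, y_pred):
            rows.append({
                "protein_id": k.protein_id,
                "position": k.position,
                "wt": k.wt_aa,
                "var": k.var_aa,
                "observed": float(yt),
                "predicted": float(yp),
                "abs_error": abs(float(yp - yt)),
                "sq_error": float((yp - yt) ** 2),
                "pct_error": (abs(float(yp - yt)) / abs(float(yt)) * 100.0
                              if yt != 0 else math.nan),
            })
    error_table = pd.DataFrame(
        rows, columns=["protein_id", "position", "wt", "var", "observed",
                       "predicted", "abs_error", "sq_error", "pct_error"])
    return reports, error_table


def masked_external_eval(
    dataset: DMSDataset,
    model: TrainedModel,
    config: FeatureSetConfig,
    mask_fraction: float,
    seed: int = 0,
    embeddings=None,
    jse_lambda: float = 1.0,
) -> MetricsReport:
    """Mask a fraction of observed records and predict them with a model
    trained elsewhere; positional priors come from the unmasked remainder."""
    if not (0.0 < mask_fraction < 1.0):
        raise ValueError(f"mask_fraction must lie in (0, 1), got {mask_fraction}")
    keys = _observed_substitution_keys(dataset)
    rng = np.random.default_rng(seed)
    order = sorted(keys)
    rng.shuffle(order)
    n_mask = _round_half_up(mask_fraction * len(order))
    masked = order[:n_mask]
    unmasked = order[n_mask:]
    score_of = {r.key: r.norm_score for r in dataset.substitution_records()}
    priors = _build_priors(dataset, config, unmasked, within_protein=False,
                           jse_lambda=jse_lambda)
    if priors:
        masked_proteins = {k.protein_id for k in masked}
        covered = {k.protein_id for k in unmasked}
        orphans = masked_proteins - covered
        if orphans:
            warnings.warn(
                f"proteins fully masked, priors fall back: {sorted(orphans)}"
            )
    fm = assemble_features(dataset, config, priors=priors,
                           embeddings=embeddings, keys=masked)
    y_true = np.array([score_of[k] for k in masked])
    y_pred = predict(model, fm)
    report = compute_metrics(y_true, y_pred)
    report.n_train = len(unmasked)
    report.n_test = len(masked)
    report.strategy = "masked_external"
    report.flags["mask_fraction"] = mask_fraction
    report.flags["seed"] = seed
    return report


def zero_shot_eval(
    dataset: DMSDataset,
    model: TrainedModel,
    config: FeatureSetConfig,
    embeddings=None,
) -> MetricsReport:
    """Score a prior-free model on proteins it never saw.

    Refuses configurations containing positional priors: those leak the
    target protein's own assay into prediction, which zero-shot evaluation
    exists to exclude.
    """
    if config.needs_priors:
        raise ValueError(
            "zero-shot evaluation requires a preset without positional priors "
            "(mean_dms/jse_dms)"
        )
    keys = _observed_substitution_keys(dataset)
    score_of = {r.key: r.norm_score for r in dataset.substitution_records()}
    fm = assemble_features(dataset, config, embeddings=embeddings, keys=keys)
    y_true = np.array([score_of[k] for k in keys])
    y_pred = predict(model, fm)
    report = compute_metrics(y_true, y_pred)
    report.n_test = len(keys)
    report.strategy = "zero_shot"
    return report
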