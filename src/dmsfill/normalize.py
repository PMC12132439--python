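"""Score normalization and position-level tolerance priors.

Raw assay scores are rescaled against two study baselines so that the
wild-type score maps to 1 and the nonsense (loss-of-function) baseline maps
to 0::

    s_norm = (s_raw - s_wt) / (s_wt - s_nons) + 1

The transform is affine and invertible and deliberately does not clip:
hyperstable variants or scoring artifacts may land above 1 or below 0.

Positional priors summarize site-specific mutational tolerance: the mean
normalized score of the observed variants at each (protein, position), or a
James-Stein-style shrinkage of that mean toward the protein-wide mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, NamedTuple

import numpy as np

from .core_io import DMSDataset, DMSRecord, VariantKey


class BaselineError(ValueError):
    """Raised when normalization baselines are missing or degenerate."""


@dataclass(frozen=True)
class BaselinePair:
    """Wild-type score s_wt and nonsense baseline s_nons for one protein."""

    wt_score: float
    nonsense_baseline: float
    nonsense_aggregator: Literal["mean", "median"] = "mean"

    def __post_init__(self) -> None:
        if self.wt_score == self.nonsense_baseline:
            raise BaselineError(
                f"wild-type score equals nonsense baseline ({self.wt_score}); "
                "normalization denominator would be zero"
            )


def estimate_baselines(
    dataset: DMSDataset,
    protein_id: str,
    aggregator: Literal["mean", "median"] = "mean",
) -> BaselinePair:
    """Determine s_wt and s_nons for one protein.

    Study-supplied baselines on the domain entry take precedence; otherwise
    s_nons is the mean (or median) of the protein's nonsense raw scores.
    s_wt must be study-supplied — there is no substitute for the wild-type
    anchor.
    """
    dom = dataset.domains[protein_id]
    wt = dom.wt_score
    if math.isnan(wt):
        raise BaselineError(f"{protein_id}: no study-supplied wild-type score")
    nons = dom.nonsense_baseline
    if math.isnan(nons):
        raws = [
            r.raw_score
            for r in dataset.nonsense_records(protein_id)
            if not math.isnan(r.raw_score)
        ]
        if not raws:
            raise BaselineError(
                f"{protein_id}: no nonsense records and no supplied baseline"
            )
        nons = float(np.mean(raws) if aggregator == "mean" else np.median(raws))
    return BaselinePair(wt, nons, aggregator)


def estimate_all_baselines(
    dataset: DMSDataset, aggregator: Literal["mean", "median"] = "mean"
) -> dict[str, BaselinePair]:
    return {
        pid: estimate_baselines(dataset, pid, aggregator) for pid in dataset.domains
    }


def normalize_scores(
    dataset: DMSDataset, baselines: dict[str, BaselinePair]
) -> DMSDataset:
    """Fill ``norm_score`` on every record from its raw score (no clipping)."""
    new_records = []
    for rec in dataset.records:
        b = baselines.get(rec.key.protein_id)
        if b is None:
            raise BaselineError(f"no baselines for protein {rec.key.protein_id!r}")
        if math.isnan(rec.raw_score):
            raise BaselineError(
                f"{rec.key.protein_id}:{rec.key.token()} has no raw score"
            )
        norm = (rec.raw_score - b.wt_score) / (b.wt_score - b.nonsense_baseline) + 1.0
        new_records.append(replace(rec, norm_score=norm))
    return DMSDataset(
        domains=dict(dataset.domains),
        records=new_records,
        aux_columns=dict(dataset.aux_columns),
    )


def denormalize_scores(
    dataset: DMSDataset, baselines: dict[str, BaselinePair]
) -> DMSDataset:
    """Inverse of :func:`normalize_scores`: reconstruct raw scores."""
    new_records = []
    for rec in dataset.records:
        b = baselines[rec.key.protein_id]
        raw = (rec.norm_score - 1.0) * (b.wt_score - b.nonsense_baseline) + b.wt_score
        new_records.append(replace(rec, raw_score=raw))
    return DMSDataset(
        domains=dict(dataset.domains),
        records=new_records,
        aux_columns=dict(dataset.aux_columns),
    )


# ---------------------------------------------------------------------------
# Positional priors
# ---------------------------------------------------------------------------


class PriorLookup(NamedTuple):
    value: float
    fallback_used: bool


@dataclass
class PositionPrior:
    """Per-(protein, position) tolerance prior with observation counts."""

    entries: dict[tuple[str, int], float]
    n_obs: dict[tuple[str, int], int]
    protein_means: dict[str, float]
    global_mean: float
    source: Literal["train_only", "all_observed"] = "all_observed"
    kind: Literal["mean_dms", "jse_dms"] = "mean_dms"
    within_protein: bool = False


def _scoped_records(
    dataset: DMSDataset, scope: Iterable[VariantKey] | None
) -> list[DMSRecord]:
    recs = dataset.substitution_records()
    if scope is not None:
        scope_set = set(scope)
        recs = [r for r in recs if r.key in scope_set]
    for r in recs:
        if math.isnan(r.norm_score):
            raise ValueError(
                f"record {r.key.protein_id}:{r.key.token()} in prior scope "
                "lacks a normalized score"
            )
    return recs


def positional_mean(
    dataset: DMSDataset,
    scope: Iterable[VariantKey] | None = None,
    source: Literal["train_only", "all_observed"] = "all_observed",
) -> PositionPrior:
    """Mean normalized score per (protein, position) over the given scope."""
    recs = _scoped_records(dataset, scope)
    sums: dict[tuple[str, int], float] = {}
    counts: dict[tuple[str, int], int] = {}
    protein_sums: dict[str, float] = {}
    protein_counts: dict[str, int] = {}
    for r in recs:
        k = (r.key.protein_id, r.key.position)
        sums[k] = sums.get(k, 0.0) + r.norm_score
        counts[k] = counts.get(k, 0) + 1
        protein_sums[r.key.protein_id] = (
            protein_sums.get(r.key.protein_id, 0.0) + r.norm_score
        )
        protein_counts[r.key.protein_id] = protein_counts.get(r.key.protein_id, 0) + 1
    entries = {k: sums[k] / counts[k] for k in sums}
    protein_means = {p: protein_sums[p] / protein_counts[p] for p in protein_sums}
    global_mean = (
        sum(protein_sums.values()) / sum(protein_counts.values())
        if protein_counts
        else math.nan
    )
    return PositionPrior(entries, counts, protein_means, global_mean,
                         source=source, kind="mean_dms")


def james_stein_prior(
    dataset: DMSDataset,
    scope: Iterable[VariantKey] | None = None,
    lam: float = 1.0,
    source: Literal["train_only", "all_observed"] = "all_observed",
) -> PositionPrior:
    """Shrink each position mean toward the protein-wide mean.

    prior(P, pos) = (n * m_pos + lam * m_P) / (n + lam); lam=0 reduces to the
    plain positional mean.
    """
    if lam < 0:
        raise ValueError(f"shrinkage strength must be >= 0, got {lam}")
    base = positional_mean(dataset, scope, source=source)
    entries = {}
    for (pid, pos), m_pos in base.entries.items():
        n = base.n_obs[(pid, pos)]
        m_p = base.protein_means[pid]
        entries[(pid, pos)] = (n * m_pos + lam * m_p) / (n + lam)
    return PositionPrior(entries, dict(base.n_obs), dict(base.protein_means),
                         base.global_mean, source=source, kind="jse_dms",
                         within_protein=base.within_protein)


def lookup_prior(
    prior: PositionPrior,
    key: VariantKey,
    fallback: Literal["protein_mean", "global_mean", "missing"] = "protein_mean",
) -> PriorLookup:
    """Prior for a variant's position, with a leakage-safe fallback chain.

    Unobserved positions fall back to the protein-wide mean of the prior's
    source scope, then the global mean; ``missing`` yields NaN instead.
    """
    v = prior.entries.get((key.protein_id, key.position))
    if v is not None:
        return PriorLookup(v, False)
    if fallback == "missing":
        return PriorLookup(math.nan, True)
    if fallback == "protein_mean":
        pm = prior.protein_means.get(key.protein_id)
        if pm is not None:
            return PriorLookup(pm, True)
    return PriorLookup(prior.global_mean, True)
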