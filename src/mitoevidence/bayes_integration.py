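"""Naive Bayes likelihood-ratio integration of binary predictor calls.

Each predictor s_i is scored against the gold standard: L1 is the likelihood
ratio P(call=1 | mitochondrial) / P(call=1 | non-mitochondrial) and L0 the
analogous ratio for a 0 call, estimated as (pseudocounted) relative
frequencies.  Assuming the predictors conditionally independent given the
class, a protein's evidence combines multiplicatively, so its integrated
score is the sum of base-10 log likelihood ratios:

    logLR(p) = sum_i log10 L_i(call_i(p))

Posterior odds = prior odds x 10^logLR, with prior odds n_pos / (n_total -
n_pos).  A protein is called mitochondrial when logLR strictly exceeds the
chosen threshold (1.37 in the motivating study; log10(19) ~ 1.28 is the
break-even point at prior odds of 1 in 19).  Base 10 is used throughout —
the published thresholds are only consistent with base 10.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_model import (
    FeatureMatrix,
    Label,
    ProteinCatalog,
    ValidationError,
)

__all__ = [
    "PredictorLikelihood",
    "LikelihoodTable",
    "OddsModel",
    "IntegrationResult",
    "estimate_likelihood_ratios",
    "prior_odds",
    "integrate",
    "classify",
    "merge_group_direct",
    "merge_group_indirect",
    "assemble_core_set",
]


@dataclass(frozen=True)
class PredictorLikelihood:
    """Per-predictor likelihood ratios with the 2x2 tallies behind them."""

    predictor_id: str
    l1: float
    l0: float
    # calls=1/0 among scored positives / negatives (audit trail)
    n1_pos: int
    n0_pos: int
    n1_neg: int
    n0_neg: int

    def __post_init__(self) -> None:
        for name in ("l1", "l0"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValidationError(
                    f"{self.predictor_id}: {name}={v} must be finite and positive; "
                    "use a pseudocount alpha > 0 to avoid zero frequencies"
                )


@dataclass
class LikelihoodTable:
    ratios: dict[str, PredictorLikelihood]
    alpha: float

    def __getitem__(self, predictor_id: str) -> PredictorLikelihood:
        return self.ratios[predictor_id]

    def __contains__(self, predictor_id: str) -> bool:
        return predictor_id in self.ratios


@dataclass(frozen=True)
class OddsModel:
    """Prior odds of mitochondrial localization; log base fixed at 10."""

    n_pos: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 < self.n_pos < self.n_total:
            raise ValidationError("need 0 < n_pos < n_total")

    @property
    def prior_odds(self) -> float:
        return self.n_pos / (self.n_total - self.n_pos)


@dataclass
class IntegrationResult:
    """Per-protein summed log10 likelihood ratio and posterior odds."""

    protein_ids: list[str]
    loglr: np.ndarray
    odds: OddsModel | None = None

    def posterior_odds(self) -> np.ndarray:
        if self.odds is None:
            raise ValidationError("no prior-odds model attached")
        return self.odds.prior_odds * 10.0 ** self.loglr


def estimate_likelihood_ratios(
    features: FeatureMatrix,
    catalog: ProteinCatalog,
    alpha: float = 1.0,
) -> LikelihoodTable:
    """Estimate L1 and L0 for every predictor from the gold standard.

    Class-conditional call frequencies use a symmetric pseudocount:
    P(call=c | class) = (count + alpha) / (n_class + 2*alpha).  Missing calls
    are excluded from that predictor's tallies.  With alpha = 0 a zero
    frequency raises instead of producing an infinite ratio.
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    labels = catalog.labels
    is_pos = np.array(
        [labels.get(pid) is Label.POSITIVE for pid in features.protein_ids]
    )
    is_neg = np.array(
        [labels.get(pid) is Label.NEGATIVE for pid in features.protein_ids]
    )
    ratios: dict[str, PredictorLikelihood] = {}
    for j, sid in enumerate(features.predictor_ids):
        col = features.calls[:, j]
        scored = ~np.isnan(col)
        pos_calls = col[scored & is_pos]
        neg_calls = col[scored & is_neg]
        if len(pos_calls) == 0 or len(neg_calls) == 0:
            raise ValidationError(
                f"predictor {sid!r} scores no gold-standard "
                f"{'positives' if len(pos_calls) == 0 else 'negatives'}"
            )
        n1p, n0p = int(pos_calls.sum()), int((1 - pos_calls).sum())
        n1n, n0n = int(neg_calls.sum()), int((1 - neg_calls).sum())
        if alpha == 0 and 0 in (n1p, n0p, n1n, n0n):
            raise ValidationError(
                f"predictor {sid!r} has a zero cell count; "
                "use alpha > 0 for a finite likelihood ratio"
            )
        p1_pos = (n1p + alpha) / (len(pos_calls) + 2 * alpha)
        p1_neg = (n1n + alpha) / (len(neg_calls) + 2 * alpha)
        ratios[sid] = PredictorLikelihood(
            predictor_id=sid,
            l1=p1_pos / p1_neg,
            l0=(1.0 - p1_pos) / (1.0 - p1_neg),
            n1_pos=n1p,
            n0_pos=n0p,
            n1_neg=n1n,
            n0_neg=n0n,
        )
    return LikelihoodTable(ratios=ratios, alpha=alpha)


def prior_odds(n_pos: int, n_total: int) -> float:
    """Prior odds of a protein being mitochondrial: n_pos / (n_total - n_pos).

    With ~1,500 expected mitochondrial proteins among ~30,480 nucleus-encoded
    proteins this is about 1 in 19.
    """
    return OddsModel(n_pos, n_total).prior_odds


def integrate(
    features: FeatureMatrix,
    lr: LikelihoodTable,
    missing_policy: str = "skip",
    odds: OddsModel | None = None,
) -> IntegrationResult:
    """Sum per-predictor log10 likelihood ratios into one score per protein.

    ``missing_policy``:
      * ``skip`` (default) — a missing call contributes nothing (absence of
        evidence is no evidence),
      * ``as_absent`` — a missing call is treated as call = 0.
    """
    if missing_policy not in ("skip", "as_absent"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    loglr = np.zeros(len(features.protein_ids))
    for j, sid in enumerate(features.predictor_ids):
        if sid not in lr:
            raise ValidationError(f"predictor {sid!r} absent from likelihood table")
        pl = lr[sid]
        col = features.calls[:, j]
        missing = np.isnan(col)
        contrib = np.where(col == 1.0, math.log10(pl.l1), math.log10(pl.l0))
        if missing_policy == "skip":
            contrib = np.where(missing, 0.0, contrib)
        else:
            contrib = np.where(missing, math.log10(pl.l0), contrib)
        loglr += contrib
    return IntegrationResult(list(features.protein_ids), loglr, odds=odds)


def classify(scores: IntegrationResult, threshold: float) -> np.ndarray:
    """Boolean calls: positive iff logLR strictly exceeds the threshold."""
    if not math.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    return scores.loglr > threshold


def merge_group_indirect(
    features: FeatureMatrix,
    group: set[str],
    record_threshold: int,
    merged_id: str | None = None,
) -> FeatureMatrix:
    """Merge a predictor group by record counting.

    The merged call is 1 iff at least ``record_threshold`` predictors in the
    group call 1 (missing calls count as no record).  A protein missing from
    every group predictor gets a missing merged call.  Returns a one-column
    :class:`FeatureMatrix`.
    """
    if not group:
        raise ValidationError("group must be non-empty")
    unknown = group - set(features.predictor_ids)
    if unknown:
        raise ValidationError(f"unknown predictor ids in group: {sorted(unknown)}")
    if not 1 <= record_threshold <= len(group):
        raise ValidationError(
            f"record_threshold {record_threshold} outside [1, {len(group)}]"
        )
    cols = [j for j, sid in enumerate(features.predictor_ids) if sid in group]
    sub = features.calls[:, cols]
    records = np.nansum(sub, axis=1)
    merged = (records >= record_threshold).astype(float)
    merged[np.isnan(sub).all(axis=1)] = np.nan
    if merged_id is None:
        merged_id = "+".join(sorted(group))
    return FeatureMatrix(list(features.protein_ids), [merged_id], merged[:, None])


def merge_group_direct(
    features: FeatureMatrix, group: set[str], merged_id: str | None = None
) -> FeatureMatrix:
    """Direct merge: union of the group's predictions (logical OR)."""
    return merge_group_indirect(features, group, record_threshold=1, merged_id=merged_id)


def assemble_core_set(
    integrated_calls: set[str],
    experimental_positives: set[str],
    known_negatives: set[str],
) -> set[str]:
    """Core set = (integrated predictions ∪ experimental positives) \\ negatives."""
    return (set(integrated_calls) | set(experimental_positives)) - set(known_negatives)
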