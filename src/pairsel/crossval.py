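"""Stratified k-fold internal cross-validation with per-fold chains.

The data are partitioned into mutually exclusive, exhaustive folds with the
case:control ratio preserved across folds (up to integer rounding; ratio
preservation takes precedence over exactly equal fold sizes, because the
case-control ratio can strongly affect the selection).  One chain is fitted
per calibration set; held-out individuals receive model-averaged validated
probabilities, pooled over folds for the final metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ChainSettings, PriorSpec
from .sampler import run_chain
from .summaries import classification_metrics, inclusion_probabilities, predict

__all__ = ["FoldPlan", "stratified_folds", "cross_validate"]


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of each individual to exactly one validation fold."""

    assignment: np.ndarray  # fold index per individual
    nfolds: int
    seed: int

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", a)
        if a.min() < 0 or a.max() >= self.nfolds:
            raise ValueError("fold indices out of range")

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


def stratified_folds(y, nfolds: int, seed: int) -> FoldPlan:
    """Random stratified fold assignment: within-class permutation followed by
    round-robin allocation, so per-fold class counts differ by at most one."""
    y = np.asarray(y)
    if nfolds < 2:
        raise ValueError("nfolds must be at least 2")
    rng = np.random.default_rng(seed)
    assignment = np.empty(y.size, dtype=int)
    for cls in (1, 0):
        members = np.flatnonzero(y == cls)
        if members.size < nfolds:
            raise ValueError(
                f"class {cls} has {members.size} members, fewer than "
                f"nfolds={nfolds}")
        perm = rng.permutation(members)
        assignment[perm] = np.arange(perm.size) % nfolds
    return FoldPlan(assignment, nfolds, seed)


def _fold_seeds(master_seed: int, nfolds: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(nfolds)]


def _default_fitter(train_design, prior: PriorSpec, settings: ChainSettings):
    chain = run_chain(train_design, prior, settings)
    return chain


def cross_validate(design, prior: PriorSpec, settings: ChainSettings,
                   foldplan: FoldPlan, fitter=None) -> dict:
    """Fit one chain per calibration set and pool held-out predictions.

    Returns a dict with the pooled cross-validated probabilities (one per
    individual, in data order), classification metrics on them, and per-fold
    cluster inclusion probabilities with their across-fold average and
    spread (sample SD of the fold-wise probabilities).

    ``fitter(train_design, prior, settings) -> object`` may replace the chain
    fit; the returned object must either be a Chain or expose
    ``predict_proba(design) -> probabilities`` (useful for stub predictors in
    validation and for comparator models).
    """
    if fitter is None:
        fitter = _default_fitter
    if foldplan.assignment.size != design.n:
        raise ValueError("fold plan does not match the design size")
    seeds = _fold_seeds(settings.seed, foldplan.nfolds)
    probs = np.full(design.n, np.nan)
    per_fold_inclusion = []
    for fold in range(foldplan.nfolds):
        test_idx = foldplan.fold_indices(fold)
        train_idx = np.flatnonzero(foldplan.assignment != fold)
        fold_settings = ChainSettings(
            n_iter=settings.n_iter, burn_in=settings.burn_in,
            thin=settings.thin, seed=seeds[fold],
            prior_only=settings.prior_only, fix_scales=settings.fix_scales)
        fitted = fitter(design.subset(train_idx), prior, fold_settings)
        if hasattr(fitted, "predict_proba"):
            probs[test_idx] = fitted.predict_proba(design.subset(test_idx))
            per_fold_inclusion.append(np.zeros(design.p))
        else:
            probs[test_idx] = predict(fitted, design.subset(test_idx))
            per_fold_inclusion.append(inclusion_probabilities(fitted).p_any)
    assert not np.isnan(probs).any()
    per_fold = np.vstack(per_fold_inclusion)
    avg = per_fold.mean(axis=0)
    sd = per_fold.std(axis=0, ddof=1) if foldplan.nfolds > 1 else np.zeros(design.p)
    order = np.argsort(-avg, kind="stable")
    return {
        "cv_probabilities": probs,
        "metrics": classification_metrics(probs, design.y),
        "per_fold_inclusion": per_fold,
        "inclusion_avg": avg,
        "inclusion_sd": sd,
        "rank_by_avg": order,
    }
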