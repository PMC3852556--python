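"""Majority-voting training protocol and cross-validation harness.

Training shuffles the samples, splits them into K (odd) nearly equal
stratified sub-blocks, and fits one model per block; prediction takes
the majority of the K member votes. The evaluation harness runs
repeated stratified k-fold cross-validation, reporting per-repeat
metrics and their arithmetic mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .core import (
    IasplsModel,
    SCHEMA_VERSION,
    fit_iaspls,
    predict_scores,
    standardize_columns,
    validate_response,
)
from .errors import DataError
from .features import FeatureMatrix
from .metrics import ConfusionCounts, classification_metrics, confusion_counts

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IasplsParams:
    """Hyperparameters forwarded to :func:`iaspls.core.fit_iaspls`."""

    n_components: int = 3
    sparsity: float = 0.5
    ridge_alpha: float = 1.0
    max_iter: int = 10
    tol: float = 1e-6

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "sparsity": self.sparsity,
            "ridge_alpha": self.ridge_alpha,
            "max_iter": self.max_iter,
            "tol": self.tol,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "IasplsParams":
        return cls(**{k: payload[k] for k in cls().to_dict() if k in payload})


def _as_array(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _fit_member(X: np.ndarray, y: np.ndarray, params: IasplsParams) -> IasplsModel:
    design = standardize_columns(X)
    return fit_iaspls(
        design,
        y,
        n_components=params.n_components,
        sparsity=params.sparsity,
        ridge_alpha=params.ridge_alpha,
        max_iter=params.max_iter,
        tol=params.tol,
    )


@dataclass
class VotingEnsemble:
    """K models trained on disjoint stratified sub-blocks; K odd."""

    K: int
    members: list[IasplsModel]
    seed: int
    repeat_index: int = 0

    def save(self, path: str | Path) -> None:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "K": self.K,
            "seed": self.seed,
            "repeat_index": self.repeat_index,
            "members": [m.to_dict() for m in self.members],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "VotingEnsemble":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise DataError(
                f"unsupported ensemble schema version: {payload.get('schema_version')!r}"
            )
        return cls(
            K=int(payload["K"]),
            members=[IasplsModel.from_dict(m) for m in payload["members"]],
            seed=int(payload["seed"]),
            repeat_index=int(payload.get("repeat_index", 0)),
        )


def _stratified_blocks(
    y: np.ndarray, K: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Shuffle indices and deal them into K nearly equal stratified blocks."""
    blocks: list[list[int]] = [[] for _ in range(K)]
    for cls_value in (1, -1):
        idx = np.flatnonzero(y == cls_value)
        idx = rng.permutation(idx)
        for j, sample in enumerate(idx):
            blocks[j % K].append(int(sample))
    return [np.array(sorted(b), dtype=int) for b in blocks]


def train_voting_ensemble(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    K: int = 3,
    params: IasplsParams | None = None,
    seed: int = 0,
    repeat_index: int = 0,
) -> VotingEnsemble:
    """Train K models on disjoint stratified sub-blocks of (X, y).

    K must be odd so that majority votes cannot tie. Raises if any
    sub-block would lose a class (advice: use a smaller K).
    """
    if K < 1 or K % 2 == 0:
        raise DataError(f"K must be an odd positive integer, got {K}")
    params = params or IasplsParams()
    Xa = _as_array(X)
    y = validate_response(y)
    if Xa.shape[0] != y.shape[0]:
        raise DataError("X and y disagree on sample count")
    rng = np.random.default_rng(seed + 7919 * repeat_index)
    blocks = _stratified_blocks(y, K, rng)
    members = []
    for b, idx in enumerate(blocks):
        if len(np.unique(y[idx])) < 2:
            raise DataError(
                f"sub-block {b} lost a class; use a smaller K than {K}"
            )
        members.append(_fit_member(Xa[idx], y[idx], params))
    return VotingEnsemble(K=K, members=members, seed=seed, repeat_index=repeat_index)


def predict_by_vote(
    ensemble: VotingEnsemble, X_new: FeatureMatrix | np.ndarray
) -> np.ndarray:
    """Majority vote over member predictions; +1 iff more than K/2 vote +1."""
    Xa = _as_array(X_new)
    votes = np.stack(
        [predict_scores(m, Xa)[1] for m in ensemble.members], axis=0
    )
    positives = (votes == 1).sum(axis=0)
    return np.where(positives * 2 > ensemble.K, 1, -1)


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationPlan:
    """Protocol parameters for repeated stratified cross-validation."""

    n_folds: int = 5
    train_fraction: float = 2.0 / 3.0
    n_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise DataError("need at least 2 folds")
        if not 0 < self.train_fraction < 1:
            raise DataError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise DataError("need at least 1 repeat")


@dataclass
class FoldResult:
    repeat: int
    fold: int
    counts: ConfusionCounts


@dataclass
class CrossValidationResult:
    """Per-fold counts, per-repeat metrics and their arithmetic mean."""

    folds: list[FoldResult]
    repeat_metrics: list[dict[str, float]]
    mean_metrics: dict[str, float]
    plan: EvaluationPlan


#: A trainer takes (X_train, y_train, seed) and returns a predictor
#: mapping X_test -> labels. Used to swap the learner in harness tests.
TrainerType = Callable[[np.ndarray, np.ndarray, int], Callable[[np.ndarray], np.ndarray]]


def _default_trainer(
    K: int, params: IasplsParams
) -> TrainerType:
    def trainer(X_tr: np.ndarray, y_tr: np.ndarray, seed: int):
        ensemble = train_voting_ensemble(X_tr, y_tr, K=K, params=params, seed=seed)
        return lambda X_te: predict_by_vote(ensemble, X_te)

    return trainer


def _balance_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Downsample the larger class to the size of the smaller one."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == -1)
    m = min(len(pos), len(neg))
    keep = np.concatenate(
        [rng.choice(pos, size=m, replace=False), rng.choice(neg, size=m, replace=False)]
    )
    return np.sort(keep)


def cross_validate(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    plan: EvaluationPlan | None = None,
    K: int = 3,
    params: IasplsParams | None = None,
    balanced: bool = False,
    trainer: TrainerType | None = None,
) -> CrossValidationResult:
    """Repeated stratified k-fold cross-validation with voting ensembles.

    Each repeat reshuffles both the fold assignment and the sub-block
    partition (seed + repeat index). With *balanced*, the larger class
    is downsampled per repeat to match the smaller one. A custom
    *trainer* may replace the ensemble (harness tests).
    """
    plan = plan or EvaluationPlan()
    params = params or IasplsParams()
    Xa = _as_array(X)
    y = validate_response(y)
    if Xa.shape[0] != y.shape[0]:
        raise DataError("X and y disagree on sample count")
    if Xa.shape[0] < plan.n_folds:
        raise DataError("fewer samples than folds")
    trainer = trainer or _default_trainer(K, params)

    folds: list[FoldResult] = []
    repeat_metrics: list[dict[str, float]] = []
    for r in range(1, plan.n_repeats + 1):
        rng = np.random.default_rng(plan.seed + r)
        if balanced:
            active = _balance_indices(y, rng)
        else:
            active = np.arange(len(y))
        X_r, y_r = Xa[active], y[active]
        splitter = StratifiedKFold(
            n_splits=plan.n_folds, shuffle=True, random_state=plan.seed + r
        )
        repeat_counts = ConfusionCounts(0, 0, 0, 0)
        for f, (train_idx, test_idx) in enumerate(splitter.split(X_r, y_r)):
            if len(np.unique(y_r[train_idx])) < 2:
                raise DataError("degenerate stratification: training fold lost a class")
            predict = trainer(X_r[train_idx], y_r[train_idx], plan.seed + r)
            pred = predict(X_r[test_idx])
            counts = confusion_counts(y_r[test_idx], pred)
            folds.append(FoldResult(repeat=r, fold=f, counts=counts))
            repeat_counts = repeat_counts + counts
        repeat_metrics.append(classification_metrics(repeat_counts))

    mean_metrics = {
        key: float(np.mean([m[key] for m in repeat_metrics]))
        for key in ("Sn", "Sp", "ACC", "MCC")
    }
    return CrossValidationResult(
        folds=folds, repeat_metrics=repeat_metrics, mean_metrics=mean_metrics, plan=plan
    )


def write_report(
    results: dict[str, CrossValidationResult], path: str | Path
) -> None:
    """Write a tab-separated evaluation report.

    One row per (section, repeat, fold) with raw counts and metrics,
    one summary row per (section, repeat), and a mean row per section.
    """
    with open(path, "w") as fh:
        fh.write(
            "section\trepeat\tfold\tTP\tTN\tFP\tFN\tSn\tSp\tACC\tMCC\n"
        )
        for section, result in results.items():
            for fr in result.folds:
                m = classification_metrics(fr.counts)
                fh.write(
                    f"{section}\t{fr.repeat}\t{fr.fold}\t"
                    f"{fr.counts.TP}\t{fr.counts.TN}\t{fr.counts.FP}\t{fr.counts.FN}\t"
                    f"{m['Sn']:.6f}\t{m['Sp']:.6f}\t{m['ACC']:.6f}\t{m['MCC']:.6f}\n"
                )
            for r, m in enumerate(result.repeat_metrics, 1):
                fh.write(
                    f"{section}\t{r}\trepeat_summary\t\t\t\t\t"
                    f"{m['Sn']:.6f}\t{m['Sp']:.6f}\t{m['ACC']:.6f}\t{m['MCC']:.6f}\n"
                )
            m = result.mean_metrics
            fh.write(
                f"{section}\tmean\t\t\t\t\t\t"
                f"{m['Sn']:.6f}\t{m['Sp']:.6f}\t{m['ACC']:.6f}\t{m['MCC']:.6f}\n"
            )
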