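"""Sparse partial least squares with iteratively adaptive penalties.

The engine fits univariate-response (class-coded y in {-1, +1}) PLS
models whose per-component weight vectors are sparsified by adaptive
soft-thresholding: each variable i carries a penalty weight
``omega_i = 1 / |beta_i|`` derived from ridge-regression importance
estimates, and the weights are re-derived from the fitted coefficients
until the selected support stabilizes.

All fitting happens on column-standardized predictors; predictions
standardize new rows with the *training* means and scales.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DataError, NumericalError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: floor applied to |beta| before inversion, keeping penalties finite
OMEGA_EPSILON = 1e-12


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizedDesign:
    """A column-standardized predictor matrix plus its transform metadata.

    Retained columns have mean 0 and standard deviation 1; columns with
    zero variance are recorded in ``dropped_columns`` and zeroed in
    ``X`` (they keep their index so that downstream weight vectors stay
    aligned with the raw columns).
    """

    X: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    dropped_columns: np.ndarray  # sorted integer indices

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def kept_mask(self) -> np.ndarray:
        mask = np.ones(self.n_features, dtype=bool)
        mask[self.dropped_columns] = False
        return mask

    def transform(self, X_raw: np.ndarray) -> np.ndarray:
        """Standardize new rows with the stored means and scales."""
        X_raw = np.asarray(X_raw, dtype=float)
        if X_raw.ndim != 2 or X_raw.shape[1] != self.n_features:
            raise DataError(
                f"expected {self.n_features} columns, got "
                f"{X_raw.shape[1] if X_raw.ndim == 2 else 'non-matrix'}"
            )
        sds = np.where(self.kept_mask, self.column_sds, 1.0)
        out = (X_raw - self.column_means) / sds
        out[:, ~self.kept_mask] = 0.0
        return out

    def inverse_transform(self, X_std: np.ndarray) -> np.ndarray:
        """Map standardized rows back to the raw scale (dropped columns
        are restored to their constant training value)."""
        sds = np.where(self.kept_mask, self.column_sds, 0.0)
        return X_std * sds + self.column_means


def standardize_columns(X: np.ndarray, sd_tol: float = 1e-12) -> StandardizedDesign:
    """Center and scale columns; record zero-variance columns as dropped."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError("design must be a 2-D matrix")
    if X.shape[0] < 2:
        raise DataError("standardization requires at least 2 rows")
    if not np.isfinite(X).all():
        raise DataError("design contains non-finite entries")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    dropped = np.flatnonzero(sds <= sd_tol)
    safe_sds = sds.copy()
    safe_sds[dropped] = 1.0
    Xs = (X - means) / safe_sds
    Xs[:, dropped] = 0.0
    return StandardizedDesign(
        X=Xs, column_means=means, column_sds=sds, dropped_columns=dropped
    )


def validate_response(y: np.ndarray) -> np.ndarray:
    """Check a class-coded response vector (entries in {-1, +1})."""
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise DataError("response entries must be -1 or +1")
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present for fitting")
    return y


# ---------------------------------------------------------------------------
# ridge importance and soft thresholding
# ---------------------------------------------------------------------------

def ridge_coefficients(
    design: StandardizedDesign, y: np.ndarray, alpha: float = 1.0
) -> np.ndarray:
    """Solve ``(X'X + alpha I) beta = X'y`` on retained columns.

    Dropped (zero-variance) columns get coefficient zero.
    """
    if alpha <= 0:
        raise DataError(f"ridge alpha must be positive, got {alpha}")
    y = np.asarray(y, dtype=float).ravel()
    if not np.isfinite(y).all():
        raise DataError("response contains non-finite entries")
    keep = design.kept_mask
    Xk = design.X[:, keep]
    G = Xk.T @ Xk + alpha * np.eye(Xk.shape[1])
    beta_k = np.linalg.solve(G, Xk.T @ y)
    beta = np.zeros(design.n_features)
    beta[keep] = beta_k
    return beta


@dataclass
class SparseDirection:
    """A penalized weight vector for one latent component.

    ``raw`` is the soft-thresholded vector before normalization; ``u``
    is its unit-norm version, or all-zero when every entry was
    thresholded away (``is_zero``).
    """

    u: np.ndarray
    raw: np.ndarray
    lambda1: float
    omega: np.ndarray
    support: np.ndarray  # sorted indices of nonzero raw entries

    @property
    def is_zero(self) -> bool:
        return self.support.size == 0


def sparse_weight_vector(
    m: np.ndarray, lambda1: float, omega: np.ndarray
) -> SparseDirection:
    """Adaptive soft-thresholding of the cross-covariance vector *m*.

    Returns the elementwise minimizer of
    ``||m - u||^2 + 2 * lambda1 * sum_i omega_i * |u_i|``:
    ``raw_i = sign(m_i) * max(|m_i| - lambda1 * omega_i, 0)``,
    normalized to unit length when any entry survives.
    """
    m = np.asarray(m, dtype=float).ravel()
    omega = np.asarray(omega, dtype=float).ravel()
    if omega.shape != m.shape:
        raise DataError("omega must have the same length as m")
    if np.any(omega <= 0):
        raise DataError("omega entries must be positive")
    if lambda1 < 0:
        raise DataError("lambda1 must be nonnegative")
    raw = np.sign(m) * np.maximum(np.abs(m) - lambda1 * omega, 0.0)
    support = np.flatnonzero(raw)
    norm = np.linalg.norm(raw)
    u = raw / norm if norm > 0 else np.zeros_like(raw)
    return SparseDirection(u=u, raw=raw, lambda1=float(lambda1), omega=omega, support=support)


# ---------------------------------------------------------------------------
# fitted model
# ---------------------------------------------------------------------------

@dataclass
class IasplsModel:
    """A fitted sparse-PLS classifier on the standardized scale."""

    n_components: int
    weight_vectors: np.ndarray  # p x A
    loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    coefficients: np.ndarray  # p, standardized scale
    intercept: float
    omega_final: np.ndarray
    hyperparams: dict
    iterations_run: int
    standardization: StandardizedDesign

    @property
    def support(self) -> np.ndarray:
        """Indices with nonzero regression coefficients."""
        return np.flatnonzero(self.coefficients)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "n_components": int(self.n_components),
            "weight_vectors": self.weight_vectors.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "omega_final": self.omega_final.tolist(),
            "hyperparams": self.hyperparams,
            "iterations_run": int(self.iterations_run),
            "standardization": {
                "column_means": self.standardization.column_means.tolist(),
                "column_sds": self.standardization.column_sds.tolist(),
                "dropped_columns": self.standardization.dropped_columns.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "IasplsModel":
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise DataError(
                f"unsupported model schema version: {payload.get('schema_version')!r}"
            )
        std = payload["standardization"]
        means = np.asarray(std["column_means"], dtype=float)
        design = StandardizedDesign(
            X=np.zeros((0, len(means))),
            column_means=means,
            column_sds=np.asarray(std["column_sds"], dtype=float),
            dropped_columns=np.asarray(std["dropped_columns"], dtype=int),
        )
        return cls(
            n_components=int(payload["n_components"]),
            weight_vectors=np.asarray(payload["weight_vectors"], dtype=float),
            loadings=np.asarray(payload["loadings"], dtype=float),
            y_loadings=np.asarray(payload["y_loadings"], dtype=float),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            intercept=float(payload["intercept"]),
            omega_final=np.asarray(payload["omega_final"], dtype=float),
            hyperparams=dict(payload["hyperparams"]),
            iterations_run=int(payload["iterations_run"]),
            standardization=design,
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str | Path) -> "IasplsModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _component_lambda(
    m: np.ndarray, omega: np.ndarray, lambda1: float | None, sparsity: float | None
) -> float:
    """Resolve the per-component threshold from either an absolute
    lambda or a sparsity fraction eta (lambda = eta * max |m_i|/omega_i,
    which keeps the support nonempty for eta < 1)."""
    if lambda1 is not None and sparsity is not None:
        raise DataError("give either lambda1 or sparsity, not both")
    if lambda1 is not None:
        return float(lambda1)
    if sparsity is None:
        return 0.0
    if not 0.0 <= sparsity < 1.0:
        raise DataError(f"sparsity must be in [0, 1), got {sparsity}")
    peak = np.max(np.abs(m) / omega)
    return float(sparsity * peak)


def fit_sparse_pls(
    design: StandardizedDesign,
    y: np.ndarray,
    n_components: int,
    lambda1: float | None = None,
    sparsity: float | None = None,
    omega: np.ndarray | None = None,
    _hyperparams: dict | None = None,
    _iterations_run: int = 1,
) -> IasplsModel:
    """One sparse-PLS pass with fixed penalty weights.

    Components are extracted sequentially: the cross-covariance
    ``m = X_a' y_c`` is soft-thresholded into a unit direction u, the
    score ``t = X_a u`` produces X- and y-loadings, and X is deflated by
    its rank-one reconstruction. Coefficients are rebuilt as
    ``B = W (P'W)^{-1} C`` with intercept ``mean(y)`` (X is centered).
    Extraction stops early if a direction is entirely thresholded away.
    """
    y = validate_response(y)
    if y.shape[0] != design.n_samples:
        raise DataError("response length does not match design rows")
    p = design.n_features
    max_rank = min(design.n_samples - 1, p)
    if not 1 <= n_components <= max_rank:
        raise DataError(
            f"n_components must be in [1, {max_rank}], got {n_components}"
        )
    if omega is None:
        omega = np.ones(p)
    omega = np.asarray(omega, dtype=float).ravel()

    y_mean = float(y.mean())
    y_c = y - y_mean
    Xa = design.X.copy()

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros(n_components)
    extracted = 0
    for a in range(n_components):
        m = Xa.T @ y_c
        lam = _component_lambda(m, omega, lambda1, sparsity)
        direction = sparse_weight_vector(m, lam, omega)
        if direction.is_zero:
            if a == 0:
                raise NumericalError(
                    "first weight vector entirely thresholded away; "
                    "decrease lambda1 / the sparsity fraction"
                )
            logger.info("component %d all-zero; stopping at %d components", a + 1, a)
            break
        t = Xa @ direction.u
        tt = float(t @ t)
        if tt <= 1e-300:
            logger.info("degenerate score at component %d; stopping", a + 1)
            break
        W[:, a] = direction.u
        P[:, a] = Xa.T @ t / tt
        C[a] = float(y_c @ t) / tt
        Xa = Xa - np.outer(t, P[:, a])
        extracted += 1

    W, P, C = W[:, :extracted], P[:, :extracted], C[:extracted]
    # B = W (P'W)^{-1} C  on the standardized scale
    coef = W @ np.linalg.solve(P.T @ W, C)
    hyper = dict(_hyperparams or {})
    hyper.setdefault("lambda1", lambda1)
    hyper.setdefault("sparsity", sparsity)
    hyper.setdefault("n_components", int(n_components))
    return IasplsModel(
        n_components=extracted,
        weight_vectors=W,
        loadings=P,
        y_loadings=C,
        coefficients=coef,
        intercept=y_mean,
        omega_final=omega,
        hyperparams=hyper,
        iterations_run=_iterations_run,
        standardization=design,
    )


def fit_iaspls(
    design: StandardizedDesign,
    y: np.ndarray,
    n_components: int = 3,
    sparsity: float = 0.5,
    ridge_alpha: float = 1.0,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> IasplsModel:
    """Iteratively adaptive sparse PLS.

    Penalty weights start from ridge-regression importances,
    ``omega_i = 1 / max(|beta_i|, eps)``, and are re-derived from the
    sparse-PLS coefficients of each pass. Iteration stops when the
    relative coefficient change falls below *tol*, when the selected
    support is unchanged between passes, or after *max_iter* passes
    (non-convergence is logged, not raised).
    """
    y = validate_response(y)
    if max_iter < 1:
        raise DataError("max_iter must be at least 1")
    hyper = {
        "sparsity": sparsity,
        "n_components": int(n_components),
        "ridge_alpha": ridge_alpha,
        "max_iter": int(max_iter),
        "tol": tol,
    }
    beta = ridge_coefficients(design, y, ridge_alpha)
    model: IasplsModel | None = None
    prev_support: tuple[int, ...] | None = None
    iterations = 0
    for iterations in range(1, max_iter + 1):
        omega = 1.0 / np.maximum(np.abs(beta), OMEGA_EPSILON)
        model = fit_sparse_pls(
            design,
            y,
            n_components=n_components,
            sparsity=sparsity,
            omega=omega,
            _hyperparams=hyper,
            _iterations_run=iterations,
        )
        new_beta = model.coefficients
        denom = np.linalg.norm(beta)
        delta = np.linalg.norm(new_beta - beta) / denom if denom > 0 else np.inf
        support = tuple(model.support.tolist())
        beta = new_beta
        if delta < tol:
            break
        if prev_support is not None and support == prev_support:
            break
        prev_support = support
    else:  # pragma: no cover - loop always breaks or exhausts
        pass
    if iterations == max_iter:
        logger.warning("reached max_iter=%d without convergence", max_iter)
    assert model is not None
    model.iterations_run = iterations
    return model


def predict_scores(
    model: IasplsModel, X_new: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Decision scores and hard labels for raw (unstandardized) rows.

    Rows are standardized with the training means and scales; the score
    is ``x_std . B + intercept`` and the label is +1 when the score is
    >= 0 (ties go to the positive class), else -1.
    """
    X_std = model.standardization.transform(np.asarray(X_new, dtype=float))
    scores = X_std @ model.coefficients + model.intercept
    labels = np.where(scores >= 0.0, 1, -1)
    return scores, labels


# ---------------------------------------------------------------------------
# hyperparameter selection
# ---------------------------------------------------------------------------

DEFAULT_SPARSITY_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1))
DEFAULT_COMPONENT_GRID: tuple[int, ...] = tuple(range(1, 11))


def select_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    sparsity_grid: Sequence[float] = DEFAULT_SPARSITY_GRID,
    component_grid: Sequence[int] = DEFAULT_COMPONENT_GRID,
    n_folds: int = 3,
    ridge_alpha: float = 1.0,
    max_iter: int = 5,
    seed: int = 0,
) -> tuple[float, int]:
    """Pick (sparsity, n_components) by stratified cross-validated accuracy.

    Ties favor the sparser, then smaller model. Operates on raw X; each
    training split is standardized independently.
    """
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = validate_response(y)
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    best: tuple[float, float, int] | None = None  # (-acc, sparsity, A)
    for eta in sparsity_grid:
        for A in component_grid:
            if A > min(len(y) - len(y) // n_folds - 1, X.shape[1]):
                continue
            correct = 0
            total = 0
            try:
                for train_idx, test_idx in splitter.split(X, y):
                    design = standardize_columns(X[train_idx])
                    model = fit_iaspls(
                        design,
                        y[train_idx],
                        n_components=A,
                        sparsity=eta,
                        ridge_alpha=ridge_alpha,
                        max_iter=max_iter,
                    )
                    _, labels = predict_scores(model, X[test_idx])
                    correct += int((labels == y[test_idx]).sum())
                    total += len(test_idx)
            except (DataError, NumericalError):
                continue
            acc = correct / total
            key = (-acc, -eta, A)
            if best is None or key < best[0]:
                best = (key, eta, A)
    if best is None:
        raise NumericalError("no hyperparameter combination could be fitted")
    return float(best[1]), int(best[2])
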