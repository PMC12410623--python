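"""Maximum-likelihood logistic regression by iteratively reweighted least squares.

A small, fast Newton solver used by every fitting path in the package
(development, backward elimination, bootstrap replay, recalibration fits).
Standard errors come from the inverse observed information at the optimum.
Complete separation and exact collinearity are detected and raised as typed
errors rather than returned as silently enormous coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit


class SeparationError(RuntimeError):
    """The likelihood is unbounded: some linear combination separates the classes."""


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"design columns are collinear; aliased: {aliased}")


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration limit."""


@dataclass
class LogitResult:
    """Coefficients (log-odds), observed-information SEs and the log-likelihood."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    llf: float
    n: int
    events: int
    n_iter: int
    cov: np.ndarray = field(repr=False, default=None)

    def coef_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.coef)))


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # pivoted-QR style detection: add columns one at a time, flag those that
    # do not increase the rank
    if X.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    aliased: list[str] = []
    kept = np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            aliased.append(name)
    raise CollinearityError(aliased)


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    offset: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    check_separation: bool = True,
) -> LogitResult:
    """Fit P(y=1) = expit(offset + X @ beta) by Newton/IRLS.

    Parameters
    ----------
    X : (n, k) design matrix, including any intercept column.
    y : (n,) 0/1 outcome indicators.
    names : column names for error messages and reporting.
    offset : fixed additive term on the log-odds scale (e.g. a frozen linear
        predictor when re-estimating only an intercept).
    tol : relative log-likelihood change declaring convergence.

    Raises
    ------
    SeparationError, CollinearityError, ConvergenceError
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    events = int(y.sum())
    if events == 0 or events == n:
        raise ValueError("outcome has a single class; need at least one event and one non-event")
    _check_rank(X, list(names))
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    beta = np.zeros(k)
    eta = off + X @ beta
    llf = _loglik(y, eta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p = expit(eta)
        w = p * (1.0 - p)
        # guard against zero weights at extreme fitted probabilities
        w = np.clip(w, 1e-12, None)
        grad = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rank checked above
            raise SeparationError(f"singular information matrix: {exc}") from exc
        # step-halving to keep the likelihood non-decreasing
        new_beta, new_eta, new_llf = beta + step, None, -np.inf
        for _ in range(30):
            new_eta = off + X @ new_beta
            new_llf = _loglik(y, new_eta)
            if new_llf >= llf - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        rel = abs(new_llf - llf) / (abs(llf) + 1e-10)
        beta, eta, llf = new_beta, new_eta, new_llf
        if check_separation and np.max(np.abs(beta)) > 25.0:
            p = expit(eta)
            fitted_extreme = np.all(p[y == 1] > 1 - 1e-6) and np.all(p[y == 0] < 1e-6)
            if fitted_extreme:
                raise SeparationError(
                    "complete separation detected: fitted probabilities are all 0/1 "
                    f"and |coefficients| reach {np.max(np.abs(beta)):.1f}"
                )
        if rel < tol:
            break
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
    p = expit(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    return LogitResult(list(names), beta, se, float(llf), n, events, n_iter, cov)


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
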