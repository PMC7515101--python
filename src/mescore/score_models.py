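"""Score functions, log-likelihoods and support-construction rules.

Four families are covered: normal mean with known variance, Poisson rate,
gamma shape/rate, and binary logistic regression.  Each family exposes plain
score/log-likelihood functions plus a `ScoreModel` bundle consumed by the
entropy solver; `build_support` encodes the data-driven rules used to pick
the discrete parameter supports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import digamma, expit, gammaln, xlogy

from .me_core import DimensionError, SupportGrid, WeightMatrix

__all__ = [
    "ScoreModel",
    "LogisticDesign",
    "normal_score",
    "normal_loglik",
    "poisson_score",
    "poisson_loglik",
    "gamma_score",
    "gamma_loglik",
    "logistic_score",
    "logistic_loglik",
    "logistic_score_jac",
    "logistic_me_parameterization",
    "build_support",
    "normal_model",
    "poisson_model",
    "gamma_model",
    "logistic_model",
]


@dataclass(frozen=True)
class ScoreModel:
    """Contract between a likelihood model and the entropy solver.

    ``score(theta, data)`` must be the gradient of ``loglik(theta, data)``;
    ``score_jac`` (optional) returns the J x J Jacobian dU/dtheta and speeds
    up the solver; ``natural_range`` declares per-parameter admissible
    intervals which the supports must respect.
    """

    name: str
    dimension: int
    score: Callable
    loglik: Callable
    natural_range: tuple[tuple[float, float], ...]
    default_support_rule: Callable
    score_jac: Callable | None = None


@dataclass(frozen=True)
class LogisticDesign:
    """Design matrix (leading intercept column) and 0/1 responses."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.shape[0] != y.size:
            raise DimensionError(
                f"design has {X.shape[0]} rows but response has {y.size}"
            )
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("responses must be 0/1")
        if not np.allclose(X[:, 0], 1.0):
            raise ValueError("first design column must be the intercept (all ones)")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn("design matrix is column-rank deficient", stacklevel=2)
        if X.shape[0] <= X.shape[1]:
            warnings.warn("fewer observations than parameters", stacklevel=2)

    @classmethod
    def from_predictors(cls, predictors: np.ndarray, y: np.ndarray) -> "LogisticDesign":
        predictors = np.atleast_2d(np.asarray(predictors, dtype=float))
        if predictors.shape[0] == 1 and np.asarray(y).size > 1:
            predictors = predictors.T
        return cls(np.column_stack([np.ones(predictors.shape[0]), predictors]), y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# normal mean, known variance
# ---------------------------------------------------------------------------


def normal_loglik(mu: float, y: np.ndarray, sigma2: float = 1.0) -> float:
    y = _as_sample(y)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return float(-0.5 * np.sum((y - mu) ** 2) / sigma2)


def normal_score(mu: float, y: np.ndarray, sigma2: float = 1.0) -> np.ndarray:
    """U(mu) = (sum(y) - n*mu) / sigma2; vanishes at the sample mean."""
    y = _as_sample(y)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return np.array([(y.sum() - y.size * np.asarray(mu).item()) / sigma2])


# ---------------------------------------------------------------------------
# Poisson rate
# ---------------------------------------------------------------------------


def poisson_loglik(lam: float, y: np.ndarray) -> float:
    y = _as_sample(y)
    lam = float(np.asarray(lam).item())
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return float(xlogy(y, lam).sum() - y.size * lam - gammaln(y + 1).sum())


def poisson_score(lam: float, y: np.ndarray) -> np.ndarray:
    """U(lambda) = -n + sum(y)/lambda; vanishes at the sample mean."""
    y = _as_sample(y)
    lam = float(np.asarray(lam).item())
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return np.array([-float(y.size) + y.sum() / lam])


# ---------------------------------------------------------------------------
# gamma shape alpha, rate rho
# ---------------------------------------------------------------------------


def gamma_loglik(alpha: float, rho: float, y: np.ndarray) -> float:
    y = _as_sample(y)
    if alpha <= 0 or rho <= 0 or np.any(y <= 0):
        raise ValueError("alpha, rho and all observations must be positive")
    n = y.size
    return float(
        (alpha - 1.0) * np.log(y).sum()
        - rho * y.sum()
        + n * alpha * np.log(rho)
        - n * gammaln(alpha)
    )


def gamma_score(alpha: float, rho: float, y: np.ndarray) -> np.ndarray:
    """Gradient of the gamma log-likelihood, ordered (d/dalpha, d/drho).

    Both components vanish at the maximum-likelihood estimate::

        d l / d alpha = sum(log y) + n log(rho) - n psi(alpha)
        d l / d rho   = -sum(y) + n alpha / rho
    """
    y = _as_sample(y)
    if alpha <= 0 or rho <= 0 or np.any(y <= 0):
        raise ValueError("alpha, rho and all observations must be positive")
    n = y.size
    return np.array(
        [
            np.log(y).sum() + n * np.log(rho) - n * digamma(alpha),
            -y.sum() + n * alpha / rho,
        ]
    )


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


def logistic_loglik(beta: np.ndarray, design: LogisticDesign) -> float:
    eta = design.X @ _check_beta(beta, design)
    # log(1 + exp(eta)) computed stably
    return float(design.y @ eta - np.logaddexp(0.0, eta).sum())


def logistic_score(beta: np.ndarray, design: LogisticDesign) -> np.ndarray:
    """U(beta) = X' (y - pi(beta)) with pi the logistic mean."""
    beta = _check_beta(beta, design)
    pi = expit(design.X @ beta)
    return design.X.T @ (design.y - pi)


def logistic_score_jac(beta: np.ndarray, design: LogisticDesign) -> np.ndarray:
    """dU/dbeta = -X' W X with W = diag(pi (1 - pi))."""
    beta = _check_beta(beta, design)
    pi = expit(design.X @ beta)
    w = pi * (1.0 - pi)
    return -design.X.T @ (design.X * w[:, None])


def logistic_me_parameterization(P, z: np.ndarray) -> np.ndarray:
    """Coefficients from a weight matrix on a shared support, beta_j = z @ P_j.

    Semantic form of the Kronecker-product reparameterization of the logistic
    coefficients: every coefficient is the expectation of the common grid ``z``
    under its own weight row.  Agrees with `reparameterize` on a grid shared
    across parameters.
    """
    if isinstance(P, WeightMatrix):
        P = P.as_matrix()
    P = np.atleast_2d(np.asarray(P, dtype=float))
    z = np.asarray(z, dtype=float)
    if P.shape[1] != z.size:
        raise DimensionError(
            f"weight matrix has {P.shape[1]} columns but support has {z.size} points"
        )
    return P @ z


# ---------------------------------------------------------------------------
# support construction
# ---------------------------------------------------------------------------


def build_support(
    model_kind: str,
    data,
    K: int,
    *,
    delta: float = 3.0,
    bound: float = 10.0,
    bounds_override: list[tuple[float, float]] | None = None,
) -> SupportGrid:
    """Equally spaced supports following the per-family range rules.

    normal:   [min y, max y] (widened to +-1 around a constant sample);
    poisson:  [0, max y];
    gamma:    [0, alpha_up + delta] and [0, rho_up + delta], where
              alpha_up = 1/(2M), rho_up = alpha_up/mean(y),
              M = log(mean(y)) - mean(log y)  (moment-style upper guesses);
    logistic: common symmetric grid [-bound, bound] for every coefficient,
              data interpreted as a `LogisticDesign`.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if bounds_override is not None:
        return SupportGrid(
            tuple(np.linspace(lo, hi, K) for lo, hi in bounds_override)
        )

    if model_kind == "normal":
        y = _as_sample(data)
        lo, hi = float(y.min()), float(y.max())
        if hi - lo < 1e-12:  # constant sample: widen around the single value
            lo, hi = lo - 1.0, hi + 1.0
        return SupportGrid((np.linspace(lo, hi, K),), ("mu",))

    if model_kind == "poisson":
        y = _as_sample(data)
        if np.any(y < 0):
            raise ValueError("Poisson sample must be nonnegative")
        return SupportGrid((np.linspace(0.0, float(y.max()), K),), ("lambda",))

    if model_kind == "gamma":
        y = _as_sample(data)
        if np.any(y <= 0):
            raise ValueError("gamma sample must be strictly positive")
        ybar = float(y.mean())
        M = float(np.log(ybar) - np.log(y).mean())
        alpha_up = 1.0 / (2.0 * M)
        rho_up = alpha_up / ybar
        return SupportGrid(
            (
                np.linspace(0.0, alpha_up + delta, K),
                np.linspace(0.0, rho_up + delta, K),
            ),
            ("alpha", "rho"),
        )

    if model_kind == "logistic":
        if isinstance(data, LogisticDesign):
            J = data.n_params
        else:
            J = int(data)
        z = np.linspace(-bound, bound, K)
        return SupportGrid(
            tuple(z.copy() for _ in range(J)),
            ("beta0",) + tuple(f"beta{j}" for j in range(1, J)),
        )

    raise ValueError(f"unknown model kind {model_kind!r}")


def gamma_support_bounds(y: np.ndarray) -> tuple[float, float]:
    """Upper support guesses (alpha_up, rho_up) used by the gamma rule."""
    y = _as_sample(y)
    ybar = float(y.mean())
    M = float(np.log(ybar) - np.log(y).mean())
    a = 1.0 / (2.0 * M)
    return a, a / ybar


# ---------------------------------------------------------------------------
# model bundles
# ---------------------------------------------------------------------------

_UNBOUNDED = (-np.inf, np.inf)
_POSITIVE = (0.0, np.inf)
_TINY = 1e-10  # keeps solver line searches off the open boundary


def normal_model(sigma2: float = 1.0) -> ScoreModel:
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return ScoreModel(
        name="normal",
        dimension=1,
        score=lambda theta, y: normal_score(theta[0], y, sigma2),
        loglik=lambda theta, y: normal_loglik(theta[0], y, sigma2),
        natural_range=(_UNBOUNDED,),
        default_support_rule=lambda y, K, **kw: build_support("normal", y, K, **kw),
        score_jac=lambda theta, y: np.array([[-_as_sample(y).size / sigma2]]),
    )


def poisson_model() -> ScoreModel:
    return ScoreModel(
        name="poisson",
        dimension=1,
        score=lambda theta, y: poisson_score(max(theta[0], _TINY), y),
        loglik=lambda theta, y: poisson_loglik(max(theta[0], _TINY), y),
        natural_range=(_POSITIVE,),
        default_support_rule=lambda y, K, **kw: build_support("poisson", y, K, **kw),
        score_jac=lambda theta, y: np.array(
            [[-_as_sample(y).sum() / max(theta[0], _TINY) ** 2]]
        ),
    )


def gamma_model() -> ScoreModel:
    def _jac(theta, y):
        a, r = max(theta[0], _TINY), max(theta[1], _TINY)
        n = _as_sample(y).size
        from scipy.special import polygamma

        return np.array(
            [[-n * float(polygamma(1, a)), n / r], [n / r, -n * a / r**2]]
        )

    return ScoreModel(
        name="gamma",
        dimension=2,
        score=lambda theta, y: gamma_score(
            max(theta[0], _TINY), max(theta[1], _TINY), y
        ),
        loglik=lambda theta, y: gamma_loglik(
            max(theta[0], _TINY), max(theta[1], _TINY), y
        ),
        natural_range=(_POSITIVE, _POSITIVE),
        default_support_rule=lambda y, K, **kw: build_support("gamma", y, K, **kw),
        score_jac=_jac,
    )


def logistic_model(n_params: int) -> ScoreModel:
    return ScoreModel(
        name="logistic",
        dimension=n_params,
        score=lambda theta, design: logistic_score(theta, design),
        loglik=lambda theta, design: logistic_loglik(theta, design),
        natural_range=tuple(_UNBOUNDED for _ in range(n_params)),
        default_support_rule=lambda design, K, **kw: build_support(
            "logistic", design, K, **kw
        ),
        score_jac=lambda theta, design: logistic_score_jac(theta, design),
    )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _as_sample(y) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty sample")
    return y


def _check_beta(beta: np.ndarray, design: LogisticDesign) -> np.ndarray:
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.size != design.n_params:
        raise DimensionError(
            f"beta has {beta.size} entries but design has {design.n_params} columns"
        )
    return beta
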