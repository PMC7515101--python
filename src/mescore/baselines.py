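"""Reference logistic estimators and separation diagnostics.

Provides the two comparison fitters used alongside the entropy solver —
plain Newton–Raphson (iteratively reweighted least squares) and Firth's
bias-corrected scoring, whose Jeffreys-prior penalty keeps estimates finite
under separation — plus a linear-programming test for complete or quasi
separation of binary data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.special import expit

from .score_models import LogisticDesign, logistic_loglik

__all__ = [
    "GlmFit",
    "SeparationStatus",
    "fit_logistic_nr",
    "fit_logistic_firth",
    "detect_separation",
]

_DIVERGENCE_THRESHOLD = 1e3
_WEIGHT_FLOOR = 1e-10


@dataclass(frozen=True)
class GlmFit:
    beta_hat: np.ndarray
    converged: bool
    iterations: int
    max_abs_score: float
    diverging: bool
    message: str = ""


@dataclass(frozen=True)
class SeparationStatus:
    """Outcome of the separation test.

    ``status`` is 'none', 'quasi' or 'complete'; when separation is present
    ``certificate`` holds a direction d with d @ x_i >= 0 for every y_i = 1
    and <= 0 for every y_i = 0 (all strict for 'complete').
    """

    status: str
    certificate: np.ndarray | None = None

    @property
    def separated(self) -> bool:
        return self.status != "none"


def fit_logistic_nr(
    design: LogisticDesign,
    tol: float = 1e-8,
    max_iterations: int = 50,
    divergence_threshold: float = _DIVERGENCE_THRESHOLD,
) -> GlmFit:
    """Logistic maximum likelihood by iteratively reweighted least squares.

    Stops when the score norm drops below ``tol``; sets ``diverging`` when a
    coefficient exceeds ``divergence_threshold`` in magnitude or the working
    weights collapse (both symptoms of infinite maximum-likelihood estimates).
    A singular working-information matrix yields ``converged=False`` with a
    reason, never an exception.
    """
    X, y = design.X, design.y
    beta = np.zeros(design.n_params)
    max_u = np.inf
    for it in range(1, max_iterations + 1):
        pi = expit(X @ beta)
        u = X.T @ (y - pi)
        max_u = float(np.max(np.abs(u)))
        if max_u < tol:
            return GlmFit(beta, True, it - 1, max_u, _diverging(beta, pi, divergence_threshold))
        w = np.clip(pi * (1.0 - pi), _WEIGHT_FLOOR, None)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, u)
        except np.linalg.LinAlgError:
            return GlmFit(
                beta, False, it, max_u, True, "singular working-information matrix"
            )
        beta = beta + step
    pi = expit(X @ beta)
    max_u = float(np.max(np.abs(X.T @ (y - pi))))
    return GlmFit(
        beta,
        max_u < tol,
        max_iterations,
        max_u,
        _diverging(beta, pi, divergence_threshold),
        "" if max_u < tol else "score tolerance not reached",
    )


_WEIGHT_COLLAPSE = 1e-6  # max_i pi(1-pi) below this: no curvature left anywhere


def _diverging(beta: np.ndarray, pi: np.ndarray, threshold: float) -> bool:
    w = pi * (1.0 - pi)
    return bool(np.any(np.abs(beta) > threshold) or np.max(w) < _WEIGHT_COLLAPSE)


def fit_logistic_firth(
    design: LogisticDesign,
    tol: float = 1e-8,
    max_iterations: int = 200,
) -> GlmFit:
    """Firth's bias-corrected logistic fit via modified-score iterations.

    Solves U*(beta) = X'(y - pi + h (1/2 - pi)) = 0 with h the hat-matrix
    diagonal of the working weighted least squares — the stationarity
    condition of the Jeffreys-penalized log-likelihood l(beta) +
    log det I(beta) / 2, whose maximiser is finite even under complete
    separation.  Newton steps are halved until the penalized likelihood does
    not decrease.
    """
    X, y = design.X, design.y
    beta = np.zeros(design.n_params)

    def penalized(b: np.ndarray) -> float:
        pi = expit(X @ b)
        w = np.clip(pi * (1.0 - pi), _WEIGHT_FLOOR, None)
        sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
        if sign <= 0:
            return -np.inf
        return logistic_loglik(b, design) + 0.5 * logdet

    def modified_score(b: np.ndarray):
        pi = expit(X @ b)
        w = np.clip(pi * (1.0 - pi), _WEIGHT_FLOOR, None)
        info = X.T @ (X * w[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return None, None
        xw = X * np.sqrt(w)[:, None]
        h = np.einsum("ij,jk,ik->i", xw, info_inv, xw)
        u_star = X.T @ (y - pi + h * (0.5 - pi))
        return u_star, info_inv

    obj = penalized(beta)
    max_u = np.inf
    for it in range(1, max_iterations + 1):
        u_star, info_inv = modified_score(beta)
        if u_star is None:
            return GlmFit(beta, False, it, max_u, True, "singular information matrix")
        max_u = float(np.max(np.abs(u_star)))
        if max_u < tol:
            return GlmFit(beta, True, it - 1, max_u, False)
        step = info_inv @ u_star
        # step halving keeps the penalized likelihood non-decreasing
        for _ in range(20):
            cand = beta + step
            cand_obj = penalized(cand)
            if cand_obj >= obj - 1e-12:
                break
            step = step / 2.0
        beta, obj = cand, cand_obj
    u_star, _ = modified_score(beta)
    max_u = float(np.max(np.abs(u_star))) if u_star is not None else np.inf
    return GlmFit(
        beta,
        max_u < tol,
        max_iterations,
        max_u,
        bool(np.any(np.abs(beta) > _DIVERGENCE_THRESHOLD)),
        "" if max_u < tol else "modified-score tolerance not reached",
    )


def detect_separation(design: LogisticDesign, tol: float = 1e-9) -> SeparationStatus:
    """Linear-programming test for separation of a binary design.

    Searches for a direction d with (2 y_i - 1) x_i' d >= 0 for all i,
    maximising the total slack with d box-bounded in [-1, 1].  A zero optimum
    means only the trivial direction exists (no separation); a positive
    optimum with every slack strict certifies complete separation, otherwise
    quasi separation (some observations sit exactly on the separating
    hyperplane, the hallmark of infinite but partially identified maximum
    likelihood estimates).
    """
    X, y = design.X, design.y
    signed = (2.0 * y - 1.0)[:, None] * X  # rows: s_i x_i'
    J = design.n_params

    # complete separation: maximise the minimum slack t over box-bounded d
    c = np.zeros(J + 1)
    c[-1] = -1.0
    res = linprog(
        c,
        A_ub=np.column_stack([-signed, np.ones(design.n)]),  # t - s_i x_i'd <= 0
        b_ub=np.zeros(design.n),
        bounds=[(-1.0, 1.0)] * J + [(None, 1.0)],
        method="highs",
    )
    if res.status == 0 and -res.fun > tol:
        return SeparationStatus("complete", certificate=res.x[:J])

    # quasi separation: any nonzero direction with nonnegative slack everywhere
    res = linprog(
        -signed.sum(axis=0),  # maximise total slack
        A_ub=-signed,
        b_ub=np.zeros(design.n),
        bounds=[(-1.0, 1.0)] * J,
        method="highs",
    )
    if res.status == 0 and float((signed @ res.x).sum()) > tol:
        return SeparationStatus("quasi", certificate=res.x)
    return SeparationStatus("none")
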