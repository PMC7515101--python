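"""Maximum-entropy solution of likelihood score equations.

A model parameter vector ``theta`` (length J) is rewritten as a tuple of
expectations of discrete distributions: for each parameter j the user fixes a
finite grid of admissible values ``z_j`` (the *support*) and the parameter
becomes ``theta_j = z_j @ p_j`` with ``p_j`` an unknown probability vector.
Solving the likelihood equation U(theta) = 0 is then recast as a concave
program on a product of simplices::

    maximize    H(p_1, ..., p_J) = -sum_j p_j @ log(p_j)
    subject to  U(theta(p)) = 0,   p_j @ 1 = 1  for every j

The entropy objective selects, among all weight configurations consistent
with the score constraint, the least informative one; when the score has a
root inside the box spanned by the supports, theta(p_hat) coincides with the
maximum-likelihood estimate.  When no root exists inside the box (e.g.
logistic regression under complete separation) the constraint set is empty
and the solver returns the best-effort violation minimiser, flagged
``feasible=False``.

For a normal mean with known variance the program has a closed Gibbs-form
solution indexed by a single Lagrange multiplier; `solve_me_normal_closed`
recovers it by one-dimensional root finding and serves as an independent
oracle for the general solver.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import xlogy

__all__ = [
    "SupportGrid",
    "WeightMatrix",
    "SolverOptions",
    "MEProblem",
    "MEFit",
    "DiagnosticReport",
    "reparameterize",
    "entropy",
    "solve_me_score",
    "solve_me_normal_closed",
    "check_solution",
]

_ROW_SUM_TOL = 1e-8


class DimensionError(ValueError):
    """Raised when supports, weights, or model dimensions disagree."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SupportGrid:
    """Per-parameter support vectors z_j.

    Each row is a strictly increasing grid of at least two finite points; the
    parameter it represents is confined to ``[z_j[0], z_j[-1]]``.  Grids may
    have different lengths across parameters.
    """

    points_per_param: tuple[np.ndarray, ...]
    param_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        rows = tuple(np.asarray(z, dtype=float) for z in self.points_per_param)
        object.__setattr__(self, "points_per_param", rows)
        names = self.param_names or tuple(f"theta{j}" for j in range(len(rows)))
        if len(names) != len(rows):
            raise DimensionError(
                f"{len(names)} parameter names for {len(rows)} support rows"
            )
        object.__setattr__(self, "param_names", tuple(names))
        for name, z in zip(names, rows):
            if z.ndim != 1 or z.size < 2:
                raise ValueError(
                    f"support for {name!r} needs at least 2 points (a point mass "
                    "leaves nothing to estimate)"
                )
            if not np.all(np.isfinite(z)):
                raise ValueError(f"support for {name!r} contains non-finite points")
            if not np.all(np.diff(z) > 0):
                raise ValueError(f"support for {name!r} must be strictly increasing")

    @property
    def dimension(self) -> int:
        return len(self.points_per_param)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(z.size for z in self.points_per_param)

    def box(self) -> list[tuple[float, float]]:
        """Admissible interval [min z_j, max z_j] per parameter."""
        return [(float(z[0]), float(z[-1])) for z in self.points_per_param]

    def check_brackets(self, ranges: Sequence[tuple[float, float]]) -> None:
        """Verify every grid lies inside the caller-declared admissible range."""
        for name, z, (lo, hi) in zip(self.param_names, self.points_per_param, ranges):
            if z[0] < lo - 1e-12 or z[-1] > hi + 1e-12:
                raise ValueError(
                    f"support for {name!r} spans [{z[0]}, {z[-1]}], outside the "
                    f"admissible range [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class WeightMatrix:
    """Row-wise probability weights, one simplex vector per parameter."""

    rows: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        rows = tuple(np.asarray(p, dtype=float) for p in self.rows)
        object.__setattr__(self, "rows", rows)
        for j, p in enumerate(rows):
            if p.ndim != 1:
                raise DimensionError(f"weight row {j} is not a vector")
            if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
                raise ValueError(f"weight row {j} has entries outside [0, 1]")
            if abs(p.sum() - 1.0) > _ROW_SUM_TOL:
                raise ValueError(
                    f"weight row {j} sums to {p.sum():.10f}, not 1 "
                    f"(tolerance {_ROW_SUM_TOL})"
                )

    @classmethod
    def uniform(cls, sizes: Sequence[int]) -> "WeightMatrix":
        return cls(tuple(np.full(k, 1.0 / k) for k in sizes))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "WeightMatrix":
        m = np.asarray(matrix, dtype=float)
        return cls(tuple(m[j] for j in range(m.shape[0])))

    @property
    def dimension(self) -> int:
        return len(self.rows)

    def as_matrix(self) -> np.ndarray:
        """Stack rows into a J x K matrix; requires a common K."""
        sizes = {p.size for p in self.rows}
        if len(sizes) > 1:
            raise DimensionError("rows have unequal lengths; no matrix form")
        return np.vstack(self.rows)


@dataclass(frozen=True)
class SolverOptions:
    """Tuning knobs of the constrained entropy solver.

    ``constraint_tolerance`` decides feasibility (max |U| at the optimum);
    ``optimality_tolerance`` is the objective stopping tolerance of the inner
    sequential quadratic program; ``probability_floor`` clips weights inside
    logarithms only, reported weights are not floored.  When the equality-
    constrained phase fails to reach feasibility the solver minimises
    ``violation_weight * ||U||^2 / 2 - entropy_tiebreak * H`` instead (the
    entropy term selects a unique interior violation minimiser).
    """

    max_iterations: int = 500
    constraint_tolerance: float = 1e-8
    optimality_tolerance: float = 1e-12
    initial_weights: WeightMatrix | None = None
    probability_floor: float = 1e-12
    violation_weight: float = 1.0
    entropy_tiebreak: float = 1e-3

    def __post_init__(self) -> None:
        if self.constraint_tolerance <= 0 or self.optimality_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.probability_floor < 0.5:
            raise ValueError("probability_floor must lie in (0, 1/K)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["initial_weights"] = (
            None
            if self.initial_weights is None
            else [row.tolist() for row in self.initial_weights.rows]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SolverOptions":
        d = dict(d)
        w = d.get("initial_weights")
        if w is not None:
            d["initial_weights"] = WeightMatrix(tuple(np.asarray(r) for r in w))
        return cls(**d)


@dataclass(frozen=True)
class MEProblem:
    """A score model paired with supports and solver options."""

    model: "ScoreModel"  # noqa: F821 - defined in score_models
    supports: SupportGrid
    options: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if self.supports.dimension != self.model.dimension:
            raise DimensionError(
                f"model has {self.model.dimension} parameters but supports "
                f"declare {self.supports.dimension} rows"
            )
        self.supports.check_brackets(self.model.natural_range)


@dataclass(frozen=True)
class MEFit:
    """Solution bundle of the maximum-entropy score problem."""

    theta_hat: np.ndarray
    weights_hat: WeightMatrix
    entropy_value: float
    score_residual: np.ndarray
    multipliers: dict | None
    converged: bool
    feasible: bool
    iterations: int
    message: str = ""

    @property
    def max_abs_residual(self) -> float:
        return float(np.max(np.abs(self.score_residual)))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def reparameterize(supports: SupportGrid, weights: WeightMatrix) -> np.ndarray:
    """Map weights to parameter values, theta_j = z_j @ p_j."""
    if supports.dimension != weights.dimension:
        raise DimensionError(
            f"{supports.dimension} support rows vs {weights.dimension} weight rows"
        )
    out = np.empty(supports.dimension)
    for j, (name, z, p) in enumerate(
        zip(supports.param_names, supports.points_per_param, weights.rows)
    ):
        if z.size != p.size:
            raise DimensionError(
                f"parameter {name!r}: support has {z.size} points but weights "
                f"have {p.size}"
            )
        out[j] = z @ p
    return out


def entropy(weights: WeightMatrix) -> float:
    """Shannon entropy -sum_j p_j @ log(p_j), with 0*log(0) = 0."""
    return float(-sum(xlogy(p, p).sum() for p in weights.rows))


# ---------------------------------------------------------------------------
# general constrained solver
# ---------------------------------------------------------------------------


def _flatten(weights: WeightMatrix) -> np.ndarray:
    return np.concatenate(weights.rows)


def _split(x: np.ndarray, sizes: Sequence[int]) -> tuple[np.ndarray, ...]:
    return tuple(np.split(x, np.cumsum(sizes)[:-1]))


def solve_me_score(problem: MEProblem, data) -> MEFit:
    """Solve the entropy-maximisation program for an arbitrary score model.

    Phase one runs an equality-constrained sequential quadratic program from
    uniform weights.  If the score constraint cannot be met (no root of U
    inside the support box, e.g. separated logistic data) a second phase
    minimises the squared constraint violation with a small entropy tie-break
    and the fit is flagged ``feasible=False``.  Non-convergence is reported in
    the returned fit, never raised.
    """
    model, supports, opts = problem.model, problem.supports, problem.options
    sizes = supports.sizes
    J = supports.dimension
    nvar = int(sum(sizes))
    floor = opts.probability_floor

    def theta_of(x: np.ndarray) -> np.ndarray:
        return np.array(
            [z @ p for z, p in zip(supports.points_per_param, _split(x, sizes))]
        )

    def score_of(x: np.ndarray) -> np.ndarray:
        return np.asarray(model.score(theta_of(x), data), dtype=float)

    # d theta / d x is block-diagonal with the support vectors on the blocks
    dtheta = np.zeros((J, nvar))
    offset = 0
    for j, z in enumerate(supports.points_per_param):
        dtheta[j, offset : offset + z.size] = z
        offset += z.size

    have_jac = getattr(model, "score_jac", None) is not None

    def score_jac_x(x: np.ndarray) -> np.ndarray:
        return np.asarray(model.score_jac(theta_of(x), data)) @ dtheta

    def neg_entropy(x: np.ndarray) -> float:
        return float(xlogy(x, np.clip(x, floor, None)).sum())

    def neg_entropy_grad(x: np.ndarray) -> np.ndarray:
        return np.log(np.clip(x, floor, None)) + 1.0

    # row-normalization constraints, A x = 1
    A = np.zeros((J, nvar))
    offset = 0
    for j, k in enumerate(sizes):
        A[j, offset : offset + k] = 1.0
        offset += k
    norm_con = {"type": "eq", "fun": lambda x: A @ x - 1.0, "jac": lambda x: A}
    score_con: dict = {"type": "eq", "fun": score_of}
    if have_jac:
        score_con["jac"] = score_jac_x

    x0 = _flatten(
        opts.initial_weights
        if opts.initial_weights is not None
        else WeightMatrix.uniform(sizes)
    )
    bounds = [(0.0, 1.0)] * nvar

    res = minimize(
        neg_entropy,
        x0,
        jac=neg_entropy_grad,
        method="SLSQP",
        bounds=bounds,
        constraints=[norm_con, score_con],
        options={"maxiter": opts.max_iterations, "ftol": opts.optimality_tolerance},
    )
    x, iterations, converged, message = res.x, res.nit, bool(res.success), res.message
    feasible = float(np.max(np.abs(score_of(x)))) <= opts.constraint_tolerance

    if not feasible:
        # phase two: best-effort violation minimiser (infeasible constraints,
        # typically complete separation); entropy tie-break keeps it unique.
        w, tau = opts.violation_weight, opts.entropy_tiebreak

        def violation(x: np.ndarray) -> float:
            u = score_of(x)
            return 0.5 * w * float(u @ u) + tau * neg_entropy(x)

        kwargs: dict = {}
        if have_jac:
            kwargs["jac"] = lambda x: (
                w * score_jac_x(x).T @ score_of(x) + tau * neg_entropy_grad(x)
            )
        res2 = minimize(
            violation,
            x0,
            method="SLSQP",
            bounds=bounds,
            constraints=[norm_con],
            options={"maxiter": opts.max_iterations, "ftol": opts.optimality_tolerance},
            **kwargs,
        )
        x, message = res2.x, res2.message
        iterations += res2.nit
        converged = bool(res2.success)
        feasible = float(np.max(np.abs(score_of(x)))) <= opts.constraint_tolerance

    x = np.clip(x, 0.0, 1.0)
    rows = tuple(p / p.sum() for p in _split(x, sizes))
    weights = WeightMatrix(rows)
    theta = reparameterize(supports, weights)
    residual = np.asarray(model.score(theta, data), dtype=float)
    return MEFit(
        theta_hat=theta,
        weights_hat=weights,
        entropy_value=entropy(weights),
        score_residual=residual,
        multipliers=_kkt_multipliers(_flatten(weights), A, score_con, neg_entropy_grad)
        if feasible
        else None,
        converged=converged,
        feasible=feasible,
        iterations=int(iterations),
        message=str(message),
    )


def _kkt_multipliers(x, A, score_con, neg_entropy_grad) -> dict | None:
    """Least-squares Lagrange multipliers at an interior feasible point.

    Stationarity of the Lagrangean gives grad(-H) = A' l0 + (dU/dx)' l1 on
    coordinates away from the bounds; the system is solved in the least-squares
    sense and reported for diagnostic purposes only.
    """
    try:
        jac = score_con.get("jac")
        if jac is None:
            return None
        G = np.vstack([A, np.atleast_2d(jac(x))])
        interior = x > 1e-6
        if interior.sum() < G.shape[0]:
            return None
        sol, *_ = np.linalg.lstsq(G[:, interior].T, neg_entropy_grad(x)[interior], rcond=None)
        J = A.shape[0]
        return {"normalization": sol[:J], "score": sol[J:]}
    except Exception:  # diagnostics must never break a fit
        return None


# ---------------------------------------------------------------------------
# closed-form path for the normal mean
# ---------------------------------------------------------------------------


def solve_me_normal_closed(
    y: np.ndarray,
    sigma2: float,
    z: np.ndarray,
    tol: float = 1e-12,
) -> MEFit:
    """Gibbs-form solution for the normal-mean score with known variance.

    Stationarity of the entropy Lagrangean gives weights
    ``p(l1) = exp(-z * l1 * n / sigma2) / Z`` for a scalar multiplier ``l1``;
    the score constraint reduces to ``z @ p(l1) = mean(y)``.  The map
    ``l1 -> z @ p(l1)`` is strictly decreasing, so the multiplier is found by
    bracketed one-dimensional root finding (bracket grown geometrically from
    [-1, 1] until the residual changes sign).
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if y.size == 0:
        raise ValueError("empty sample")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not np.all(np.diff(z) > 0) or z.size < 2:
        raise ValueError("support must be strictly increasing with K >= 2")
    n = y.size
    ybar = float(y.mean())
    if not z[0] <= ybar <= z[-1]:
        raise ValueError(
            f"sample mean {ybar:.6g} lies outside the support [{z[0]:.6g}, "
            f"{z[-1]:.6g}]; no score root exists there — widen the support"
        )

    scale = n / sigma2

    def gibbs(lam: float) -> np.ndarray:
        e = -z * lam * scale
        e -= e.max()  # numerical stabilisation of the softmax
        p = np.exp(e)
        return p / p.sum()

    def residual(lam: float) -> float:
        return float(z @ gibbs(lam) - ybar)

    lo, hi = -1.0, 1.0
    while residual(lo) * residual(hi) > 0:
        lo *= 2.0
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - mean interior => sign change exists
            raise RuntimeError("failed to bracket the multiplier")
    lam1 = 0.0 if residual(0.0) == 0.0 else brentq(residual, lo, hi, xtol=tol)
    p_hat = gibbs(lam1)
    weights = WeightMatrix((p_hat,))
    theta = np.array([float(z @ p_hat)])
    # lambda0 follows from the normalization condition of the stationarity system
    log_z_const = float(np.log(np.exp(-z * lam1 * scale).sum()))
    return MEFit(
        theta_hat=theta,
        weights_hat=weights,
        entropy_value=entropy(weights),
        score_residual=np.array([scale * (ybar - theta[0]) * 1.0]),
        multipliers={"lambda0": log_z_const - 1.0, "lambda1": float(lam1)},
        converged=True,
        feasible=True,
        iterations=0,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosticReport:
    """Structured pass/fail re-verification of a fit."""

    checks: dict[str, tuple[bool, float]]

    @property
    def ok(self) -> bool:
        return all(passed for passed, _ in self.checks.values())

    def failures(self) -> list[str]:
        return [name for name, (passed, _) in self.checks.items() if not passed]

    def to_dict(self) -> dict:
        return {
            name: {"passed": passed, "value": value}
            for name, (passed, value) in self.checks.items()
        }


def check_solution(fit: MEFit, problem: MEProblem, data) -> DiagnosticReport:
    """Recompute score residuals, row sums, entropy and box containment."""
    supports, opts = problem.supports, problem.options
    checks: dict[str, tuple[bool, float]] = {}

    row_err = max(abs(float(p.sum()) - 1.0) for p in fit.weights_hat.rows)
    checks["row_normalization"] = (row_err <= _ROW_SUM_TOL, row_err)

    neg = min(float(p.min()) for p in fit.weights_hat.rows)
    checks["nonnegative_weights"] = (neg >= -1e-12, neg)

    theta = reparameterize(supports, fit.weights_hat)
    theta_err = float(np.max(np.abs(theta - fit.theta_hat)))
    checks["theta_consistent_with_weights"] = (theta_err <= 1e-8, theta_err)

    box_ok = all(
        lo - 1e-9 <= t <= hi + 1e-9 for t, (lo, hi) in zip(theta, supports.box())
    )
    checks["box_containment"] = (box_ok, float(np.max(np.abs(theta))))

    resid = float(
        np.max(np.abs(np.asarray(problem.model.score(theta, data), dtype=float)))
    )
    checks["score_residual"] = (resid <= max(opts.constraint_tolerance, 1e-6), resid)

    h = entropy(fit.weights_hat)
    h_max = float(sum(np.log(k) for k in supports.sizes))
    checks["entropy_bound"] = (h <= h_max + 1e-9, h)

    return DiagnosticReport(checks=checks)
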