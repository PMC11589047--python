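"""Probability limits (estimands) of FG and DB treatment-effect estimators.

When the cloglog CIF model is fit to data generated by an arbitrary
competing-risks process, the estimators converge to well-defined limits
``beta_star`` that solve the *expected* estimating equations.  With a
correctly specified censoring model the censoring drops out of those
expectations, so the limits are deterministic functionals of the true
process and can be computed by quadrature and root finding -- no simulation.

Notation for a binary treatment with ``p_x = P(X=1)``:

* FG expected pseudo-score (density scale):
  ``integral over (0, tau] of s1(t) - [s1b(t;b)/s0b(t;b)] * s0(t) dt`` with
  ``s_l(t) = sum_x P(x) x^l f1(t|x)`` (expected weighted event terms) and
  ``s_lb(t;b) = sum_x P(x) x^l exp(b x) (1 - F1(t|x))`` (expected weighted
  at-risk terms, using E[Ydagger(t)|x] = 1 - F1(t-|x)).

  With the *standard* weights ``1(Cr >= min(T,t)) / G(min(T,t))`` each weight
  has conditional expectation 1, so the limit is free of the censoring law.
  With *stabilized* weights ``G(t) 1(Cr >= min(T,t)) / G(min(T,t))`` every
  expected term picks up a common factor G(t): the at-zero roots of Theorem-2
  type are unchanged, but away from a null the root -- hence the estimand --
  depends on the censoring distribution.  Passing ``censoring_survivor``
  computes that stabilized-weight limit.
* DB expected estimating equations: R+1 equations in (alpha_1..alpha_R, b)
  obtained by replacing the weighted responses by their expectations
  ``F1(s_r|x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from ._link import g, h, hprime
from .process import TrueProcess

__all__ = [
    "FGLimit",
    "DBLimit",
    "expected_fg_score",
    "fg_limit",
    "db_limit",
    "db_grid",
    "limit_cif_curves",
    "DEFAULT_GRID_CONVENTION",
]

# Grid placements considered for the R equi-spaced DB time points in (0, tau).
# "interior" r*tau/(R+1) is the default; see docs/methods.md for the
# numerical comparison that fixed this choice.
_GRID_CONVENTIONS = {
    "interior": lambda R, tau: np.arange(1, R + 1) * tau / (R + 1),
    "right": lambda R, tau: np.arange(1, R + 1) * tau / R,
    "midpoint": lambda R, tau: (np.arange(1, R + 1) - 0.5) * tau / R,
}
DEFAULT_GRID_CONVENTION = "interior"


def db_grid(R: int, tau: float, convention: str = DEFAULT_GRID_CONVENTION) -> np.ndarray:
    """R equi-spaced DB grid times in (0, tau] under a named convention."""
    return _GRID_CONVENTIONS[convention](R, tau)


def _score_pieces(process: TrueProcess, beta: float, p_x: float):
    eb = np.exp(beta)

    def s0(t):
        return (1 - p_x) * process.f1(t, 0) + p_x * process.f1(t, 1)

    def s1(t):
        return p_x * process.f1(t, 1)

    def s0b(t):
        return (1 - p_x) * (1 - process.F1(t, 0)) + p_x * eb * (1 - process.F1(t, 1))

    def s1b(t):
        return p_x * eb * (1 - process.F1(t, 1))

    return s0, s1, s0b, s1b


def _as_survivor(censoring_survivor):
    if censoring_survivor is None:
        return lambda t: 1.0
    if callable(censoring_survivor):
        return censoring_survivor
    rate = float(censoring_survivor)
    return lambda t: np.exp(-rate * np.asarray(t, dtype=float))


def expected_fg_score(
    process: TrueProcess,
    beta: float,
    p_x: float = 0.5,
    tau: float | None = None,
    censoring_survivor=None,
) -> float:
    """Expected FG pseudo-score per subject at coefficient ``beta``.

    With standard weights (``censoring_survivor=None``) the IPCW weights have
    conditional expectation 1 under a correct censoring model, so the score
    expectation does not involve the censoring distribution.  Passing the
    random-withdrawal survivor function ``G`` (a callable of time, or an
    exponential rate) gives the stabilized-weight expected score, whose
    integrand carries the common factor G(t).  Where no one is expected at
    risk (``s0b = 0``) the integrand is defined as 0.
    """
    tau = process.tau if tau is None else tau
    s0, s1, s0b, s1b = _score_pieces(process, beta, p_x)
    G = _as_survivor(censoring_survivor)

    def integrand(t):
        t = np.asarray(t)
        denom = s0b(t)
        if np.ndim(denom) == 0 and denom <= 0:
            return 0.0
        return G(t) * (s1(t) - s1b(t) / denom * s0(t))

    val, _ = integrate.quad(integrand, 0.0, tau, epsabs=1e-10, epsrel=1e-10, limit=200)
    return float(val)


@dataclass
class FGLimit:
    """Solved FG probability limit with its baseline-limit curve."""

    beta_star: float
    tgrid: np.ndarray
    gamma_star: np.ndarray  # limiting baseline cumulative subdistribution hazard
    p_x: float
    tau: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def alpha_star(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.gamma_star)

    def f1_star(self, x: int, tgrid=None) -> np.ndarray:
        """Limiting fitted CIF 1 - exp(-Gamma_star(t) * exp(beta_star * x))."""
        if tgrid is None:
            gam = self.gamma_star
        else:
            gam = np.interp(np.asarray(tgrid, dtype=float), self.tgrid, self.gamma_star)
        return -np.expm1(-gam * np.exp(self.beta_star * x))


def fg_limit(
    process: TrueProcess,
    p_x: float = 0.5,
    tau: float | None = None,
    censoring_survivor=None,
    bracket: tuple[float, float] = (-5.0, 5.0),
    n_grid: int = 401,
) -> FGLimit:
    """Probability limit of the FG estimator under ``process``.

    ``beta_star`` is the root of :func:`expected_fg_score` on ``bracket``;
    the limiting baseline cumulative subdistribution hazard is accumulated
    as ``integral of s0(u) / s0b(u; beta_star) du`` on a fine grid (the G(t)
    factor of the stabilized-weight form cancels in this ratio, so the
    baseline limit does not depend on the weight style).
    """
    tau = process.tau if tau is None else tau
    lo, hi = bracket
    flo = expected_fg_score(process, lo, p_x, tau, censoring_survivor)
    fhi = expected_fg_score(process, hi, p_x, tau, censoring_survivor)
    if flo * fhi > 0:
        raise RuntimeError(
            f"expected FG score has no sign change on {bracket}: "
            f"score({lo})={flo:.3g}, score({hi})={fhi:.3g}"
        )
    beta_star, res = optimize.brentq(
        lambda b: expected_fg_score(process, b, p_x, tau, censoring_survivor),
        lo,
        hi,
        xtol=1e-12,
        rtol=8.9e-16,
        full_output=True,
    )
    residual = expected_fg_score(process, beta_star, p_x, tau, censoring_survivor)

    s0, _, s0b, _ = _score_pieces(process, beta_star, p_x)
    tgrid = np.linspace(0.0, tau, n_grid)
    vals = np.zeros(n_grid)
    for k in range(1, n_grid):
        piece, _ = integrate.quad(
            lambda u: s0(u) / s0b(u),
            tgrid[k - 1],
            tgrid[k],
            epsabs=1e-12,
            epsrel=1e-10,
        )
        vals[k] = vals[k - 1] + piece
    return FGLimit(
        beta_star=float(beta_star),
        tgrid=tgrid,
        gamma_star=vals,
        p_x=p_x,
        tau=tau,
        diagnostics={
            "bracket": bracket,
            "iterations": res.iterations,
            "residual": residual,
        },
    )


@dataclass
class DBLimit:
    """Solved DB probability limit on a grid of R time points."""

    grid: np.ndarray
    alpha_star: np.ndarray
    beta_star: float
    p_x: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def R(self) -> int:
        return len(self.grid)

    def f1_star(self, x: int) -> np.ndarray:
        return h(self.alpha_star + self.beta_star * x)


def _db_expected_equations(theta, F1_by_arm, p_x):
    R = len(theta) - 1
    alpha, beta = theta[:R], theta[R]
    out = np.zeros(R + 1)
    for arm, w in ((0, 1.0 - p_x), (1, p_x)):
        eta = alpha + beta * arm
        mu = h(eta)
        wgt = w * hprime(eta) / (mu * (1.0 - mu))
        resid = F1_by_arm[arm] - mu
        out[:R] += wgt * resid
        if arm == 1:
            out[R] = np.sum(wgt * resid)
    return out


def db_limit(
    process: TrueProcess,
    grid=None,
    p_x: float = 0.5,
    R: int = 6,
    convention: str = DEFAULT_GRID_CONVENTION,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> DBLimit:
    """Probability limit of the DB estimator under ``process``.

    Solves the R+1 expected estimating equations jointly by Newton iteration
    with a numerical Jacobian (forward step 1e-6), initialized at the true
    control-arm CIF transforms and beta = 0; falls back to step-halving when
    a full step does not reduce the residual.
    """
    if grid is None:
        grid = db_grid(R, process.tau, convention)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or grid[0] <= 0 or grid[-1] > process.tau:
        raise ValueError("grid must be strictly increasing inside (0, tau]")
    F1_by_arm = {arm: np.asarray(process.F1(grid, arm), dtype=float) for arm in (0, 1)}
    if np.any(F1_by_arm[0] <= 0) or np.any(F1_by_arm[1] <= 0):
        raise ValueError("F1(s_r | x) must be positive at every grid point")

    Rn = len(grid)
    theta = np.append(g(F1_by_arm[0]), 0.0)
    fun = lambda th: _db_expected_equations(th, F1_by_arm, p_x)
    fval = fun(theta)
    it = 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(fval, np.inf) < tol:
            break
        J = np.empty((Rn + 1, Rn + 1))
        step = 1e-6
        for j in range(Rn + 1):
            pert = theta.copy()
            pert[j] += step
            J[:, j] = (fun(pert) - fval) / step
        try:
            delta = np.linalg.solve(J, -fval)
        except np.linalg.LinAlgError:
            delta = -np.linalg.lstsq(J, fval, rcond=None)[0]
        scale = 1.0
        base = np.linalg.norm(fval)
        for _ in range(30):
            cand = theta + scale * delta
            fcand = fun(cand)
            if np.linalg.norm(fcand) < base:
                theta, fval = cand, fcand
                break
            scale *= 0.5
        else:
            break
    residual = float(np.linalg.norm(fun(theta), np.inf))
    if residual > 1e-8:
        raise RuntimeError(f"DB limit solver did not converge: residual {residual:.3g}")
    return DBLimit(
        grid=grid,
        alpha_star=theta[:Rn],
        beta_star=float(theta[Rn]),
        p_x=p_x,
        diagnostics={"iterations": it, "residual": residual},
    )


def limit_cif_curves(limit, x: int, tgrid=None) -> np.ndarray:
    """Limiting fitted CIF values for arm ``x`` from a solved limit object."""
    if isinstance(limit, FGLimit):
        return limit.f1_star(x, tgrid=tgrid)
    if isinstance(limit, DBLimit):
        if tgrid is not None and not np.array_equal(np.asarray(tgrid), limit.grid):
            raise ValueError("DB limits are defined only on their own grid")
        return limit.f1_star(x)
    raise TypeError(f"unsupported limit object {type(limit)!r}")
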