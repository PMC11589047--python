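"""True data-generating competing-risks processes.

Two parametric families of three-state competing-risks processes (initial
state 0, event of interest k=1, competing event k=2) for a binary treatment
indicator ``x``:

* :class:`IntensityProcess` -- multiplicative cause-specific intensities
  constant in time, ``lambda_0k(t|x) = lambda_k * exp(gamma_k * x)``.
* :class:`CIFProcess` -- the process is specified directly through cumulative
  incidence functions with a cloglog-linear treatment effect on the CIF of
  the event of interest.  Two sub-families are supported: the ``indirect``
  construction in which a single coefficient ``beta`` drives both CIFs, and
  the ``extended`` construction with a separate coefficient ``beta2`` for the
  competing-event CIF.

Every process exposes the marginal functions S, F1, F2, the subdensities
f1, f2 and the cause-specific intensities, all vectorized over time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional, Union

import numpy as np
import yaml

__all__ = [
    "IntensityProcess",
    "CIFProcess",
    "ProcessCurves",
    "TrueProcess",
    "calibrate_intensity_process",
    "calibrate_cif_process",
    "evaluate_process",
    "process_to_dict",
    "process_from_dict",
    "process_to_yaml",
    "process_from_yaml",
]


class ProcessCurves(NamedTuple):
    """Marginal functions of a competing-risks process at one (t, x) point.

    ``lam1``/``lam2`` are cause-specific intensities ``f_k / S``; they are
    NaN where the event-free probability S is zero (undefined, not an error).
    """

    S: np.ndarray
    F1: np.ndarray
    F2: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    lam1: np.ndarray
    lam2: np.ndarray


def _identity(t):
    return np.asarray(t, dtype=float)


def _numeric_derivative(fn: Callable, t: np.ndarray) -> np.ndarray:
    # adaptive central differences, step scaled to the time argument
    t = np.asarray(t, dtype=float)
    hstep = 1e-5 * np.maximum(t, 1.0)
    lo = np.maximum(t - hstep, 0.0)
    return (fn(t + hstep) - fn(lo)) / (t + hstep - lo)


@dataclass(frozen=True)
class IntensityProcess:
    """Competing-risks process with constant multiplicative intensities.

    Parameters
    ----------
    lambda1, lambda2 : float
        Baseline 0-1 and 0-2 intensities (events per unit time); must be
        nonnegative and not both zero.
    gamma1, gamma2 : float
        Log treatment effects on the respective intensities.
    tau : float
        Administrative follow-up horizon.
    """

    lambda1: float
    lambda2: float
    gamma1: float = 0.0
    gamma2: float = 0.0
    tau: float = 1.0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0 or self.lambda1 + self.lambda2 <= 0:
            raise ValueError("intensities must be nonnegative with a positive total")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def rates(self, x: int) -> tuple[float, float]:
        return (
            self.lambda1 * np.exp(self.gamma1 * x),
            self.lambda2 * np.exp(self.gamma2 * x),
        )

    def total_rate(self, x: int) -> float:
        l1, l2 = self.rates(x)
        return l1 + l2

    def S(self, t, x):
        t = np.asarray(t, dtype=float)
        return np.exp(-self.total_rate(x) * t)

    def _cif(self, t, x, k):
        t = np.asarray(t, dtype=float)
        l1, l2 = self.rates(x)
        lam = l1 + l2
        lk = l1 if k == 1 else l2
        return (lk / lam) * -np.expm1(-lam * t)

    def F1(self, t, x):
        return self._cif(t, x, 1)

    def F2(self, t, x):
        return self._cif(t, x, 2)

    def f1(self, t, x):
        l1, _ = self.rates(x)
        return l1 * self.S(t, x)

    def f2(self, t, x):
        _, l2 = self.rates(x)
        return l2 * self.S(t, x)

    def lam1(self, t, x):
        t = np.asarray(t, dtype=float)
        l1, _ = self.rates(x)
        return np.broadcast_to(np.asarray(l1, dtype=float), t.shape).copy() if t.shape else np.asarray(l1)

    def lam2(self, t, x):
        t = np.asarray(t, dtype=float)
        _, l2 = self.rates(x)
        return np.broadcast_to(np.asarray(l2, dtype=float), t.shape).copy() if t.shape else np.asarray(l2)


PsiLike = Union[None, Callable, tuple]


def _as_psi(psi: PsiLike) -> tuple[Callable, Optional[Callable]]:
    """Normalize a time-transform argument to (psi, psi_derivative-or-None)."""
    if psi is None:
        return _identity, lambda t: np.ones_like(np.asarray(t, dtype=float))
    if isinstance(psi, tuple):
        fn, deriv = psi
        return fn, deriv
    return psi, None


@dataclass(frozen=True)
class CIFProcess:
    """Competing-risks process specified through its CIFs.

    The CIF of the event of interest follows the cloglog-linear form

        F1(t|x) = 1 - (1 - q * (1 - exp(-psi1(t))))**exp(beta * x),

    with ``q = F1(inf | x=0)`` in (0,1).  The competing-event CIF depends on
    the sub-family:

    * ``family="indirect"``: both CIFs are driven by ``beta`` alone,
      F2(t|x) = (1-q)**exp(beta*x) * (1 - exp(-psi2(t)*exp(beta*x))),
      so no treatment effect on F1 implies none on F2 either.
    * ``family="extended"``: the competing-event CIF has its own coefficient,
      F2(t|x) = (1-q)**exp(beta*x) * (1 - exp(-psi2(t)*exp(beta2*x))),
      allowing equal F1 curves while the F2 curves differ.

    ``psi1``/``psi2`` are nonnegative increasing time transforms; the default
    is the identity.  A callable or a ``(fn, derivative)`` tuple is accepted;
    with a bare callable the subdensities fall back to adaptive central
    differences.
    """

    family: str
    q: float
    beta: float = 0.0
    beta2: float = 0.0
    psi1: PsiLike = None
    psi2: PsiLike = None
    tau: float = 1.0

    def __post_init__(self):
        if self.family not in ("indirect", "extended"):
            raise ValueError(f"unknown CIF family {self.family!r}")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must be in (0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    # -- internal helpers -------------------------------------------------
    def _psi(self, which: int):
        return _as_psi(self.psi1 if which == 1 else self.psi2)

    def _beta2_eff(self, x: int) -> float:
        # exponent scaling the time transform of F2; in the indirect family
        # beta plays that role, in the extended family beta2 does
        return self.beta if self.family == "indirect" else self.beta2

    # -- marginal functions ----------------------------------------------
    def F1(self, t, x):
        psi1, _ = self._psi(1)
        u = -np.expm1(-psi1(np.asarray(t, dtype=float)))
        return -np.expm1(np.exp(self.beta * x) * np.log1p(-self.q * u))

    def F1_inf(self, x) -> float:
        return -np.expm1(np.exp(self.beta * x) * np.log1p(-self.q))

    def F2(self, t, x):
        psi2, _ = self._psi(2)
        t = np.asarray(t, dtype=float)
        scale = np.exp(self._beta2_eff(x) * x)
        f2inf = 1.0 - self.F1_inf(x)
        return f2inf * -np.expm1(-psi2(t) * scale)

    def S(self, t, x):
        return 1.0 - self.F1(t, x) - self.F2(t, x)

    def f1(self, t, x):
        psi1, d1 = self._psi(1)
        t = np.asarray(t, dtype=float)
        dpsi = d1(t) if d1 is not None else _numeric_derivative(psi1, t)
        eb = np.exp(self.beta * x)
        inner = 1.0 - self.q * -np.expm1(-psi1(t))
        return eb * inner ** (eb - 1.0) * self.q * np.exp(-psi1(t)) * dpsi

    def f2(self, t, x):
        psi2, d2 = self._psi(2)
        t = np.asarray(t, dtype=float)
        dpsi = d2(t) if d2 is not None else _numeric_derivative(psi2, t)
        scale = np.exp(self._beta2_eff(x) * x)
        f2inf = 1.0 - self.F1_inf(x)
        return f2inf * np.exp(-psi2(t) * scale) * scale * dpsi

    def lam1(self, t, x):
        return _safe_ratio(self.f1(t, x), self.S(t, x))

    def lam2(self, t, x):
        return _safe_ratio(self.f2(t, x), self.S(t, x))


TrueProcess = Union[IntensityProcess, CIFProcess]


def _safe_ratio(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast_shapes(num.shape, den.shape), np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return out


def calibrate_intensity_process(
    p_exit: float,
    p_type1: float,
    exp_g1: float = 1.0,
    exp_g2: float = 1.0,
    tau: float = 1.0,
) -> IntensityProcess:
    """Build constant intensities matching control-arm exit probabilities.

    Solves for ``lambda1, lambda2`` such that, in the control arm,
    ``P(T <= tau) = p_exit`` and the conditional probability that an exit by
    ``tau`` is of type 1 equals ``p_type1``.  For constant intensities the
    type of the exit is independent of its time, so the conditional share
    equals ``lambda1 / (lambda1 + lambda2)`` exactly.
    """
    if not 0.0 < p_exit < 1.0:
        raise ValueError("p_exit must be in (0, 1)")
    if not 0.0 < p_type1 <= 1.0:
        raise ValueError("p_type1 must be in (0, 1]")
    if exp_g1 <= 0 or exp_g2 <= 0:
        raise ValueError("intensity ratios must be positive")
    total = -np.log1p(-p_exit) / tau
    return IntensityProcess(
        lambda1=p_type1 * total,
        lambda2=(1.0 - p_type1) * total,
        gamma1=float(np.log(exp_g1)),
        gamma2=float(np.log(exp_g2)),
        tau=tau,
    )


def calibrate_cif_process(
    f1_at_tau: float,
    exp_b: float = 1.0,
    exp_b2: float = 1.0,
    family: str = "extended",
    tau: float = 1.0,
    psi1: PsiLike = None,
    psi2: PsiLike = None,
) -> CIFProcess:
    """Build a CIF-based process with a target control-arm F1 at ``tau``.

    ``q = F1(inf | x=0)`` is chosen so that ``F1(tau | x=0) = f1_at_tau``,
    i.e. ``q = f1_at_tau / (1 - exp(-psi1(tau)))``.
    """
    if exp_b <= 0 or exp_b2 <= 0:
        raise ValueError("effect ratios must be positive")
    psi1_fn, _ = _as_psi(psi1)
    denom = -np.expm1(-psi1_fn(np.asarray(tau, dtype=float)))
    q = float(f1_at_tau / denom)
    if not 0.0 < q < 1.0:
        raise ValueError(
            f"target F1(tau|0)={f1_at_tau} infeasible: implied q={q:.4f} not in (0,1)"
        )
    return CIFProcess(
        family=family,
        q=q,
        beta=float(np.log(exp_b)),
        beta2=float(np.log(exp_b2)),
        psi1=psi1,
        psi2=psi2,
        tau=tau,
    )


def evaluate_process(process: TrueProcess, t, x: int) -> ProcessCurves:
    """Evaluate all marginal functions of ``process`` at times ``t``, arm ``x``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    S = process.S(t, x)
    undefined = np.asarray(S) <= 0  # no survivors: intensities flagged NaN
    return ProcessCurves(
        S=S,
        F1=process.F1(t, x),
        F2=process.F2(t, x),
        f1=process.f1(t, x),
        f2=process.f2(t, x),
        lam1=np.where(undefined, np.nan, process.lam1(t, x)),
        lam2=np.where(undefined, np.nan, process.lam2(t, x)),
    )


# -- serialization --------------------------------------------------------

def process_to_dict(process: TrueProcess) -> dict:
    if isinstance(process, IntensityProcess):
        return {
            "kind": "intensity",
            "lambda1": float(process.lambda1),
            "lambda2": float(process.lambda2),
            "gamma1": float(process.gamma1),
            "gamma2": float(process.gamma2),
            "tau": float(process.tau),
        }
    if not isinstance(process, CIFProcess):
        raise TypeError(f"unsupported process type {type(process)!r}")
    if process.psi1 is not None or process.psi2 is not None:
        raise ValueError("processes with custom time transforms do not serialize")
    return {
        "kind": "cif",
        "family": process.family,
        "q": float(process.q),
        "beta": float(process.beta),
        "beta2": float(process.beta2),
        "tau": float(process.tau),
    }


def process_from_dict(spec: dict) -> TrueProcess:
    spec = dict(spec)
    kind = spec.pop("kind")
    if kind == "intensity":
        return IntensityProcess(**spec)
    if kind == "cif":
        return CIFProcess(**spec)
    raise ValueError(f"unknown process kind {kind!r}")


def process_to_yaml(process: TrueProcess) -> str:
    return yaml.safe_dump(process_to_dict(process), sort_keys=False)


def process_from_yaml(text: str) -> TrueProcess:
    return process_from_dict(yaml.safe_load(io.StringIO(text)))
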