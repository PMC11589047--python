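"""Generation of observed competing-risks data under a true process.

The simulator draws latent exit times and event types from either process
family, then applies independent exponential random withdrawal plus
administrative censoring at ``tau``.  The withdrawal rate can be calibrated
so that a target fraction ``pi_r`` of type-1 events occurring by ``tau`` is
lost to follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Union

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .process import CIFProcess, IntensityProcess, TrueProcess

__all__ = [
    "LatentSample",
    "LatentData",
    "CensoringSpec",
    "ObservedDataset",
    "draw_competing_risks",
    "calibrate_censoring_rate",
    "apply_censoring",
    "simulate_observed",
]

_RngLike = Union[int, np.random.Generator]


def _as_rng(seed: _RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class LatentSample(NamedTuple):
    """One latent record: exit time T, event type in {1,2}, treatment x."""

    T: float
    event_type: int
    x: int


@dataclass
class LatentData:
    """Column-oriented container of latent samples.

    ``T`` may contain ``np.inf`` sentinels for CIF-family draws whose uniform
    variate exceeds the total incidence reachable on the search interval;
    such records are administratively censored downstream.
    """

    T: np.ndarray
    event_type: np.ndarray
    x: np.ndarray

    def __len__(self) -> int:
        return len(self.T)

    def __getitem__(self, i):
        if isinstance(i, (int, np.integer)):
            return LatentSample(float(self.T[i]), int(self.event_type[i]), int(self.x[i]))
        return LatentData(self.T[i], self.event_type[i], self.x[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


@dataclass(frozen=True)
class CensoringSpec:
    """Random-withdrawal specification: exponential rate and horizon."""

    rho: float
    tau: float
    pi_r: float | None = None

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class ObservedDataset:
    """Observed records: time = min(T, Cr, tau), status in {0,1,2}, x in {0,1}."""

    time: np.ndarray
    status: np.ndarray
    x: np.ndarray
    tau: float

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.x = np.asarray(self.x, dtype=int)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self.time)),
                "time": self.time,
                "status": self.status,
                "x": self.x,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tau: float | None = None) -> "ObservedDataset":
        required = {"time", "status", "x"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        status = df["status"].to_numpy()
        if not np.isin(status, [0, 1, 2]).all():
            raise ValueError("status must be coded 0 (censored), 1, or 2")
        tau = float(df["time"].max()) if tau is None else float(tau)
        return cls(df["time"].to_numpy(float), status, df["x"].to_numpy(int), tau)

    @classmethod
    def from_csv(cls, path, tau: float | None = None) -> "ObservedDataset":
        return cls.from_frame(pd.read_csv(path), tau=tau)


def _invert_total_cif(process: CIFProcess, u: np.ndarray, x: int) -> np.ndarray:
    """Solve F1(t|x) + F2(t|x) = u for t by vectorized bisection.

    The search interval is [0, 50*tau]; draws beyond the reachable total
    incidence get a +inf sentinel.
    """
    hi = 50.0 * process.tau

    def total(t):
        return process.F1(t, x) + process.F2(t, x)

    out = np.full(u.shape, np.inf)
    reachable = u < total(np.asarray(hi))
    if not reachable.any():
        return out
    lo_v = np.zeros(reachable.sum())
    hi_v = np.full(reachable.sum(), hi)
    ur = u[reachable]
    # 64 halvings bring the bracket width below 50*tau * 2**-64 ~ 3e-18*tau
    for _ in range(64):
        mid = 0.5 * (lo_v + hi_v)
        high = total(mid) >= ur
        hi_v = np.where(high, mid, hi_v)
        lo_v = np.where(high, lo_v, mid)
    out[reachable] = 0.5 * (lo_v + hi_v)
    return out


def draw_competing_risks(
    n: int,
    process: TrueProcess,
    p_x: float = 0.5,
    rng_seed: _RngLike = 0,
) -> LatentData:
    """Draw ``n`` latent (T, event type, x) triples from the true process.

    For the intensity family, T | x is exponential with the total rate and
    the type is an independent Bernoulli draw with the intensity share.  For
    the CIF families, T solves ``F1(t|x) + F2(t|x) = U`` (inversion) and the
    type is Bernoulli with probability ``lam1 / (lam1 + lam2)`` at T.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if not 0.0 < p_x < 1.0:
        raise ValueError("p_x must be in (0, 1)")
    rng = _as_rng(rng_seed)
    x = (rng.random(n) < p_x).astype(int)
    T = np.empty(n)
    event_type = np.ones(n, dtype=int)
    u_type = rng.random(n)

    if isinstance(process, IntensityProcess):
        u_time = rng.random(n)
        for arm in (0, 1):
            mask = x == arm
            lam = process.total_rate(arm)
            T[mask] = -np.log1p(-u_time[mask]) / lam
            l1, l2 = process.rates(arm)
            event_type[mask] = np.where(u_type[mask] < l1 / (l1 + l2), 1, 2)
        return LatentData(T, event_type, x)

    u_time = rng.random(n)
    for arm in (0, 1):
        mask = x == arm
        t_arm = _invert_total_cif(process, u_time[mask], arm)
        T[mask] = t_arm
        finite = np.isfinite(t_arm)
        tf = t_arm[finite]
        f1 = process.f1(tf, arm)
        f2 = process.f2(tf, arm)
        p1 = f1 / (f1 + f2)
        types = np.ones(finite.sum(), dtype=int)
        types[u_type[mask][finite] >= p1] = 2
        sub = event_type[mask]
        sub[finite] = types
        event_type[mask] = sub
    return LatentData(T, event_type, x)


def _pi_r_given_rho(process: TrueProcess, tau: float, rho: float, p_x: float) -> float:
    """P(Cr < T1 | T1 <= min(T2, tau)) averaged over arms with weights P(X=x)."""
    total = 0.0
    for arm, w in ((0, 1.0 - p_x), (1, p_x)):
        f1tau = float(process.F1(tau, arm))
        num, _ = integrate.quad(
            lambda t: -np.expm1(-rho * t) * process.f1(np.asarray(t), arm),
            0.0,
            tau,
            epsabs=1e-12,
            epsrel=1e-10,
        )
        total += w * num / f1tau
    return total


def calibrate_censoring_rate(
    process: TrueProcess,
    tau: float,
    pi_r: float,
    p_x: float = 0.5,
) -> float:
    """Exponential withdrawal rate ``rho`` achieving the target ``pi_r``.

    ``pi_r`` is the probability that a type-1 event occurring by ``tau`` is
    randomly lost to follow-up, computed per arm and averaged over arms with
    weights ``P(X=x)``.
    """
    if not 0.0 <= pi_r < 1.0:
        raise ValueError("pi_r must be in [0, 1)")
    if pi_r == 0.0:
        return 0.0
    lo, hi = 0.0, 1.0
    while _pi_r_given_rho(process, tau, hi, p_x) < pi_r:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError(f"pi_r={pi_r} unattainable with exponential withdrawal")
    return float(
        optimize.brentq(
            lambda r: _pi_r_given_rho(process, tau, r, p_x) - pi_r,
            lo,
            hi,
            xtol=1e-12,
            rtol=1e-12,
        )
    )


def apply_censoring(
    samples: LatentData,
    spec: CensoringSpec,
    rng_seed: _RngLike = 0,
) -> ObservedDataset:
    """Apply exponential random withdrawal and administrative censoring.

    The observed time is ``min(T, Cr, tau)``; status is the event type when
    the exit is observed and 0 otherwise.  Withdrawal is independent of the
    event process, so the independent-censoring assumption holds by
    construction.
    """
    rng = _as_rng(rng_seed)
    n = len(samples)
    if spec.rho > 0:
        cr = rng.exponential(1.0 / spec.rho, size=n)
    else:
        cr = np.full(n, np.inf)
    c_net = np.minimum(cr, spec.tau)
    observed = samples.T <= c_net
    time = np.where(observed, samples.T, c_net)
    status = np.where(observed, samples.event_type, 0)
    return ObservedDataset(time=time, status=status, x=samples.x.copy(), tau=spec.tau)


def simulate_observed(
    n: int,
    process: TrueProcess,
    pi_r: float = 0.0,
    p_x: float = 0.5,
    rng_seed: _RngLike = 0,
    rho: float | None = None,
) -> ObservedDataset:
    """Convenience wrapper: draw latent data, calibrate rho if needed, censor."""
    rng = _as_rng(rng_seed)
    tau = process.tau
    if rho is None:
        rho = calibrate_censoring_rate(process, tau, pi_r, p_x)
    latent = draw_competing_risks(n, process, p_x=p_x, rng_seed=rng)
    return apply_censoring(latent, CensoringSpec(rho=rho, tau=tau, pi_r=pi_r), rng_seed=rng)
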