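"""Classical two-sample competing-risks tests and a sample-size formula.

Each test is labeled by the null hypothesis it targets:

* ``H0lambda_k`` -- no treatment effect on the 0-k cause-specific intensity
  (cause-specific log-rank; Cox Wald).
* ``H0lambda1lambda2`` -- the global intensity null (2-df joint Cox Wald).
* ``H0F1`` -- equal CIFs of the event of interest (Gray's test; the FG and
  DB robust Wald tests live in their own modules).

The sample-size calculator implements the Schoenfeld-type formula of
Latouche, Porcher and Chevret for the Fine-Gray model, driven by the
proportion of observed type-1 events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from lifelines.statistics import logrank_test
from scipy import stats

from .simulate import ObservedDataset

__all__ = [
    "TestResult",
    "SampleSizeInputs",
    "logrank_cause_specific",
    "cox_cause_specific_wald",
    "joint_cox_wald",
    "gray_test",
    "latouche_sample_size",
]


@dataclass
class TestResult:
    name: str
    hypothesis_label: str
    statistic: float
    df: int
    p_value: float
    estimate: Optional[float] = None
    se: Optional[float] = None
    note: str = ""


@dataclass(frozen=True)
class SampleSizeInputs:
    """Inputs of the FG sample-size formula."""

    beta1: float      # alternative log subdistribution hazard ratio
    p_obs: float      # P(T1 <= C): proportion of observed type-1 events
    omega: float = 0.05   # two-sided size
    power: float = 0.8
    p_x: float = 0.5


# -- binary-covariate Cox partial likelihood --------------------------------

def _cox_binary(time, event, x, tol=1e-10, max_iter=50):
    """Newton solve of the Cox partial likelihood for one binary covariate.

    Breslow handling of ties.  Returns (gamma_hat, se, converged).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    x = np.asarray(x, dtype=int)
    if not event.any():
        raise ValueError("no events")
    te, counts = np.unique(time[event], return_counts=True)
    d1 = np.bincount(
        np.searchsorted(te, time[event & (x == 1)]), minlength=te.size
    ).astype(float)
    d_all = counts.astype(float)
    n_at = {}
    for arm in (0, 1):
        u = np.sort(time[x == arm])
        n_at[arm] = u.size - np.searchsorted(u, te, side="left")
    if d1.sum() == 0 or d1.sum() == d_all.sum():
        return math.inf if d1.sum() else -math.inf, math.nan, False

    gamma = 0.0
    for _ in range(max_iter):
        eg = math.exp(gamma)
        denom = n_at[0] + eg * n_at[1]
        p = eg * n_at[1] / denom
        U = float(np.sum(d1 - d_all * p))
        I = float(np.sum(d_all * p * (1.0 - p)))
        if I <= 0:
            return gamma, math.nan, False
        step = U / I
        gamma += step
        if abs(step) < tol:
            break
        if abs(gamma) > 25:
            return math.copysign(math.inf, gamma), math.nan, False
    eg = math.exp(gamma)
    denom = n_at[0] + eg * n_at[1]
    p = eg * n_at[1] / denom
    I = float(np.sum(d_all * p * (1.0 - p)))
    return gamma, 1.0 / math.sqrt(I), True


def logrank_cause_specific(data: ObservedDataset, cause: int = 1) -> TestResult:
    """Two-sample log-rank for the cause-k intensity; other causes censor."""
    event = data.status == cause
    if not event.any():
        raise ValueError(f"no events of cause {cause}")
    mask1 = data.x == 1
    res = logrank_test(
        data.time[~mask1],
        data.time[mask1],
        event_observed_A=event[~mask1],
        event_observed_B=event[mask1],
    )
    return TestResult(
        name=f"logrank_cause{cause}",
        hypothesis_label=f"H0lambda{cause}",
        statistic=float(res.test_statistic),
        df=1,
        p_value=float(res.p_value),
    )


def cox_cause_specific_wald(data: ObservedDataset, cause: int = 1) -> TestResult:
    """Wald test of gamma_k = 0 in the cause-k Cox model."""
    event = data.status == cause
    if not event.any():
        raise ValueError(f"no events of cause {cause}")
    gamma, se, converged = _cox_binary(data.time, event, data.x)
    if not converged or not math.isfinite(gamma):
        return TestResult(
            name=f"cox_cause{cause}",
            hypothesis_label=f"H0lambda{cause}",
            statistic=math.nan,
            df=1,
            p_value=math.nan,
            estimate=gamma,
            note="monotone partial likelihood",
        )
    z2 = (gamma / se) ** 2
    return TestResult(
        name=f"cox_cause{cause}",
        hypothesis_label=f"H0lambda{cause}",
        statistic=float(z2),
        df=1,
        p_value=float(stats.chi2.sf(z2, df=1)),
        estimate=gamma,
        se=se,
    )


def joint_cox_wald(data: ObservedDataset) -> TestResult:
    """2-df Wald test of gamma_1 = gamma_2 = 0 from the two cause-specific fits."""
    parts = [cox_cause_specific_wald(data, cause) for cause in (1, 2)]
    stat = sum(p.statistic for p in parts)
    return TestResult(
        name="cox_joint",
        hypothesis_label="H0lambda1lambda2",
        statistic=float(stat),
        df=2,
        p_value=float(stats.chi2.sf(stat, df=2)),
        note="; ".join(p.note for p in parts if p.note),
    )


# -- Gray's test ------------------------------------------------------------

def _km_exit(time, status):
    """KM of the exit time (any event) evaluated as a left-continuous lookup."""
    te, d, n_at = _counting(time, status != 0)
    surv = np.cumprod(1.0 - d / n_at)
    return te, surv


def _counting(time, event):
    te, counts = np.unique(time[event], return_counts=True)
    d = counts.astype(float)
    u = np.sort(time)
    n_at = (u.size - np.searchsorted(u, te, side="left")).astype(float)
    return te, d, n_at


def _left_lookup(grid, values, t, fill=1.0):
    """values on [grid[k], grid[k+1]) evaluated at t-, i.e. strictly before t."""
    idx = np.searchsorted(grid, np.asarray(t, dtype=float), side="left")
    padded = np.concatenate([[fill], values])
    return padded[idx]


def gray_test(data: ObservedDataset, cause: int = 1, rho: float = 0.0) -> TestResult:
    """Gray's two-sample test of equal CIFs for the event of interest.

    The score compares group-specific subdistribution-hazard increments
    against the pooled increments, with at-risk sets ``R_j(t) = Y_j(t)
    (1 - F1_j(t-)) / S_j(t-)`` that keep prior competing-event subjects at
    risk (reweighted for censoring) and weight ``(1 - F1_pooled(t-))**rho``
    (default rho = 0).  The variance is the empirical second moment of the
    per-subject influence contributions, which include correction terms for
    the estimated group survivor and CIF curves inside R_j.
    """
    if cause == 2:
        data = ObservedDataset(
            time=data.time, status=np.where(data.status == 0, 0, 3 - data.status),
            x=data.x, tau=data.tau,
        )
    time, status, x = data.time, data.status, data.x
    ev1 = status == 1
    if not ev1.any():
        raise ValueError("no events of the cause of interest")

    # evaluation grid: every distinct disease-event time (both causes)
    tg = np.unique(time[status != 0])

    # group-specific ingredients of R_j(t-) on the grid
    R, Yg = {}, {}
    for arm in (0, 1):
        sel = x == arm
        ts, surv = _km_exit(time[sel], status[sel])
        s_left = _left_lookup(ts, surv, tg)
        te_g, d1_g, natg = _counting(time[sel], status[sel] == 1)
        s_left_own = _left_lookup(ts, surv, te_g)
        f1_left = _left_lookup(te_g, np.cumsum(s_left_own * d1_g / natg), tg, fill=0.0)
        u = np.sort(time[sel])
        y = (u.size - np.searchsorted(u, tg, side="left")).astype(float)
        Yg[arm] = y
        with np.errstate(divide="ignore", invalid="ignore"):
            R[arm] = np.where(s_left > 0, y * (1.0 - f1_left) / s_left, 0.0)

    def _d_at(mask):
        # per-grid-time event counts for a subject mask
        return np.bincount(
            np.searchsorted(tg, time[mask]), minlength=tg.size
        ).astype(float)

    d1 = {arm: _d_at(ev1 & (x == arm)) for arm in (0, 1)}
    d2 = {arm: _d_at((status == 2) & (x == arm)) for arm in (0, 1)}
    d1_tot = d1[0] + d1[1]
    d2_tot = d2[0] + d2[1]
    Rtot = R[0] + R[1]

    # pooled H0 plug-ins at t-
    ts_p, surv_p = _km_exit(time, status)
    tep, d1p, natp = _counting(time, ev1)
    F1_left = _left_lookup(
        tep, np.cumsum(_left_lookup(ts_p, surv_p, tep) * d1p / natp), tg, fill=0.0
    )
    te2, d2p, natp2 = _counting(time, status == 2)
    F2_left = _left_lookup(
        te2, np.cumsum(_left_lookup(ts_p, surv_p, te2) * d2p / natp2), tg, fill=0.0
    )

    weight = (1.0 - F1_left) ** rho
    with np.errstate(divide="ignore", invalid="ignore"):
        dlam1_sub = np.where(Rtot > 0, d1_tot / Rtot, 0.0)  # pooled subdist increments
        share = np.where(Rtot > 0, R[1] / Rtot, 0.0)
    z = float(np.sum(weight * (d1[1] - d1_tot * share)))

    # --- per-subject influence terms -------------------------------------
    # The score is the observed-minus-expected form
    #   z = integral w(t) [dN11 - (R1/Rtot) dN1tot]
    # whose martingale linearization has coefficients w*R0/Rtot (treated-arm
    # cause-1 martingale) and -w*R1/Rtot (control), plus a correction for
    # the estimated survivor/CIF curves inside R_j with kernel
    #   Ia(u) = sum_{t > u} w(t) * (R1 R0 / Rtot) dLam1_sub(t) / (1 - F1(t-)).
    with np.errstate(divide="ignore", invalid="ignore"):
        w2 = np.where(Rtot > 0, R[1] * R[0] / Rtot, 0.0)
    ia_incr = weight * w2 * dlam1_sub / np.maximum(1.0 - F1_left, 1e-12)
    Ia_after = np.concatenate([np.cumsum(ia_incr[::-1])[::-1][1:], [0.0]])

    # pooled cause-specific hazard increments (for the compensators)
    y_tot = Yg[0] + Yg[1]
    dlam1_cs = d1_tot / y_tot
    dlam2_cs = d2_tot / y_tot

    V = 0.0
    for arm, sign in ((1, 1.0), (0, -1.0)):
        with np.errstate(divide="ignore", invalid="ignore"):
            w1 = np.where(
                Rtot > 0,
                R[0] / Rtot if arm == 1 else -R[1] / Rtot,
                0.0,
            )
        ydiv = np.maximum(Yg[arm], 1.0)
        c1 = weight * w1 - sign * F2_left * Ia_after / ydiv
        c2 = -sign * (1.0 - F1_left) * Ia_after / ydiv
        sel = x == arm
        ut, st = time[sel], status[sel]
        h = np.zeros(sel.sum())
        pos = np.searchsorted(tg, ut)  # exact index for disease events
        has1 = st == 1
        h[has1] = c1[pos[has1]]
        has2 = st == 2
        h[has2] = c2[pos[has2]]
        # compensator: minus cumulative sums over grid times <= u_i
        comp = np.concatenate([[0.0], np.cumsum(c1 * dlam1_cs + c2 * dlam2_cs)])
        h -= comp[np.searchsorted(tg, ut, side="right")]
        V += float(np.sum(h**2))

    stat = z**2 / V if V > 0 else math.nan
    return TestResult(
        name="gray",
        hypothesis_label="H0F1",
        statistic=float(stat),
        df=1,
        p_value=float(stats.chi2.sf(stat, df=1)),
        note=f"score={z:.6g}, var={V:.6g}",
    )


# -- sample size ------------------------------------------------------------

def latouche_sample_size(
    inputs: SampleSizeInputs | None = None,
    *,
    beta1: float | None = None,
    p_obs: float | None = None,
    omega: float = 0.05,
    power: float = 0.8,
    p_x: float = 0.5,
) -> tuple[int, float]:
    """Sample size for a two-sided FG Wald test of beta = 0 against beta1.

    n = (z_{1-omega/2} + z_{power})^2 / (P(T1<=C) * beta1^2 * P(X=1) P(X=0))

    Returns (ceiling, unrounded value).
    """
    if inputs is None:
        inputs = SampleSizeInputs(
            beta1=beta1, p_obs=p_obs, omega=omega, power=power, p_x=p_x
        )
    if inputs.beta1 is None or inputs.beta1 == 0:
        raise ValueError("beta1 must be nonzero")
    if not 0 < inputs.p_obs <= 1:
        raise ValueError("p_obs must be in (0, 1]")
    if not 0 < inputs.omega < 1 or not 0 < inputs.power < 1:
        raise ValueError("omega and power must be in (0, 1)")
    za = stats.norm.ppf(1.0 - inputs.omega / 2.0)
    zb = stats.norm.ppf(inputs.power)
    raw = (za + zb) ** 2 / (
        inputs.p_obs * inputs.beta1**2 * inputs.p_x * (1.0 - inputs.p_x)
    )
    return int(math.ceil(raw)), float(raw)
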