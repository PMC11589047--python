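"""Inverse-probability-of-censoring weighting (IPCW).

Estimates the survivor function ``G(u) = P(Cr > u)`` of the random
withdrawal time by Kaplan-Meier with reversed roles (withdrawals are the
events, disease events censor), and builds the weights and weighted
responses shared by the Fine-Gray and direct-binomial procedures.

Conventions: the estimate is a right-continuous step function; weights
evaluate it at the left limit ``Ghat(u-)`` so that a subject withdrawn at a
jump point keeps a finite weight.  At a time shared by a disease event and a
withdrawal, the disease event is processed first (it leaves the risk set for
the withdrawal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import ObservedDataset

__all__ = ["CensoringEstimate", "km_censoring", "ipcw_weight", "weighted_response"]


@dataclass
class _StepSurvivor:
    """Right-continuous nonincreasing step function with value 1 at 0-."""

    jump_times: np.ndarray  # sorted, unique
    values: np.ndarray      # value on [jump_times[k], jump_times[k+1])

    def _eval(self, u, side):
        u = np.asarray(u, dtype=float)
        if self.jump_times.size == 0:
            return np.ones(u.shape)
        idx = np.searchsorted(self.jump_times, u, side=side)
        padded = np.concatenate([[1.0], self.values])
        return padded[idx]

    def __call__(self, u):
        return self._eval(u, "right")

    def left(self, u):
        """Left limit: value just before u."""
        return self._eval(u, "left")


def _km_reversed(time: np.ndarray, status: np.ndarray) -> _StepSurvivor:
    """KM for the withdrawal time: status==0 records are its events.

    Tied disease events at a withdrawal time are removed from the risk set
    before the withdrawal is processed.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    is_cens_event = status[order] == 0
    uniq, start = np.unique(t, return_index=True)
    counts = np.diff(np.append(start, len(t)))
    # events (withdrawals) and disease events at each unique time
    cum_cens = np.cumsum(is_cens_event)
    ends = start + counts - 1
    d_cens = cum_cens[ends] - np.where(start > 0, cum_cens[start - 1], 0)
    d_disease = counts - d_cens
    n_at_risk = len(t) - np.concatenate(([0], np.cumsum(counts)[:-1]))
    risk_for_withdrawal = n_at_risk - d_disease  # disease events precede
    has_event = d_cens > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(
            has_event & (risk_for_withdrawal > 0),
            1.0 - d_cens / np.maximum(risk_for_withdrawal, 1),
            1.0,
        )
    surv = np.cumprod(factors)
    keep = has_event
    if not keep.any():
        return _StepSurvivor(np.array([]), np.array([]))
    return _StepSurvivor(uniq[keep], surv[keep])


@dataclass
class CensoringEstimate:
    """Estimated censoring survivor function, optionally stratified by arm."""

    overall: _StepSurvivor
    by_arm: dict | None = None

    @property
    def stratified(self) -> bool:
        return self.by_arm is not None

    def ghat(self, u, x=None):
        """Right-continuous evaluation of Ghat(u) (per-arm if stratified)."""
        if not self.stratified:
            return self.overall(u)
        return self._eval(u, x, left=False)

    def ghat_left(self, u, x=None):
        """Left-limit evaluation Ghat(u-), the value used in weights."""
        if not self.stratified:
            return self.overall.left(u)
        return self._eval(u, x, left=True)

    def _eval(self, u, x, left):
        u = np.asarray(u, dtype=float)
        x = np.broadcast_to(np.asarray(x, dtype=int), u.shape)
        out = np.empty(u.shape)
        for arm, fn in self.by_arm.items():
            mask = x == arm
            out[mask] = fn.left(u[mask]) if left else fn(u[mask])
        return out


def km_censoring(data: ObservedDataset, strata: bool = False) -> CensoringEstimate:
    """Kaplan-Meier estimate of ``G(u) = P(Cr > u)`` with role reversal.

    ``strata=True`` fits separate curves per treatment arm; the default
    (unstratified) matches a common censoring distribution across arms.
    """
    if len(data) == 0:
        raise ValueError("dataset is empty")
    overall = _km_reversed(data.time, data.status)
    if not strata:
        return CensoringEstimate(overall=overall)
    by_arm = {
        arm: _km_reversed(data.time[data.x == arm], data.status[data.x == arm])
        for arm in (0, 1)
    }
    return CensoringEstimate(overall=overall, by_arm=by_arm)


def _check_positive(gvals, times):
    bad = gvals <= 0
    if np.any(bad):
        t_bad = np.atleast_1d(times)[np.atleast_1d(bad)][0]
        raise ValueError(
            f"censoring survivor estimate is 0 at time {t_bad:g}; weight undefined"
        )


def ipcw_weight(
    time,
    status,
    t,
    ghat: CensoringEstimate,
    tau: float,
    style: str = "standard",
    x=None,
):
    """IPCW weight ``w(t)`` of records with observed (time, status).

    standard:   w(t) = 1(t <= tau) * 1(not lost before min(T, t)) / Ghat(min(T,t)-)
    stabilized: the standard weight multiplied by Ghat(t-).

    A record with a disease event (status 1 or 2) has known T = time and was
    observed, so the loss indicator is 1 and the weight freezes at the event
    time.  A record withdrawn at ``time`` contributes only while t <= time.
    Vectorized over records; ``t`` may be a scalar or a matching array.
    """
    if style not in ("standard", "stabilized"):
        raise ValueError(f"unknown weight style {style!r}")
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    t = np.broadcast_to(np.asarray(t, dtype=float), time.shape)
    known_T = status != 0
    anchor = np.where(known_T, np.minimum(time, t), t)
    at_risk = np.where(known_T, True, t <= time)
    in_window = t <= tau
    active = at_risk & in_window
    gvals = np.asarray(ghat.ghat_left(anchor, x=x), dtype=float)
    _check_positive(gvals[active], anchor[active] if anchor.shape else anchor)
    w = np.zeros(time.shape)
    np.divide(1.0, gvals, out=w, where=active & (gvals > 0))
    if style == "stabilized":
        w = w * np.asarray(ghat.ghat_left(t, x=x), dtype=float)
    return w


def weighted_response(
    time,
    status,
    sr: float,
    ghat: CensoringEstimate,
    x=None,
):
    """IPCW-weighted state-1 occupancy indicator at grid time ``sr``.

    ``Ntilde_1(sr) = 1(not lost before min(T, sr)) * N1(sr) / Ghat(min(T,sr)-)``;
    it is nonzero only for observed type-1 events by ``sr`` and then equals
    ``1 / Ghat(T-)``, which has the same expectation as the (possibly
    unobservable) indicator ``N1(sr)`` under independent censoring.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    event_by_sr = (status == 1) & (time <= sr)
    out = np.zeros(time.shape)
    if np.any(event_by_sr):
        gvals = np.asarray(
            ghat.ghat_left(
                time[event_by_sr],
                x=None if x is None else np.asarray(x)[event_by_sr],
            ),
            dtype=float,
        )
        _check_positive(gvals, time[event_by_sr])
        out[event_by_sr] = 1.0 / gvals
    return out
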