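"""Fine-Gray estimation of the cloglog CIF model for a binary treatment.

The subdistribution-hazard form of the model is a proportional hazards model
for the improper time ``T1``: subjects with a prior competing event stay in
the risk set, and inverse-probability-of-censoring weights handle the fact
that ``N1(t)`` is unknown for subjects lost to follow-up.  Estimation solves
the weighted partial pseudo-score by Newton-Raphson; the baseline cumulative
subdistribution hazard is the Breslow-type accumulation at the solution.

The robust (sandwich) variance combines per-subject score residuals with an
additional term for the uncertainty of the Kaplan-Meier censoring-survivor
estimate, derived from the KM influence function; a subject-resampling
bootstrap (which refits the censoring estimate in every resample) is
available as an alternative.

A time-varying treatment effect ``beta(t) = beta + nu * b(t)`` is supported
for goodness-of-fit checking: because the only covariate is binary, the
model with covariates (X, X*b(t)) is fit by the same engine with the arm-1
log relative risk ``beta + nu * b(t)`` evaluated at each event time.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .ipcw import CensoringEstimate, km_censoring
from .simulate import ObservedDataset

__all__ = [
    "FineGrayRegression",
    "fg_fit",
    "fg_robust_variance",
    "fg_timevarying_fit",
    "FGDivergedError",
]


class FGDivergedError(RuntimeError):
    """Raised when the pseudo-likelihood is monotone (diverging coefficient)."""


_B_FORMS = {
    "t": lambda t: t,
    "logt": lambda t: np.log(t),
}


def _resolve_bform(b_form):
    if b_form is None:
        return None
    if callable(b_form):
        return b_form
    try:
        return _B_FORMS[b_form]
    except KeyError:
        raise ValueError(f"unknown b_form {b_form!r}; use 't', 'logt' or a callable")


@dataclass
class _Engine:
    """All per-event and per-arm arrays needed by the FG pseudo-score."""

    te: np.ndarray        # sorted type-1 event times
    xe: np.ndarray        # treatment of the subject failing at te
    phi: np.ndarray       # (m, d) time basis at event times
    w_event: np.ndarray   # weight of each event's own jump
    base: dict            # arm -> (m,) weighted at-risk totals at te
    g_left_te: dict       # arm -> Ghat(te-)
    n_free: dict          # arm -> count with u_i >= te
    p2: dict              # arm -> prefix sums over prior type-2 subjects
    style: str


def _build_engine(time, status, x, ghat: CensoringEstimate, tau, style, bfun):
    ev = status == 1
    if not ev.any():
        raise ValueError("no type-1 events in the data")
    order = np.argsort(time[ev], kind="stable")
    te = time[ev][order]
    xe = x[ev][order]
    m = te.size
    phi = np.ones((m, 1)) if bfun is None else np.column_stack([np.ones(m), bfun(te)])

    base, g_left_te, n_free, p2 = {}, {}, {}, {}
    for arm in (0, 1):
        sel = x == arm
        u_arm = np.sort(time[sel])
        g_te = np.asarray(ghat.ghat_left(te, x=arm), dtype=float)
        if np.any(g_te <= 0):
            raise ValueError("censoring survivor estimate reaches 0 before an event time")
        n_at = u_arm.size - np.searchsorted(u_arm, te, side="left")
        u2 = time[sel & (status == 2)]
        o2 = np.argsort(u2)
        u2 = u2[o2]
        inv_g2 = 1.0 / np.asarray(ghat.ghat_left(u2, x=arm), dtype=float)
        cum2 = np.concatenate(([0.0], np.cumsum(inv_g2)))
        p2_arm = cum2[np.searchsorted(u2, te, side="left")]
        if style == "standard":
            base[arm] = n_at / g_te + p2_arm
        else:
            base[arm] = n_at + g_te * p2_arm
        g_left_te[arm] = g_te
        n_free[arm] = n_at
        p2[arm] = (u2, inv_g2, cum2)

    if style == "standard":
        g_ev = np.asarray(ghat.ghat_left(te, x=xe), dtype=float)
        w_event = 1.0 / g_ev
    else:
        w_event = np.ones(m)
    return _Engine(te, xe, phi, w_event, base, g_left_te, n_free, p2, style)


def _score_info(eng: _Engine, theta):
    lp1 = eng.phi @ theta  # arm-1 log relative risk at each event time
    exp1 = np.exp(lp1)
    s0 = eng.base[0] + exp1 * eng.base[1]
    share1 = exp1 * eng.base[1] / s0            # (m,)
    xbar = eng.phi * share1[:, None]            # (m, d) = S1/S0
    z_event = eng.xe[:, None] * eng.phi
    U = ((z_event - xbar) * eng.w_event[:, None]).sum(axis=0)
    # S2/S0 = phi phi' * share1 ; I = sum w (S2/S0 - xbar xbar')
    d = eng.phi.shape[1]
    I = np.zeros((d, d))
    wshare = eng.w_event * share1
    phiw = eng.phi * wshare[:, None]
    I += eng.phi.T @ phiw
    xbw = xbar * eng.w_event[:, None]
    I -= xbar.T @ xbw
    return U, I, s0, xbar, share1


def _newton(eng: _Engine, tol=1e-10, max_iter=50):
    d = eng.phi.shape[1]
    theta = np.zeros(d)
    U, I, s0, xbar, share1 = _score_info(eng, theta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.abs(U).max() < tol:
            break
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            raise FGDivergedError("singular information matrix (collinear time basis?)")
        scale = 1.0
        base_norm = np.linalg.norm(U)
        for _ in range(25):
            cand = theta + scale * step
            Uc, Ic, s0c, xbarc, share1c = _score_info(eng, cand)
            if np.linalg.norm(Uc) < base_norm:
                theta, U, I, s0, xbar, share1 = cand, Uc, Ic, s0c, xbarc, share1c
                break
            scale *= 0.5
        else:
            break
        if np.abs(theta).max() > 25:
            raise FGDivergedError(
                "coefficient diverging: monotone pseudo-likelihood "
                "(no type-1 events in one arm?)"
            )
    converged = bool(np.abs(U).max() < 1e-8)
    return theta, U, I, s0, xbar, share1, n_iter, converged


def _residuals(eng, theta, time, status, x, ghat, dgamma, xbar):
    """Per-subject score residuals eta_i (n, d)."""
    n = time.size
    d = eng.phi.shape[1]
    te = eng.te
    eta = np.zeros((n, d))

    # own-event term
    ev = status == 1
    order = np.argsort(time[ev], kind="stable")
    idx_ev = np.flatnonzero(ev)[order]
    eta[idx_ev] = (eng.xe[:, None] * eng.phi - xbar) * eng.w_event[:, None]

    exp1 = np.exp(eng.phi @ theta)
    for arm in (0, 1):
        sel = x == arm
        coef = exp1 if arm == 1 else np.ones_like(exp1)
        vec = coef[:, None] * (arm * eng.phi - xbar) * dgamma[:, None]  # (m, d)
        g_te = eng.g_left_te[arm]
        wf = (1.0 / g_te) if eng.style == "standard" else np.ones_like(g_te)
        pre = np.concatenate([np.zeros((1, d)), np.cumsum(vec * wf[:, None], axis=0)])
        # events at te <= u_i contribute while the subject is event-free
        pos = np.searchsorted(te, time[sel], side="right")
        eta[sel] -= pre[pos]
        # prior-type-2 tail: events at te > u_i with frozen weight 1/Ghat(u_i-)
        sel2 = sel & (status == 2)
        if sel2.any():
            ct = g_te if eng.style == "stabilized" else np.ones_like(g_te)
            tail = np.concatenate(
                [np.cumsum((vec * ct[:, None])[::-1], axis=0)[::-1], np.zeros((1, d))]
            )
            pos2 = np.searchsorted(te, time[sel2], side="right")
            inv_g_u = 1.0 / np.asarray(ghat.ghat_left(time[sel2], x=arm), dtype=float)
            eta[sel2] -= inv_g_u[:, None] * tail[pos2]
    return eta


def _censoring_psi(eng, theta, time, status, x, ghat, dgamma, xbar):
    """Per-subject censoring-estimation terms psi_i (n, d).

    Derived from the first-order expansion of the score in the KM censoring
    estimate: psi_i = integral of q(s)/pi(s) with respect to subject i's
    censoring martingale, where q(s) collects the sensitivity of every
    weighted score term to the censoring survivor at s.  Only the
    unstratified KM case is covered (the only one exercised here).
    """
    n = time.size
    d = eng.phi.shape[1]
    te = eng.te
    m = te.size
    exp1 = np.exp(eng.phi @ theta)

    # censoring "events" (withdrawals) and at-risk counts for the censoring KM
    cens_times = np.sort(time[status == 0])
    if cens_times.size == 0:
        return np.zeros((n, d))
    sc, d_c = np.unique(cens_times, return_counts=True)
    u_all = np.sort(time)
    nrisk_sc = n - np.searchsorted(u_all, sc, side="left")

    # tail sums over event times (te >= s) of the q(s) building blocks
    def tail(arr):  # arr (m, d) -> cumulative sums from the right, padded
        return np.concatenate([np.cumsum(arr[::-1], axis=0)[::-1], np.zeros((1, d))])

    pos_sc = np.searchsorted(te, sc, side="left")

    q = np.zeros((sc.size, d))
    for arm in (0, 1):
        coef = exp1 if arm == 1 else np.ones_like(exp1)
        vec = coef[:, None] * (arm * eng.phi - xbar) * dgamma[:, None]  # (m, d)
        g_te = eng.g_left_te[arm]
        u2, inv_g2, cum2 = eng.p2[arm]
        q_arm_at_s = cum2[np.searchsorted(u2, sc, side="left")]  # sum 1/G(u-) u<s
        if eng.style == "stabilized":
            tail_g = tail(vec * g_te[:, None])
            q -= q_arm_at_s[:, None] * tail_g[pos_sc]
        else:
            # compensator: event-free + all prior type-2 at te, minus type-2
            # with u < s; enters dMhat with a minus sign
            p2_te = cum2[np.searchsorted(u2, te, side="left")]
            full = vec * (eng.n_free[arm] / g_te + p2_te)[:, None]
            q -= tail(full)[pos_sc]
            q += q_arm_at_s[:, None] * tail(vec)[pos_sc]
    if eng.style == "standard":
        ev_term = (eng.xe[:, None] * eng.phi - xbar) * eng.w_event[:, None]
        q += tail(ev_term)[pos_sc]
    q /= n

    # psi_i = 1(withdrawn at u_i) q(u_i)/pi(u_i) - sum_{sc <= u_i} q/pi * dLambda_c
    pi_sc = nrisk_sc / n
    ratio = q / pi_sc[:, None]
    psi = np.zeros((n, d))
    wd = status == 0
    pos_u = np.searchsorted(sc, time[wd])
    psi[wd] = ratio[pos_u]
    dlam = d_c / nrisk_sc
    comp = np.concatenate([np.zeros((1, d)), np.cumsum(ratio * dlam[:, None], axis=0)])
    psi -= comp[np.searchsorted(sc, time, side="right")]
    return psi


def _as_arrays(X, y, tau):
    """Accept ObservedDataset, (X, y) arrays, or DataFrame-style input."""
    if isinstance(X, ObservedDataset):
        data = X
        return data.time, data.status, data.x, data.tau
    Xa = np.asarray(X)
    if Xa.ndim == 2:
        if Xa.shape[1] != 1:
            raise ValueError("only a single binary treatment column is supported")
        Xa = Xa[:, 0]
    xv = Xa.astype(int)
    if not np.isin(xv, [0, 1]).all():
        raise ValueError("treatment must be binary 0/1")
    if hasattr(y, "dtype") and getattr(y.dtype, "names", None):
        status = np.asarray(y["status"], dtype=int)
        time = np.asarray(y["time"], dtype=float)
    else:
        ya = np.asarray(y, dtype=float)
        if ya.ndim != 2 or ya.shape[1] != 2:
            raise ValueError(
                "y must be a structured array with fields (status, time) "
                "or an (n, 2) array of [time, status]"
            )
        time, status = ya[:, 0], ya[:, 1].astype(int)
    tau = float(np.max(time)) if tau is None else float(tau)
    return time, status, xv, tau


class FineGrayRegression:
    """Fine-Gray cloglog CIF regression for a binary treatment.

    scikit-learn style estimator: construct with hyperparameters, call
    ``fit(X, y)`` where ``X`` holds the binary treatment and ``y`` the
    (time, status) outcome (status 0 censored, 1 event of interest,
    2 competing event); an :class:`~cifmiss.simulate.ObservedDataset` can be
    passed directly as ``fit(data)``.

    Parameters
    ----------
    weight_style : "stabilized" | "standard"
        IPCW style.  Stabilized weights multiply by Ghat(t-), the convention
        of the reference Fine-Gray software; both give consistent estimates
        under a correct model.
    cens_strata : bool
        Estimate the censoring survivor separately per arm.
    b_form : None | "t" | "logt" | callable
        When set, fits the extended model beta(t) = beta + nu * b(t) and
        reports a Wald test of the time-constant effect (nu = 0).
    variance : "robust" | "none"
        Sandwich variance including the censoring-estimation term (falls
        back to the score-only sandwich when the censoring KM is stratified).

    Attributes (after fit)
    ----------------------
    coef_ : (d,) estimated coefficients (beta, and nu when b_form is set)
    se_robust_, var_robust_ : sandwich standard errors / covariance
    se_naive_ : inverse-information standard errors
    info_, omega_ : curvature and middle matrix of the sandwich
    baseline_times_, baseline_cumhaz_ : Breslow step function of Gamma(t)
    n_iter_, converged_, score_norm_ : Newton diagnostics
    wald_nu_, p_value_nu_ : time-constant-effect test (b_form fits only)
    """

    def __init__(
        self,
        weight_style: str = "stabilized",
        cens_strata: bool = False,
        b_form=None,
        variance: str = "robust",
        tol: float = 1e-10,
        max_iter: int = 50,
    ):
        self.weight_style = weight_style
        self.cens_strata = cens_strata
        self.b_form = b_form
        self.variance = variance
        self.tol = tol
        self.max_iter = max_iter

    # -- sklearn plumbing --------------------------------------------------
    def get_params(self, deep=True):
        return {
            "weight_style": self.weight_style,
            "cens_strata": self.cens_strata,
            "b_form": self.b_form,
            "variance": self.variance,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y=None, tau=None, ghat: CensoringEstimate | None = None):
        if self.weight_style not in ("standard", "stabilized"):
            raise ValueError(f"unknown weight style {self.weight_style!r}")
        time, status, x, tau = _as_arrays(X, y, tau)
        data = ObservedDataset(time=time, status=status, x=x, tau=tau)
        if ghat is None:
            ghat = km_censoring(data, strata=self.cens_strata)
        bfun = _resolve_bform(self.b_form)
        eng = _build_engine(time, status, x, ghat, tau, self.weight_style, bfun)
        theta, U, I, s0, xbar, share1, n_iter, converged = _newton(
            eng, tol=self.tol, max_iter=self.max_iter
        )
        dgamma = eng.w_event / s0
        self.coef_ = theta
        self.info_ = I
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.score_norm_ = float(np.abs(U).max())
        self.baseline_times_ = eng.te
        self.baseline_cumhaz_ = np.cumsum(dgamma)
        self.tau_ = tau
        self.ghat_ = ghat
        self.n_ = time.size
        try:
            Iinv = np.linalg.inv(I)
        except np.linalg.LinAlgError:  # degenerate design (e.g. single arm)
            Iinv = np.linalg.pinv(I)
        with np.errstate(invalid="ignore"):
            self.se_naive_ = np.sqrt(np.diag(Iinv))
        if self.variance == "robust":
            eta = _residuals(eng, theta, time, status, x, ghat, dgamma, xbar)
            if ghat.stratified:
                infl = eta  # censoring-estimation term available unstratified only
            else:
                infl = eta + _censoring_psi(
                    eng, theta, time, status, x, ghat, dgamma, xbar
                )
            omega = infl.T @ infl
            self.omega_ = omega
            self.var_robust_ = Iinv @ omega @ Iinv
            self.se_robust_ = np.sqrt(np.diag(self.var_robust_))
        if bfun is not None:
            self.wald_nu_ = float(self.coef_[1] ** 2 / self.var_robust_[1, 1])
            from scipy import stats

            self.p_value_nu_ = float(stats.chi2.sf(self.wald_nu_, df=1))
        return self

    # -- post-fit API ------------------------------------------------------
    @property
    def beta_(self) -> float:
        return float(self.coef_[0])

    def cumhaz(self, t) -> np.ndarray:
        """Breslow estimate of the baseline cumulative subdistribution hazard."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.baseline_times_, t, side="right")
        padded = np.concatenate([[0.0], self.baseline_cumhaz_])
        return padded[idx]

    def predict_cif(self, x, t) -> np.ndarray:
        """Fitted F1(t | x) = 1 - exp(-Gamma(t) exp(beta x)) (constant-effect fit)."""
        if self.b_form is not None:
            raise ValueError("predict_cif is defined for the constant-effect model")
        return -np.expm1(-self.cumhaz(t) * np.exp(self.beta_ * np.asarray(x)))

    def wald(self) -> tuple[float, float]:
        """Robust Wald z and two-sided p-value for beta = 0."""
        from scipy import stats

        z = self.beta_ / self.se_robust_[0]
        return float(z), float(2 * stats.norm.sf(abs(z)))


def fg_fit(
    data: ObservedDataset,
    ghat: CensoringEstimate | None = None,
    weight_style: str = "stabilized",
    **kwargs,
) -> FineGrayRegression:
    """Fit the constant-effect FG model to an observed dataset."""
    model = FineGrayRegression(weight_style=weight_style, **kwargs)
    return model.fit(data, ghat=ghat)


def fg_timevarying_fit(
    data: ObservedDataset,
    ghat: CensoringEstimate | None = None,
    b_form="t",
    weight_style: str = "stabilized",
    **kwargs,
) -> FineGrayRegression:
    """Fit the extended model beta(t) = beta + nu b(t); Wald test of nu = 0."""
    model = FineGrayRegression(weight_style=weight_style, b_form=b_form, **kwargs)
    return model.fit(data, ghat=ghat)


def fg_robust_variance(
    fit: FineGrayRegression,
    data: ObservedDataset | None = None,
    method: str = "sandwich",
    n_boot: int = 500,
    rng_seed=0,
) -> np.ndarray:
    """Robust SE of the coefficients: analytic sandwich or subject bootstrap.

    The bootstrap resamples subjects with replacement and re-estimates both
    the censoring survivor and the coefficients in every resample, so the
    uncertainty of Ghat is propagated.
    """
    if method == "sandwich":
        return fit.se_robust_
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}")
    if data is None:
        raise ValueError("bootstrap requires the original dataset")
    rng = np.random.default_rng(rng_seed)
    n = len(data)
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = ObservedDataset(
            time=data.time[idx], status=data.status[idx], x=data.x[idx], tau=data.tau
        )
        try:
            refit = FineGrayRegression(**fit.get_params()).set_params(
                variance="none"
            ).fit(boot)
        except (FGDivergedError, ValueError):
            continue
        draws.append(refit.coef_)
    draws = np.asarray(draws)
    return draws.std(axis=0, ddof=1)
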