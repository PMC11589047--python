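"""Scenario configuration, rejection-rate studies, and estimand surfaces.

One replicate = simulate a trial (latent draws, calibrated exponential
withdrawal, administrative censoring), run the requested battery of tests,
and record rejections at the nominal level.  Per-replicate random streams
are derived from (master seed, scenario id, replicate index), so results do
not depend on how replicates are distributed over workers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from .db import db_fit
from .estimands import db_limit, fg_limit
from .fg import FGDivergedError, fg_fit
from .hyptests import (
    cox_cause_specific_wald,
    gray_test,
    joint_cox_wald,
    logrank_cause_specific,
)
from .ipcw import km_censoring
from .process import (
    TrueProcess,
    calibrate_cif_process,
    calibrate_intensity_process,
    process_from_dict,
)
from .simulate import CensoringSpec, apply_censoring, calibrate_censoring_rate, draw_competing_risks

__all__ = [
    "ScenarioConfig",
    "RejectionTable",
    "load_scenario",
    "process_from_config",
    "run_rejection_study",
    "estimand_surface",
    "DEFAULT_TESTS",
]

DEFAULT_TESTS = ("lr1", "cox1", "coxjoint", "gray", "fg", "db6", "db3")


@dataclass
class ScenarioConfig:
    """One Monte-Carlo scenario: a true process plus study-design knobs."""

    process: TrueProcess
    n: int = 1000
    nsim: int = 2000
    pi_r: float = 0.2
    p_x: float = 0.5
    grid_R: Sequence[int] = (6, 3)
    tests: Sequence[str] = DEFAULT_TESTS
    seed: int = 1
    scenario_id: int = 0
    omega: float = 0.05

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.nsim < 1:
            raise ValueError("nsim must be at least 1")


def process_from_config(spec: dict) -> TrueProcess:
    """Build a process from a config block, calibrated or explicit.

    Intensity family: either explicit {lambda1, lambda2, gamma1, gamma2} or
    calibrated {p_exit, p_type1, exp_g1, exp_g2}.  CIF family: either
    explicit {q, beta, beta2, family} or calibrated {f1_at_tau, exp_b,
    exp_b2, family}.
    """
    spec = dict(spec)
    kind = spec.pop("kind", "intensity")
    tau = float(spec.pop("tau", 1.0))
    if kind == "intensity":
        if "p_exit" in spec:
            return calibrate_intensity_process(
                p_exit=spec["p_exit"],
                p_type1=spec["p_type1"],
                exp_g1=spec.get("exp_g1", 1.0),
                exp_g2=spec.get("exp_g2", 1.0),
                tau=tau,
            )
        return process_from_dict({"kind": "intensity", "tau": tau, **spec})
    if kind == "cif":
        if "f1_at_tau" in spec:
            return calibrate_cif_process(
                f1_at_tau=spec["f1_at_tau"],
                exp_b=spec.get("exp_b", 1.0),
                exp_b2=spec.get("exp_b2", 1.0),
                family=spec.get("family", "extended"),
                tau=tau,
            )
        return process_from_dict({"kind": "cif", "tau": tau, **spec})
    raise ValueError(f"unknown process kind {kind!r}")


def load_scenario(path) -> ScenarioConfig:
    """Read a YAML scenario file into a :class:`ScenarioConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "process" not in raw:
        raise ValueError("scenario file must be a mapping with a 'process' block")
    process = process_from_config(raw["process"])
    kwargs = {
        k: raw[k]
        for k in ("n", "nsim", "pi_r", "p_x", "grid_R", "tests", "seed", "omega")
        if k in raw
    }
    return ScenarioConfig(process=process, **kwargs)


@dataclass
class RejectionTable:
    """Result of a rejection-rate study."""

    table: pd.DataFrame              # columns: test, rate, mc_se, n_fail
    beta_star: dict                  # computed limiting values, no simulation
    config: ScenarioConfig

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        for key, val in self.beta_star.items():
            out[key] = val
        return out


def _one_replicate(process, n, rho, p_x, tau, tests, omega, seed_key):
    rng = np.random.default_rng(seed_key)
    latent = draw_competing_risks(n, process, p_x=p_x, rng_seed=rng)
    data = apply_censoring(latent, CensoringSpec(rho=rho, tau=tau), rng_seed=rng)
    out = {}
    ghat = km_censoring(data) if any(t in tests for t in ("fg", "db6", "db3")) else None
    for t in tests:
        try:
            if t == "lr1":
                out[t] = logrank_cause_specific(data, 1).p_value < omega
            elif t == "cox1":
                out[t] = cox_cause_specific_wald(data, 1).p_value < omega
            elif t == "coxjoint":
                out[t] = joint_cox_wald(data).p_value < omega
            elif t == "gray":
                out[t] = gray_test(data, 1).p_value < omega
            elif t == "fg":
                out[t] = fg_fit(data, ghat=ghat).wald()[1] < omega
            elif t in ("db6", "db3"):
                out[t] = db_fit(data, R=int(t[2:]), ghat=ghat).wald()[1] < omega
            else:
                raise ValueError(f"unknown test {t!r}")
        except (FGDivergedError, ValueError, np.linalg.LinAlgError) as exc:
            out[t] = None
            out[f"_err_{t}"] = str(exc)
    return out


def _limits_for(config: ScenarioConfig, rho: float) -> dict:
    """Limiting values matching the study design (stabilized FG weights)."""
    out = {}
    try:
        out["beta_star_fg"] = fg_limit(
            config.process, p_x=config.p_x, censoring_survivor=rho
        ).beta_star
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        out["beta_star_fg"] = np.nan
        warnings.warn(f"FG limit failed: {exc}", stacklevel=2)
    for R in config.grid_R:
        try:
            out[f"beta_star_db{R}"] = db_limit(
                config.process, p_x=config.p_x, R=R
            ).beta_star
        except (RuntimeError, ValueError) as exc:  # pragma: no cover
            out[f"beta_star_db{R}"] = np.nan
            warnings.warn(f"DB limit failed: {exc}", stacklevel=2)
    return out


def run_rejection_study(
    config: ScenarioConfig,
    n_jobs: int = 1,
    compute_limits: bool = True,
) -> RejectionTable:
    """Monte-Carlo rejection rates for the configured battery of tests.

    Replicate-level fit failures are counted as non-rejections (conservative
    for size studies) and reported in the ``n_fail`` column.
    """
    process, tau = config.process, config.process.tau
    rho = calibrate_censoring_rate(process, tau, config.pi_r, config.p_x)
    keys = [
        (config.seed, config.scenario_id, rep) for rep in range(config.nsim)
    ]
    results = Parallel(n_jobs=n_jobs)(
        delayed(_one_replicate)(
            process, config.n, rho, config.p_x, tau, tuple(config.tests),
            config.omega, key,
        )
        for key in keys
    )
    rows = []
    for t in config.tests:
        vals = [r[t] for r in results]
        n_fail = sum(v is None for v in vals)
        rej = np.array([bool(v) for v in vals])  # None -> False (non-rejection)
        rate = rej.mean()
        rows.append(
            {
                "test": t,
                "rate": rate,
                "mc_se": float(np.sqrt(rate * (1 - rate) / config.nsim)),
                "n_fail": n_fail,
            }
        )
    beta_star = _limits_for(config, rho) if compute_limits else {}
    return RejectionTable(table=pd.DataFrame(rows), beta_star=beta_star, config=config)


def estimand_surface(
    exp_g2_values: Iterable[float],
    p_type1_values: Iterable[float],
    exp_g1_values: Iterable[float] = (1.0, 0.75, 0.6),
    method: str = "fg",
    grid_R: int = 6,
    p_exit: float = 0.6,
    tau: float = 1.0,
    p_x: float = 0.5,
    pi_r: float | None = 0.2,
) -> pd.DataFrame:
    """Deterministic surface of exp(beta_star) over a grid of true processes.

    For the FG method, ``pi_r`` selects the withdrawal fraction whose
    calibrated exponential survivor enters the stabilized-weight limit (None
    gives the censoring-free standard-weight limit).  Solver failures at a
    grid point are recorded as NaN.
    """
    rows = []
    for eg1 in exp_g1_values:
        for p1 in p_type1_values:
            for eg2 in exp_g2_values:
                process = calibrate_intensity_process(p_exit, p1, eg1, eg2, tau=tau)
                try:
                    if method == "fg":
                        rho = (
                            calibrate_censoring_rate(process, tau, pi_r, p_x)
                            if pi_r
                            else None
                        )
                        bstar = fg_limit(
                            process, p_x=p_x, censoring_survivor=rho
                        ).beta_star
                    elif method == "db":
                        bstar = db_limit(process, p_x=p_x, R=grid_R).beta_star
                    else:
                        raise ValueError(f"unknown method {method!r}")
                except RuntimeError:
                    bstar = np.nan
                rows.append(
                    {
                        "exp_g1": eg1,
                        "exp_g2": eg2,
                        "p_type1": p1,
                        "method": method if method == "fg" else f"db{grid_R}",
                        "beta_star": bstar,
                        "exp_beta_star": float(np.exp(bstar)),
                    }
                )
    return pd.DataFrame(rows)
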