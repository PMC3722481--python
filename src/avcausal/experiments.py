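"""Experiment drivers: trial simulation, proportion-of-unity curves,
localization-bias curves, integration thresholds and parameter sweeps.

Disparity experiments place the sources symmetrically, S_V = -D/2 and
S_A = +D/2, which keeps both bumps well away from the strip edges for every
disparity on the default grid.  Each trial draws sensed positions, builds
the noisy input, runs the recurrent dynamics to convergence and reads out
the bump count, position estimates and localization bias.

Reproducibility: a master seed spawns one independent random stream per
trial (NumPy ``SeedSequence`` spawning, indexed by trial counter), so the
per-trial CSV is bitwise reproducible for a given configuration and the
trials are embarrassingly parallel in principle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import bayes as bayes_mod
from .network import (
    ConnectivityParams,
    NetworkGeometry,
    build_connectivity,
    build_geometry,
    run_dynamics,
)
from .readout import (
    InvalidTrialError,
    TrialOutcome,
    assign_positions,
    classify_cause,
    detect_bumps,
    localization_bias,
)
from .stimulus import StimulusConfig, make_trial_input

__all__ = [
    "NetworkModel",
    "ExperimentConfig",
    "SweepResult",
    "MODEL_NAMES",
    "make_model",
    "integration_threshold_net",
    "proportion_integration_closed_form",
    "run_trials",
    "run_unity_curve",
    "run_bias_experiment",
    "summarize_unity",
    "summarize_bias",
    "threshold_sweep",
    "DEFAULT_DISPARITIES",
    "BIAS_DISPARITIES",
]

logger = logging.getLogger(__name__)

#: Disparity grid used for proportion-of-unity curves (deg).
DEFAULT_DISPARITIES: tuple[float, ...] = tuple(np.arange(0.0, 30.1, 2.5))
#: Disparity grid used for bias curves (D=0 excluded: bias is undefined there).
BIAS_DISPARITIES: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

ModelName = Literal["network-linear", "network-squared", "network-noinhib", "bayes"]
MODEL_NAMES: tuple[str, ...] = ("network-linear", "network-squared", "network-noinhib", "bayes")


class NetworkModel:
    """A configured recurrent network plus its readout: runs single trials.

    Bundles the geometry, the (cached, dense) weight matrix, the dynamics
    settings and the bump-detector settings so repeated trials do not rebuild
    the N x N kernel.
    """

    def __init__(
        self,
        geom: NetworkGeometry | None = None,
        conn: ConnectivityParams | None = None,
        mode: Literal["linear", "squared"] = "linear",
        input_steps: int = 5,
        max_steps: int = 100,
        tol: float = 1e-9,
        threshold_frac: float = 0.1,
        min_sep: float = 3.0,
        assign_rule: Literal["nearest", "weakest"] = "nearest",
    ) -> None:
        self.geom = geom if geom is not None else build_geometry()
        self.conn = conn if conn is not None else ConnectivityParams()
        self.mode = mode
        self.input_steps = input_steps
        self.max_steps = max_steps
        self.tol = tol
        self.threshold_frac = threshold_frac
        self.min_sep = min_sep
        self.assign_rule = assign_rule
        self.weights = build_connectivity(self.geom, self.conn)

    def run_trial(
        self,
        stim: StimulusConfig,
        rng: np.random.Generator | None = None,
        sensory_noise: bool = True,
        input_noise: bool = True,
    ) -> TrialOutcome:
        """Simulate one trial end to end and read out the outcome.

        States with 0 or >= 3 bumps are returned flagged invalid (C=0)
        rather than raised, so batch drivers can log and exclude them.
        """
        ext = make_trial_input(
            stim, self.geom, rng, sensory_noise=sensory_noise, input_noise=input_noise
        )
        res = run_dynamics(
            ext.h,
            self.weights,
            mode=self.mode,
            input_steps=self.input_steps,
            max_steps=self.max_steps,
            tol=self.tol,
        )
        bumps = detect_bumps(
            res.state.u, self.geom, threshold_frac=self.threshold_frac, min_sep=self.min_sep
        )
        try:
            c = classify_cause(bumps)
        except InvalidTrialError as err:
            return TrialOutcome(
                x_v=ext.x_v,
                x_a=ext.x_a,
                c=0,
                s_hat_v=math.nan,
                s_hat_a=math.nan,
                bias=math.nan,
                valid=False,
                n_bumps=bumps.count,
                converged=res.converged,
                reason=str(err),
            )
        s_hat_v, s_hat_a = assign_positions(bumps, ext.x_v, ext.x_a, rule=self.assign_rule)
        bias = (
            localization_bias(s_hat_a, stim.s_a, stim.s_v) if stim.s_v != stim.s_a else math.nan
        )
        return TrialOutcome(
            x_v=ext.x_v,
            x_a=ext.x_a,
            c=c,
            s_hat_v=s_hat_v,
            s_hat_a=s_hat_a,
            bias=bias,
            valid=True,
            n_bumps=bumps.count,
            converged=res.converged,
        )


def make_model(name: str, conn: ConnectivityParams | None = None, **kwargs) -> NetworkModel:
    """Construct a named network variant.

    ``network-linear`` is the threshold-linear model; ``network-squared``
    swaps in the strong (exponent-2) normalization; ``network-noinhib``
    removes lateral inhibition (m2 = 0) while keeping linear normalization.
    """
    base = conn if conn is not None else ConnectivityParams()
    if name == "network-linear":
        return NetworkModel(conn=base, mode="linear", **kwargs)
    if name == "network-squared":
        return NetworkModel(conn=base, mode="squared", **kwargs)
    if name == "network-noinhib":
        return NetworkModel(conn=replace(base, m2=0.0), mode="linear", **kwargs)
    raise ValueError(f"unknown network model {name!r} (expected one of {MODEL_NAMES[:3]})")


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings for a disparity experiment (unity curve or bias curve)."""

    disparities: tuple[float, ...] = DEFAULT_DISPARITIES
    n_trials: int = 500
    base_seed: int = 0
    model: str = "network-linear"
    stim: StimulusConfig = field(default_factory=StimulusConfig)
    bayes_params: bayes_mod.BayesParams = field(default_factory=bayes_mod.BayesParams)
    noiseless: bool = False

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}")
        if any(abs(d) > 70.0 for d in self.disparities):
            raise ValueError("disparities must keep sources within +/-35 deg of center")


@dataclass(frozen=True)
class SweepResult:
    """Integration threshold as a function of one swept parameter."""

    parameter: str
    grid: tuple[float, ...]
    thresholds: tuple[float, ...]  # deg; nan marks a degenerate grid point


# ---------------------------------------------------------------------------
# integration thresholds


def _noiseless_cause(model: NetworkModel, stim: StimulusConfig, d: float) -> int:
    out = model.run_trial(
        stim.at_disparity(d).noiseless(), rng=None, sensory_noise=False, input_noise=False
    )
    if not out.valid:
        raise InvalidTrialError(
            f"noiseless run at disparity {d} produced {out.n_bumps} bumps"
        )
    return out.c


def integration_threshold_net(
    model: NetworkModel,
    stim: StimulusConfig | None = None,
    d_max: float = 40.0,
    resolution: float = 0.05,
    coarse_step: float = 2.5,
) -> float:
    """Network integration threshold D0 (deg) from noiseless simulation.

    With all noise off the cause verdict is a deterministic step function of
    the disparity; D0 is the switch point, located by a coarse upward scan
    followed by bisection to ``resolution``.  Sources are placed
    symmetrically about 0.  Returns ``d_max`` if the network still fuses at
    the scan limit; raises if it already splits at D=0 (degenerate
    parameters).
    """
    stim = stim if stim is not None else StimulusConfig()
    if _noiseless_cause(model, stim, 0.0) != 1:
        raise ValueError("network reports two sources already at zero disparity")
    lo, hi = 0.0, None
    d = coarse_step
    while d <= d_max + 1e-9:
        if _noiseless_cause(model, stim, d) == 2:
            hi = d
            break
        lo = d
        d += coarse_step
    if hi is None:
        logger.warning("no segregation up to d_max=%.1f deg; threshold truncated", d_max)
        return d_max
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if _noiseless_cause(model, stim, mid) == 1:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def proportion_integration_closed_form(
    d, d0: float, sigma_vx: float = 3.0, sigma_ax: float = 6.5
):
    """Closed-form proportion of integration I(D) under sensory noise.

    The sensed disparity is Gaussian around the true disparity D with
    variance sigma_vx^2 + sigma_ax^2; integration happens when it falls
    within +/-D0, so I(D) = Phi((D + D0)/s) - Phi((D - D0)/s).
    """
    if d0 < 0:
        raise ValueError("d0 must be nonnegative")
    s = math.hypot(sigma_vx, sigma_ax)
    d = np.asarray(d, dtype=float)
    out = norm.cdf((d + d0) / s) - norm.cdf((d - d0) / s)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Monte-Carlo disparity experiments


def _bayes_trials(cfg: ExperimentConfig) -> pd.DataFrame:
    params = cfg.bayes_params
    rows = []
    ss = np.random.SeedSequence(cfg.base_seed)
    children = ss.spawn(len(cfg.disparities) * cfg.n_trials)
    k = 0
    for d in cfg.disparities:
        s_v, s_a = -d / 2.0, +d / 2.0
        for trial in range(cfg.n_trials):
            rng = np.random.default_rng(children[k])
            if cfg.noiseless:
                x_v, x_a = s_v, s_a
            else:
                x_v = rng.normal(s_v, params.sigma_v)
                x_a = rng.normal(s_a, params.sigma_a)
            c = bayes_mod.decide_cause(x_v, x_a, params)
            s_hat_v, s_hat_a = bayes_mod.optimal_estimates(x_v, x_a, c, params)
            bias = (s_hat_a - s_a) / (s_v - s_a) if s_v != s_a else math.nan
            rows.append(
                dict(
                    model=cfg.model,
                    disparity=d,
                    trial=trial,
                    seed=cfg.base_seed,
                    s_v=s_v,
                    s_a=s_a,
                    x_v=x_v,
                    x_a=x_a,
                    c=c,
                    s_hat_v=s_hat_v,
                    s_hat_a=s_hat_a,
                    bias=bias,
                    valid=True,
                    n_bumps=c,
                    converged=True,
                )
            )
            k += 1
    return pd.DataFrame(rows)


def run_trials(cfg: ExperimentConfig, model: NetworkModel | None = None) -> pd.DataFrame:
    """Run the full trial grid for ``cfg`` and return one row per trial.

    Columns: model, disparity, trial, seed, s_v, s_a, x_v, x_a, c, s_hat_v,
    s_hat_a, bias, valid, n_bumps, converged.  For ``model='bayes'`` the
    ideal observer replaces the network, with the same schema.
    """
    if cfg.model == "bayes":
        return _bayes_trials(cfg)
    if model is None:
        model = make_model(cfg.model)
    rows = []
    ss = np.random.SeedSequence(cfg.base_seed)
    children = ss.spawn(len(cfg.disparities) * cfg.n_trials)
    k = 0
    for d in cfg.disparities:
        stim = cfg.stim.at_disparity(d)
        if cfg.noiseless:
            stim = stim.noiseless()
        n_invalid = 0
        for trial in range(cfg.n_trials):
            rng = np.random.default_rng(children[k])
            out = model.run_trial(
                stim,
                rng,
                sensory_noise=not cfg.noiseless,
                input_noise=not cfg.noiseless,
            )
            if not out.valid:
                n_invalid += 1
                logger.info("invalid trial (D=%.2f, trial=%d): %s", d, trial, out.reason)
            rows.append(
                dict(
                    model=cfg.model,
                    disparity=d,
                    trial=trial,
                    seed=cfg.base_seed,
                    s_v=stim.s_v,
                    s_a=stim.s_a,
                    x_v=out.x_v,
                    x_a=out.x_a,
                    c=out.c,
                    s_hat_v=out.s_hat_v,
                    s_hat_a=out.s_hat_a,
                    bias=out.bias,
                    valid=out.valid,
                    n_bumps=out.n_bumps,
                    converged=out.converged,
                )
            )
            k += 1
        if n_invalid > 0.2 * cfg.n_trials:
            logger.warning(
                "disparity %.2f: %d/%d trials invalid", d, n_invalid, cfg.n_trials
            )
    return pd.DataFrame(rows)


def summarize_unity(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-disparity proportion of common-cause verdicts over valid trials."""
    rows = []
    for d, grp in trials.groupby("disparity", sort=True):
        valid = grp[grp["valid"]]
        n_valid = len(valid)
        prop = float((valid["c"] == 1).mean()) if n_valid else math.nan
        rows.append(
            dict(disparity=d, prop_unity=prop, n_valid=n_valid, n_trials=len(grp))
        )
    return pd.DataFrame(rows)


def summarize_bias(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-disparity conditional bias means and SEMs, plus unity proportion.

    Empty cause classes yield nan (missing), never zero.
    """
    rows = []
    for d, grp in trials.groupby("disparity", sort=True):
        valid = grp[grp["valid"]]
        row = dict(disparity=d, n_valid=len(valid), n_trials=len(grp))
        for c in (1, 2):
            cls = valid.loc[valid["c"] == c, "bias"].to_numpy(dtype=float)
            row[f"n_c{c}"] = cls.size
            row[f"mean_bias_c{c}"] = float(cls.mean()) if cls.size else math.nan
            row[f"sem_bias_c{c}"] = (
                float(cls.std(ddof=1) / math.sqrt(cls.size)) if cls.size > 1 else math.nan
            )
        row["prop_unity"] = (
            float((valid["c"] == 1).mean()) if len(valid) else math.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def run_unity_curve(
    cfg: ExperimentConfig, model: NetworkModel | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proportion-of-unity curve: (per-trial table, per-disparity summary)."""
    trials = run_trials(cfg, model=model)
    return trials, summarize_unity(trials)


def run_bias_experiment(
    cfg: ExperimentConfig, model: NetworkModel | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Localization-bias curve: (per-trial table, per-disparity summary)."""
    if any(d == 0 for d in cfg.disparities):
        raise ValueError("bias is undefined at zero disparity; drop D=0 from the grid")
    trials = run_trials(cfg, model=model)
    return trials, summarize_bias(trials)


def pooled_bias(trials: pd.DataFrame, c: int = 1) -> float:
    """Mean bias pooled over all valid trials of cause class ``c``, weighting
    each trial equally across the disparity grid."""
    mask = trials["valid"] & (trials["c"] == c)
    vals = trials.loc[mask, "bias"].to_numpy(dtype=float)
    return float(vals.mean()) if vals.size else math.nan


# ---------------------------------------------------------------------------
# parameter sweeps


def threshold_sweep(
    which: Literal["M1_over_M2", "sigma1", "sigma2", "pco"],
    grid: Sequence[float],
    conn: ConnectivityParams | None = None,
    bayes_params: bayes_mod.BayesParams | None = None,
    stim: StimulusConfig | None = None,
    **model_kwargs,
) -> SweepResult:
    """Integration threshold along a one-parameter grid.

    Network sweeps (``M1_over_M2`` varies m1 at fixed m2; ``sigma1``;
    ``sigma2``) measure D0 by noiseless bisection per grid point; the
    ``pco`` sweep uses the Bayesian closed form.  Degenerate grid points
    (no single bump at D=0) are reported as nan with a log entry.
    """
    grid = tuple(float(g) for g in grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("sweep grid must be strictly increasing")
    base = conn if conn is not None else ConnectivityParams()
    thresholds: list[float] = []
    if which == "pco":
        bp = bayes_params if bayes_params is not None else bayes_mod.BayesParams()
        for p in grid:
            thresholds.append(bayes_mod.integration_threshold(replace(bp, p_co=p)))
        return SweepResult(parameter=which, grid=grid, thresholds=tuple(thresholds))

    for g in grid:
        if which == "M1_over_M2":
            c = replace(base, m1=g * base.m2)
        elif which == "sigma1":
            c = replace(base, sigma1=g)
        elif which == "sigma2":
            c = replace(base, sigma2=g)
        else:
            raise ValueError(f"unknown sweep parameter {which!r}")
        try:
            model = NetworkModel(conn=c, mode="linear", **model_kwargs)
            thresholds.append(integration_threshold_net(model, stim=stim))
        except (ValueError, InvalidTrialError) as err:
            logger.warning("sweep %s=%g degenerate: %s", which, g, err)
            thresholds.append(math.nan)
    return SweepResult(parameter=which, grid=grid, thresholds=tuple(thresholds))
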