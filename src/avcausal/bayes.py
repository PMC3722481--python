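"""Bayesian ideal observer for audiovisual causal inference.

The observer receives noisy sensed positions x_V ~ N(S_V, sigma_V^2) and
x_A ~ N(S_A, sigma_A^2) and holds a prior ``p_co`` that the two cues share a
common source.  Sources are uniform on a strip of width ``a``.  Integrating
out the (uniform) source positions gives the posterior probability of a
common cause as a function of the sensed disparity D = x_V - x_A:

    p(C=1 | x_V, x_A) = a q(D) p_co / (a q(D) p_co + 1 - p_co)

with q(D) the Gaussian density of the disparity under a common cause,
q(D) = N(D; 0, sigma_V^2 + sigma_A^2).  The MAP cause decision fuses the
cues (inverse-variance weighting) when C=1 and passes them through when
C=2.  Setting the posterior to 1/2 yields a closed-form integration
threshold

    D0 = sqrt( 2 (sigma_V^2 + sigma_A^2)
               * ln[ a p_co / ((1 - p_co) sqrt(2 pi (sigma_V^2+sigma_A^2))) ] )

defined whenever the log argument exceeds 1; otherwise the observer never
integrates and the threshold is reported as 0.

Note the likelihood widths here (defaults sigma_V = 3, sigma_A = 6.5 deg)
play the role of the *sensory-noise* widths of the network's stimulus model,
not of the input-bump widths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BayesParams",
    "BayesBiasResult",
    "q_of_d",
    "posterior_common",
    "decide_cause",
    "optimal_estimates",
    "integration_threshold",
    "simulate_bias",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BayesParams:
    """Ideal-observer parameters: common-cause prior, likelihood widths (deg),
    and the width ``a`` of the uniform source range [-a/2, a/2]."""

    p_co: float = 0.2
    sigma_v: float = 3.0
    sigma_a: float = 6.5
    a: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_co <= 1.0:
            raise ValueError("p_co must lie in [0, 1]")
        if not (self.sigma_v > 0 and self.sigma_a > 0):
            raise ValueError("likelihood widths must be positive")
        if not self.a > 0:
            raise ValueError("spatial range a must be positive")

    @property
    def disparity_var(self) -> float:
        """Variance of the sensed disparity under a common cause."""
        return self.sigma_v**2 + self.sigma_a**2


@dataclass(frozen=True)
class BayesBiasResult:
    """Conditional localization-bias summary from :func:`simulate_bias`."""

    mean_bias_c1: float  # nan if no trial integrated
    mean_bias_c2: float  # nan if every trial integrated
    prop_c1: float
    n_c1: int
    n_c2: int
    sem_bias_c1: float
    sem_bias_c2: float


def q_of_d(d, params: BayesParams):
    """Density of the sensed disparity under a common cause: N(d; 0, sV^2+sA^2)."""
    var = params.disparity_var
    d = np.asarray(d, dtype=float)
    out = np.exp(-(d**2) / (2 * var)) / np.sqrt(2 * np.pi * var)
    return out if out.ndim else float(out)


def posterior_common(x_v, x_a, params: BayesParams):
    """Posterior probability that the two cues share a source."""
    aq = params.a * np.asarray(q_of_d(np.asarray(x_v, float) - np.asarray(x_a, float), params))
    out = aq * params.p_co / (aq * params.p_co + (1.0 - params.p_co))
    return out if out.ndim else float(out)


def decide_cause(x_v: float, x_a: float, params: BayesParams) -> int:
    """MAP cause: C=1 iff p(C=1|x) >= 1/2 (exact tie resolved to C=1)."""
    return 1 if posterior_common(x_v, x_a, params) >= 0.5 else 2


def optimal_estimates(x_v, x_a, c: int, params: BayesParams):
    """Optimal position estimates given the cause.

    C=2: the cues are independent, estimates pass through unchanged.
    C=1: both estimates equal the precision-weighted fusion
    (x_v / sV^2 + x_a / sA^2) / (1 / sV^2 + 1 / sA^2).
    """
    if c == 2:
        return x_v, x_a
    if c == 1:
        wv, wa = 1.0 / params.sigma_v**2, 1.0 / params.sigma_a**2
        fused = (np.asarray(x_v, float) * wv + np.asarray(x_a, float) * wa) / (wv + wa)
        fused = fused if fused.ndim else float(fused)
        return fused, fused
    raise ValueError(f"cause must be 1 or 2, got {c}")


def integration_threshold(params: BayesParams) -> float:
    """Closed-form integration threshold D0 (deg): the sensed disparity at
    which the posterior of a common cause crosses 1/2.

    Returns 0.0 (never integrates) when no real solution exists, i.e. when
    even at D=0 the posterior stays below 1/2; returns inf when p_co = 1
    (always integrates).
    """
    if params.p_co == 1.0:
        return math.inf
    var = params.disparity_var
    ratio = params.a * params.p_co / ((1.0 - params.p_co) * math.sqrt(2 * math.pi * var))
    if ratio < 1.0:
        logger.warning(
            "no integration threshold: a*p_co/((1-p_co)*sqrt(2 pi (sV^2+sA^2))) = %.4g < 1; "
            "observer never reports a common cause",
            ratio,
        )
        return 0.0
    return math.sqrt(2 * var * math.log(ratio))


def simulate_bias(
    s_v: float,
    s_a: float,
    params: BayesParams,
    n_trials: int,
    rng: np.random.Generator,
) -> BayesBiasResult:
    """Monte-Carlo localization bias of the ideal observer at fixed sources.

    Per trial: draw sensed positions, take the MAP cause, form the optimal
    auditory estimate and its bias (s_hat_a - s_a)/(s_v - s_a); the summary
    conditions on the cause class.  Empty classes report nan means.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if s_v == s_a:
        raise ValueError("bias undefined when sources coincide")
    x_v = rng.normal(s_v, params.sigma_v, size=n_trials)
    x_a = rng.normal(s_a, params.sigma_a, size=n_trials)
    post = np.asarray(posterior_common(x_v, x_a, params))
    common = post >= 0.5
    fused, _ = optimal_estimates(x_v, x_a, 1, params)
    s_hat_a = np.where(common, fused, x_a)
    bias = (s_hat_a - s_a) / (s_v - s_a)

    def _stats(mask: np.ndarray) -> tuple[float, float, int]:
        k = int(mask.sum())
        if k == 0:
            return math.nan, math.nan, 0
        vals = bias[mask]
        sem = float(vals.std(ddof=1) / math.sqrt(k)) if k > 1 else math.nan
        return float(vals.mean()), sem, k

    m1, sem1, n1 = _stats(common)
    m2, sem2, n2 = _stats(~common)
    return BayesBiasResult(
        mean_bias_c1=m1,
        mean_bias_c2=m2,
        prop_c1=n1 / n_trials,
        n_c1=n1,
        n_c2=n2,
        sem_bias_c1=sem1,
        sem_bias_c2=sem2,
    )
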