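"""Noisy audiovisual external input to the network.

A trial presents two Gaussian input bumps on the angle grid: a visual bump
of amplitude ``m_v`` and width ``sigma_v`` at the sensed position ``x_v``,
and an auditory bump (``m_a``, ``sigma_a``) at ``x_a``.  The sensed
positions are themselves noisy: ``x_v ~ Normal(s_v, sigma_vx^2)`` and
``x_a ~ Normal(s_a, sigma_ax^2)`` around the true source positions, modeling
sensory noise upstream of the network.  On top of the smooth two-bump mean,
each neuron receives independent Gaussian noise whose variance equals the
local mean drive (variance = mean, a rate-like noise model for cortical
input).

Defaults: m_v = m_a = 10, sigma_v = 1 deg, sigma_a = 2 deg, so the visual
bump is twice as tall as the auditory one (vision is the more reliable cue);
sensory noise sigma_vx = 3 deg, sigma_ax = 6.5 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import NetworkGeometry

__all__ = ["StimulusConfig", "ExternalInput", "sample_positions", "mean_input", "sample_external_input", "make_trial_input"]


@dataclass(frozen=True)
class StimulusConfig:
    """Input-bump and sensory-noise parameters for one audiovisual trial.

    ``s_v``/``s_a`` are the true source positions (deg); ``sigma_vx`` /
    ``sigma_ax`` the sensory-noise s.d. of the sensed positions.  Setting
    both noise widths to zero gives the noiseless regime ``x = s``.
    """

    s_v: float = 0.0
    s_a: float = 0.0
    m_v: float = 10.0
    m_a: float = 10.0
    sigma_v: float = 1.0
    sigma_a: float = 2.0
    sigma_vx: float = 3.0
    sigma_ax: float = 6.5

    def __post_init__(self) -> None:
        if not (self.sigma_v > 0 and self.sigma_a > 0):
            raise ValueError("bump widths sigma_v, sigma_a must be positive")
        if self.sigma_vx < 0 or self.sigma_ax < 0:
            raise ValueError("sensory-noise widths must be nonnegative")

    def at_disparity(self, d: float) -> "StimulusConfig":
        """Symmetric placement at disparity ``d``: s_v = -d/2, s_a = +d/2."""
        return replace(self, s_v=-d / 2.0, s_a=+d / 2.0)

    def noiseless(self) -> "StimulusConfig":
        """Copy with sensory noise switched off (x_v = s_v, x_a = s_a)."""
        return replace(self, sigma_vx=0.0, sigma_ax=0.0)


@dataclass(frozen=True)
class ExternalInput:
    """One realized trial input: sensed positions, mean profile, noisy drive."""

    x_v: float
    x_a: float
    mean_h: np.ndarray = field(repr=False)
    h: np.ndarray = field(repr=False)


def sample_positions(
    cfg: StimulusConfig,
    rng: np.random.Generator,
    bounds: tuple[float, float] = (-50.0, 50.0),
) -> tuple[float, float]:
    """Draw sensed positions x_v ~ N(s_v, sigma_vx^2), x_a ~ N(s_a, sigma_ax^2).

    Draws falling outside ``bounds`` are rejected and redrawn (per cue), since
    the angle grid cannot represent bumps off the strip; with default
    geometry and sources well inside the strip this is vanishingly rare.
    """
    lo, hi = bounds

    def _draw(mean: float, sd: float) -> float:
        if sd == 0.0:
            if not lo <= mean <= hi:
                raise ValueError(f"source position {mean} outside strip {bounds}")
            return mean
        while True:
            x = rng.normal(mean, sd)
            if lo <= x <= hi:
                return float(x)

    return _draw(cfg.s_v, cfg.sigma_vx), _draw(cfg.s_a, cfg.sigma_ax)


def mean_input(
    x_v: float, x_a: float, cfg: StimulusConfig, geom: NetworkGeometry
) -> np.ndarray:
    """Mean external drive: two Gaussian bumps evaluated on the angle grid.

    <h_i> = m_v/(sqrt(2 pi) sigma_v) exp(-(th_i - x_v)^2 / (2 sigma_v^2))
          + m_a/(sqrt(2 pi) sigma_a) exp(-(th_i - x_a)^2 / (2 sigma_a^2))
    """
    th = geom.preferred_angles
    vis = cfg.m_v / (np.sqrt(2 * np.pi) * cfg.sigma_v) * np.exp(
        -((th - x_v) ** 2) / (2 * cfg.sigma_v**2)
    )
    aud = cfg.m_a / (np.sqrt(2 * np.pi) * cfg.sigma_a) * np.exp(
        -((th - x_a) ** 2) / (2 * cfg.sigma_a**2)
    )
    return vis + aud


def sample_external_input(mean_h: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Add per-neuron Gaussian noise with variance equal to the local mean.

    h_i = <h_i> + z_i, z_i ~ Normal(0, <h_i>) independently.  The result may
    dip below zero; rectification happens downstream in the threshold-linear
    normalization, not here.
    """
    mean_h = np.asarray(mean_h, dtype=float)
    if np.any(mean_h < 0):
        raise ValueError("mean input must be nonnegative (variance = mean)")
    return mean_h + rng.normal(0.0, np.sqrt(mean_h))


def make_trial_input(
    cfg: StimulusConfig,
    geom: NetworkGeometry,
    rng: np.random.Generator | None = None,
    sensory_noise: bool = True,
    input_noise: bool = True,
) -> ExternalInput:
    """Sample a complete trial input (positions, mean profile, noisy drive).

    The noise realization ``z`` is drawn once per trial; the same ``h``
    vector is presented on every step of the input window.  With both noise
    flags off the call is deterministic and ``rng`` may be omitted.
    """
    if (sensory_noise or input_noise) and rng is None:
        raise ValueError("rng is required when noise is enabled")
    if sensory_noise:
        x_v, x_a = sample_positions(cfg, rng)
    else:
        x_v, x_a = cfg.s_v, cfg.s_a
    mh = mean_input(x_v, x_a, cfg, geom)
    h = sample_external_input(mh, rng) if input_noise else mh.copy()
    return ExternalInput(x_v=x_v, x_a=x_a, mean_h=mh, h=h)
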