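"""Recurrent network: geometry, Mexican-hat connectivity, discrete-time dynamics.

The model is a single-layer recurrent network of ``N`` rate neurons labelled
by evenly spaced preferred angles on a linear strip (default 1000 neurons on
[-50, 50] degrees, i.e. 0.1 deg spacing).  Excitatory and inhibitory
populations are collapsed into one equivalent population coupled by a
difference-of-Gaussians ("Mexican hat") kernel: short-range excitation of
strength ``M1``/range ``sigma1``, longer-range inhibition of strength
``M2``/range ``sigma2``.

Dynamics are discrete-time.  The net input at step ``t`` is

    a_i(t) = h_i + sum_j J_ij u_j(t)

with the external drive ``h`` present only during an initial input window
(default five steps, with ``a(0) = h`` and ``u(0) = 0``), after which the
network runs freely on recurrence alone.  Firing rates follow from the net
input through divisive normalization, in one of two variants:

* ``linear``  -- threshold-linear numerator, normalized by the population
  mean of the rectified input: ``u_i = [a_i]_+ / (1 + mean_j [a_j]_+)``.
  Weak (exponent-1) normalization; multiple activity bumps can coexist.
* ``squared`` -- squared numerator, normalized by the population mean of the
  squared input: ``u_i = a_i^2 / (1 + mean_j a_j^2)``.  Strong (exponent-2)
  normalization; iterating it amplifies the tallest local excitation until a
  single bump survives (winner-take-all).

The strip is *not* periodic: angular distance is the plain difference of
preferred angles.  Stimuli should be kept well inside the strip (the
experiment drivers keep sources within +/-35 deg) to avoid edge effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "NetworkGeometry",
    "ConnectivityParams",
    "NetworkState",
    "DynamicsResult",
    "build_geometry",
    "build_connectivity",
    "net_input",
    "normalize_linear",
    "normalize_squared",
    "run_dynamics",
    "trajectory_frame",
]

NormalizationMode = Literal["linear", "squared"]


@dataclass(frozen=True)
class NetworkGeometry:
    """Uniform grid of preferred angles on a (non-periodic) strip."""

    n: int
    angle_min: float
    angle_max: float
    preferred_angles: np.ndarray = field(repr=False)

    @property
    def spacing(self) -> float:
        """Grid spacing in degrees."""
        return (self.angle_max - self.angle_min) / self.n


@dataclass(frozen=True)
class ConnectivityParams:
    """Mexican-hat kernel parameters.

    ``m1``/``sigma1`` set the strength and range (deg) of excitation,
    ``m2``/``sigma2`` those of lateral inhibition.  Defaults m1=28, m2=10,
    sigma1=1.5 deg, sigma2=3 deg give net excitation within roughly +/-2 deg
    of a neuron and net inhibition beyond.
    """

    m1: float = 28.0
    m2: float = 10.0
    sigma1: float = 1.5
    sigma2: float = 3.0

    def __post_init__(self) -> None:
        if not self.m1 > 0:
            raise ValueError(f"m1 must be positive, got {self.m1}")
        if self.m2 < 0:
            raise ValueError(f"m2 must be nonnegative, got {self.m2}")
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ValueError("sigma1 and sigma2 must be positive")


@dataclass(frozen=True)
class NetworkState:
    """Snapshot of the network: rates ``u``, net input ``a``, step index ``t``."""

    u: np.ndarray = field(repr=False)
    a: np.ndarray = field(repr=False)
    t: int


@dataclass(frozen=True)
class DynamicsResult:
    """Final state of :func:`run_dynamics` plus convergence metadata.

    ``converged`` is False when the sup-norm change of ``u`` never dropped
    below ``tol`` within ``max_steps`` free-running steps; the final state is
    still returned and usable.  ``trajectory`` holds per-step rate vectors
    (rows indexed by t) when recording was requested, else None.
    """

    state: NetworkState
    converged: bool
    n_steps: int
    trajectory: np.ndarray | None = field(default=None, repr=False)


def build_geometry(
    n: int = 1000, angle_min: float = -50.0, angle_max: float = 50.0
) -> NetworkGeometry:
    """Lay out ``n`` preferred angles evenly over ``[angle_min, angle_max)``.

    The i-th angle is ``angle_min + i * (angle_max - angle_min) / n``; with
    the defaults this is ``0.1 * i - 50`` degrees, i = 0..999.
    """
    if n < 2:
        raise ValueError(f"need at least 2 neurons, got n={n}")
    if not angle_min < angle_max:
        raise ValueError(f"inverted angle range [{angle_min}, {angle_max}]")
    spacing = (angle_max - angle_min) / n
    angles = angle_min + spacing * np.arange(n, dtype=float)
    return NetworkGeometry(n=n, angle_min=angle_min, angle_max=angle_max, preferred_angles=angles)


def build_connectivity(geom: NetworkGeometry, params: ConnectivityParams) -> np.ndarray:
    """Dense N x N Mexican-hat weight matrix.

    J_ij = m1 / (sqrt(2 pi) sigma1) * exp(-(th_i - th_j)^2 / (2 sigma1^2))
         - m2 / (sqrt(2 pi) sigma2) * exp(-(th_i - th_j)^2 / (2 sigma2^2))

    Symmetric, translation-invariant in the angle difference, non-periodic.
    """
    th = geom.preferred_angles
    d2 = (th[:, None] - th[None, :]) ** 2
    exc = params.m1 / (np.sqrt(2 * np.pi) * params.sigma1) * np.exp(-d2 / (2 * params.sigma1**2))
    inh = params.m2 / (np.sqrt(2 * np.pi) * params.sigma2) * np.exp(-d2 / (2 * params.sigma2**2))
    return exc - inh


def net_input(u: np.ndarray, weights: np.ndarray, h: np.ndarray | None = None) -> np.ndarray:
    """Net input ``a = h + J u`` (recurrent drive plus optional external drive)."""
    u = np.asarray(u, dtype=float)
    if weights.shape != (u.size, u.size):
        raise ValueError(f"weight matrix {weights.shape} does not match u of length {u.size}")
    a = weights @ u
    if h is not None:
        h = np.asarray(h, dtype=float)
        if h.shape != u.shape:
            raise ValueError(f"external input shape {h.shape} does not match u {u.shape}")
        a = a + h
    return a


def normalize_linear(a: np.ndarray) -> np.ndarray:
    """Threshold-linear divisive normalization (exponent 1).

    u_i = [a_i]_+ / (1 + mean_j [a_j]_+).  The denominator is >= 1, so the
    output is finite and nonnegative, and the population mean of u is < 1.
    """
    rect = np.maximum(np.asarray(a, dtype=float), 0.0)
    return rect / (1.0 + rect.mean())


def normalize_squared(a: np.ndarray) -> np.ndarray:
    """Squared divisive normalization (exponent 2), the strong variant.

    u_i = a_i^2 / (1 + mean_j a_j^2).  Nonnegative by construction; repeated
    application sharpens the tallest peak at the expense of the others.
    """
    sq = np.square(np.asarray(a, dtype=float))
    return sq / (1.0 + sq.mean())


_NORMALIZERS = {"linear": normalize_linear, "squared": normalize_squared}


def run_dynamics(
    h: np.ndarray,
    weights: np.ndarray,
    mode: NormalizationMode = "linear",
    input_steps: int = 5,
    max_steps: int = 100,
    tol: float = 1e-9,
    record_trajectory: bool = False,
) -> DynamicsResult:
    """Iterate the network to a (approximate) fixed point.

    The external input ``h`` drives the net input for ``input_steps`` steps
    (t = 0 .. input_steps-1), starting from ``a(0) = h`` and ``u(0) = 0``;
    afterwards the net input is purely recurrent.  Each step applies the
    selected normalization: ``u(t+1) = f(a(t))``.  Iteration stops once the
    sup-norm change of ``u`` falls below ``tol`` during the free-running
    phase, or at ``max_steps``; non-convergence is reported via the
    ``converged`` flag, never raised.
    """
    if input_steps < 1:
        raise ValueError("input_steps must be >= 1")
    if max_steps <= input_steps:
        raise ValueError("max_steps must exceed input_steps")
    normalize = _NORMALIZERS[mode]
    h = np.asarray(h, dtype=float)

    u = np.zeros_like(h)
    a = h.copy()  # a(0) = h
    traj = [u.copy()] if record_trajectory else None
    converged = False
    t = 0
    while t < max_steps:
        u_next = normalize(a)  # u(t+1)
        t += 1
        if traj is not None:
            traj.append(u_next.copy())
        # Only judge convergence once the input window is over: the update
        # map changes at t = input_steps, so earlier stationarity is spurious.
        if t > input_steps and np.max(np.abs(u_next - u)) < tol:
            u = u_next
            converged = True
            break
        u = u_next
        a = weights @ u
        if t < input_steps:
            a = a + h

    state = NetworkState(u=u, a=a, t=t)
    trajectory = np.array(traj) if traj is not None else None
    return DynamicsResult(state=state, converged=converged, n_steps=t, trajectory=trajectory)


def trajectory_frame(result: DynamicsResult, geom: NetworkGeometry):
    """Long-format trajectory table with columns ``t, theta, u`` (diagnostics)."""
    import pandas as pd

    if result.trajectory is None:
        raise ValueError("dynamics were run without record_trajectory=True")
    n_t, n = result.trajectory.shape
    return pd.DataFrame(
        {
            "t": np.repeat(np.arange(n_t), n),
            "theta": np.tile(geom.preferred_angles, n_t),
            "u": result.trajectory.ravel(),
        }
    )
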