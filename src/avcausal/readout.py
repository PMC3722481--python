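"""Reading out the converged network state: bump detection, cause
classification, position estimates and the localization-bias statistic.

A converged state with one activity bump means the network attributed both
cues to a common source (C=1) and the bump position is the fused estimate;
two bumps mean independent sources (C=2) and each bump position estimates
one cue.  The bias statistic quantifies the ventriloquism effect:

    bias = (S_hat_A - S_A) / (S_V - S_A)

i.e. the shift of the estimated auditory position toward the visual source,
normalized by the true separation.  bias = 1 is complete visual capture,
bias = 0 no shift, and negative values mean repulsion away from the visual
side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import find_peaks

from .network import NetworkGeometry

__all__ = [
    "Bump",
    "BumpSet",
    "TrialOutcome",
    "InvalidTrialError",
    "detect_bumps",
    "classify_cause",
    "assign_positions",
    "localization_bias",
]


class InvalidTrialError(ValueError):
    """Raised when a converged state has 0 or >= 3 bumps and cannot be
    classified as a one- or two-source outcome."""


@dataclass(frozen=True)
class Bump:
    position: float  # degrees, center of mass of the supra-threshold region
    height: float  # peak firing rate


@dataclass(frozen=True)
class BumpSet:
    """Detected activity bumps, sorted by position."""

    peaks: tuple[Bump, ...]

    @property
    def count(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class TrialOutcome:
    """Per-trial record of one simulated audiovisual trial."""

    x_v: float
    x_a: float
    c: int  # 1 = common cause, 2 = independent causes; 0 when invalid
    s_hat_v: float
    s_hat_a: float
    bias: float
    valid: bool
    n_bumps: int
    converged: bool = True
    reason: str = ""


def detect_bumps(
    u: np.ndarray,
    geom: NetworkGeometry,
    threshold_frac: float = 0.1,
    min_sep: float = 3.0,
) -> BumpSet:
    """Locate activity bumps in a nonnegative rate vector.

    Local maxima above ``threshold_frac * max(u)`` are candidate peaks;
    candidates closer than ``min_sep`` degrees are merged, keeping the
    taller (peaks within the lateral-inhibition range belong to one hill).
    Each surviving peak's position is refined as the center of mass of the
    contiguous supra-threshold region around it, split at the activity
    minimum between neighboring peaks that share a region.

    An all-zero state yields an empty BumpSet; callers treat that as an
    invalid trial.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    if min_sep <= 0:
        raise ValueError("min_sep must be positive")
    u = np.asarray(u, dtype=float)
    peak_max = u.max(initial=0.0)
    if peak_max <= 0.0:
        return BumpSet(peaks=())

    th = geom.preferred_angles
    height_thr = threshold_frac * peak_max
    idx, _ = find_peaks(u, height=height_thr)
    # Endpoints can carry a maximum that find_peaks (interior-only) misses.
    for edge in (0, u.size - 1):
        inner = 1 if edge == 0 else u.size - 2
        if u[edge] >= height_thr and u[edge] > u[inner]:
            idx = np.sort(np.append(idx, edge))
    if idx.size == 0:
        return BumpSet(peaks=())

    # Greedy merge: tallest first, drop candidates within min_sep of a keeper.
    order = idx[np.argsort(u[idx])[::-1]]
    kept: list[int] = []
    for i in order:
        if all(abs(th[i] - th[j]) >= min_sep for j in kept):
            kept.append(i)
    kept.sort()

    # Contiguous supra-threshold runs; a run shared by several kept peaks is
    # split at the activity minimum between consecutive peaks.
    above = u >= height_thr
    boundaries = np.flatnonzero(np.diff(above.astype(int)))
    run_starts = np.r_[0, boundaries + 1]
    run_ends = np.r_[boundaries, u.size - 1]

    def _run_of(i: int) -> tuple[int, int]:
        k = np.searchsorted(run_starts, i, side="right") - 1
        return int(run_starts[k]), int(run_ends[k])

    bumps: list[Bump] = []
    for pos, i in enumerate(kept):
        lo, hi = _run_of(i)
        if pos > 0:
            prev = kept[pos - 1]
            plo, phi = _run_of(prev)
            if (plo, phi) == (lo, hi):  # shared run: cut at the valley
                valley = prev + int(np.argmin(u[prev : i + 1]))
                lo = max(lo, valley + 1)
        if pos < len(kept) - 1:
            nxt = kept[pos + 1]
            nlo, nhi = _run_of(nxt)
            if (nlo, nhi) == _run_of(i):
                valley = i + int(np.argmin(u[i : nxt + 1]))
                hi = min(hi, valley)
        seg = slice(lo, hi + 1)
        com = float(np.sum(th[seg] * u[seg]) / np.sum(u[seg]))
        bumps.append(Bump(position=com, height=float(u[i])))
    return BumpSet(peaks=tuple(sorted(bumps, key=lambda b: b.position)))


def classify_cause(bumps: BumpSet) -> int:
    """Map bump count to the causal verdict: 1 bump -> C=1, 2 bumps -> C=2."""
    if bumps.count not in (1, 2):
        raise InvalidTrialError(f"state has {bumps.count} bumps; expected 1 or 2")
    return bumps.count


def assign_positions(
    bumps: BumpSet,
    x_v: float,
    x_a: float,
    rule: Literal["nearest", "weakest"] = "nearest",
) -> tuple[float, float]:
    """Identify (S_hat_V, S_hat_A) among the detected bumps.

    One bump: both estimates equal its position (fused percept).  Two bumps:
    under the default ``nearest`` rule the bump closer to the sensed auditory
    position x_a is auditory; an exact tie falls back to the shorter bump
    (auditory input is the weaker drive).  The ``weakest`` rule assigns the
    shorter bump to audition outright.
    """
    c = classify_cause(bumps)
    if c == 1:
        p = bumps.peaks[0].position
        return p, p
    b1, b2 = bumps.peaks
    if rule == "weakest":
        aud, vis = (b1, b2) if b1.height <= b2.height else (b2, b1)
    elif rule == "nearest":
        d1, d2 = abs(b1.position - x_a), abs(b2.position - x_a)
        if d1 < d2:
            aud, vis = b1, b2
        elif d2 < d1:
            aud, vis = b2, b1
        else:  # equidistant: the weaker bump is auditory
            aud, vis = (b1, b2) if b1.height <= b2.height else (b2, b1)
    else:
        raise ValueError(f"unknown assignment rule {rule!r}")
    return vis.position, aud.position


def localization_bias(s_hat_a: float, s_a: float, s_v: float) -> float:
    """Normalized auditory shift (S_hat_A - S_A) / (S_V - S_A)."""
    if s_v == s_a:
        raise ValueError("bias undefined when the sources coincide (S_V = S_A)")
    return (s_hat_a - s_a) / (s_v - s_a)
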