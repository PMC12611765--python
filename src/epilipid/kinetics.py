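"""Inhibited-autoxidation kinetic trace analysis.

Fluorescence-reported lipid peroxidation in the presence of a
radical-trapping antioxidant shows two phases: a lag (inhibited) phase
of slow signal growth while the antioxidant is consumed, then a
propagation phase of fast growth.  The lag time is estimated as the
intersection of two tangents — a baseline line fitted to the initial
fraction of the trace and the maximum-slope line from a short sliding
window — which is robust to gain differences between plate readers.
A threshold-crossing estimator is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticTrace",
    "LagResult",
    "TooFewPoints",
    "lag_time",
    "propagation_rate",
    "normalized_delta_signal",
]


class TooFewPoints(ValueError):
    """Kinetic analysis needs at least 10 samples."""


@dataclass(frozen=True)
class KineticTrace:
    """A single-well fluorescence time course."""

    time: np.ndarray        # s, strictly increasing
    signal: np.ndarray      # a.u., >= 0
    channel: str = "oxidized BODIPY-C11"

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape:
            raise ValueError("time and signal must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if (s < 0).any():
            raise ValueError("signal must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class LagResult:
    lag: float              # s; 0 when uninhibited
    censored: bool          # propagation never begins within the trace
    baseline_slope: float
    max_slope: float


def _window_slopes(t: np.ndarray, s: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Slope and intercept of a least-squares line in each sliding window."""
    n = t.size - width + 1
    slopes = np.empty(n)
    inters = np.empty(n)
    for i in range(n):
        tw, sw = t[i:i + width], s[i:i + width]
        m, b = np.polyfit(tw, sw, 1)
        slopes[i] = m
        inters[i] = b
    return slopes, inters


def _fit_line(t: np.ndarray, s: np.ndarray) -> tuple[float, float, float]:
    m, b = np.polyfit(t, s, 1)
    sse = float(np.sum((s - (m * t + b)) ** 2))
    return float(m), float(b), sse


def lag_time(
    trace: KineticTrace,
    baseline_fraction: float = 0.10,
    method: str = "tangent",
    threshold_fraction: float = 0.10,
    max_breakpoints: int = 200,
) -> LagResult:
    """Lag time of a two-phase trace.

    tangent (default): the trace is segmented at the breakpoint
    minimising the two-line least-squares error; the intersection of the
    baseline tangent (fit of the initial segment) with the maximum-slope
    tangent (fit of the propagation segment) is the lag.  Returns 0 when
    the two slopes are indistinguishable from the start (uninhibited
    trace) and a censored result when the signal never rises above
    baseline noise (propagation never begins).

    threshold: first time the signal crosses ``threshold_fraction`` of
    its total rise (gain-sensitive; provided for comparison).
    """
    t, s = trace.time, trace.signal
    if t.size < 10:
        raise TooFewPoints(f"need >= 10 points, got {t.size}")
    nb = max(int(round(baseline_fraction * t.size)), 3)
    mb0, bb0 = np.polyfit(t[:nb], s[:nb], 1)
    resid_sd = float(np.std(s[:nb] - (mb0 * t[:nb] + bb0)))

    signal_rise = float(s.max() - s.min())
    noise_floor = max(5.0 * resid_sd, 1e-12 * max(signal_rise, 1.0))
    if signal_rise <= noise_floor:
        return LagResult(lag=np.nan, censored=True, baseline_slope=mb0, max_slope=mb0)

    if method == "threshold":
        level = s[0] + threshold_fraction * (s[-1] - s[0])
        above = np.nonzero(s >= level)[0]
        lag = float(t[above[0]]) if above.size else np.nan
        return LagResult(lag=max(lag - t[0], 0.0), censored=not above.size,
                         baseline_slope=mb0, max_slope=np.nan)

    # two-segment least squares over candidate breakpoints
    lo, hi = 3, t.size - 3
    step = max((hi - lo) // max_breakpoints, 1)
    best = None
    for k in range(lo, hi, step):
        mb, bb, sse_l = _fit_line(t[:k], s[:k])
        mp, bp, sse_r = _fit_line(t[k:], s[k:])
        sse = sse_l + sse_r
        if best is None or sse < best[0]:
            best = (sse, mb, bb, mp, bp)
    _, mb, bb, mp, bp = best

    if mp <= 0 or (mp - mb) <= 0.10 * abs(mp):
        # propagation-like slope from the very start: no inhibited phase
        return LagResult(lag=0.0, censored=False, baseline_slope=mb, max_slope=mp)

    t_int = (bb - bp) / (mp - mb)
    lag = max(float(t_int - t[0]), 0.0)
    return LagResult(lag=lag, censored=False, baseline_slope=mb, max_slope=mp)


def propagation_rate(trace: KineticTrace, slope_window: int | None = None) -> float:
    """Maximum sliding-window linear-fit slope (a.u. per time unit).

    The window defaults to a quarter of the trace; short windows track
    fast transients but inflate the maximum under noise (max of many
    noisy slope estimates).
    """
    t, s = trace.time, trace.signal
    if t.size < 2:
        raise TooFewPoints("need >= 2 points for a slope")
    if slope_window is None:
        slope_window = max(5, t.size // 4)
    width = min(max(slope_window, 2), t.size)
    slopes, _ = _window_slopes(t, s, width)
    return float(slopes.max())


def normalized_delta_signal(trace: KineticTrace) -> KineticTrace:
    """Signal divided by its value at the reaction start (first point)."""
    if trace.signal[0] <= 0:
        raise ValueError("signal at the reaction start must be > 0")
    return KineticTrace(trace.time, trace.signal / trace.signal[0], trace.channel)
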