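"""Scalar summaries of effector-output timecourses.

The output of one network configuration is a timecourse of bound effector
(nM in simulations, background-subtracted AU in bead data).  Three summary
features characterise it: the integrated signal (amplitude x duration),
the initial rate of activation, and a transient score in [0, 1] measuring
how far the response overshoots its final steady level.  Two cross-system
ratios compare configurations: the distortion score (mutant vs wild type)
and the feedback gain (feedback vs constitutive-GEF system), both defined
as ratios of integrated signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Timecourse",
    "FeatureSet",
    "normalize_to_max",
    "integrated_signal",
    "initial_rate",
    "transient_score",
    "pulse_width",
    "extract_features",
    "distortion_score",
    "feedback_gain",
]

#: Fraction of the peak defining the initial-rate fitting window.
INITIAL_RATE_WINDOW = 0.10
#: Number of trailing samples averaged to estimate the final level.
FINAL_VALUE_POINTS = 3


@dataclass(frozen=True)
class Timecourse:
    """A sampled output trace: strictly increasing times, one value each."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if len(t) < 2:
            raise ValueError("a timecourse needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("missing/non-finite values are not allowed")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class FeatureSet:
    integrated_signal: float   # value units x s
    initial_rate: float        # value units / s
    peak_value: float
    peak_time: float           # s
    final_value: float
    pulse_width_s: float
    transient_score: float     # dimensionless, in [0, 1]

    def as_dict(self) -> dict[str, float]:
        return dict(vars(self))


def normalize_to_max(tc: Timecourse) -> Timecourse:
    """Scale so the maximum is 1, retaining only the shape of the response."""
    peak = float(np.max(tc.values))
    if peak <= 0:
        raise ValueError("cannot normalize a trace with no positive values")
    return Timecourse(tc.times, tc.values / peak)


def integrated_signal(tc: Timecourse) -> float:
    """Trapezoidal integral of the trace over its full time span."""
    return float(np.trapezoid(tc.values, tc.times))


def _final_value(tc: Timecourse) -> float:
    k = min(FINAL_VALUE_POINTS, len(tc.values))
    return float(np.mean(tc.values[-k:]))


def initial_rate(tc: Timecourse) -> float:
    """Least-squares slope over the rise up to 10% of peak (>= 3 points)."""
    if len(tc.times) < 3:
        raise ValueError("initial_rate needs at least 3 points")
    peak = float(np.max(tc.values))
    if peak <= 0:
        return 0.0
    above = np.nonzero(tc.values >= INITIAL_RATE_WINDOW * peak)[0]
    stop = above[0] if len(above) else len(tc.values) - 1
    stop = max(int(stop), 2)  # at least 3 points in the fit
    t, v = tc.times[: stop + 1], tc.values[: stop + 1]
    return float(np.polyfit(t, v, 1)[0])


def transient_score(tc: Timecourse) -> float:
    """Overshoot measure (peak - final)/peak, clipped to [0, 1].

    Zero for monotone non-decreasing traces; approaches one when the
    response decays to nearly nothing after its peak.
    """
    peak = float(np.max(tc.values))
    if peak <= 0:
        raise ValueError("transient_score requires a positive peak")
    if np.all(np.diff(tc.values) >= 0):
        return 0.0  # still rising: no overshoot by definition
    return float(np.clip((peak - _final_value(tc)) / peak, 0.0, 1.0))


def pulse_width(tc: Timecourse) -> float:
    """Time spent above the half-way level (peak + final)/2."""
    peak = float(np.max(tc.values))
    level = 0.5 * (peak + _final_value(tc))
    above = tc.values >= level
    if not above.any():
        return 0.0
    # accumulate time over segments where the trace is above the level,
    # with linear interpolation at the crossings
    t, v = tc.times, tc.values
    width = 0.0
    for i in range(len(t) - 1):
        a_in, b_in = above[i], above[i + 1]
        dt = t[i + 1] - t[i]
        if a_in and b_in:
            width += dt
        elif a_in != b_in and v[i + 1] != v[i]:
            frac = (level - v[i]) / (v[i + 1] - v[i])
            width += dt * (1.0 - frac) if a_in else dt * frac
    return float(width)


def extract_features(tc: Timecourse) -> FeatureSet:
    peak_i = int(np.argmax(tc.values))
    peak = float(tc.values[peak_i])
    return FeatureSet(
        integrated_signal=integrated_signal(tc),
        initial_rate=initial_rate(tc) if len(tc.times) >= 3 else 0.0,
        peak_value=peak,
        peak_time=float(tc.times[peak_i]),
        final_value=_final_value(tc),
        pulse_width_s=pulse_width(tc) if peak > 0 else 0.0,
        transient_score=transient_score(tc) if peak > 0 else 0.0,
    )


def _ratio_of_integrals(num: Timecourse, den: Timecourse, what: str) -> float:
    if len(num.times) != len(den.times) or not np.allclose(num.times, den.times):
        raise ValueError(f"{what} requires both traces on the same time grid")
    denom = integrated_signal(den)
    if denom <= 0:
        raise ValueError(f"{what}: reference trace has non-positive integral")
    return integrated_signal(num) / denom


def distortion_score(mutant: Timecourse, wt: Timecourse) -> float:
    """Fold-change in integrated signal of a mutant system relative to WT."""
    return _ratio_of_integrals(mutant, wt, "distortion_score")


def feedback_gain(fb: Timecourse, base: Timecourse) -> float:
    """Ratio of integrated signal with feedback to the constitutive system."""
    return _ratio_of_integrals(fb, base, "feedback_gain")
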