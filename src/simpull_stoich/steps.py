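"""Trace normalization and rule-based photobleaching step counting.

The step-counting oracle encodes the manual labeling criteria used to
build classifier training sets: a photobleaching event is a stepwise,
sustained (> 25 camera counts by default) decrease in fluorescence;
counting stops early the first time the trace *increases* by a step
(blinking or re-binding); traces whose variability prevents resolving
discrete drops are rejected as too noisy.

Counting runs on raw camera counts (the 25-count rule is in counts);
classifier inputs are separately Z-score normalized.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GREEN, FARRED, IntensityTrace, classes_for

__all__ = [
    "NormalizedTrace", "StepAnnotation", "zscore_normalize",
    "count_steps_oracle", "bin_class", "bleach_half_time",
    "RuleBasedClassifier",
]


@dataclass
class NormalizedTrace:
    """Z-scored trace (zero mean, unit population SD over the full trace)."""

    z_values: np.ndarray
    source_mean: float
    source_sd: float
    spot_id: int = -1
    channel: str = GREEN


@dataclass
class StepAnnotation:
    """Step-count annotation for one trace under the labeling rules."""

    raw_step_count: int
    early_stopped: bool
    step_frames: list = field(default_factory=list)
    step_sizes: list = field(default_factory=list)
    quality: str = "accepted"       # "accepted" | "too_noisy"
    channel: str = FARRED

    def __post_init__(self) -> None:
        if self.raw_step_count != len(self.step_frames):
            raise ValueError("raw_step_count must equal len(step_frames)")


def zscore_normalize(trace) -> NormalizedTrace:
    """Z-score a trace over its full length with the population SD.

    Raises ``ValueError("degenerate trace")`` for constant traces
    (downstream these are binned as rejected).
    """
    if isinstance(trace, IntensityTrace):
        x = trace.values
        spot_id, channel = trace.spot_id, trace.channel
    else:
        x = np.asarray(trace, dtype=float)
        spot_id, channel = -1, GREEN
    if x.size < 2:
        raise ValueError("trace must have length >= 2")
    mean = float(x.mean())
    sd = float(x.std())  # population SD
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate trace")
    return NormalizedTrace(z_values=(x - mean) / sd, source_mean=mean,
                           source_sd=sd, spot_id=spot_id, channel=channel)


# ---------------------------------------------------------------------------
# changepoint segmentation (iterative binary splitting, squared-error cost)


def _best_split(x: np.ndarray, min_duration: int) -> tuple[int, float] | None:
    """Best single changepoint of ``x`` under squared-error cost.

    Returns ``(t, gain)`` for the split minimizing SSE(left) + SSE(right)
    with both sides >= ``min_duration``, or None if the segment is too
    short to split.
    """
    n = x.size
    if n < 2 * min_duration:
        return None
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    t = np.arange(min_duration, n - min_duration + 1)
    left = cs2[t] - cs[t] ** 2 / t
    right = (cs2[n] - cs2[t]) - (cs[n] - cs[t]) ** 2 / (n - t)
    total = cs2[n] - cs[n] ** 2 / n
    sse = left + right
    best = int(np.argmin(sse))
    return int(t[best]), float(total - sse[best])


def _segment(x: np.ndarray, min_duration: int, gate: float) -> list[int]:
    """Recursive binary segmentation; a split is kept when the two new
    segment means differ by more than ``gate``."""
    changepoints: list[int] = []

    def recurse(a: int, b: int) -> None:
        res = _best_split(x[a:b], min_duration)
        if res is None:
            return
        t, gain = res
        if gain <= 0:
            return
        left_mean = x[a:a + t].mean()
        right_mean = x[a + t:b].mean()
        if abs(right_mean - left_mean) <= gate:
            return
        changepoints.append(a + t)
        recurse(a, a + t)
        recurse(a + t, b)

    recurse(0, x.size)
    return sorted(changepoints)


def count_steps_oracle(trace, step_threshold: float = 25.0,
                       min_duration: int = 5, noise_gate: float = 3.0,
                       noise_gate_frac: float = 0.5,
                       channel: str = FARRED) -> StepAnnotation:
    """Count photobleaching steps in a raw-count trace.

    The trace is segmented into piecewise-constant levels by iterative
    binary changepoint splitting (squared-error cost); candidate splits
    must leave segments of at least ``min_duration`` frames and change
    the segment mean by more than ``noise_gate`` times a robust noise SD
    (median absolute successive difference / (0.6745 * sqrt(2))).
    Changepoints are then visited in time order: a downward mean change
    greater than ``step_threshold`` counts as one photobleaching step;
    the first upward change greater than ``step_threshold`` terminates
    counting (``early_stopped``). The trace is marked ``too_noisy`` when
    the post-fit residual SD exceeds ``noise_gate_frac`` of the median
    accepted step size.
    """
    if isinstance(trace, IntensityTrace):
        x = trace.values
        channel = trace.channel
    else:
        x = np.asarray(trace, dtype=float)
    if x.size < 2 * min_duration or not np.all(np.isfinite(x)):
        return StepAnnotation(raw_step_count=0, early_stopped=False,
                              quality="too_noisy", channel=channel)

    diffs = np.diff(x)
    sigma = float(np.median(np.abs(diffs - np.median(diffs)))) / (0.6745 * np.sqrt(2.0))
    gate = noise_gate * sigma
    cps = _segment(x, min_duration, gate)

    bounds = [0, *cps, x.size]
    means = [x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    step_frames: list[int] = []
    step_sizes: list[float] = []
    early = False
    for i, cp in enumerate(cps):
        delta = means[i + 1] - means[i]
        if delta < -step_threshold:
            step_frames.append(cp)
            step_sizes.append(-delta)
        elif delta > step_threshold:
            early = True
            break

    fit = np.concatenate([np.full(b - a, m) for a, b, m in
                          zip(bounds[:-1], bounds[1:], means)])
    residual_sd = float((x - fit).std())
    quality = "accepted"
    if step_sizes and residual_sd > noise_gate_frac * float(np.median(step_sizes)):
        quality = "too_noisy"
    return StepAnnotation(raw_step_count=len(step_frames), early_stopped=early,
                          step_frames=step_frames, step_sizes=step_sizes,
                          quality=quality, channel=channel)


def bin_class(channel: str, annotation: StepAnnotation) -> str:
    """Bin a step annotation into its channel's class set.

    Far-red: too-noisy or 0 steps -> rejected; 1 -> "1-step";
    2 -> "2-step"; >= 3 -> "3-and-higher". Green: exactly one accepted
    step -> "1-step"; anything else (0, >= 2, or too noisy) -> rejected.
    """
    classes_for(channel)  # validates the channel name
    k = annotation.raw_step_count
    if channel == GREEN:
        return "1-step" if (k == 1 and annotation.quality == "accepted") \
            else "rejected"
    if annotation.quality != "accepted" or k == 0:
        return "rejected"
    if k == 1:
        return "1-step"
    if k == 2:
        return "2-step"
    return "3-and-higher"


def bleach_half_time(annotations, n_frames: int, frame_rate: float
                     ) -> tuple[float, float]:
    """Survival-based bleach half-time from first-step frames.

    ``survival(t)`` is the fraction of traces whose first accepted step
    falls after frame ``t`` (traces with no accepted step never bleach
    and are right-censored at infinity). The half-time is the linearly
    interpolated time at which survival crosses 0.5. Returns
    ``(frames, seconds)``.
    """
    first = []
    for ann in annotations:
        if ann.step_frames and ann.quality == "accepted":
            first.append(float(ann.step_frames[0]))
        else:
            first.append(np.inf)
    first = np.asarray(first, dtype=float)
    if first.size == 0 or not np.isfinite(first).any():
        raise ValueError("no accepted first steps; cannot estimate half-time")
    with np.errstate(invalid="ignore"):  # inf - inf in censored quantiles
        half = float(np.quantile(first, 0.5))
    if not np.isfinite(half):
        raise ValueError("insufficient bleaching: survival never reaches 0.5")
    return half, half / frame_rate


class RuleBasedClassifier:
    """Channel classifier that applies the labeling rules directly.

    Shares the ``classify_traces`` interface with the trained CNNs, so
    the five-step pipeline can run with either. Operates on raw counts
    (the step threshold is in camera counts).
    """

    def __init__(self, channel: str, step_threshold: float = 25.0,
                 min_duration: int = 5, noise_gate: float = 3.0,
                 noise_gate_frac: float = 0.5):
        classes_for(channel)
        self.channel = channel
        self.step_threshold = step_threshold
        self.min_duration = min_duration
        self.noise_gate = noise_gate
        self.noise_gate_frac = noise_gate_frac

    def annotate(self, raw_trace) -> StepAnnotation:
        return count_steps_oracle(raw_trace, self.step_threshold,
                                  self.min_duration, self.noise_gate,
                                  self.noise_gate_frac, channel=self.channel)

    def classify_traces(self, raw_traces: np.ndarray) -> np.ndarray:
        raw_traces = np.atleast_2d(np.asarray(raw_traces, dtype=float))
        return np.array([bin_class(self.channel, self.annotate(t))
                         for t in raw_traces])
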