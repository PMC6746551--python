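"""Quantification of movement speed, motor slowing and recovery from tap events.

The primitive observable is a stream of tap events (time + effector label).
A movement *cycle* runs from one occurrence of the first effector through the
whole sequence back to the first effector; speed is expressed in cycles per
10 s so that different effectors and tasks are comparable.  Motor slowing is
the decline of binned speed within a trial; the recovery index compares the
speed flanking a rest break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TapStream",
    "BinnedSeries",
    "SlowingResult",
    "detect_taps",
    "cycle_times",
    "bin_speed",
    "normalise_to_control",
    "recovery_index",
    "fit_slope",
    "pearson_r",
    "pacing_compliance",
    "sliding_rate",
    "slowing_pct",
]


@dataclass
class TapStream:
    """Ordered, effector-tagged tap events for one trial.

    ``effector_cycle`` gives the effector order defining one movement cycle
    (e.g. ``("index", "middle")`` for alternating tapping, or a 4-element
    finger sequence).  A single-effector task has a one-element cycle and its
    cycle times are simply inter-tap intervals.
    """

    times: np.ndarray
    effectors: np.ndarray
    effector_cycle: tuple[str, ...]
    subject: str = ""
    condition: str = ""
    trial: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.effectors = np.asarray(self.effectors, dtype=object)
        if len(self.times) != len(self.effectors):
            raise ValueError("times and effectors must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        known = set(self.effector_cycle)
        if len(self.times) and not set(self.effectors).issubset(known):
            raise ValueError("every effector label must appear in effector_cycle")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject,
                "condition": self.condition,
                "trial": self.trial,
                "time_s": self.times,
                "effector": self.effectors,
            }
        )


@dataclass
class BinnedSeries:
    """Values aggregated into labelled time bins (half-open [start, end))."""

    bin_edges: np.ndarray  # shape (n, 2)
    values: np.ndarray
    unit: str = ""
    overlapping: bool = False

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float).reshape(-1, 2)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.bin_edges):
            raise ValueError("values and bin_edges must have equal length")
        if not self.overlapping:
            starts = self.bin_edges[:, 0]
            ends = self.bin_edges[:, 1]
            if np.any(np.diff(starts) <= 0) or np.any(starts[1:] < ends[:-1] - 1e-12):
                raise ValueError("bins must be ordered and non-overlapping")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SlowingResult:
    """Per-bin speed with the derived slowing summary for one trial/subject."""

    speed: BinnedSeries
    normalised: BinnedSeries | None
    slowing_pct: float
    slope: float


def detect_taps(
    force: np.ndarray,
    fs: float,
    threshold: float | None = None,
    refractory_ms: float = 50.0,
    effector: str = "tap",
) -> TapStream:
    """Detect tap events as rising threshold crossings of a force trace.

    The threshold defaults to 50 % of the trace's 99th-percentile amplitude;
    crossings closer together than the refractory period are merged into one
    event.  A flat trace yields an empty stream.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if refractory_ms <= 0:
        raise ValueError("refractory must be positive")
    force = np.asarray(force, dtype=float)
    if threshold is None:
        peak = np.percentile(force, 99)
        if peak <= 0:
            return TapStream(np.array([]), np.array([]), (effector,))
        threshold = 0.5 * peak
    above = force >= threshold
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if len(force) and above[0]:
        rising = np.concatenate(([0], rising))
    refractory_n = int(round(refractory_ms / 1000.0 * fs))
    kept: list[int] = []
    for i in rising:
        if not kept or i - kept[-1] >= refractory_n:
            kept.append(int(i))
    times = np.asarray(kept, dtype=float) / fs
    return TapStream(times, np.array([effector] * len(times), dtype=object), (effector,))


def cycle_times(stream: TapStream) -> np.ndarray:
    """Durations of completed movement cycles (first effector to first effector).

    Incomplete trailing cycles are dropped.  For single-effector tasks this is
    the inter-tap interval.  Returns an empty array if no cycle completes.
    """
    if len(stream) == 0:
        raise ValueError("empty tap stream")
    first = stream.effector_cycle[0]
    anchor_times = stream.times[stream.effectors == first]
    if len(anchor_times) < 2:
        return np.array([])
    return np.diff(anchor_times)


def _cycle_starts(stream: TapStream) -> np.ndarray:
    first = stream.effector_cycle[0]
    anchors = stream.times[stream.effectors == first]
    return anchors[:-1]  # starts of completed cycles only


def bin_speed(
    stream: TapStream,
    bin_width: float = 10.0,
    duration: float | None = None,
    t0: float | None = None,
    method: str = "count",
) -> BinnedSeries:
    """Binned movement speed in cycles per 10 s.

    ``method="count"`` (default) counts completed cycles per bin — a cycle is
    assigned to the bin containing its start event — rescaled to a 10 s
    basis.  ``method="rate"`` averages instantaneous rates (1/cycle-time) of
    cycles starting within the bin, which is preferable for bins much
    shorter than a cycle count can resolve (e.g. 1 s bins).

    Trial time zero defaults to the first tap of the stream.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(stream) == 0:
        if duration is None:
            raise ValueError("duration required for an empty stream")
        edges = _make_edges(0.0, duration, bin_width)
        return BinnedSeries(edges, np.zeros(len(edges)), unit="cycles per 10 s")

    if t0 is None:
        t0 = float(stream.times[0])
    if duration is None:
        duration = float(stream.times[-1] - t0) + 1e-9
    edges = _make_edges(t0, t0 + duration, bin_width)

    durations = cycle_times(stream)
    starts = _cycle_starts(stream)
    values = np.zeros(len(edges))
    for k, (lo, hi) in enumerate(edges):
        in_bin = (starts >= lo) & (starts < hi)
        if method == "count":
            values[k] = in_bin.sum() * (10.0 / bin_width)
        elif method == "rate":
            values[k] = 10.0 * np.mean(1.0 / durations[in_bin]) if in_bin.any() else 0.0
        else:
            raise ValueError(f"unknown method {method!r}")
    return BinnedSeries(edges, values, unit="cycles per 10 s")


def _make_edges(start: float, stop: float, width: float) -> np.ndarray:
    n = max(1, int(np.ceil((stop - start) / width - 1e-9)))
    lo = start + width * np.arange(n)
    return np.column_stack([lo, lo + width])


def normalise_to_control(
    slowing: BinnedSeries, control: BinnedSeries, per_bin: bool = False
) -> BinnedSeries:
    """Express a slowing-condition series as a fraction of the control condition.

    By default each bin is divided by the subject-level mean control speed
    (one scalar); ``per_bin=True`` divides bin-wise instead (requires equal
    bin counts).
    """
    if slowing.unit != control.unit:
        raise ValueError("series must share a unit")
    if per_bin:
        if len(slowing) != len(control):
            raise ValueError("per-bin normalisation needs equal bin counts")
        denom = control.values
    else:
        denom = np.mean(control.values)
    if np.any(np.asarray(denom) == 0):
        raise ZeroDivisionError("control speed is zero")
    return BinnedSeries(slowing.bin_edges, slowing.values / denom, unit="fraction of control")


def recovery_index(pre_break: BinnedSeries, post_break: BinnedSeries) -> float:
    """Speed in the first 10 s after a break minus the last 10 s before it.

    ``pre_break`` and ``post_break`` are the binned speeds of the trials
    flanking the break; a higher index indicates greater recovery of tapping
    speed during the break.
    """
    if len(pre_break) == 0 or len(post_break) == 0:
        raise ValueError("both flanking trials are required")
    return float(post_break.values[0] - pre_break.values[-1])


def fit_slope(values, x=None) -> float:
    """Ordinary least-squares slope of values against bin index (or given x)."""
    if isinstance(values, BinnedSeries):
        values = values.values
    y = np.asarray(values, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least two points")
    x = np.arange(1, len(y) + 1, dtype=float) if x is None else np.asarray(x, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and values must have equal length")
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def pearson_r(x, y, return_p: bool = False):
    """Sample Pearson correlation (optionally with a two-sided t-test p value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    return (float(res.statistic), float(res.pvalue)) if return_p else float(res.statistic)


def sliding_rate(stream: TapStream, window: float = 1.0, dt: float = 0.1) -> np.ndarray:
    """Sliding-average cycle frequency (Hz) sampled every ``dt`` seconds.

    The instantaneous rate is the step function 1/cycle-duration over each
    completed cycle; a boxcar of length ``window`` is averaged over it (time
    points whose window is not fully covered by cycles are dropped).
    """
    starts = _cycle_starts(stream)
    durations = cycle_times(stream)
    if len(durations) == 0:
        return np.array([])
    t0 = float(starts[0])
    t1 = float(starts[-1] + durations[-1])
    fine = 0.01
    grid = np.arange(t0, t1, fine)
    inst = np.interp(grid, starts, 1.0 / durations)  # step-ish rate profile
    n_win = max(1, int(round(window / fine)))
    kernel = np.ones(n_win) / n_win
    smooth = np.convolve(inst, kernel, mode="valid")
    out_t = np.arange(t0 + window, t1, dt)
    idx = np.clip(((out_t - window - t0) / fine).astype(int), 0, len(smooth) - 1)
    return smooth[idx]


def pacing_compliance(rate_trace: np.ndarray, target: float, tol: float = 0.2) -> float:
    """Fraction of samples of a frequency trace within ``target +/- tol`` Hz."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    rate_trace = np.asarray(rate_trace, dtype=float)
    if len(rate_trace) == 0:
        raise ValueError("empty rate trace")
    return float(np.mean(np.abs(rate_trace - target) <= tol))


def slowing_pct(series: BinnedSeries) -> float:
    """Percent decline from the first to the last bin of a speed series."""
    first, last = series.values[0], series.values[-1]
    if first == 0:
        raise ZeroDivisionError("first bin speed is zero")
    return float(100.0 * (first - last) / first)
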