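"""EMG envelope extraction and the agonist-normalised coactivation index.

Coactivation (cocontraction) of an antagonist muscle pair is scored as the
area under the pointwise minimum of the two rectified-and-smoothed EMG
envelopes, normalised to the area under the agonist envelope.  The index is
0 for perfectly alternating bursts and 1 when the antagonist envelope covers
the agonist everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .tapping import BinnedSeries

__all__ = [
    "EmgTrace",
    "Envelope",
    "extract_envelope",
    "coactivation_index",
    "bin_coactivation",
    "background_rms",
]


@dataclass
class EmgTrace:
    """Multi-channel raw EMG: sampling rate plus named channel arrays (mV)."""

    fs: float
    channels: dict[str, np.ndarray]
    subject: str = ""
    condition: str = ""
    trial: int = 0

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class Envelope:
    """Non-negative amplitude envelope of one EMG channel."""

    fs: float
    samples: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


def _butter_zero_phase(x: np.ndarray, fs: float, cutoff, btype: str, order: int = 4):
    sos = signal.butter(order, cutoff, btype=btype, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def extract_envelope(raw: np.ndarray, fs: float, channel: str = "") -> Envelope:
    """High-pass at 20 Hz, full-wave rectify, low-pass at 10 Hz (zero-phase).

    Both filters are 4th-order Butterworth applied forward-backward, so the
    envelope is delay-free.  The output has the same length as the input.
    """
    if fs <= 40:
        raise ValueError("sampling rate too low for the 20 Hz / 10 Hz band")
    x = np.asarray(raw, dtype=float)
    hp = _butter_zero_phase(x, fs, 20.0, "highpass")
    env = _butter_zero_phase(np.abs(hp), fs, 10.0, "lowpass")
    return Envelope(fs=fs, samples=np.maximum(env, 0.0), channel=channel)


def coactivation_index(agonist: Envelope, antagonist: Envelope) -> float:
    """Joint area under the two envelopes divided by the agonist area.

    "Joint area" is the area under the pointwise minimum; integration is
    trapezoidal on the shared sample grid.
    """
    if agonist.fs != antagonist.fs or len(agonist.samples) != len(antagonist.samples):
        raise ValueError("envelopes must share sampling rate and length")
    dx = 1.0 / agonist.fs
    area_ag = np.trapezoid(agonist.samples, dx=dx)
    if area_ag <= 0:
        raise ZeroDivisionError("agonist envelope area is zero")
    joint = np.trapezoid(np.minimum(agonist.samples, antagonist.samples), dx=dx)
    return float(joint / area_ag)


def bin_coactivation(
    agonist: Envelope,
    antagonist: Envelope,
    bin_width: float = 10.0,
    control_value: float | None = None,
) -> BinnedSeries:
    """Coactivation index per time bin, optionally normalised to a control value."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n = len(agonist.samples)
    per_bin = int(round(bin_width * agonist.fs))
    n_bins = n // per_bin
    values = []
    edges = []
    for k in range(n_bins):
        sl = slice(k * per_bin, (k + 1) * per_bin)
        a = Envelope(agonist.fs, agonist.samples[sl])
        b = Envelope(antagonist.fs, antagonist.samples[sl])
        values.append(coactivation_index(a, b))
        edges.append((k * bin_width, (k + 1) * bin_width))
    values = np.asarray(values)
    unit = "coactivation index"
    if control_value is not None:
        if control_value == 0:
            raise ZeroDivisionError("control coactivation is zero")
        values = values / control_value
        unit = "fraction of control"
    return BinnedSeries(np.asarray(edges), values, unit=unit)


def background_rms(
    raw: np.ndarray,
    fs: float,
    pulse_time: float,
    window: tuple[float, float] = (-0.110, -0.010),
) -> float:
    """RMS of the raw EMG in a pre-pulse window (default 110 to 10 ms before).

    Used to screen TMS trials for muscle activity before the stimulus; times
    in ``window`` are in seconds relative to the pulse.
    """
    x = np.asarray(raw, dtype=float)
    i0 = int(round((pulse_time + window[0]) * fs))
    i1 = int(round((pulse_time + window[1]) * fs))
    if i0 < 0 or i1 > len(x) or i1 <= i0:
        raise ValueError("background window lies outside the epoch")
    seg = x[i0:i1]
    return float(np.sqrt(np.mean(seg**2)))
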