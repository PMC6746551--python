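"""Band-limited amplitude envelopes and break-period binning for source traces.

Operates on already source-localised single-channel time series recorded
during rest breaks after tapping.  The alpha (mu) rhythm amplitude over the
sensorimotor cortex indexes inhibitory tone: its suppression after tapping,
and the speed with which it relaxes back to baseline, quantify the recovery
of cortical inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .emg import Envelope

__all__ = [
    "BandSpec",
    "BreakPower",
    "ALPHA",
    "BETA",
    "GAMMA",
    "ALPHA_NARROW",
    "BETA_WIDE",
    "band_envelope",
    "bin_break_power",
    "first_principal_component",
]


@dataclass(frozen=True)
class BandSpec:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError("band edges must satisfy 0 < low < high")


# Band presets.  The analysis preset uses alpha 8-14 / beta 15-30; the
# alternative narrow-alpha convention (8-12 / 14-30) is also provided.
ALPHA = BandSpec("alpha", 8.0, 14.0)
BETA = BandSpec("beta", 15.0, 30.0)
GAMMA = BandSpec("gamma", 30.0, 40.0)
ALPHA_NARROW = BandSpec("alpha", 8.0, 12.0)
BETA_WIDE = BandSpec("beta", 14.0, 30.0)


@dataclass
class BreakPower:
    """Mean band amplitude in the three 10 s epochs of a 30 s break."""

    epochs: np.ndarray  # length 3
    condition: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if len(self.epochs) != 3:
            raise ValueError("a 30 s break has exactly three 10 s epochs")


def band_envelope(
    x: np.ndarray, fs: float, band: BandSpec, method: str = "block"
) -> Envelope:
    """Band-pass, rectify and smooth to one amplitude value per second.

    ``method="block"`` (default) averages the rectified signal in
    non-overlapping 1 s blocks; ``method="sliding"`` applies a true 1 s
    moving average and then samples at 1 Hz.
    """
    if band.high >= fs / 2:
        raise ValueError("band must lie below the Nyquist frequency")
    x = np.asarray(x, dtype=float)
    sos = signal.butter(4, (band.low, band.high), btype="bandpass", fs=fs, output="sos")
    rect = np.abs(signal.sosfiltfilt(sos, x))
    n_per_s = int(round(fs))
    n_sec = len(rect) // n_per_s
    if method == "block":
        vals = rect[: n_sec * n_per_s].reshape(n_sec, n_per_s).mean(axis=1)
    elif method == "sliding":
        kernel = np.ones(n_per_s) / n_per_s
        smooth = np.convolve(rect, kernel, mode="same")
        centers = (np.arange(n_sec) + 0.5) * n_per_s
        vals = smooth[centers.astype(int)]
    else:
        raise ValueError(f"unknown method {method!r}")
    return Envelope(fs=1.0, samples=vals, channel=band.name)


def bin_break_power(envelope: Envelope, condition: str = "") -> BreakPower:
    """Mean amplitude over seconds 0-10, 10-20 and 20-30 of a break."""
    vals = envelope.samples
    if len(vals) < 30:
        raise ValueError("envelope must cover a full 30 s break")
    epochs = np.array([vals[0:10].mean(), vals[10:20].mean(), vals[20:30].mean()])
    return BreakPower(epochs=epochs, condition=condition)


def first_principal_component(voxels: np.ndarray) -> np.ndarray:
    """Collapse a (n_samples, n_voxels) ROI array to its first PC time course.

    The sign is fixed so the component correlates positively with the mean
    across voxels.
    """
    voxels = np.asarray(voxels, dtype=float)
    centred = voxels - voxels.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    pc = centred @ vt[0]
    if np.dot(pc, centred.mean(axis=1)) < 0:
        pc = -pc
    return pc
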