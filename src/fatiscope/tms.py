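"""MEP amplitude extraction, trial screening, SICI and surround inhibition.

Paired-pulse short-interval intracortical inhibition (SICI) compares motor
evoked potentials (MEPs) after a conditioning-plus-test pulse pair (CS+TS)
with test-pulse-only trials (TS):  inhibition = 1 - mean(CS+TS)/mean(TS),
so larger values mean stronger GABA_A-ergic inhibition.  Surround
inhibition compares the MEP of a non-involved muscle probed at movement
onset (TMS_Move) with the same probe at rest (TMS_Con); ratios below one
indicate that the moving effector suppresses its neighbours.

Trials pass a three-stage screening cascade before aggregation:

1. remove trials whose pre-pulse background EMG RMS exceeds 0.1 mV;
2. remove trials whose background RMS deviates from the per-pulse-type mean
   by more than 2.5 standard deviations (computed on stage-1 survivors);
3. remove MEP amplitudes outside the Tukey fences
   [Q1 - 1.5*IQR, Q3 + 1.5*IQR], computed per grouping cell on stage-2
   survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emg import background_rms

__all__ = [
    "MepTrial",
    "MepSession",
    "ScreeningReport",
    "mep_amplitude",
    "screen_trials",
    "sici",
    "surround_inhibition",
    "assign_timepoints",
    "normalise_to_pre",
    "si_subject_gate",
    "SICI_BREAK_WINDOWS",
    "SICI_NARRATIVE_WINDOWS",
    "SURROUND_BREAK_WINDOWS",
]

# Break-interval schemes for mapping pulse times (s, relative to break onset)
# to timepoint labels.  The printed SICI intervals overlap; a pulse may carry
# several labels and contributes to each.  The non-overlapping narrative
# 0-10/10-20/20-30 s bins are exposed as an alternative.
SICI_BREAK_WINDOWS = {"bin1": (3.5, 22.0), "bin2": (7.5, 27.5), "bin3": (12.5, 33.5)}
SICI_NARRATIVE_WINDOWS = {"bin1": (0.0, 10.0), "bin2": (10.0, 20.0), "bin3": (20.0, 30.0)}
SURROUND_BREAK_WINDOWS = {"bin1": (5.0, 14.0), "bin2": (19.0, 32.0), "bin3": (33.0, 50.0)}

_SCHEMES = {
    "sici": SICI_BREAK_WINDOWS,
    "sici_narrative": SICI_NARRATIVE_WINDOWS,
    "surround": SURROUND_BREAK_WINDOWS,
}


@dataclass
class MepTrial:
    """One TMS trial: epoch samples around the pulse plus pulse metadata.

    ``epoch_start`` is the time of the first epoch sample relative to the
    pulse (negative; the epoch must cover at least [-120 ms, +60 ms]).
    ``timepoint`` labels the measurement block ("Pre", "Post", a break-bin
    label, or "" when it is to be derived from ``pulse_time``).
    """

    pulse_type: str  # "TS" | "CS+TS" | "TMS_Move" | "TMS_Con"
    pulse_time: float  # s within the break (NaN for Pre/Post blocks)
    epoch: np.ndarray  # mV
    fs: float
    epoch_start: float = -0.2
    muscle: str = "FDI"
    timepoint: str = ""
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.epoch = np.asarray(self.epoch, dtype=float)
        t_last = self.epoch_start + len(self.epoch) / self.fs
        if self.epoch_start > -0.120 or t_last < 0.060:
            raise ValueError("epoch must cover at least [-120 ms, +60 ms] around the pulse")


@dataclass
class MepSession:
    """All TMS trials of one subject and condition (one experimental day)."""

    trials: list[MepTrial]
    subject: str = ""
    condition: str = ""

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class ScreeningReport:
    """Per-trial screening outcome and the resulting inclusion fraction.

    ``table`` has one row per trial with columns ``trial_id, pulse_type,
    timepoint, background_rms, amplitude, flag`` where flag is one of
    ``kept``, ``removed_bgEMG_abs``, ``removed_bgEMG_sd``,
    ``removed_MEP_fence``.
    """

    table: pd.DataFrame

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[self.table["flag"] == "kept"]

    @property
    def inclusion_fraction(self) -> float:
        return float((self.table["flag"] == "kept").mean())

    def kept_amplitudes(self, pulse_type: str, timepoint: str) -> np.ndarray:
        k = self.kept
        m = (k["pulse_type"] == pulse_type) & (k["timepoint"] == timepoint)
        return k.loc[m, "amplitude"].to_numpy()


def mep_amplitude(trial: MepTrial, response_window: tuple[float, float] = (0.015, 0.060)) -> float:
    """Peak-to-peak amplitude (mV) of the epoch within the response window."""
    lo, hi = response_window
    i0 = int(round((lo - trial.epoch_start) * trial.fs))
    i1 = int(round((hi - trial.epoch_start) * trial.fs))
    if i0 < 0 or i1 > len(trial.epoch) or i1 <= i0:
        raise ValueError("response window lies outside the epoch")
    seg = trial.epoch[i0:i1]
    return float(seg.max() - seg.min())


def _quartiles(x: np.ndarray, convention: str) -> tuple[float, float]:
    if convention == "linear":
        return tuple(np.percentile(x, [25, 75]))  # type: ignore[return-value]
    if convention == "tukey_hinges":
        s = np.sort(x)
        n = len(s)
        half = (n + 1) // 2
        lower, upper = s[:half], s[n - half:]
        return float(np.median(lower)), float(np.median(upper))
    raise ValueError(f"unknown quartile convention {convention!r}")


def screen_trials(
    session: MepSession,
    bg_abs_limit: float = 0.1,
    bg_sd_limit: float = 2.5,
    fence_factor: float = 1.5,
    quartile_convention: str = "linear",
    response_window: tuple[float, float] = (0.015, 0.060),
    bg_window: tuple[float, float] = (-0.110, -0.010),
    min_fence_group: int = 4,
) -> ScreeningReport:
    """Apply the three screening stages in order and report per-trial flags.

    Stage 2 statistics are computed per pulse type on stage-1 survivors;
    stage 3 fences are computed within each (timepoint, pulse type) cell on
    stage-2 survivors.  Cells with fewer than ``min_fence_group`` trials are
    left unfenced (flagged kept) rather than raising.
    """
    rows = []
    for trial in session.trials:
        pulse_sample_time = -trial.epoch_start  # pulse position within epoch
        bg = background_rms(trial.epoch, trial.fs, pulse_sample_time, bg_window)
        amp = mep_amplitude(trial, response_window)
        rows.append(
            {
                "trial_id": trial.trial_id,
                "pulse_type": trial.pulse_type,
                "timepoint": trial.timepoint,
                "background_rms": bg,
                "amplitude": amp,
                "flag": "kept",
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return ScreeningReport(table)

    # stage 1: absolute background limit
    table.loc[table["background_rms"] > bg_abs_limit, "flag"] = "removed_bgEMG_abs"

    # stage 2: background outliers per pulse type among stage-1 survivors
    for ptype, grp in table[table["flag"] == "kept"].groupby("pulse_type"):
        mu = grp["background_rms"].mean()
        sd = grp["background_rms"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        bad = grp.index[np.abs(grp["background_rms"] - mu) > bg_sd_limit * sd]
        table.loc[bad, "flag"] = "removed_bgEMG_sd"

    # stage 3: MEP amplitude fences per (timepoint, pulse type) cell
    survivors = table[table["flag"] == "kept"]
    for (_, _), grp in survivors.groupby(["timepoint", "pulse_type"]):
        if len(grp) < min_fence_group:
            continue
        q1, q3 = _quartiles(grp["amplitude"].to_numpy(), quartile_convention)
        iqr = q3 - q1
        lo, hi = q1 - fence_factor * iqr, q3 + fence_factor * iqr
        bad = grp.index[(grp["amplitude"] < lo) | (grp["amplitude"] > hi)]
        table.loc[bad, "flag"] = "removed_MEP_fence"

    return ScreeningReport(table)


def sici(ts: np.ndarray, cs_ts: np.ndarray) -> float:
    """Inhibition = 1 - mean(CS+TS)/mean(TS) on kept trials.

    The ratio uses cell means (not per-trial pairs) because TS and CS+TS
    pulses are delivered as separate pseudo-randomised trials.
    """
    ts = np.asarray(ts, dtype=float)
    cs_ts = np.asarray(cs_ts, dtype=float)
    if len(ts) == 0 or len(cs_ts) == 0:
        raise ValueError("both pulse types need at least one kept trial")
    m_ts = ts.mean()
    if m_ts == 0:
        raise ZeroDivisionError("mean TS amplitude is zero")
    return float(1.0 - cs_ts.mean() / m_ts)


def surround_inhibition(move: np.ndarray, con: np.ndarray) -> float:
    """SI ratio = mean(TMS_Move)/mean(TMS_Con); values < 1 indicate inhibition."""
    move = np.asarray(move, dtype=float)
    con = np.asarray(con, dtype=float)
    if len(move) == 0 or len(con) == 0:
        raise ValueError("both pulse types need at least one kept trial")
    m_con = con.mean()
    if m_con <= 0:
        raise ZeroDivisionError("mean TMS_Con amplitude is zero")
    return float(move.mean() / m_con)


def assign_timepoints(pulse_times, scheme: str = "sici") -> list[tuple[str, ...]]:
    """Map pulse times (s within the break) to break-bin labels.

    With the overlapping printed SICI intervals a pulse may fall in several
    windows and receives every matching label; aggregation then counts it in
    each.  Pulses outside all windows are labelled ``("unassigned",)``.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    windows = _SCHEMES[scheme]
    out: list[tuple[str, ...]] = []
    for t in np.asarray(pulse_times, dtype=float):
        labels = tuple(name for name, (lo, hi) in windows.items() if lo <= t <= hi)
        out.append(labels if labels else ("unassigned",))
    return out


def normalise_to_pre(break_values, pre_value: float) -> np.ndarray:
    """Divide per-bin break values by the subject's Pre measurement."""
    if not np.isfinite(pre_value) or pre_value == 0:
        raise ZeroDivisionError("Pre value must be finite and non-zero")
    return np.asarray(break_values, dtype=float) / pre_value


def si_subject_gate(pre_si: float, threshold: float = 1.0) -> bool:
    """True (include) iff the subject shows surround inhibition at Pre (SI < 1)."""
    return bool(pre_si < threshold)
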