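"""Seeded synthetic cohorts: tap streams, force, EMG, MEP sessions, EEG breaks.

Every dataset is driven by the surround-inhibition fatigue model: a subject
is a draw of model parameters, a trial is a simulated trajectory, and each
recording modality is rendered from that trajectory with modality-specific
noise.  The ground truth behind every rendered signal (planted slowing,
per-bin coactivation, inhibition levels, envelope recovery constants,
contaminated trials) is written to a manifest so analyses can be validated
by parameter recovery.

All randomness flows through a single ``numpy`` Generator seeded from the
config, so identical (config, seed) pairs produce byte-identical datasets.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emg import EmgTrace
from .model import ModelParams, ModelTrajectory, ProtocolSpec, simulate_trial
from .tapping import TapStream
from .tms import MepSession, MepTrial, SICI_NARRATIVE_WINDOWS, SURROUND_BREAK_WINDOWS

__all__ = [
    "CohortConfig",
    "sample_subject_params",
    "generate_taps",
    "render_force",
    "generate_emg",
    "generate_mep_session",
    "generate_eeg_breaks",
    "generate_cohort",
]

BREAK_LENGTHS = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

# Planted inhibition / surround-inhibition levels per condition.  The slowing
# condition releases inhibition immediately after tapping (low SICI in the
# first break bin) and recovers within the break; the control condition shows
# only a minor, quickly recovering release.
SICI_PROFILE_SLOWING = {"Pre": 0.45, "bin1": 0.20, "bin2": 0.35, "bin3": 0.45, "Post": 0.45}
SICI_PROFILE_CONTROL = {"Pre": 0.45, "bin1": 0.38, "bin2": 0.42, "bin3": 0.45, "Post": 0.45}
SI_PROFILE_SLOWING = {"Pre": 0.40, "bin1": 0.60, "bin2": 0.48, "bin3": 0.40, "Post": 0.40}
SI_PROFILE_CONTROL = {"Pre": 0.40, "bin1": 0.45, "bin2": 0.42, "bin3": 0.40, "Post": 0.40}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Subject-to-subject variability multiplies the base model parameters by
    log-normal factors: ``lambda_cv`` scales the fatigue and recovery rates
    *jointly* (subjects who slow faster also recover faster, the coupling
    observed behaviourally), ``v0_cv`` scales maximal speed and ``beta_cv``
    the overlap-to-slowing coupling.
    """

    n_subjects: int = 17
    seed: int = 0
    base_params: ModelParams = field(default_factory=ModelParams)
    lambda_cv: float = 0.35
    v0_cv: float = 0.08
    beta_cv: float = 0.08
    jitter_cv: float = 0.05
    force_noise_sd: float = 0.05
    emg_noise_sd: float = 0.01
    mep_sigma_log: float = 0.3
    mep_contamination_rate: float = 0.05
    mep_n_per_cell: int = 24
    mep_n_pre_post: int = 18
    eeg_tau_slowing: float = 12.0
    eeg_tau_control: float = 3.0
    eeg_depth: float = 0.6
    eeg_noise_sd: float = 0.1
    n_trials: int = 2
    n_eeg_breaks: int = 4
    tap_s: float = 30.0
    control_tap_s: float = 10.0
    break_s: float = 30.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("lambda_cv", "v0_cv", "beta_cv", "jitter_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def sample_subject_params(config: CohortConfig, rng: np.random.Generator) -> ModelParams:
    """Draw one subject's model parameters around the cohort base values."""
    base = config.base_params

    def lognorm(cv: float) -> float:
        if cv == 0:
            return 1.0
        sigma = math.sqrt(math.log(1 + cv**2))
        return float(rng.lognormal(mean=-sigma**2 / 2, sigma=sigma))

    lam = lognorm(config.lambda_cv)
    return dataclasses.replace(
        base,
        v0=base.v0 * lognorm(config.v0_cv),
        beta=min(base.beta * lognorm(config.beta_cv), 0.95 / 0.45),
        lambda_dec=base.lambda_dec * lam,
        lambda_rec=base.lambda_rec * lam,
    )


# ---------------------------------------------------------------------------
# tap streams and force traces
# ---------------------------------------------------------------------------

def generate_taps(
    trajectory: ModelTrajectory,
    jitter_cv: float = 0.05,
    rng: np.random.Generator | None = None,
    effector_cycle: tuple[str, ...] = ("index", "middle"),
    subject: str = "",
    condition: str = "",
    trial: int = 0,
) -> TapStream:
    """Realise a tap stream as a renewal process along the speed trajectory.

    Cycle durations are gamma-distributed with mean ``1/speed(t)`` and the
    given coefficient of variation; within a cycle the effectors fire in
    order at equal sub-intervals.  Taps are only produced during tapping
    segments of the trajectory.
    """
    if jitter_cv < 0:
        raise ValueError("jitter_cv must be non-negative")
    if np.any(trajectory.speed_t <= 0):
        raise ValueError("trajectory speed must be positive everywhere")
    if rng is None:
        rng = np.random.default_rng()
    times: list[float] = []
    effectors: list[str] = []
    t_grid = trajectory.times
    dt = t_grid[1] - t_grid[0] if len(t_grid) > 1 else 0.01
    n_eff = len(effector_cycle)

    # iterate over contiguous tapping segments
    mask = trajectory.tapping
    boundaries = np.flatnonzero(np.diff(mask.astype(int))) + 1
    seg_edges = np.concatenate(([0], boundaries, [len(mask)]))
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        if not mask[a]:
            continue
        t = float(t_grid[a])
        t_end = float(t_grid[b - 1]) + dt
        while t < t_end:
            # a cycle started before the segment end is completed in full
            # (movements are not truncated mid-cycle), so the closing
            # first-effector tap of the last cycle may spill slightly past
            # the nominal segment end.
            speed = float(np.interp(t, t_grid, trajectory.speed_t))
            mean_T = 1.0 / speed
            if jitter_cv == 0:
                T = mean_T
            else:
                shape = 1.0 / jitter_cv**2
                T = float(rng.gamma(shape, mean_T / shape))
            for j, eff in enumerate(effector_cycle):
                times.append(t + T * j / n_eff)
                effectors.append(eff)
            t += T
        # closing first-effector tap so the final cycle of the segment is
        # complete (its duration is measurable)
        times.append(t)
        effectors.append(effector_cycle[0])
    return TapStream(
        np.asarray(times), np.asarray(effectors, dtype=object), effector_cycle,
        subject=subject, condition=condition, trial=trial,
    )


def render_force(
    stream: TapStream,
    fs: float = 1000.0,
    duration: float | None = None,
    noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
    pulse_ms: float = 30.0,
) -> np.ndarray:
    """Render a force trace: a half-sine pulse per tap plus Gaussian noise."""
    if rng is None:
        rng = np.random.default_rng()
    if duration is None:
        duration = float(stream.times[-1]) + 0.1 if len(stream) else 1.0
    n = int(round(duration * fs))
    trace = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    n_pulse = int(round(pulse_ms / 1000.0 * fs))
    pulse = np.sin(np.pi * np.arange(n_pulse) / n_pulse)
    for t in stream.times:
        i0 = int(round(t * fs))
        i1 = min(i0 + n_pulse, n)
        if i0 < n:
            trace[i0:i1] += pulse[: i1 - i0]
    return trace


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def generate_emg(
    trajectory: ModelTrajectory,
    fs: float = 1000.0,
    rng: np.random.Generator | None = None,
    coa_profile: np.ndarray | None = None,
    burst_width: float = 0.5,
    noise_sd: float = 0.01,
    window: tuple[float, float] | None = None,
    subject: str = "",
    condition: str = "",
) -> EmgTrace:
    """Render agonist/antagonist EMG whose measured coactivation tracks the model.

    The agonist (APB) bursts at movement phase 0 and the antagonist (EPL) at
    phase pi, each as band-limited noise (20-450 Hz) under a Gaussian phase
    envelope.  A copy of the agonist-phase envelope scaled by the momentary
    coactivation level leaks into the antagonist channel, so the
    envelope-overlap index recovers the planted coactivation profile.

    ``coa_profile`` (same grid as the trajectory) overrides the model's
    ``coa_t``; ``window`` restricts rendering to a time range (default: the
    first tapping segment).
    """
    if fs < 500:
        raise ValueError("fs must be at least 500 Hz")
    if rng is None:
        rng = np.random.default_rng()
    t_grid = trajectory.times
    coa_t = trajectory.coa_t if coa_profile is None else np.asarray(coa_profile, dtype=float)
    if len(coa_t) != len(t_grid):
        raise ValueError("coa_profile must match the trajectory grid")

    if window is None:
        first_tap = np.flatnonzero(trajectory.tapping)
        if len(first_tap) == 0:
            raise ValueError("trajectory has no tapping segment")
        i0 = int(first_tap[0])
        stops = np.flatnonzero(~trajectory.tapping[i0:])
        n_seg = int(stops[0]) if len(stops) else len(t_grid) - i0
        dt_grid = t_grid[1] - t_grid[0] if len(t_grid) > 1 else 0.01
        window = (float(t_grid[i0]), float(t_grid[i0] + n_seg * dt_grid))

    t = np.arange(window[0], window[1], 1.0 / fs)
    speed = np.interp(t, t_grid, trajectory.speed_t)
    coa = np.interp(t, t_grid, coa_t)
    phase = 2 * np.pi * np.cumsum(speed) / fs  # integrated movement phase

    def phase_env(center: float) -> np.ndarray:
        d = np.mod(phase - center + np.pi, 2 * np.pi) - np.pi
        return np.exp(-(d**2) / (2 * burst_width**2))

    env_ag = phase_env(0.0)
    env_ant = phase_env(np.pi) + coa * env_ag

    def carrier(n: int) -> np.ndarray:
        from scipy import signal as sp_signal

        white = rng.normal(0.0, 1.0, n)
        sos = sp_signal.butter(4, (20.0, min(450.0, 0.45 * fs)), btype="bandpass",
                               fs=fs, output="sos")
        return sp_signal.sosfilt(sos, white)

    apb = carrier(len(t)) * env_ag
    epl = carrier(len(t)) * env_ant
    if noise_sd > 0:
        apb = apb + rng.normal(0.0, noise_sd, len(t))
        epl = epl + rng.normal(0.0, noise_sd, len(t))
    return EmgTrace(fs=fs, channels={"APB": apb, "EPL": epl},
                    subject=subject, condition=condition)


# ---------------------------------------------------------------------------
# MEP sessions
# ---------------------------------------------------------------------------

_PULSE_TYPES = {"sici": ("TS", "CS+TS"), "surround": ("TMS_Con", "TMS_Move")}
_TIME_DRAWS = {
    "sici": {k: (lo + 0.5, hi - 0.5) for k, (lo, hi) in SICI_NARRATIVE_WINDOWS.items()},
    "surround": {k: (lo, hi) for k, (lo, hi) in SURROUND_BREAK_WINDOWS.items()},
}


def _mep_epoch(
    amplitude: float,
    fs: float,
    rng: np.random.Generator,
    bg_rms: float,
    epoch_start: float = -0.2,
    epoch_len: float = 0.3,
    onset: float = 0.018,
    period: float = 0.032,
) -> np.ndarray:
    """One epoch: background noise of given RMS plus a biphasic MEP wave.

    The MEP is a triangular biphasic deflection of peak-to-peak
    ``amplitude`` starting at ``onset`` seconds after the pulse, well inside
    the default 15-60 ms response window.  Its vertices fall exactly on the
    sample grid so the planted peak-to-peak value is recovered exactly in
    the noise-free case.
    """
    n = int(round(epoch_len * fs))
    epoch = rng.normal(0.0, bg_rms, n) if bg_rms > 0 else np.zeros(n)
    t = np.arange(n) / fs + epoch_start
    q = period / 4.0
    knots_t = onset + np.array([0.0, q, 3 * q, 4 * q])
    knots_v = (amplitude / 2.0) * np.array([0.0, 1.0, -1.0, 0.0])
    in_wave = (t >= knots_t[0]) & (t <= knots_t[-1])
    epoch[in_wave] += np.interp(t[in_wave], knots_t, knots_v)
    return epoch


def generate_mep_session(
    inhibition_profile: dict[str, float],
    n_per_cell: int = 24,
    contamination_rate: float = 0.05,
    rng: np.random.Generator | None = None,
    mode: str = "sici",
    n_pre_post: int = 18,
    sigma_log: float = 0.3,
    ts_median: float = 1.0,
    fs: float = 5000.0,
    bg_rms: float = 0.005,
    subject: str = "",
    condition: str = "",
) -> tuple[MepSession, dict]:
    """Generate a full TMS session with planted inhibition per timepoint.

    In ``sici`` mode the profile maps timepoints to inhibition levels
    (CS+TS median = TS median * (1 - inhibition)); in ``surround`` mode to
    SI ratios (TMS_Move median = TMS_Con median * ratio).  Amplitudes are
    log-normal around the cell median; a ``contamination_rate`` fraction of
    trials gets pre-pulse background RMS drawn uniformly from
    [0.12, 0.3] mV, comfortably above the 0.1 mV screening cut.

    Returns the session plus a ground-truth dict (planted levels and the ids
    of contaminated trials).
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    if any(v >= 1 for v in inhibition_profile.values()) and mode == "sici":
        raise ValueError("inhibition levels must be < 1")
    if rng is None:
        rng = np.random.default_rng()
    ref_type, mod_type = _PULSE_TYPES[mode]

    trials: list[MepTrial] = []
    contaminated: list[int] = []
    trial_id = 0
    for timepoint, level in inhibition_profile.items():
        n_cell = n_pre_post if timepoint in ("Pre", "Post") else n_per_cell
        for pulse_type in (ref_type, mod_type):
            if pulse_type == ref_type:
                median = ts_median
            else:
                median = ts_median * ((1.0 - level) if mode == "sici" else level)
            for _ in range(n_cell):
                amp = float(median * rng.lognormal(0.0, sigma_log)) if sigma_log > 0 else median
                contam = rng.random() < contamination_rate
                rms = float(rng.uniform(0.12, 0.3)) if contam else bg_rms
                if timepoint in ("Pre", "Post"):
                    pulse_time = math.nan
                else:
                    lo, hi = _TIME_DRAWS[mode][timepoint]
                    pulse_time = float(rng.uniform(lo, hi))
                trials.append(
                    MepTrial(
                        pulse_type=pulse_type,
                        pulse_time=pulse_time,
                        epoch=_mep_epoch(amp, fs, rng, rms),
                        fs=fs,
                        timepoint=timepoint,
                        trial_id=trial_id,
                    )
                )
                if contam:
                    contaminated.append(trial_id)
                trial_id += 1
    # pseudo-randomise trial order (ids keep identity)
    order = rng.permutation(len(trials))
    session = MepSession([trials[i] for i in order], subject=subject, condition=condition)
    truth = {"profile": dict(inhibition_profile), "mode": mode,
             "contaminated_trials": sorted(contaminated)}
    return session, truth


# ---------------------------------------------------------------------------
# EEG breaks
# ---------------------------------------------------------------------------

def generate_eeg_breaks(
    recovery_tau: float,
    n_breaks: int = 4,
    rng: np.random.Generator | None = None,
    depth: float = 0.6,
    amplitude: float = 1.0,
    f_osc: float = 10.0,
    fs: float = 200.0,
    duration: float = 30.0,
    noise_sd: float = 0.1,
) -> np.ndarray:
    """Alpha-band source traces for rest breaks after tapping.

    The oscillation amplitude starts suppressed by ``depth`` and relaxes
    exponentially back to baseline with time constant ``recovery_tau``;
    broadband Gaussian noise is added on top.  Returns an array of shape
    (n_breaks, duration*fs).
    """
    if recovery_tau <= 0:
        raise ValueError("recovery_tau must be positive")
    if rng is None:
        rng = np.random.default_rng()
    t = np.arange(int(round(duration * fs))) / fs
    amp = amplitude * (1.0 - depth * np.exp(-t / recovery_tau))
    out = np.empty((n_breaks, len(t)))
    for k in range(n_breaks):
        phi = rng.uniform(0, 2 * np.pi)
        x = amp * np.sin(2 * np.pi * f_osc * t + phi)
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, len(t))
        out[k] = x
    return out


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def _trajectory_speed_bins(traj: ModelTrajectory, t0: float, t1: float,
                           width: float = 10.0) -> list[float]:
    out = []
    t = t0
    while t + width <= t1 + 1e-9:
        m = (traj.times >= t) & (traj.times < t + width)
        out.append(float(traj.speed_t[m].mean() * 10.0))  # cycles per 10 s
        t += width
    return out


def _subject_truth(params: ModelParams, config: CohortConfig) -> dict:
    """Noise-free planted quantities for one subject."""
    proto = ProtocolSpec.tap_then_rest(config.tap_s, config.break_s)
    traj = simulate_trial(params, proto, config.dt)
    bins = _trajectory_speed_bins(traj, 0.0, config.tap_s)
    coa_bins = []
    t = 0.0
    while t + 10.0 <= config.tap_s + 1e-9:
        m = (traj.times >= t) & (traj.times < t + 10.0)
        coa_bins.append(float(traj.coa_t[m].mean()))
        t += 10.0
    slowing_pct = 100.0 * (bins[0] - bins[-1]) / bins[0]

    rec_idx = {}
    for brk in BREAK_LENGTHS:
        p = ProtocolSpec(segments=(("tapping", config.tap_s), ("rest", brk), ("tapping", 10.0)))
        tr = simulate_trial(params, p, config.dt)
        pre = _trajectory_speed_bins(tr, config.tap_s - 10.0, config.tap_s)[0]
        post = _trajectory_speed_bins(tr, config.tap_s + brk, config.tap_s + brk + 10.0)[0]
        rec_idx[brk] = post - pre
    xs = np.asarray(BREAK_LENGTHS)
    ys = np.asarray([rec_idx[b] for b in BREAK_LENGTHS])
    rec_slope = float(np.polyfit(xs, ys, 1)[0])
    slow_slope = float(np.polyfit([1, 2, 3], bins[:3], 1)[0])
    return {
        "speed_bins_slowing": bins,
        "slowing_pct": slowing_pct,
        "coa_bins": coa_bins,
        "recovery_index": {str(k): v for k, v in rec_idx.items()},
        "recovery_slope": rec_slope,
        "slowing_slope": slow_slope,
    }


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> Path:
    """Write a complete synthetic dataset for every subject of the cohort.

    Layout::

        out/
          manifest.json                      ground truth + config
          sub-XX/
            slowing/events.csv  control/events.csv
            recovery/events.csv              pre/post streams per break length
            slowing/force.csv
            <cond>/emg.npz + emg.json
            <cond>/mep_sici.csv + mep_sici_epochs.npz
            <cond>/mep_surround.csv + mep_surround_epochs.npz
            <cond>/eeg.npz + eeg.json
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"config": config.to_dict(), "subjects": {}}

    for s in range(config.n_subjects):
        sid = f"sub-{s + 1:02d}"
        sdir = out / sid
        params = sample_subject_params(config, rng)
        truth = _subject_truth(params, config)
        truth["params"] = dataclasses.asdict(params)
        truth["eeg_tau"] = {"slowing": config.eeg_tau_slowing, "control": config.eeg_tau_control}

        for condition, tap_s in (("slowing", config.tap_s), ("control", config.control_tap_s)):
            cdir = sdir / condition
            cdir.mkdir(parents=True, exist_ok=True)
            proto = ProtocolSpec.tap_then_rest(tap_s, config.break_s)
            frames = []
            for trial in range(config.n_trials):
                traj = simulate_trial(params, proto, config.dt)
                stream = generate_taps(traj, config.jitter_cv, rng,
                                       subject=sid, condition=condition, trial=trial)
                frames.append(stream.to_frame())
                if condition == "slowing" and trial == 0:
                    force = render_force(stream, 1000.0, proto.total_duration,
                                         config.force_noise_sd, rng)
                    pd.DataFrame({"force": force}).to_csv(cdir / "force.csv", index=False)
                    emg = generate_emg(traj, 1000.0, rng, noise_sd=config.emg_noise_sd,
                                       subject=sid, condition=condition)
                    np.savez(cdir / "emg.npz", **emg.channels)
                    (cdir / "emg.json").write_text(json.dumps(
                        {"fs_hz": emg.fs, "channels": list(emg.channels)}))
            pd.concat(frames).to_csv(cdir / "events.csv", index=False)

            sici_profile = SICI_PROFILE_SLOWING if condition == "slowing" else SICI_PROFILE_CONTROL
            si_profile = SI_PROFILE_SLOWING if condition == "slowing" else SI_PROFILE_CONTROL
            for mode, profile in (("sici", sici_profile), ("surround", si_profile)):
                session, mep_truth = generate_mep_session(
                    profile, config.mep_n_per_cell, config.mep_contamination_rate, rng,
                    mode=mode, n_pre_post=config.mep_n_pre_post,
                    sigma_log=config.mep_sigma_log, subject=sid, condition=condition)
                rows = [{"trial_id": tr.trial_id, "pulse_type": tr.pulse_type,
                         "timepoint": tr.timepoint, "pulse_time_s": tr.pulse_time,
                         "epoch_ref": f"mep_{mode}_epochs.npz:{tr.trial_id}"}
                        for tr in session.trials]
                pd.DataFrame(rows).to_csv(cdir / f"mep_{mode}.csv", index=False)
                np.savez(cdir / f"mep_{mode}_epochs.npz",
                         **{str(tr.trial_id): tr.epoch for tr in session.trials})
                truth[f"mep_{mode}_{condition}"] = mep_truth

            tau = config.eeg_tau_slowing if condition == "slowing" else config.eeg_tau_control
            breaks = generate_eeg_breaks(tau, config.n_eeg_breaks, rng,
                                         depth=config.eeg_depth,
                                         noise_sd=config.eeg_noise_sd)
            np.savez(cdir / "eeg.npz", breaks=breaks)
            (cdir / "eeg.json").write_text(json.dumps(
                {"fs_hz": 200.0, "tau_s": tau, "condition": condition}))

        # recovery experiment: pre/post tap streams around each break length
        rdir = sdir / "recovery"
        rdir.mkdir(parents=True, exist_ok=True)
        rec_frames = []
        for brk in BREAK_LENGTHS:
            proto = ProtocolSpec(segments=(("tapping", config.tap_s), ("rest", brk),
                                           ("tapping", 10.0)))
            for rep in range(config.n_trials):
                traj = simulate_trial(params, proto, config.dt)
                stream = generate_taps(traj, config.jitter_cv, rng, subject=sid,
                                       condition="recovery", trial=rep)
                df = stream.to_frame()
                df["break_s"] = brk
                # the closing tap of the pre segment may spill slightly past
                # the nominal tapping end; breaks are >= 5 s so a 2 s margin
                # separates the segments unambiguously
                df["phase"] = np.where(df["time_s"] < config.tap_s + 2.0, "pre", "post")
                rec_frames.append(df)
        pd.concat(rec_frames).to_csv(rdir / "events.csv", index=False)

        manifest["subjects"][sid] = truth

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
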