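"""End-to-end orchestration: simulate a cohort, run every analysis, report.

Stages communicate only through files written in the output directory, so
each stage can be re-run from the data on disk.  The final product is a set
of tidy long-format CSV tables (ready for external mixed-effects tooling), a
group summary, and a parameter-recovery report comparing every estimated
quantity against the generator's ground-truth manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import eeg as eeg_mod
from .cohort import BREAK_LENGTHS, CohortConfig, generate_cohort
from .emg import Envelope, bin_coactivation, extract_envelope
from .tapping import (
    BinnedSeries,
    TapStream,
    bin_speed,
    fit_slope,
    normalise_to_control,
    pearson_r,
    recovery_index,
    slowing_pct,
)
from .tms import MepSession, MepTrial, screen_trials, sici, surround_inhibition

logger = logging.getLogger("fatiscope")

__all__ = ["RunConfig", "RecoveryReport", "run_pipeline", "summarise_group"]

_TIMEPOINTS = ("Pre", "bin1", "bin2", "bin3", "Post")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    bin_width: float = 10.0
    normalisation: str = "scalar"  # scalar control mean, or "per_bin"
    # speed estimator: mean instantaneous rate per bin ("rate", unbiased at
    # bin edges) or completed-cycle counts ("count")
    speed_method: str = "rate"
    band: str = "alpha"
    tol_slowing_pct: float = 3.0
    tol_coa: float = 0.05
    tol_inhibition: float = 0.05
    tol_alpha_rel: float = 0.10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RecoveryReport:
    """Planted-vs-estimated comparison for every manifest quantity."""

    rows: pd.DataFrame

    @property
    def all_passed(self) -> bool:
        return bool(self.rows["passed"].all())

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _events_to_stream(df: pd.DataFrame) -> TapStream:
    effs = tuple(pd.unique(df["effector"]))
    return TapStream(df["time_s"].to_numpy(), df["effector"].to_numpy(),
                     effs if effs else ("tap",))


def _load_mep_session(cdir: Path, mode: str) -> MepSession:
    table = pd.read_csv(cdir / f"mep_{mode}.csv")
    epochs = np.load(cdir / f"mep_{mode}_epochs.npz")
    trials = [
        MepTrial(
            pulse_type=row.pulse_type,
            pulse_time=row.pulse_time_s,
            epoch=epochs[str(row.trial_id)],
            fs=5000.0,
            timepoint=row.timepoint,
            trial_id=int(row.trial_id),
        )
        for row in table.itertuples()
    ]
    return MepSession(trials)


def _analyse_tapping(data_dir: Path, subjects: list[str], config: RunConfig,
                     out: Path) -> pd.DataFrame:
    rows = []
    for sid in subjects:
        streams = {}
        for condition, dur in (("slowing", config.cohort.tap_s),
                               ("control", config.cohort.control_tap_s)):
            df = pd.read_csv(data_dir / sid / condition / "events.csv")
            per_trial = []
            for trial, tdf in df.groupby("trial"):
                stream = _events_to_stream(tdf)
                series = bin_speed(stream, config.bin_width, duration=dur, t0=0.0,
                                   method=config.speed_method)
                per_trial.append(series.values)
            vals = np.mean(per_trial, axis=0)
            streams[condition] = BinnedSeries(series.bin_edges, vals,
                                              unit="cycles per 10 s")
        norm = normalise_to_control(streams["slowing"], streams["control"],
                                    per_bin=config.normalisation == "per_bin")
        for k, v in enumerate(streams["slowing"].values):
            rows.append({"subject": sid, "condition": "slowing", "bin": k + 1,
                         "speed": v, "normalised": norm.values[k]})
        for k, v in enumerate(streams["control"].values):
            rows.append({"subject": sid, "condition": "control", "bin": k + 1,
                         "speed": v, "normalised": 1.0})
    table = pd.DataFrame(rows)
    table.to_csv(out / "speeds.csv", index=False)
    return table


def _analyse_recovery(data_dir: Path, subjects: list[str], config: RunConfig,
                      out: Path) -> pd.DataFrame:
    rows = []
    for sid in subjects:
        df = pd.read_csv(data_dir / sid / "recovery" / "events.csv")
        for (brk, rep), tdf in df.groupby(["break_s", "trial"]):
            pre = _events_to_stream(tdf[tdf["phase"] == "pre"])
            post_df = tdf[tdf["phase"] == "post"]
            post = _events_to_stream(post_df)
            pre_bins = bin_speed(pre, 10.0, duration=config.cohort.tap_s, t0=0.0,
                                 method=config.speed_method)
            post_bins = bin_speed(post, 10.0, duration=10.0,
                                  t0=config.cohort.tap_s + brk,
                                  method=config.speed_method)
            rows.append({"subject": sid, "break_s": brk, "trial": rep,
                         "recovery_index": recovery_index(pre_bins, post_bins),
                         "pre_last_bin": pre_bins.values[-1],
                         "slowing_slope": fit_slope(pre_bins)})
    table = pd.DataFrame(rows)
    table.to_csv(out / "recovery.csv", index=False)
    return table


def _analyse_emg(data_dir: Path, subjects: list[str], config: RunConfig,
                 out: Path) -> pd.DataFrame:
    rows = []
    for sid in subjects:
        cdir = data_dir / sid / "slowing"
        if not (cdir / "emg.npz").exists():
            continue
        sidecar = json.loads((cdir / "emg.json").read_text())
        npz = np.load(cdir / "emg.npz")
        fs = sidecar["fs_hz"]
        env_ag = extract_envelope(npz["APB"], fs, "APB")
        env_ant = extract_envelope(npz["EPL"], fs, "EPL")
        series = bin_coactivation(env_ag, env_ant, config.bin_width)
        for k, v in enumerate(series.values):
            rows.append({"subject": sid, "bin": k + 1, "coactivation": v})
    table = pd.DataFrame(rows)
    table.to_csv(out / "coactivation.csv", index=False)
    return table


def _analyse_tms(data_dir: Path, subjects: list[str], out: Path) -> pd.DataFrame:
    rows = []
    for sid in subjects:
        for condition in ("slowing", "control"):
            cdir = data_dir / sid / condition
            for mode, stat in (("sici", sici), ("surround", surround_inhibition)):
                session = _load_mep_session(cdir, mode)
                report = screen_trials(session)
                ref, mod = (("TS", "CS+TS") if mode == "sici"
                            else ("TMS_Con", "TMS_Move"))
                for tp in _TIMEPOINTS:
                    a_ref = report.kept_amplitudes(ref, tp)
                    a_mod = report.kept_amplitudes(mod, tp)
                    if len(a_ref) == 0 or len(a_mod) == 0:
                        continue
                    value = (sici(a_ref, a_mod) if mode == "sici"
                             else surround_inhibition(a_mod, a_ref))
                    rows.append({"subject": sid, "condition": condition,
                                 "measure": mode, "timepoint": tp,
                                 "value": value,
                                 "n_kept": len(a_ref) + len(a_mod),
                                 "inclusion": report.inclusion_fraction})
    table = pd.DataFrame(rows)
    table.to_csv(out / "tms.csv", index=False)
    return table


def _analyse_eeg(data_dir: Path, subjects: list[str], config: RunConfig,
                 out: Path) -> pd.DataFrame:
    band = {"alpha": eeg_mod.ALPHA, "beta": eeg_mod.BETA, "gamma": eeg_mod.GAMMA}[config.band]
    rows = []
    for sid in subjects:
        for condition in ("slowing", "control"):
            cdir = data_dir / sid / condition
            sidecar = json.loads((cdir / "eeg.json").read_text())
            breaks = np.load(cdir / "eeg.npz")["breaks"]
            for b_ix, trace in enumerate(breaks):
                env = eeg_mod.band_envelope(trace, sidecar["fs_hz"], band)
                bp = eeg_mod.bin_break_power(env, condition)
                for e_ix, v in enumerate(bp.epochs):
                    rows.append({"subject": sid, "condition": condition,
                                 "break": b_ix, "epoch": e_ix + 1, "amplitude": v})
    table = pd.DataFrame(rows)
    table.to_csv(out / "alpha.csv", index=False)
    return table


def summarise_group(table: pd.DataFrame, value: str, by: list[str]) -> pd.DataFrame:
    """Across-subject mean and standard error per group (no inference)."""
    subj_means = table.groupby(by + ["subject"], as_index=False)[value].mean()
    n_subjects = subj_means["subject"].nunique()
    if n_subjects < 2:
        raise ValueError("group summary needs at least two subjects")
    g = subj_means.groupby(by)[value]
    out = g.agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)),
                n="count").reset_index()
    return out


def _build_recovery_report(manifest: dict, speeds: pd.DataFrame,
                           recovery: pd.DataFrame, coa: pd.DataFrame,
                           tms: pd.DataFrame, alpha: pd.DataFrame,
                           config: RunConfig) -> RecoveryReport:
    rows = []
    subjects = manifest["subjects"]

    # mean slowing percentage
    planted_slow = np.mean([s["slowing_pct"] for s in subjects.values()])
    est_slow = speeds[speeds["condition"] == "slowing"].groupby("subject").apply(
        lambda d: slowing_pct(BinnedSeries(
            np.column_stack([(d["bin"] - 1) * 10.0, d["bin"] * 10.0]),
            d.sort_values("bin")["speed"].to_numpy(), unit="cycles per 10 s")),
        include_groups=False).mean()
    rows.append(("slowing_pct", planted_slow, est_slow, config.tol_slowing_pct))

    # slowing/recovery slope correlation (diagnostic value, no tolerance row)
    # coactivation per bin
    coa_means = coa.groupby("bin")["coactivation"].mean()
    for b in sorted(coa_means.index):
        planted = np.mean([s["coa_bins"][b - 1] for s in subjects.values()])
        rows.append((f"coa_bin{b}", planted, coa_means[b], config.tol_coa))

    # SICI and surround inhibition per timepoint, slowing condition
    for mode in ("sici", "surround"):
        key = f"mep_{mode}_slowing"
        planted_profile = next(iter(subjects.values()))[key]["profile"]
        sub = tms[(tms["measure"] == mode) & (tms["condition"] == "slowing")]
        for tp in _TIMEPOINTS:
            est = sub[sub["timepoint"] == tp]["value"].mean()
            rows.append((f"{mode}_{tp}", planted_profile[tp], est,
                         config.tol_inhibition))

    # alpha recovery ordering: slowing suppressed in epochs 1-2, equal at 3
    a = alpha.groupby(["condition", "epoch"])["amplitude"].mean()
    e1 = a["slowing"][1] < a["control"][1]
    e2 = a["slowing"][2] < a["control"][2]
    e3 = abs(a["slowing"][3] - a["control"][3]) / a["control"][3] < config.tol_alpha_rel
    rows.append(("alpha_recovery_ordering", 1.0, float(e1 and e2 and e3), 0.5))

    table = pd.DataFrame(rows, columns=["quantity", "planted", "estimated", "tolerance"])
    table["abs_error"] = (table["estimated"] - table["planted"]).abs()
    table["passed"] = table["abs_error"] <= table["tolerance"]
    return RecoveryReport(table)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate, analyse and report; returns the output directory.

    Deterministic for a fixed (config, seed): running twice with the same
    arguments reproduces every output file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(json.dumps(config.to_dict(), indent=1))

    data_dir = out / "dataset"
    logger.info("generating cohort of %d subjects", config.cohort.n_subjects)
    generate_cohort(config.cohort, data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    subjects = sorted(manifest["subjects"])

    tables = out / "tables"
    tables.mkdir(exist_ok=True)
    speeds = _analyse_tapping(data_dir, subjects, config, tables)
    recovery = _analyse_recovery(data_dir, subjects, config, tables)
    coa = _analyse_emg(data_dir, subjects, config, tables)
    tms = _analyse_tms(data_dir, subjects, tables)
    alpha = _analyse_eeg(data_dir, subjects, config, tables)

    # group summaries (sem undefined below two subjects)
    if len(subjects) >= 2:
        summarise_group(speeds, "normalised", ["condition", "bin"]).to_csv(
            tables / "group_speeds.csv", index=False)
        summarise_group(alpha, "amplitude", ["condition", "epoch"]).to_csv(
            tables / "group_alpha.csv", index=False)
    else:
        logger.warning("single-subject cohort: group summaries skipped")

    # slowing-slope vs recovery-slope correlation across subjects
    slow_slopes = recovery.groupby("subject")["slowing_slope"].mean()
    rec_slopes = recovery.groupby("subject").apply(
        lambda d: fit_slope(d.groupby("break_s")["recovery_index"].mean().to_numpy(),
                            x=np.asarray(sorted(d["break_s"].unique()))),
        include_groups=False)
    # slowing slope is negative (speed loss per bin); compare its magnitude
    if len(rec_slopes) >= 3:
        r = pearson_r(-slow_slopes.loc[rec_slopes.index], rec_slopes)
        logger.info("slowing/recovery slope correlation r=%.3f", r)
    else:
        r = None  # undefined below three subjects
    (out / "correlation.json").write_text(json.dumps(
        {"slowing_recovery_r": r, "n": int(len(rec_slopes))}))

    report = _build_recovery_report(manifest, speeds, recovery, coa, tms, alpha, config)
    report.to_csv(out / "recovery_report.csv")
    (out / "recovery_report.json").write_text(
        report.rows.to_json(orient="records", indent=1))
    logger.info("recovery report: %d/%d quantities within tolerance",
                int(report.rows["passed"].sum()), len(report.rows))
    return out
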