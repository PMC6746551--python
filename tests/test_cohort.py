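"""Tests for the synthetic cohort generator and its ground-truth manifest."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from fatiscope.cohort import (
    CohortConfig,
    SICI_PROFILE_SLOWING,
    generate_cohort,
    generate_eeg_breaks,
    generate_emg,
    generate_mep_session,
    generate_taps,
)
from fatiscope.eeg import ALPHA, band_envelope, bin_break_power
from fatiscope.emg import bin_coactivation, coactivation_index, extract_envelope
from fatiscope.model import ModelParams, ModelTrajectory, ProtocolSpec, simulate_trial
from fatiscope.tms import screen_trials, sici


def constant_trajectory(speed=2.0, duration=10.0, dt=0.01):
    n = int(duration / dt)
    ones = np.ones(n)
    return ModelTrajectory(
        times=np.arange(n) * dt,
        g_t=ones.copy(),
        sigma_t=ones * 0.6,
        overlap_t=ones * 0.0,
        speed_t=ones * speed,
        coa_t=ones * 0.0,
        tapping=np.ones(n, dtype=bool),
    )


class TestGenerateTaps:
    def test_jitterless_constant_rate_alternation(self, rng):
        stream = generate_taps(constant_trajectory(2.0, 5.0), 0.0, rng,
                               effector_cycle=("L", "R"))
        assert np.allclose(np.diff(stream.times), 0.25)
        assert list(stream.effectors[:4]) == ["L", "R", "L", "R"]

    def test_slowing_reduces_cycle_counts(self, rng, slowing_trajectory):
        stream = generate_taps(slowing_trajectory, 0.0, rng)
        starts = stream.times[stream.effectors == stream.effector_cycle[0]][:-1]
        n1 = np.sum((starts >= 0) & (starts < 10))
        n3 = np.sum((starts >= 20) & (starts < 30))
        assert n1 > n3

    def test_nonpositive_speed_rejected(self, rng):
        traj = constant_trajectory(2.0, 1.0)
        traj.speed_t[5] = 0.0
        with pytest.raises(ValueError):
            generate_taps(traj, 0.0, rng)


class TestGenerateEmg:
    def test_zero_coactivation_profile(self, rng):
        traj = constant_trajectory(2.0, 20.0)
        emg = generate_emg(traj, 1000.0, rng, noise_sd=0.0)
        env_a = extract_envelope(emg["APB"], 1000.0)
        env_e = extract_envelope(emg["EPL"], 1000.0)
        assert coactivation_index(env_a, env_e) < 0.02

    def test_identical_channels_give_unity_index(self, rng):
        traj = constant_trajectory(2.0, 10.0)
        emg = generate_emg(traj, 1000.0, rng, noise_sd=0.0)
        env = extract_envelope(emg["APB"], 1000.0)
        assert coactivation_index(env, env) == pytest.approx(1.0)

    def test_planted_rising_profile_recovered_monotonically(self, rng):
        traj = constant_trajectory(3.0, 30.0)
        profile = np.linspace(0.2, 0.5, len(traj.times))
        emg = generate_emg(traj, 1000.0, rng, coa_profile=profile, noise_sd=0.0)
        env_a = extract_envelope(emg["APB"], 1000.0)
        env_e = extract_envelope(emg["EPL"], 1000.0)
        series = bin_coactivation(env_a, env_e, 10.0)
        assert series.values[0] < series.values[1] < series.values[2]
        planted = [profile[(traj.times >= 10 * k) & (traj.times < 10 * (k + 1))].mean()
                   for k in range(3)]
        assert np.allclose(series.values, planted, atol=0.07)

    def test_low_fs_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_emg(constant_trajectory(), 300.0, rng)


class TestGenerateMepSession:
    def test_noise_free_sici_recovery_is_exact(self, rng):
        session, truth = generate_mep_session(
            SICI_PROFILE_SLOWING, n_per_cell=8, contamination_rate=0.0, rng=rng,
            sigma_log=0.0, bg_rms=0.0)
        report = screen_trials(session)
        for tp, planted in SICI_PROFILE_SLOWING.items():
            est = sici(report.kept_amplitudes("TS", tp),
                       report.kept_amplitudes("CS+TS", tp))
            assert est == pytest.approx(planted, abs=1e-12)

    def test_no_contamination_no_stage1_removals(self, rng):
        session, _ = generate_mep_session(SICI_PROFILE_SLOWING, 12, 0.0, rng)
        report = screen_trials(session)
        assert (report.table["flag"] != "removed_bgEMG_abs").all()

    def test_contaminated_trials_removed_at_stage1(self, rng):
        session, truth = generate_mep_session(SICI_PROFILE_SLOWING, 12, 0.2, rng)
        report = screen_trials(session)
        removed = set(report.table.loc[
            report.table["flag"] == "removed_bgEMG_abs", "trial_id"])
        assert removed == set(truth["contaminated_trials"])

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_mep_session(SICI_PROFILE_SLOWING, 0, 0.0, rng)
        with pytest.raises(ValueError):
            generate_mep_session({"Pre": 1.5}, 8, 0.0, rng)

    def test_surround_mode_ratio_recovery(self, rng):
        profile = {"Pre": 0.4, "bin1": 0.6, "bin3": 0.4}
        session, _ = generate_mep_session(profile, 24, 0.0, rng, mode="surround",
                                          sigma_log=0.0, bg_rms=0.0)
        report = screen_trials(session)
        from fatiscope.tms import surround_inhibition

        for tp, planted in profile.items():
            est = surround_inhibition(report.kept_amplitudes("TMS_Move", tp),
                                      report.kept_amplitudes("TMS_Con", tp))
            assert est == pytest.approx(planted, abs=1e-12)


class TestGenerateEegBreaks:
    def test_zero_depth_flat_epochs(self, rng):
        breaks = generate_eeg_breaks(12.0, 2, rng, depth=0.0, noise_sd=0.0)
        for trace in breaks:
            bp = bin_break_power(band_envelope(trace, 200.0, ALPHA))
            assert np.allclose(bp.epochs, bp.epochs[0], rtol=0.01)

    def test_pure_sine_envelope_two_over_pi(self, rng):
        a = 0.9
        breaks = generate_eeg_breaks(5.0, 1, rng, depth=0.0, amplitude=a, noise_sd=0.0)
        env = band_envelope(breaks[0], 200.0, ALPHA)
        assert env.samples[2:-2].mean() == pytest.approx(2 * a / np.pi, rel=0.02)

    def test_condition_taus_order_binned_amplitude(self, rng):
        slow = generate_eeg_breaks(12.0, 4, rng, noise_sd=0.05)
        ctrl = generate_eeg_breaks(3.0, 4, rng, noise_sd=0.05)
        ep_s = np.mean([bin_break_power(band_envelope(x, 200.0, ALPHA)).epochs
                        for x in slow], axis=0)
        ep_c = np.mean([bin_break_power(band_envelope(x, 200.0, ALPHA)).epochs
                        for x in ctrl], axis=0)
        assert ep_s[0] < ep_c[0] and ep_s[1] < ep_c[1]
        assert abs(ep_s[2] - ep_c[2]) / ep_c[2] < 0.10

    def test_invalid_tau_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_eeg_breaks(0.0, 1, rng)


def tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for path in sorted(root.rglob("*")):
        if path.is_file():
            h.update(path.relative_to(root).as_posix().encode())
            h.update(path.read_bytes())
    return h.hexdigest()


class TestGenerateCohort:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_subjects=1, seed=7, n_trials=1, n_eeg_breaks=1,
                           mep_n_per_cell=4, mep_n_pre_post=4)
        generate_cohort(cfg, tmp_path / "a")
        generate_cohort(cfg, tmp_path / "b")
        assert tree_digest(tmp_path / "a") == tree_digest(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        cfg1 = CohortConfig(n_subjects=1, seed=7, n_trials=1, n_eeg_breaks=1,
                            mep_n_per_cell=4, mep_n_pre_post=4)
        cfg2 = CohortConfig(n_subjects=1, seed=8, n_trials=1, n_eeg_breaks=1,
                            mep_n_per_cell=4, mep_n_pre_post=4)
        generate_cohort(cfg1, tmp_path / "a")
        generate_cohort(cfg2, tmp_path / "b")
        assert tree_digest(tmp_path / "a") != tree_digest(tmp_path / "b")

    def test_manifest_contains_planted_quantities(self, tmp_path):
        cfg = CohortConfig(n_subjects=1, seed=3, n_trials=1, n_eeg_breaks=1,
                           mep_n_per_cell=4, mep_n_pre_post=4)
        out = generate_cohort(cfg, tmp_path / "d")
        manifest = json.loads((out / "manifest.json").read_text())
        truth = manifest["subjects"]["sub-01"]
        for key in ("slowing_pct", "coa_bins", "recovery_index",
                    "recovery_slope", "slowing_slope", "params",
                    "mep_sici_slowing", "mep_surround_slowing", "eeg_tau"):
            assert key in truth
        assert len(truth["coa_bins"]) == 3

    def test_no_fatigue_constant_intervals(self, tmp_path):
        base = ModelParams(lambda_dec=0.0)
        cfg = CohortConfig(n_subjects=1, seed=5, base_params=base, jitter_cv=0.0,
                           lambda_cv=0.0, v0_cv=0.0, beta_cv=0.0, n_trials=1,
                           n_eeg_breaks=1, mep_n_per_cell=4, mep_n_pre_post=4)
        out = generate_cohort(cfg, tmp_path / "d")
        import pandas as pd

        events = pd.read_csv(out / "sub-01" / "slowing" / "events.csv")
        one_trial = events[events["trial"] == 0]
        anchors = one_trial[one_trial["effector"] == one_trial["effector"].iloc[0]]
        assert np.allclose(np.diff(anchors["time_s"])[:-1],
                           np.diff(anchors["time_s"])[0], atol=1e-9)
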