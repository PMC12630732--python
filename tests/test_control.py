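"""Closed-loop behavior: PI response, locking, decoupling, convergence."""

import numpy as np
import pytest

from stabilock import default_config
from stabilock.config import build_scope
from stabilock.cli import rois_from_config
from stabilock.control import (
    LockError,
    PIController,
    StabilizationSession,
    lock,
    pi_response,
    run_loop,
    shift_reference,
    stabilization_step,
)
from stabilock.simscope import SimCamera, SimStage


def make_rig(cfg, seed=0, **session_kw):
    """Scope + proxies + session using ground-truth calibration values."""
    scope = build_scope(cfg, seed=seed)
    camera, stage = SimCamera(scope), SimStage(scope)
    fid_rois, focus_roi = rois_from_config(cfg)
    z_response = cfg.camera.pixel_size_nm / cfg.focus.gain
    session = StabilizationSession(
        fiducial_rois=fid_rois,
        focus_roi=focus_roi,
        pixel_size_nm=cfg.camera.pixel_size_nm,
        z_response_nm_per_px=z_response,
        z_axis=cfg.focus.shift_axis,
        period_s=cfg.control.period_s,
        **session_kw,
    )
    return scope, camera, stage, session


class TestPiResponse:
    def test_zero_error_zero_output(self):
        assert pi_response(PIController(), 0.0, 0.05) == 0.0

    def test_proportional_arithmetic(self):
        ctrl = PIController(kp=0.8, ki=0.0)
        assert pi_response(ctrl, 2.0, 0.05) == pytest.approx(-1.6)

    def test_integral_accumulation(self):
        # ki=0.5/s, constant 1 nm error over 4 iterations of 50 ms
        ctrl = PIController(kp=0.0, ki=0.5)
        for _ in range(4):
            out = pi_response(ctrl, 1.0, 0.05)
        assert out == pytest.approx(-0.1)

    def test_output_and_integral_clamped(self):
        ctrl = PIController(kp=1.0, ki=1.0, output_limit_nm=5.0)
        for _ in range(100):
            out = pi_response(ctrl, 100.0, 1.0)
        assert abs(out) <= 5.0
        assert abs(ctrl.ki * ctrl.integral) <= 5.0

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            pi_response(PIController(), 1.0, 0.0)


class TestLock:
    def test_lock_then_measure_same_state_is_zero(self, quiet_config):
        scope, camera, stage, session = make_rig(quiet_config)
        lock(session, camera.acquire())
        rec = stabilization_step(session, camera, stage)
        assert rec.avg_dx_nm == pytest.approx(0.0, abs=1e-9)
        assert rec.avg_dy_nm == pytest.approx(0.0, abs=1e-9)
        assert rec.dz_nm == pytest.approx(0.0, abs=1e-9)

    def test_lock_stores_all_setpoints(self, quiet_config):
        scope, camera, stage, session = make_rig(quiet_config)
        sp = lock(session, camera.acquire())
        assert sp.xy0_px.shape == (4, 2)
        assert sp.r0_px.shape == (2,)
        assert sp.z0_nm == 0.0

    def test_lock_refused_names_bad_roi(self, quiet_config):
        scope, camera, stage, session = make_rig(quiet_config)
        frame = camera.acquire()
        frame.pixels[:] = 0.0
        with pytest.raises(LockError, match="ROI 0"):
            lock(session, frame)

    def test_relock_redefines_zero(self, quiet_config):
        quiet_config.drift.velocity[:] = (1.0, 0.0, 0.0)
        scope, camera, stage, session = make_rig(quiet_config, enabled=False)
        lock(session, camera.acquire())
        for _ in range(20):
            stabilization_step(session, camera, stage)
        drifted = session.trace[-1]["avg_dx_nm"]
        assert drifted > 0.5
        lock(session, camera.acquire())
        rec = stabilization_step(session, camera, stage)
        assert abs(rec.avg_dx_nm) < 0.2


class TestStep:
    def test_zero_drift_no_commands_beyond_quantum(self, quiet_config):
        scope, camera, stage, session = make_rig(quiet_config)
        lock(session, camera.acquire())
        for _ in range(10):
            stabilization_step(session, camera, stage)
        assert np.all(np.abs(stage.get_position()) <= stage.quantum_nm + 1e-9)

    def test_step_disturbance_decays_geometrically(self, quiet_config):
        scope, camera, stage, session = make_rig(quiet_config)
        lock(session, camera.acquire())
        scope.drift_offset[0] += 5.0  # inject a 5 nm step in x
        residuals = []
        for _ in range(4):
            rec = stabilization_step(session, camera, stage)
            residuals.append(abs(rec.avg_dx_nm))
        assert residuals[-1] < 1.0
        assert residuals[0] > residuals[-1]

    def test_z_only_mode_never_commands_xy(self, quiet_config):
        quiet_config.drift.velocity[:] = (1.0, -1.0, 0.5)
        scope, camera, stage, session = make_rig(quiet_config, mode="Z")
        lock(session, camera.acquire())
        for _ in range(60):
            rec = stabilization_step(session, camera, stage)
        kinds = {k for k, _, _ in stage.command_log}
        assert kinds <= {"z"}
        assert abs(rec.dz_nm) < 1.0          # axial stays locked
        assert abs(rec.avg_dx_nm) > 1.5      # lateral drift keeps growing

    def test_xy_only_mode_never_commands_z(self, quiet_config):
        quiet_config.drift.velocity[:] = (1.0, -1.0, 0.5)
        scope, camera, stage, session = make_rig(quiet_config, mode="XY")
        lock(session, camera.acquire())
        for _ in range(60):
            stabilization_step(session, camera, stage)
        kinds = {k for k, _, _ in stage.command_log}
        assert kinds <= {"xy"}

    def test_order_independence_of_fiducials(self, quiet_config):
        results = []
        for perm in ([0, 1, 2, 3], [3, 1, 0, 2]):
            cfg = default_config()
            cfg.drift.velocity[:] = 0.0
            cfg.drift.diffusion[:] = 0.0
            cfg.camera.shot_noise = False
            cfg.camera.read_noise_sigma = 0.0
            cfg.fiducials.positions_nm = cfg.fiducials.positions_nm[perm]
            scope, camera, stage, session = make_rig(cfg)
            lock(session, camera.acquire())
            scope.drift_offset[:] = (1.7, -0.9, 0.4)
            rec = stabilization_step(session, camera, stage)
            results.append((rec.avg_dx_nm, rec.avg_dy_nm, rec.dz_nm))
        assert np.allclose(results[0], results[1], atol=1e-9)


class TestRunLoop:
    def test_record_count(self, quiet_config):
        scope, camera, stage, session = make_rig(quiet_config)
        lock(session, camera.acquire())
        trace = run_loop(session, camera, stage, 10.0)
        assert len(trace) == 185  # floor(10 / 0.054)

    def test_disabled_session_tracks_without_commands(self, quiet_config):
        quiet_config.drift.velocity[:] = (1.0, 0.0, 0.0)
        scope, camera, stage, session = make_rig(quiet_config, enabled=False)
        lock(session, camera.acquire())
        trace = run_loop(session, camera, stage, 5.0)
        assert not stage.command_log
        assert trace["avg_dx_nm"].iloc[-1] > 3.0  # drift recorded, uncorrected

    def test_closed_loop_beats_open_loop_every_seed(self):
        for seed in (1, 2, 3):
            sigmas = {}
            for enabled in (True, False):
                cfg = default_config()
                scope, camera, stage, session = make_rig(cfg, seed=seed, enabled=enabled)
                lock(session, camera.acquire())
                trace = run_loop(session, camera, stage, 20.0)
                sigmas[enabled] = trace[["avg_dx_nm", "avg_dy_nm", "dz_nm"]].std()
            assert (sigmas[True] < sigmas[False]).all(), f"seed {seed}"

    def test_quantization_floor(self, quiet_config):
        # zero drift, zero noise: residual never exceeds one stage quantum
        scope, camera, stage, session = make_rig(quiet_config)
        lock(session, camera.acquire())
        scope.drift_offset[:] = (0.9, -1.3, 0.7)
        run_loop(session, camera, stage, 2.0)
        assert np.all(np.abs(scope.net_offset) <= stage.quantum_nm.max() + 1e-9)

    def test_detached_fiducial_flagged_and_loop_survives(self):
        cfg = default_config()
        cfg.fiducials.extra_velocity_nm_s = np.array(
            [[0.0, 0.0], [60.0, 0.0], [0.0, 0.0], [0.0, 0.0]]
        )
        scope, camera, stage, session = make_rig(cfg, seed=4)
        lock(session, camera.acquire())
        trace = run_loop(session, camera, stage, 20.0)
        flag_times = trace.loc[trace["valid_mask"] != "1111", "t_s"]
        assert not flag_times.empty and flag_times.iloc[0] < 1.5
        assert (trace["valid_mask"].iloc[-1]) == "1011"
        # residual sigma after flagging stays comparable to an all-good run
        cfg2 = default_config()
        scope2, camera2, stage2, session2 = make_rig(cfg2, seed=4)
        lock(session2, camera2.acquire())
        good = run_loop(session2, camera2, stage2, 20.0)
        settled = trace[trace["t_s"] > 5.0]
        good_settled = good[good["t_s"] > 5.0]
        for col in ("avg_dx_nm", "avg_dy_nm"):
            assert settled[col].std() <= 1.2 * good_settled[col].std() + 0.05


class TestShiftReference:
    def test_zero_shift_noop(self, quiet_config):
        scope, camera, stage, session = make_rig(quiet_config)
        lock(session, camera.acquire())
        before = session.setpoint.xy0_px.copy()
        shift_reference(session, (0.0, 0.0, 0.0))
        assert np.allclose(session.setpoint.xy0_px, before)

    def test_sample_moves_by_delta(self, quiet_config):
        quiet_config.camera.shot_noise = True  # realistic conditions
        quiet_config.camera.read_noise_sigma = 2.0
        scope, camera, stage, session = make_rig(quiet_config, seed=8)
        lock(session, camera.acquire())
        run_loop(session, camera, stage, 1.0)
        base = scope.net_offset.copy()
        shift_reference(session, (10.0, 0.0, 0.0))
        run_loop(session, camera, stage, 2.0)
        moved = scope.net_offset - base
        assert moved[0] == pytest.approx(10.0, abs=0.7)
        assert abs(moved[1]) < 0.7

    def test_round_trip_returns_within_two_quanta(self, quiet_config):
        quiet_config.camera.shot_noise = True
        quiet_config.camera.read_noise_sigma = 2.0
        scope, camera, stage, session = make_rig(quiet_config, seed=9)
        lock(session, camera.acquire())
        run_loop(session, camera, stage, 1.0)
        base = scope.net_offset.copy()
        shift_reference(session, (10.0, 0.0, 0.0))
        run_loop(session, camera, stage, 2.0)
        shift_reference(session, (-10.0, 0.0, 0.0))
        run_loop(session, camera, stage, 2.0)
        assert abs(scope.net_offset[0] - base[0]) <= 2 * stage.quantum_nm[0] + 0.2

    def test_shift_out_of_roi_refused(self, quiet_config):
        scope, camera, stage, session = make_rig(quiet_config)
        lock(session, camera.acquire())
        with pytest.raises(ValueError, match="fiducial"):
            shift_reference(session, (500.0, 0.0, 0.0))

    def test_disabled_session_refused(self, quiet_config):
        scope, camera, stage, session = make_rig(quiet_config, enabled=False)
        lock(session, camera.acquire())
        with pytest.raises(RuntimeError):
            shift_reference(session, (1.0, 0.0, 0.0))
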