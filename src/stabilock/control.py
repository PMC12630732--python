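"""Closed-loop stabilization: acquire, localize, compare, correct.

One iteration of the loop acquires a triggered frame, localizes every
fiducial ROI (2D Gaussian fit seeded from the previous frame) and the
focus ROI (center of mass), converts to displacements from the setpoints,
evaluates the per-axis response function, and commands the stage.  XY and
Z processing are fully decoupled: the loop can run in lateral-only,
axial-only, or full 3D mode, and axes outside the active mode are never
commanded.

The shipped response is a PI controller with an output limit and
anti-windup; any callable with the same signature can be plugged in per
axis.  Corrections are issued as absolute stage targets (accumulated
commanded position plus correction) so quantization error does not build
up, and corrections smaller than half the stage quantum are suppressed
(dead-band) to avoid limit-cycling on the position lattice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .localize import (
    DetachmentMonitor,
    DetachmentPolicy,
    Displacement3D,
    LateralLockLost,
    Roi,
    Setpoint3D,
    SpotFit,
    average_displacement,
    center_of_mass,
    displacement_xy,
    displacement_z,
    fit_gaussian_2d,
)

__all__ = [
    "PIController",
    "StabilizationSession",
    "LockError",
    "pi_response",
    "lock",
    "stabilization_step",
    "run_loop",
    "shift_reference",
    "trace_to_frame",
    "TRACE_BASE_COLUMNS",
]

log = logging.getLogger(__name__)


class LockError(RuntimeError):
    """Raised when a setpoint lock cannot be established."""


@dataclass
class PIController:
    """Proportional-integral response for one axis.

    ``kp`` is dimensionless, ``ki`` in 1/s acting on the accumulated
    error integral (nm*s).  ``sign=-1`` encodes the convention that the
    correction opposes the measured displacement.  The integral is clamped
    so that its contribution alone cannot exceed ``output_limit`` nm
    (anti-windup), and the total output is clamped to the same limit.
    """

    kp: float = 0.8
    ki: float = 0.0
    output_limit_nm: float = 50.0
    sign: float = -1.0
    integral: float = 0.0

    def reset(self) -> None:
        self.integral = 0.0


def pi_response(ctrl: PIController, error_nm: float, dt_s: float) -> float:
    """One PI evaluation: returns the corrective stage move in nm."""
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    ctrl.integral += error_nm * dt_s
    if ctrl.ki != 0:
        lim = ctrl.output_limit_nm / abs(ctrl.ki)
        ctrl.integral = min(max(ctrl.integral, -lim), lim)
    out = ctrl.sign * (ctrl.kp * error_nm + ctrl.ki * ctrl.integral)
    return min(max(out, -ctrl.output_limit_nm), ctrl.output_limit_nm)


class StabilizationSession:
    """State of one stabilization run: ROIs, setpoints, controllers, trace.

    Parameters
    ----------
    fiducial_rois, focus_roi
        Regions of interest on the camera frame.
    pixel_size_nm, z_response_nm_per_px, z_axis
        Measurement calibration (from :mod:`stabilock.calibrate` or ground
        truth in tests).
    mode
        "XY", "Z" or "XYZ"; axes outside the mode are never commanded.
    controllers
        Mapping axis name -> response; defaults to PI(kp=0.8, ki=0) each.
    enabled
        When False the loop tracks and records but never moves the stage.
    dead_band_nm
        Minimum correction worth sending; default half the smallest stage
        quantum, set at first step if a stage proxy exposes one.
    """

    def __init__(
        self,
        fiducial_rois: list,
        focus_roi: Roi,
        pixel_size_nm: float,
        z_response_nm_per_px: float,
        z_axis=(1.0, 0.0),
        mode: str = "XYZ",
        controllers: dict | None = None,
        enabled: bool = True,
        period_s: float = 0.054,
        dead_band_nm: float | None = None,
        detachment: DetachmentPolicy | None = None,
    ):
        if mode not in ("XY", "Z", "XYZ"):
            raise ValueError("mode must be 'XY', 'Z' or 'XYZ'")
        self.fiducial_rois = list(fiducial_rois)
        self.focus_roi = focus_roi
        self.pixel_size_nm = float(pixel_size_nm)
        self.z_response_nm_per_px = float(z_response_nm_per_px)
        self.z_axis = np.asarray(z_axis, dtype=float)
        self.mode = mode
        if controllers is None:
            controllers = {a: PIController() for a in "xyz"}
        self.controllers = controllers
        self.enabled = enabled
        self.period_s = float(period_s)
        self.dead_band_nm = dead_band_nm
        self.monitor = DetachmentMonitor(len(self.fiducial_rois), detachment)
        self.setpoint: Setpoint3D | None = None
        self.commanded = np.zeros(3)
        self.trace: list[dict] = []
        self._seeds: list[SpotFit | None] = [None] * len(self.fiducial_rois)
        self._last_t = -math.inf

    @property
    def locked(self) -> bool:
        return self.setpoint is not None

    @property
    def lateral_active(self) -> bool:
        return "XY" in self.mode or self.mode == "XYZ"

    @property
    def axial_active(self) -> bool:
        return "Z" in self.mode

    def _fit_fiducials(self, frame) -> list:
        fits = []
        for i, roi in enumerate(self.fiducial_rois):
            fit = fit_gaussian_2d(roi.extract(frame), seed=self._seeds[i])
            if fit.converged:
                self._seeds[i] = fit
            fits.append(fit)
        return fits

    def trace_frame(self) -> pd.DataFrame:
        return trace_to_frame(self.trace, len(self.fiducial_rois))


TRACE_BASE_COLUMNS = ["t_s", "avg_dx_nm", "avg_dy_nm", "dz_nm", "valid_mask",
                      "cmd_x_nm", "cmd_y_nm", "cmd_z_nm", "note"]


def trace_to_frame(records: list, n_fiducials: int) -> pd.DataFrame:
    cols = ["t_s"]
    cols += [f"dx{i}_nm" for i in range(n_fiducials)]
    cols += [f"dy{i}_nm" for i in range(n_fiducials)]
    cols += TRACE_BASE_COLUMNS[1:]
    return pd.DataFrame(records, columns=cols)


def lock(session: StabilizationSession, frame) -> Setpoint3D:
    """Record the current localizations as the setpoints (zero of drift).

    All fiducial fits must converge and the focus center of mass must be
    valid; otherwise the lock is refused naming the offending ROI.
    Controller integrals and the detachment monitor are reset; commanded
    positions keep their current value.
    """
    session._seeds = [None] * len(session.fiducial_rois)
    fits = session._fit_fiducials(frame)
    for i, fit in enumerate(fits):
        if not fit.converged:
            raise LockError(f"fiducial ROI {i} failed to fit: {fit.message}")
    try:
        est = center_of_mass(session.focus_roi.extract(frame))
    except ValueError as exc:
        raise LockError(f"focus ROI invalid: {exc}") from exc

    xy0 = np.array(
        [
            [session.fiducial_rois[i].origin[1] + fits[i].x,
             session.fiducial_rois[i].origin[0] + fits[i].y]
            for i in range(len(fits))
        ]
    )
    r0 = np.array([session.focus_roi.origin[1], session.focus_roi.origin[0]]) + est.r
    session.setpoint = Setpoint3D(
        xy0_px=xy0,
        r0_px=r0,
        z0_nm=0.0,
        pixel_size_nm=session.pixel_size_nm,
        z_response_nm_per_px=session.z_response_nm_per_px,
        z_axis=session.z_axis,
    )
    for ctrl in session.controllers.values():
        ctrl.reset()
    session.monitor.reset()
    log.info("locked: %d fiducial setpoints, focus at %s px", len(fits), np.round(r0, 2))
    return session.setpoint


def _dead_band(session: StabilizationSession, stage) -> float:
    if session.dead_band_nm is not None:
        return session.dead_band_nm
    q = getattr(stage, "quantum_nm", None)
    session.dead_band_nm = 0.5 * float(np.min(q)) if q is not None else 0.0
    return session.dead_band_nm


def stabilization_step(session: StabilizationSession, camera, stage) -> Displacement3D:
    """One loop iteration: acquire, localize, compute, correct, record."""
    if not session.locked:
        raise RuntimeError("session is not locked")
    sp = session.setpoint
    frame = camera.acquire()
    t = frame.timestamp
    note = ""

    fits = session._fit_fiducials(frame)
    k = len(fits)
    dxy = np.full((k, 2), np.nan)
    fit_ok = np.zeros(k, dtype=bool)
    for i, fit in enumerate(fits):
        if fit.converged:
            gx = session.fiducial_rois[i].origin[1] + fit.x
            gy = session.fiducial_rois[i].origin[0] + fit.y
            dxy[i] = ((gx - sp.xy0_px[i, 0]) * sp.pixel_size_nm,
                      (gy - sp.xy0_px[i, 1]) * sp.pixel_size_nm)
            fit_ok[i] = True
    valid = session.monitor.update(dxy, fit_ok)

    lateral_ok = True
    try:
        avg_dx, avg_dy = average_displacement(dxy, valid)
    except LateralLockLost:
        avg_dx, avg_dy = math.nan, math.nan
        lateral_ok = False
        note = "lateral lock lost; XY paused"

    dz = math.nan
    axial_ok = True
    try:
        est = center_of_mass(session.focus_roi.extract(frame))
        r_global = est.r + np.array([session.focus_roi.origin[1], session.focus_roi.origin[0]])
        dz = displacement_z(
            FocusEstimateShim(r_global, est.mass), sp.r0_px, sp.z_response_nm_per_px, sp.z_axis
        ) - sp.z0_nm
    except ValueError as exc:
        axial_ok = False
        note = (note + "; " if note else "") + f"focus estimate failed: {exc}"

    if session.enabled:
        band = _dead_band(session, stage)
        dt = session.period_s
        if session.lateral_active and lateral_ok:
            cx = pi_response(session.controllers["x"], avg_dx, dt)
            cy = pi_response(session.controllers["y"], avg_dy, dt)
            changed = False
            if abs(cx) >= band:
                session.commanded[0] += cx
                changed = True
            if abs(cy) >= band:
                session.commanded[1] += cy
                changed = True
            if changed:
                try:
                    stage.set_xy(session.commanded[0], session.commanded[1])
                except Exception as exc:  # stage glitch: log, keep looping
                    note = (note + "; " if note else "") + f"xy command failed: {exc}"
                    log.warning("xy command failed: %s", exc)
        if session.axial_active and axial_ok:
            cz = pi_response(session.controllers["z"], dz, dt)
            if abs(cz) >= band:
                session.commanded[2] += cz
                try:
                    stage.set_z(session.commanded[2])
                except Exception as exc:
                    note = (note + "; " if note else "") + f"z command failed: {exc}"
                    log.warning("z command failed: %s", exc)

    if t <= session._last_t:
        t = math.nextafter(session._last_t, math.inf)
    session._last_t = t

    record = {"t_s": t}
    for i in range(k):
        record[f"dx{i}_nm"] = dxy[i, 0]
    for i in range(k):
        record[f"dy{i}_nm"] = dxy[i, 1]
    record.update(
        avg_dx_nm=avg_dx,
        avg_dy_nm=avg_dy,
        dz_nm=dz,
        valid_mask="".join("1" if v else "0" for v in valid),
        cmd_x_nm=session.commanded[0],
        cmd_y_nm=session.commanded[1],
        cmd_z_nm=session.commanded[2],
        note=note,
    )
    session.trace.append(record)
    return Displacement3D(
        timestamp=t, dxy_nm=dxy, valid=valid,
        avg_dx_nm=avg_dx, avg_dy_nm=avg_dy, dz_nm=dz, note=note,
    )


class FocusEstimateShim:
    """Focus estimate re-expressed in global pixel coordinates."""

    def __init__(self, r, mass):
        self.r = np.asarray(r, dtype=float)
        self.mass = mass


def run_loop(session: StabilizationSession, camera, stage, duration_s: float) -> pd.DataFrame:
    """Run the stabilization loop for a simulated duration; returns the trace.

    The number of iterations is ``floor(duration / period)``.  Step-level
    errors are recorded as trace annotations, never aborts.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(math.floor(duration_s / session.period_s + 1e-9))
    for i in range(n):
        rec = stabilization_step(session, camera, stage)
        if (i + 1) % 1000 == 0:
            log.info(
                "iteration %d/%d: avg_dx=%.2f nm avg_dy=%.2f nm dz=%.2f nm",
                i + 1, n, rec.avg_dx_nm, rec.avg_dy_nm, rec.dz_nm,
            )
    return session.trace_frame()


def shift_reference(session: StabilizationSession, delta_nm) -> Setpoint3D:
    """Shift the setpoints by ``delta`` nm (stage coordinates).

    Under closed-loop operation the sample is then driven to the new
    reference, i.e. the ground-truth sample position moves by ``delta``.
    Refused if a shifted lateral setpoint would leave its ROI interior
    (margin 3 px) — the marker would escape its fitting window.
    """
    if not session.locked:
        raise RuntimeError("session is not locked")
    if not session.enabled:
        raise RuntimeError("reference shifts require an enabled (correcting) session")
    delta = np.asarray(delta_nm, dtype=float)
    sp = session.setpoint
    new_xy = sp.xy0_px + delta[:2] / sp.pixel_size_nm
    margin = 3.0
    for i, roi in enumerate(session.fiducial_rois):
        r0, c0 = roi.origin
        nr, nc = roi.size
        x, y = new_xy[i]
        if not (c0 + margin <= x <= c0 + nc - 1 - margin and r0 + margin <= y <= r0 + nr - 1 - margin):
            raise ValueError(f"shift would push fiducial {i} outside its ROI")
    sp.xy0_px = new_xy
    sp.z0_nm += delta[2]
    return sp
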