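"""Session configuration: one YAML document describing a full run.

The config has four sections — simulator (drift, fiducials, focus beam,
camera, stage), control (gains, mode, period, dead-band), calibration
(step lists) and bookkeeping (seed, ROI sizes).  It round-trips through
YAML losslessly and every run logs the exact config used, so any result
is reproducible from its config + seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

from .simscope import (
    AxisMap,
    CameraModel,
    DriftModel,
    FiducialField,
    FocusBeamModel,
    VirtualScope,
    VirtualStage,
)

__all__ = ["ControlConfig", "CalibrationConfig", "SessionConfig",
           "default_config", "load_config", "save_config", "build_scope"]


@dataclass
class ControlConfig:
    kp: float = 0.8
    ki: float = 0.0
    mode: str = "XYZ"
    period_s: float = 0.054
    dead_band_nm: float | None = None  # None -> half the stage quantum
    output_limit_nm: float = 50.0
    fiducial_roi_px: int = 11
    focus_roi_px: int = 31


@dataclass
class CalibrationConfig:
    xy_steps_nm: list = field(default_factory=lambda: [0.0, 100.0, 200.0, 300.0, 400.0])
    z_steps_nm: list = field(default_factory=lambda: [-150.0, -75.0, 0.0, 75.0, 150.0])
    frames_per_point: int = 3


@dataclass
class SessionConfig:
    drift: DriftModel = field(default_factory=DriftModel)
    fiducials: FiducialField = field(default_factory=FiducialField)
    focus: FocusBeamModel = field(default_factory=FocusBeamModel)
    camera: CameraModel = field(default_factory=CameraModel)
    stage: VirtualStage = field(default_factory=VirtualStage)
    control: ControlConfig = field(default_factory=ControlConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    seed: int = 1
    duration_s: float = 600.0

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "duration_s": float(self.duration_s),
            "simulator": {
                "drift": {
                    "velocity_nm_s": [float(v) for v in self.drift.velocity],
                    "diffusion_nm2_s": [float(d) for d in self.drift.diffusion],
                },
                "fiducials": {
                    "positions_nm": [[float(c) for c in p] for p in self.fiducials.positions_nm],
                    "spot_sigma_nm": float(self.fiducials.spot_sigma_nm),
                    "photons_per_frame": float(self.fiducials.photons_per_frame),
                },
                "focus": {
                    "gain": float(self.focus.gain),
                    "spot_sigma_nm": float(self.focus.spot_sigma_nm),
                    "photons_per_frame": float(self.focus.photons_per_frame),
                    "base_position_nm": [float(c) for c in self.focus.base_position_nm],
                    "shift_axis": [float(c) for c in self.focus.shift_axis],
                },
                "camera": {
                    "pixel_size_nm": float(self.camera.pixel_size_nm),
                    "shape": list(self.camera.shape),
                    "baseline": float(self.camera.baseline),
                    "read_noise_sigma": float(self.camera.read_noise_sigma),
                    "shot_noise": bool(self.camera.shot_noise),
                    "exposure_ms": float(self.camera.exposure_ms),
                },
                "stage": {
                    "travel_um": [float(t) for t in self.stage.travel_um],
                    "bit_depth": int(self.stage.bit_depth),
                    "settle_lag": int(self.stage.settle_lag),
                    "axis_perm": list(self.stage.axis_map.perm),
                    "axis_signs": list(self.stage.axis_map.signs),
                },
            },
            "control": {
                "kp": float(self.control.kp),
                "ki": float(self.control.ki),
                "mode": self.control.mode,
                "period_s": float(self.control.period_s),
                "dead_band_nm": self.control.dead_band_nm,
                "output_limit_nm": float(self.control.output_limit_nm),
                "fiducial_roi_px": int(self.control.fiducial_roi_px),
                "focus_roi_px": int(self.control.focus_roi_px),
            },
            "calibration": {
                "xy_steps_nm": [float(s) for s in self.calibration.xy_steps_nm],
                "z_steps_nm": [float(s) for s in self.calibration.z_steps_nm],
                "frames_per_point": int(self.calibration.frames_per_point),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = copy.deepcopy(d)
        sim = d.get("simulator", {})
        drift = sim.get("drift", {})
        fid = sim.get("fiducials", {})
        foc = sim.get("focus", {})
        cam = sim.get("camera", {})
        stg = sim.get("stage", {})
        ctl = d.get("control", {})
        cal = d.get("calibration", {})
        cal.pop("result", None)  # calibrate --out appends results; ignore on load
        unknown = set(d) - {"seed", "duration_s", "simulator", "control", "calibration"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(
            drift=DriftModel(
                velocity=drift.get("velocity_nm_s", [0.0, 0.0, 0.0]),
                diffusion=drift.get("diffusion_nm2_s", [0.0, 0.0, 0.0]),
            ),
            fiducials=FiducialField(
                positions_nm=fid.get("positions_nm", FiducialField().positions_nm),
                spot_sigma_nm=fid.get("spot_sigma_nm", 184.0),
                photons_per_frame=fid.get("photons_per_frame", 50000.0),
            ),
            focus=FocusBeamModel(
                gain=foc.get("gain", 2.0),
                spot_sigma_nm=foc.get("spot_sigma_nm", 300.0),
                photons_per_frame=foc.get("photons_per_frame", 200000.0),
                base_position_nm=foc.get("base_position_nm", [4000.0, 4000.0]),
                shift_axis=foc.get("shift_axis", [1.0, 0.0]),
            ),
            camera=CameraModel(
                pixel_size_nm=cam.get("pixel_size_nm", 80.0),
                shape=tuple(cam.get("shape", (100, 100))),
                baseline=cam.get("baseline", 100.0),
                read_noise_sigma=cam.get("read_noise_sigma", 2.0),
                shot_noise=cam.get("shot_noise", True),
                exposure_ms=cam.get("exposure_ms", 50.0),
            ),
            stage=VirtualStage(
                travel_um=stg.get("travel_um", [20.0, 20.0, 20.0]),
                bit_depth=stg.get("bit_depth", 15),
                axis_map=AxisMap(
                    perm=tuple(stg.get("axis_perm", (0, 1, 2))),
                    signs=tuple(stg.get("axis_signs", (1, 1, 1))),
                ),
                settle_lag=stg.get("settle_lag", 0),
            ),
            control=ControlConfig(**ctl) if ctl else ControlConfig(),
            calibration=CalibrationConfig(**cal) if cal else CalibrationConfig(),
            seed=d.get("seed", 1),
            duration_s=d.get("duration_s", 600.0),
        )
        return cfg


def default_config() -> SessionConfig:
    """The shipped default scenario: ~1 nm/s drift, 4 AuNP-like fiducials
    of width 184 nm imaged at 80 nm/px with 50 ms shot-noise exposures, a
    focus reflection with gain 2, and a 20 um / 15-bit open-loop stage
    (0.61 nm quantum) corrected every 54 ms."""
    return SessionConfig(
        drift=DriftModel(velocity=[0.6, -0.6, 0.45], diffusion=[0.3, 0.3, 0.2]),
    )


def load_config(path) -> SessionConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        return SessionConfig.from_dict(data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def save_config(cfg: SessionConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def build_scope(cfg: SessionConfig, seed: int | None = None) -> VirtualScope:
    """Instantiate the virtual microscope described by a config.

    Dataclass instances are deep-copied so one config can build many
    independent scopes.
    """
    return VirtualScope(
        drift=copy.deepcopy(cfg.drift),
        field_=copy.deepcopy(cfg.fiducials),
        focus=copy.deepcopy(cfg.focus),
        camera=copy.deepcopy(cfg.camera),
        stage=copy.deepcopy(cfg.stage),
        seed=cfg.seed if seed is None else seed,
        frame_interval_s=cfg.control.period_s,
    )
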