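"""Virtual microscope for active 3D sample stabilization.

This module simulates the measurement side of a fiducial-based stabilization
system: a camera imaging bright fiducial markers (gold nanoparticles seen in
a dark-field-like TIR geometry) together with the reflection of a focused
near-infrared beam.  The reflection reports defocus: an axial sample
displacement ``dz`` appears on the camera as a lateral shift ``dr = g * dz``
of the reflection spot, where ``g`` is a geometric gain set by the tilt of
the reflected beam.

Everything is parametric.  Spots are pixel-integrated 2D Gaussians, sample
drift is advection plus Brownian motion, and the piezo stage is an open-loop
actuator quantized to ``travel / 2**bit_depth`` per axis.  The simulated
camera and stage expose the same minimal proxy contracts the control loop
uses for real hardware (:class:`SimCamera`, :class:`SimStage`), so the full
closed loop can be exercised with no hardware attached.

Conventions
-----------
* ``x`` is the image column direction (array axis 1), ``y`` the row
  direction (axis 0); a spot coordinate of ``(i, j)`` in pixels means the
  center of pixel ``(row=j, col=i)``... more precisely positions are given
  as ``(x, y)`` pairs and pixel ``(r, c)`` has center ``x = c, y = r``.
* All positions and displacements are in nanometers unless a name says
  otherwise; pixel coordinates are continuous (sub-pixel).
* Stage coordinates are centered at mid-travel: valid positions span
  ``[-travel/2, +travel/2]`` per axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

__all__ = [
    "DriftModel",
    "FiducialField",
    "FocusBeamModel",
    "CameraModel",
    "Frame",
    "AxisMap",
    "VirtualStage",
    "VirtualScope",
    "SimCamera",
    "SimStage",
    "advance_drift",
    "render_frame",
    "min_step",
    "save_frame",
    "load_frame",
]

_SQRT2 = math.sqrt(2.0)


def min_step(travel_um: float, bit_depth: int) -> float:
    """Smallest realizable stage move in nm for an open-loop piezo.

    The stage driver addresses the travel range with ``bit_depth`` bits, so
    commanded positions land on a lattice of spacing
    ``travel * 1000 / 2**bit_depth`` nm.  For a typical 20 um travel and a
    15-bit driver this is 0.61 nm, the floor for position corrections.
    """
    if travel_um <= 0:
        raise ValueError("travel must be positive")
    if bit_depth < 1:
        raise ValueError("bit_depth must be >= 1")
    return travel_um * 1000.0 / (2 ** bit_depth)


# ---------------------------------------------------------------------------
# drift
# ---------------------------------------------------------------------------


@dataclass
class DriftModel:
    """Sample drift as deterministic advection plus a random walk.

    Parameters
    ----------
    velocity : 3-vector, nm/s
        Deterministic drift velocity.  Typical thermo-mechanical drift on a
        well-isolated microscope peaks around 1 nm/s.
    diffusion : 3-vector, nm^2/s
        Variance rate of the Brownian component; each step of duration
        ``dt`` adds a zero-mean Gaussian with per-axis variance
        ``diffusion * dt``.
    seed : int
        Identifier recorded in configs; the random stream itself is owned
        by the caller (see :class:`VirtualScope`).
    """

    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    diffusion: np.ndarray = field(default_factory=lambda: np.zeros(3))
    seed: int = 0

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.diffusion = np.asarray(self.diffusion, dtype=float)
        if self.velocity.shape != (3,) or self.diffusion.shape != (3,):
            raise ValueError("velocity and diffusion must be 3-vectors")
        if np.any(self.diffusion < 0):
            raise ValueError("diffusion components must be >= 0")


def advance_drift(model: DriftModel, state, dt: float, rng: np.random.Generator):
    """Evolve the drift state by ``dt`` seconds.

    Returns ``state + velocity*dt + N(0, diffusion*dt)`` per axis.  Stepping
    through a schedule of ``dt`` values with a generator seeded once
    reproduces the same path as re-running the schedule with an identically
    seeded generator (the model holds no hidden state).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state = np.asarray(state, dtype=float)
    sigma = np.sqrt(model.diffusion * dt)
    return state + model.velocity * dt + rng.standard_normal(3) * sigma


# ---------------------------------------------------------------------------
# scene description
# ---------------------------------------------------------------------------


@dataclass
class FiducialField:
    """Layout and brightness of the fiducial markers.

    ``positions_nm`` holds one ``(x, y)`` pair per marker, in the sample
    plane at zero drift.  ``spot_sigma_nm`` is the Gaussian width of a
    marker image (184 nm is typical for a 200 nm AuNP under NIR
    illumination); ``photons_per_frame`` the expected detected counts per
    marker per exposure.  ``extra_velocity_nm_s`` gives each marker an
    independent lateral velocity on top of the common drift — zero for a
    well-attached marker, nonzero to emulate a detaching one.
    """

    positions_nm: np.ndarray = field(
        default_factory=lambda: np.array(
            [[1600.0, 1600.0], [1600.0, 6400.0], [6400.0, 1600.0], [6400.0, 6400.0]]
        )
    )
    spot_sigma_nm: float = 184.0
    photons_per_frame: float = 50000.0
    extra_velocity_nm_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions_nm = np.atleast_2d(np.asarray(self.positions_nm, dtype=float))
        if self.spot_sigma_nm <= 0:
            raise ValueError("spot_sigma_nm must be positive")
        if self.photons_per_frame <= 0:
            raise ValueError("photons_per_frame must be positive")
        if self.extra_velocity_nm_s is None:
            self.extra_velocity_nm_s = np.zeros_like(self.positions_nm)
        else:
            self.extra_velocity_nm_s = np.asarray(self.extra_velocity_nm_s, dtype=float)
            if self.extra_velocity_nm_s.shape != self.positions_nm.shape:
                raise ValueError("extra_velocity_nm_s must match positions_nm shape")

    @property
    def n_fiducials(self) -> int:
        return self.positions_nm.shape[0]


@dataclass
class FocusBeamModel:
    """Reflected focus beam: lateral image shift ``dr = gain * dz``.

    ``gain`` is nm of lateral shift per nm of defocus (sign encodes the
    reflection geometry and must be nonzero).  ``shift_axis`` is the unit
    direction of that shift in the image; it is what the Z calibration
    recovers.  The reflection is modeled as a Gaussian spot of width
    ``spot_sigma_nm`` holding ``photons_per_frame`` expected counts.
    """

    gain: float = 2.0
    spot_sigma_nm: float = 300.0
    photons_per_frame: float = 200000.0
    base_position_nm: np.ndarray = field(default_factory=lambda: np.array([4000.0, 4000.0]))
    shift_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self) -> None:
        if self.gain == 0:
            raise ValueError("gain must be nonzero")
        if self.spot_sigma_nm <= 0:
            raise ValueError("spot_sigma_nm must be positive")
        self.base_position_nm = np.asarray(self.base_position_nm, dtype=float)
        axis = np.asarray(self.shift_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("shift_axis must be a nonzero 2-vector")
        self.shift_axis = axis / norm


@dataclass
class CameraModel:
    """Camera geometry and noise.

    ``pixel_size_nm`` is the sample-plane-equivalent pixel pitch.  Noise is
    per-pixel Poisson shot noise on the expected photon image (optional),
    then a constant ``baseline`` and Gaussian read noise; output is clipped
    at zero.
    """

    pixel_size_nm: float = 80.0
    shape: tuple = (100, 100)
    baseline: float = 100.0
    read_noise_sigma: float = 2.0
    shot_noise: bool = True
    exposure_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")
        self.shape = tuple(int(s) for s in self.shape)


@dataclass
class Frame:
    """One acquired camera image (float counts) with metadata."""

    pixels: np.ndarray
    timestamp: float = 0.0
    pixel_size_nm: float = 80.0


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _pixel_integral_1d(coords: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Integral of a unit-mass 1D Gaussian over unit pixels centered at coords."""
    a = (coords - mu + 0.5) / (_SQRT2 * sigma)
    b = (coords - mu - 0.5) / (_SQRT2 * sigma)
    return 0.5 * (erf(a) - erf(b))


def _add_spot(pixels: np.ndarray, x_px: float, y_px: float, sigma_px: float, photons: float) -> None:
    """Accumulate an integrated-Gaussian spot in place (local window only)."""
    half = int(math.ceil(7.0 * sigma_px)) + 1
    nrows, ncols = pixels.shape
    r0 = max(int(math.floor(y_px)) - half, 0)
    r1 = min(int(math.ceil(y_px)) + half + 1, nrows)
    c0 = max(int(math.floor(x_px)) - half, 0)
    c1 = min(int(math.ceil(x_px)) + half + 1, ncols)
    gy = _pixel_integral_1d(np.arange(r0, r1, dtype=float), y_px, sigma_px)
    gx = _pixel_integral_1d(np.arange(c0, c1, dtype=float), x_px, sigma_px)
    pixels[r0:r1, c0:c1] += photons * np.outer(gy, gx)


def _check_margin(x_px, y_px, sigma_px, shape, label: str) -> None:
    nrows, ncols = shape
    m = 3.0 * sigma_px
    if not (m <= x_px <= ncols - 1 - m and m <= y_px <= nrows - 1 - m):
        raise ValueError(
            f"spot '{label}' at ({x_px:.2f}, {y_px:.2f}) px is closer than "
            f"3 sigma ({m:.1f} px) to the frame edge"
        )


def render_frame(
    field_: FiducialField,
    focus: FocusBeamModel,
    camera: CameraModel,
    sample_offset,
    rng: np.random.Generator | None = None,
    timestamp: float = 0.0,
    fiducial_shifts_nm: np.ndarray | None = None,
    photon_scale: float = 1.0,
) -> Frame:
    """Render one camera frame at a given ground-truth sample offset.

    Each fiducial is drawn displaced laterally by ``(offset_x, offset_y)``;
    the focus reflection is displaced by ``gain * offset_z`` along the beam's
    ``shift_axis`` and does not respond to lateral offsets (it reflects off
    the coverslip).  ``fiducial_shifts_nm`` adds per-marker lateral shifts
    (used for detachment scenarios).  With ``rng=None`` or
    ``camera.shot_noise=False`` the expected (noise-free) photon image plus
    baseline is returned.
    """
    offset = np.asarray(sample_offset, dtype=float)
    ps = camera.pixel_size_nm
    sig_f = field_.spot_sigma_nm / ps
    sig_z = focus.spot_sigma_nm / ps

    shifts = np.zeros_like(field_.positions_nm)
    if fiducial_shifts_nm is not None:
        shifts = shifts + np.asarray(fiducial_shifts_nm, dtype=float)

    expected = np.zeros(camera.shape, dtype=float)
    for k in range(field_.n_fiducials):
        x_px = (field_.positions_nm[k, 0] + offset[0] + shifts[k, 0]) / ps
        y_px = (field_.positions_nm[k, 1] + offset[1] + shifts[k, 1]) / ps
        _check_margin(x_px, y_px, sig_f, camera.shape, f"fiducial {k}")
        _add_spot(expected, x_px, y_px, sig_f, field_.photons_per_frame * photon_scale)

    r_focus = focus.base_position_nm + focus.gain * offset[2] * focus.shift_axis
    fx, fy = r_focus[0] / ps, r_focus[1] / ps
    _check_margin(fx, fy, sig_z, camera.shape, "focus")
    _add_spot(expected, fx, fy, sig_z, focus.photons_per_frame * photon_scale)

    pixels = expected
    if rng is not None and camera.shot_noise:
        pixels = rng.poisson(expected).astype(float)
    pixels = pixels + camera.baseline
    if rng is not None and camera.read_noise_sigma > 0:
        pixels = pixels + rng.normal(0.0, camera.read_noise_sigma, size=pixels.shape)
    np.clip(pixels, 0.0, None, out=pixels)
    return Frame(pixels=pixels, timestamp=timestamp, pixel_size_nm=ps)


# ---------------------------------------------------------------------------
# stage
# ---------------------------------------------------------------------------


@dataclass
class AxisMap:
    """Signed permutation mapping world (command) axes to physical stage axes.

    Physical axis ``i`` realizes ``signs[i] * world[perm[i]]``.  Cameras and
    stages do not always share axis conventions; the proxies compensate so
    the control loop always works in one world frame.
    """

    perm: tuple = (0, 1, 2)
    signs: tuple = (1, 1, 1)

    def __post_init__(self) -> None:
        if sorted(self.perm) != [0, 1, 2]:
            raise ValueError("perm must be a permutation of (0, 1, 2)")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +1 or -1")
        self.perm = tuple(int(p) for p in self.perm)
        self.signs = tuple(int(s) for s in self.signs)

    def to_physical(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return np.array([self.signs[i] * v[self.perm[i]] for i in range(3)])

    def to_world(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        out = np.empty(3)
        for i in range(3):
            out[self.perm[i]] = self.signs[i] * v[i]
        return out


@dataclass
class VirtualStage:
    """Open-loop piezo stage with a quantized position lattice.

    Commanded targets are mapped to physical axes, rounded half-to-even to
    the nearest multiple of the per-axis quantum ``travel/2**bit_depth``
    (so repeated small commands carry no directional bias), and clamped to
    the centered travel range.  ``settle_lag`` delays a command by that many
    ticks (loop iterations) before it is realized; the default 0 models
    triggered operation where moves complete between exposures.
    """

    travel_um: np.ndarray = field(default_factory=lambda: np.array([20.0, 20.0, 20.0]))
    bit_depth: int = 15
    axis_map: AxisMap = field(default_factory=AxisMap)
    settle_lag: int = 0

    def __post_init__(self) -> None:
        self.travel_um = np.asarray(self.travel_um, dtype=float)
        if self.travel_um.shape != (3,):
            raise ValueError("travel_um must be a 3-vector")
        self.position = np.zeros(3)  # physical, nm
        self.events: list[str] = []
        self._pending: list[list] = []

    @property
    def quantum_nm(self) -> np.ndarray:
        """Per-physical-axis lattice spacing in nm."""
        return np.array([min_step(t, self.bit_depth) for t in self.travel_um])

    @property
    def world_position(self) -> np.ndarray:
        return self.axis_map.to_world(self.position)

    def apply_move(self, target_world) -> np.ndarray:
        """Command an absolute move; returns the realized physical position.

        The realized position is the nearest lattice point to the (clamped)
        physical target.  Out-of-travel targets are clamped and a warning
        event is recorded rather than raising: on real hardware a refused
        move mid-loop would be worse than a saturated one.
        """
        phys = self.axis_map.to_physical(target_world)
        half = self.travel_um * 1000.0 / 2.0
        clamped = np.clip(phys, -half, half)
        if np.any(clamped != phys):
            self.events.append(f"clamped target {phys} to travel range +/-{half} nm")
        q = self.quantum_nm
        realized = np.round(clamped / q) * q
        if self.settle_lag <= 0:
            self.position = realized
        else:
            self._pending.append([realized, self.settle_lag])
        return realized

    def tick(self) -> None:
        """Advance one loop iteration; realize pending (lagged) commands."""
        if not self._pending:
            return
        remaining = []
        for entry in self._pending:
            entry[1] -= 1
            if entry[1] <= 0:
                self.position = entry[0]
            else:
                remaining.append(entry)
        self._pending = remaining


# ---------------------------------------------------------------------------
# the assembled scope and its hardware proxies
# ---------------------------------------------------------------------------


class VirtualScope:
    """Ground-truth simulation state: drift, stage, optics, clock.

    The net sample offset seen by the camera is ``drift + stage position``
    (the stage moves the sample), so a stabilization loop commanding the
    stage opposite to the measured displacement drives the net offset to
    zero.  Time is virtual: each acquisition advances the clock by
    ``frame_interval_s``, making runs deterministic and faster than real
    time.  Randomness comes from independent child streams of one seed
    (drift and frame noise separately), so enabling or disabling one noise
    source does not perturb the other.
    """

    def __init__(
        self,
        drift: DriftModel | None = None,
        field_: FiducialField | None = None,
        focus: FocusBeamModel | None = None,
        camera: CameraModel | None = None,
        stage: VirtualStage | None = None,
        seed: int = 0,
        frame_interval_s: float = 0.054,
        initial_offset=(0.0, 0.0, 0.0),
    ):
        self.drift = drift if drift is not None else DriftModel()
        self.field = field_ if field_ is not None else FiducialField()
        self.focus = focus if focus is not None else FocusBeamModel()
        self.camera = camera if camera is not None else CameraModel()
        self.stage = stage if stage is not None else VirtualStage()
        self.seed = seed
        self.frame_interval_s = frame_interval_s
        ss = np.random.SeedSequence(seed)
        child = ss.spawn(2)
        self._rng_drift = np.random.default_rng(child[0])
        self._rng_frame = np.random.default_rng(child[1])
        self.clock = 0.0
        self.drift_offset = np.asarray(initial_offset, dtype=float).copy()
        self.photon_scale = 1.0

    @property
    def net_offset(self) -> np.ndarray:
        """Ground-truth sample offset relative to the objective, nm."""
        return self.drift_offset + self.stage.world_position

    def advance(self, dt: float) -> None:
        self.drift_offset = advance_drift(self.drift, self.drift_offset, dt, self._rng_drift)
        self.clock += dt
        self.stage.tick()

    def acquire(self) -> Frame:
        """Advance one frame interval and render the resulting image."""
        self.advance(self.frame_interval_s)
        shifts = self.field.extra_velocity_nm_s * self.clock
        return render_frame(
            self.field,
            self.focus,
            self.camera,
            self.net_offset,
            rng=self._rng_frame,
            timestamp=self.clock,
            fiducial_shifts_nm=shifts,
            photon_scale=self.photon_scale,
        )


class SimCamera:
    """Camera proxy over a :class:`VirtualScope`.

    Contract used by the control loop: ``acquire() -> Frame`` (triggered,
    one frame per request) plus an optional exposure setter.  Frames are
    returned already mapped to stage axes (here the simulator world frame
    is the stage command frame, so no remapping is needed).
    """

    def __init__(self, scope: VirtualScope):
        self.scope = scope

    def acquire(self) -> Frame:
        return self.scope.acquire()

    def set_exposure(self, exposure_ms: float) -> None:
        """Change exposure; expected photon counts scale proportionally."""
        if exposure_ms <= 0:
            raise ValueError("exposure must be positive")
        self.scope.photon_scale = exposure_ms / self.scope.camera.exposure_ms


class SimStage:
    """Stage proxy over a :class:`VirtualScope`.

    Contract: ``get_position()``, independent ``set_xy(x, y)`` and
    ``set_z(z)`` (world/command coordinates, nm), and a travel-limit query.
    Every command is appended to ``command_log`` as ``(kind, values, t)``,
    which the tests use to assert axis decoupling.
    """

    def __init__(self, scope: VirtualScope):
        self.scope = scope
        self._target = scope.stage.world_position.copy()
        self.command_log: list[tuple] = []

    def get_position(self) -> np.ndarray:
        return self.scope.stage.world_position

    def set_xy(self, x: float, y: float) -> None:
        self._target[0] = x
        self._target[1] = y
        self.command_log.append(("xy", (x, y), self.scope.clock))
        self.scope.stage.apply_move(self._target)

    def set_z(self, z: float) -> None:
        self._target[2] = z
        self.command_log.append(("z", (z,), self.scope.clock))
        self.scope.stage.apply_move(self._target)

    def travel_limits_nm(self) -> np.ndarray:
        half = self.scope.stage.travel_um * 1000.0 / 2.0
        return np.stack([-half, half], axis=0)

    @property
    def quantum_nm(self) -> np.ndarray:
        """Lattice spacing expressed on world axes."""
        q = self.scope.stage.quantum_nm
        out = np.empty(3)
        for i in range(3):
            out[self.scope.stage.axis_map.perm[i]] = q[i]
        return out


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------


def save_frame(frame: Frame, path) -> None:
    """Write a frame as 16-bit grayscale TIFF with metadata in the description.

    Counts are rounded and clipped to the uint16 range; pixel size (nm/px)
    and timestamp are stored as JSON in the ImageDescription tag.
    """
    import tifffile

    data = np.clip(np.round(frame.pixels), 0, 65535).astype(np.uint16)
    meta = {"pixel_size_nm": frame.pixel_size_nm, "timestamp_s": frame.timestamp}
    tifffile.imwrite(path, data, description=json.dumps(meta))


def load_frame(path) -> Frame:
    """Read a frame written by :func:`save_frame`."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        meta = {}
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, ValueError):
                meta = {}
    return Frame(
        pixels=data,
        timestamp=float(meta.get("timestamp_s", 0.0)),
        pixel_size_nm=float(meta.get("pixel_size_nm", 1.0)),
    )
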