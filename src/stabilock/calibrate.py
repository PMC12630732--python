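"""Calibration against commanded stage motion, and trace statistics.

Two calibrations use the piezo stage itself as the length reference:

* pixel size — step the stage laterally by known amounts, localize a
  fiducial at each position, and fit commanded nm against measured px;
* Z response — step the stage axially, record the reflection-spot center
  of mass, fit the principal direction of its motion (the ``z_axis``) and
  the slope of the projected shift, giving nm of defocus per px of shift.

Both are performed with stabilization disabled (the loop would fight the
calibration motion) and are strictly linear fits; curvature shows up as a
depressed r^2.

Trace statistics follow the standard characterization of a stabilized
trace: per-axis histogram of displacements (Freedman-Diaconis bins), a
Gaussian fit giving the headline sigma, the plain sample standard
deviation co-reported as a binning-insensitive cross-check, and the
quadrature bookkeeping ``sigma_total = sqrt(sigma_CRB^2 +
sigma_stabilization^2)`` with ``sigma_stabilization^2 = sigma_x^2 +
sigma_y^2`` used when combining with a localization method's theoretical
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .localize import center_of_mass, fit_gaussian_2d

__all__ = [
    "CalibrationError",
    "CalibrationResult",
    "AxisPrecision",
    "PrecisionSummary",
    "calibrate_pixel_size",
    "calibrate_z_response",
    "precision_stats",
    "summarize_trace",
    "sigma_total",
]


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationResult:
    """Linear-fit calibration outputs with standard errors."""

    pixel_size_nm: float | None = None
    pixel_size_err: float | None = None
    z_response_nm_per_px: float | None = None
    z_response_err: float | None = None
    z_axis: np.ndarray | None = None
    r2: float = math.nan
    n_points: int = 0


def _track_peak(pixels: np.ndarray, center_px, half_search: int, fit_window: int):
    """Fit a Gaussian in a window around the brightest pixel near center_px."""
    x, y = center_px
    nr, nc = pixels.shape
    r0 = max(int(round(y)) - half_search, 0)
    r1 = min(int(round(y)) + half_search + 1, nr)
    c0 = max(int(round(x)) - half_search, 0)
    c1 = min(int(round(x)) + half_search + 1, nc)
    box = pixels[r0:r1, c0:c1]
    pr, pc = np.unravel_index(np.argmax(box), box.shape)
    pr += r0
    pc += c0
    half = fit_window // 2
    wr0 = min(max(pr - half, 0), nr - fit_window)
    wc0 = min(max(pc - half, 0), nc - fit_window)
    fit = fit_gaussian_2d(pixels[wr0 : wr0 + fit_window, wc0 : wc0 + fit_window])
    if not fit.converged:
        return None
    return (wc0 + fit.x, wr0 + fit.y)


def calibrate_pixel_size(
    stage,
    camera,
    steps_nm,
    axis: str = "x",
    start_px=None,
    half_search: int = 12,
    fit_window: int = 11,
    frames_per_point: int = 3,
) -> CalibrationResult:
    """Recover the sample-plane pixel size from commanded lateral steps.

    The stage is stepped through ``steps_nm`` along ``axis``; at each
    position one frame is acquired and a fiducial is localized by Gaussian
    fitting in a window tracked from position to position (the pixel size
    is unknown at this point, so the search is incremental).  A linear fit
    of measured px against the read-back stage position (nm) gives the
    pixel size as the inverse slope, with the standard error propagated
    from the fit.  The read-back, not the commanded target, is used so the
    stage's own quantization does not bias the slope.
    """
    steps = np.asarray(steps_nm, dtype=float)
    if len(np.unique(steps)) < 3:
        raise CalibrationError("need at least 3 distinct commanded positions")
    if axis not in ("x", "y"):
        raise CalibrationError("axis must be 'x' or 'y'")

    origin = np.array(stage.get_position(), dtype=float)
    if start_px is None:
        frame = camera.acquire()
        r, c = np.unravel_index(np.argmax(frame.pixels), frame.pixels.shape)
        start_px = (float(c), float(r))

    comp = 0 if axis == "x" else 1
    # up-then-down sweep: averaging the two visits of each step cancels
    # drift that is linear in time over the sweep
    visits = list(range(len(steps))) + list(range(len(steps) - 1, -1, -1))
    sums = np.zeros(len(steps))
    counts = np.zeros(len(steps))
    realized = np.zeros(len(steps))
    center = start_px
    for idx in visits:
        target = origin.copy()
        target[comp] += steps[idx]
        stage.set_xy(target[0], target[1])
        realized[idx] = float(np.array(stage.get_position(), dtype=float)[comp])
        for _ in range(frames_per_point):
            frame = camera.acquire()
            pos = _track_peak(frame.pixels, center, half_search, fit_window)
            if pos is None:
                stage.set_xy(origin[0], origin[1])
                raise CalibrationError(f"localization failed at step {steps[idx]} nm")
            sums[idx] += pos[comp]
            counts[idx] += 1
            center = pos
    stage.set_xy(origin[0], origin[1])

    measured = sums / counts
    order = np.argsort(steps)
    diffs = np.diff(measured[order])
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise CalibrationError("measured positions are not monotonic in the commanded steps")

    fit = linregress(realized, measured)  # slope in px/nm
    if fit.slope == 0:
        raise CalibrationError("no measurable displacement; increase the step size")
    pixel_size = 1.0 / fit.slope
    err = fit.stderr / fit.slope**2 if fit.stderr is not None else math.nan
    return CalibrationResult(
        pixel_size_nm=float(pixel_size),
        pixel_size_err=float(err),
        r2=float(fit.rvalue**2),
        n_points=len(steps),
    )


def calibrate_z_response(
    stage,
    camera,
    z_steps_nm,
    focus_roi,
    frames_per_point: int = 3,
) -> CalibrationResult:
    """Recover the Z response (nm of defocus per px of reflection shift).

    The stage is stepped axially through ``z_steps_nm``; at each position
    the reflection-spot center of mass is averaged over
    ``frames_per_point`` frames.  The principal direction of spot motion
    (by SVD of the centered positions) is the calibrated ``z_axis``,
    oriented so the projected shift increases with commanded z; the
    inverse slope of projection vs z is the response.
    """
    steps = np.asarray(z_steps_nm, dtype=float)
    if len(np.unique(steps)) < 3:
        raise CalibrationError("need at least 3 distinct commanded Z positions")

    z0 = float(np.array(stage.get_position(), dtype=float)[2])
    visits = list(range(len(steps))) + list(range(len(steps) - 1, -1, -1))
    sums = np.zeros((len(steps), 2))
    counts = np.zeros(len(steps))
    realized = np.zeros(len(steps))
    for idx in visits:
        stage.set_z(z0 + steps[idx])
        realized[idx] = float(np.array(stage.get_position(), dtype=float)[2]) - z0
        for _ in range(frames_per_point):
            frame = camera.acquire()
            est = center_of_mass(focus_roi.extract(frame))
            sums[idx] += est.r
            counts[idx] += 1
    stage.set_z(z0)

    points = sums / counts[:, None]
    centered = points - points.mean(axis=0)
    if np.abs(centered).max() < 0.02:
        raise CalibrationError(
            "reflection spot did not move measurably; increase the Z step range or beam gain"
        )
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    fit = linregress(realized, proj)  # px per nm
    if fit.slope < 0:
        axis = -axis
        proj = -proj
        fit = linregress(realized, proj)
    if fit.slope == 0 or not np.isfinite(fit.slope):
        raise CalibrationError("degenerate Z calibration; increase the step range")
    z_response = 1.0 / fit.slope
    err = fit.stderr / fit.slope**2 if fit.stderr is not None else math.nan
    return CalibrationResult(
        z_response_nm_per_px=float(z_response),
        z_response_err=float(err),
        z_axis=np.asarray(axis, dtype=float),
        r2=float(fit.rvalue**2),
        n_points=len(steps),
    )


# ---------------------------------------------------------------------------
# precision statistics
# ---------------------------------------------------------------------------


@dataclass
class AxisPrecision:
    """Per-axis width of the displacement distribution, nm."""

    sigma_nm: float
    sample_std_nm: float
    fit_ok: bool
    agreement: float  # |fit - std| / std, nan when undefined
    n_samples: int


@dataclass
class PrecisionSummary:
    """3D stabilization precision plus quadrature bookkeeping."""

    x: AxisPrecision
    y: AxisPrecision
    z: AxisPrecision
    sigma_stabilization_nm: float = math.nan
    sigma_crb_nm: float | None = None
    sigma_total_nm: float | None = None
    n_samples: int = 0

    def report(self) -> str:
        lines = ["Stabilization precision (Gaussian fit of displacement histograms)"]
        for name, ax in (("x", self.x), ("y", self.y), ("z", self.z)):
            tag = "" if ax.fit_ok else "  [histogram fit rejected; sample std reported]"
            lines.append(
                f"  sigma_{name} = {ax.sigma_nm:.3f} nm"
                f"   (sample std {ax.sample_std_nm:.3f} nm, n={ax.n_samples}){tag}"
            )
        lines.append(f"  sigma_stabilization = {self.sigma_stabilization_nm:.3f} nm  "
                     "(quadrature sum of x and y)")
        if self.sigma_total_nm is not None:
            lines.append(
                f"  sigma_total = {self.sigma_total_nm:.3f} nm  "
                f"(with sigma_CRB = {self.sigma_crb_nm:.3f} nm)"
            )
        return "\n".join(lines)


def _gauss(x, a, mu, sig):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sig**2))


def precision_stats(values, min_samples: int = 100) -> AxisPrecision:
    """Histogram + Gaussian fit width of a displacement trace.

    Bins are Freedman-Diaconis.  The fitted sigma is the headline value;
    the sample standard deviation is co-reported, and for a Gaussian-like
    trace the two agree within ~15%.  A degenerate (constant) trace or a
    failed fit reports the sample std with ``fit_ok=False``.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    if n < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {n}")
    std = float(values.std(ddof=1))
    if std <= 1e-12 * max(1.0, abs(float(values.mean()))):
        # constant trace: no distribution to fit
        return AxisPrecision(sigma_nm=0.0, sample_std_nm=0.0, fit_ok=False,
                             agreement=math.nan, n_samples=n)
    counts, edges = np.histogram(values, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        if len(centers) < 4:
            raise ValueError("too few histogram bins for a 3-parameter fit")
        popt, _ = curve_fit(
            _gauss, centers, counts,
            p0=[counts.max(), float(values.mean()), std], maxfev=10000,
        )
        sigma = abs(float(popt[2]))
        agreement = abs(sigma - std) / std
        ok = np.isfinite(sigma) and sigma > 0 and agreement <= 0.5
    except (RuntimeError, ValueError, TypeError):
        sigma, agreement, ok = std, math.nan, False
    if not ok:
        sigma = std
    return AxisPrecision(sigma_nm=sigma, sample_std_nm=std, fit_ok=bool(ok),
                         agreement=agreement, n_samples=n)


def summarize_trace(trace: pd.DataFrame, sigma_crb_nm: float | None = None) -> PrecisionSummary:
    """Per-axis precision of a stabilization trace (avg lateral + axial)."""
    px = precision_stats(trace["avg_dx_nm"].to_numpy())
    py = precision_stats(trace["avg_dy_nm"].to_numpy())
    pz = precision_stats(trace["dz_nm"].to_numpy())
    stab = math.hypot(px.sigma_nm, py.sigma_nm)
    total = sigma_total(sigma_crb_nm, stab) if sigma_crb_nm is not None else None
    return PrecisionSummary(
        x=px, y=py, z=pz,
        sigma_stabilization_nm=stab,
        sigma_crb_nm=sigma_crb_nm,
        sigma_total_nm=total,
        n_samples=min(px.n_samples, py.n_samples, pz.n_samples),
    )


def sigma_total(sigma_crb_nm: float, sigma_stab_nm: float) -> float:
    """Combined precision: quadrature sum of method CRB and stabilization."""
    if sigma_crb_nm < 0 or sigma_stab_nm < 0:
        raise ValueError("sigmas must be non-negative")
    return math.hypot(sigma_crb_nm, sigma_stab_nm)
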