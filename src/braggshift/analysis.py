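"""Measurement of Bragg-peak shifts and dose-distribution asymmetry.

Operates on the voxelized dose grids of :mod:`braggshift.simulate`:
locates the Bragg peak with sub-voxel (parabolic) refinement, measures the
lateral shift WD and depth retraction dDD against a field-free reference,
and quantifies planar asymmetry three ways --

* axis-wise 1D Gaussian fits and their sigma ratio (bending axis u over
  field axis v);
* isodose contours fitted with a shared-center inscribed circle (IC) and
  circumscribed circle (EC), whose radius difference measures departure
  from circularity at a dose level;
* a rotating-line FWHM scan through the peak, yielding FWHM_max/min and
  the angles of the principal axes relative to the beam direction.

All sub-voxel interpolation is trilinear; half-maximum crossings are found
by linear interpolation between samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage import measure as skmeasure

from .errors import ContourError, FitError, IncompatibleGridsError, NoPeakError
from .simulate import DoseGrid

__all__ = [
    "PeakLocation",
    "ShiftMeasurement",
    "PlanarSlab",
    "GaussianFit1D",
    "IsodoseFit",
    "FwhmScan",
    "find_bragg_peak",
    "measure_shifts",
    "depth_dose_curve",
    "planar_at_peak",
    "fit_gaussian_1d",
    "sigma_ratio",
    "isodose_contour",
    "fit_ic_ec",
    "skewness_by_level",
    "fwhm_scan",
]


@dataclass(frozen=True)
class PeakLocation:
    """Continuous (x, y, z) position [cm] of the dose maximum and its value."""

    x: float
    y: float
    z: float
    value: float
    index: tuple[int, int, int]


@dataclass(frozen=True)
class ShiftMeasurement:
    """WD [cm], dDD [cm] and deflection angle [deg] vs a field-free reference."""

    wd: float
    ddd: float
    angle_def: float
    reference_peak_depth: float


@dataclass
class PlanarSlab:
    """2D dose slab at the Bragg-peak depth, normalized to its own maximum.

    Axes: u is the bending axis (x), v the field axis (y); ``u``/``v`` hold
    the pixel-center coordinates [cm] and ``depth`` the slab's z position.
    """

    values: np.ndarray
    u: np.ndarray
    v: np.ndarray
    depth: float
    pixel: tuple[float, float]


@dataclass(frozen=True)
class GaussianFit1D:
    """Least-squares Gaussian fit of a 1D profile.

    ``halfwidth_asymmetry`` is (right - left)/(right + left) of the two
    half-maximum half-widths; zero for a symmetric profile.
    """

    mean: float
    sigma: float
    amplitude: float
    rms_residual: float
    halfwidth_asymmetry: float


@dataclass
class IsodoseFit:
    """IC/EC circle fit of one isodose contour.

    A single shared center minimizes the annulus area pi*(r_ec^2 - r_ic^2),
    with r_ic the minimum and r_ec the maximum distance from the center to
    the contour; ``radius_diff`` = r_ec - r_ic is the skewness metric.
    """

    level: float
    contour: np.ndarray
    center: tuple[float, float]
    r_ic: float
    r_ec: float

    @property
    def radius_diff(self) -> float:
        return self.r_ec - self.r_ic

    @property
    def mean_radius(self) -> float:
        return 0.5 * (self.r_ic + self.r_ec)


@dataclass
class FwhmScan:
    """FWHM of lines through the peak vs in-plane rotation angle.

    Angles are measured from the beam (+z) axis in [0, 180) degrees;
    ``fwhm_vertical`` is the 0-degree (beam-axis) width.
    """

    angles: np.ndarray
    fwhm: np.ndarray
    fwhm_max: float
    angle_max: float
    fwhm_min: float
    angle_min: float
    fwhm_vertical: float


def _parabolic_refine(values: np.ndarray, idx: int) -> float:
    """Sub-sample offset of a parabola through three points around idx."""
    if idx <= 0 or idx >= len(values) - 1:
        return 0.0
    y0, y1, y2 = float(values[idx - 1]), float(values[idx]), float(values[idx + 1])
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not a local maximum shape
        return 0.0
    offset = 0.5 * (y0 - y2) / denom
    return float(np.clip(offset, -0.5, 0.5))


def find_bragg_peak(grid: DoseGrid) -> PeakLocation:
    """Locate the dose maximum with 3-point parabolic refinement per axis.

    Ties are broken toward the smallest depth, then the smallest |x|.
    """
    v = grid.values
    vmax = float(v.max())
    if vmax <= 0:
        raise NoPeakError("dose grid contains no positive dose")
    cand = np.argwhere(v == vmax)
    xc = grid.grid.axis_centers(0)
    order = np.lexsort((np.abs(xc[cand[:, 0]]), cand[:, 2]))
    ix, iy, iz = (int(i) for i in cand[order[0]])
    coords = []
    for axis, idx in zip(range(3), (ix, iy, iz)):
        line = v[
            {0: np.s_[:, iy, iz], 1: np.s_[ix, :, iz], 2: np.s_[ix, iy, :]}[axis]
        ]
        off = _parabolic_refine(line, idx)
        coords.append(grid.grid.axis_centers(axis)[idx] + off * grid.grid.voxel[axis])
    return PeakLocation(x=coords[0], y=coords[1], z=coords[2], value=vmax, index=(ix, iy, iz))


def _depth_and_lateral_peak(grid: DoseGrid) -> tuple[float, float, float]:
    """Refined (z, x, y) of the Bragg peak from integrated profiles.

    The depth comes from the laterally-integrated depth-dose curve, the
    lateral position from the in-plane profiles of the peak slab -- both
    with 3-point parabolic refinement.  This is robust against the
    lateral-spread dilution that biases the raw 3D voxel maximum.
    """
    prof = grid.values.sum(axis=(0, 1), dtype=np.float64)
    if prof.max() <= 0:
        raise NoPeakError("dose grid contains no positive dose")
    iz = int(np.argmax(prof))
    zc = grid.grid.axis_centers(2)
    z = zc[iz] + _parabolic_refine(prof, iz) * grid.grid.voxel[2]
    out = [z]
    slab = grid.values[:, :, iz].astype(np.float64)
    for axis, line in ((0, slab.sum(axis=1)), (1, slab.sum(axis=0))):
        i = int(np.argmax(line))
        out.append(
            float(grid.grid.axis_centers(axis)[i]
                  + _parabolic_refine(line, i) * grid.grid.voxel[axis])
        )
    return out[0], out[1], out[2]


def measure_shifts(grid_b: DoseGrid, grid_0: DoseGrid) -> ShiftMeasurement:
    """WD, dDD and deflection angle of an in-field grid vs its B=0 reference.

    WD is the in-plane lateral distance of the in-field Bragg peak from the
    field-free beam axis (located by the reference peak); dDD is the
    reference peak depth minus the in-field peak depth.  Peak positions use
    the integrated depth-dose curve and the peak-slab lateral profiles.
    """
    pb = grid_b.provenance
    p0 = grid_0.provenance
    if p0.get("field_t", 0.0) != 0.0:
        raise IncompatibleGridsError("reference grid must have zero field")
    for key in ("energy_mev", "grid_extent_cm", "grid_voxel_cm", "grid_origin_cm"):
        if pb.get(key) != p0.get(key):
            raise IncompatibleGridsError(f"grids differ in {key}")
    zb, xb, yb = _depth_and_lateral_peak(grid_b)
    z0, x0, y0 = _depth_and_lateral_peak(grid_0)
    wd = math.hypot(xb - x0, yb - y0)
    ddd = z0 - zb
    angle = math.degrees(math.atan2(wd, zb)) if zb > 0 else 0.0
    return ShiftMeasurement(wd=wd, ddd=ddd, angle_def=angle, reference_peak_depth=z0)


def depth_dose_curve(
    grid: DoseGrid, normalization: str = "surface"
) -> tuple[np.ndarray, np.ndarray]:
    """Laterally-integrated dose per z-slab, normalized to surface or maximum."""
    profile = grid.values.sum(axis=(0, 1), dtype=np.float64)
    z = grid.grid.axis_centers(2)
    if normalization == "surface":
        if profile[0] <= 0:
            raise ValueError("zero entrance dose; cannot normalize to surface")
        profile = profile / profile[0]
    elif normalization == "max":
        profile = profile / profile.max()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return z, profile


def planar_at_peak(grid: DoseGrid, smooth_sigma_px: float = 0.0) -> PlanarSlab:
    """The z-slab containing the refined Bragg peak, max-normalized.

    Axes are relabeled u = bending axis (x) and v = field axis (y).
    ``smooth_sigma_px`` applies an in-plane Gaussian filter (pixels) before
    normalization -- useful to de-noise sampled (mc) slabs ahead of
    contour extraction.
    """
    peak = find_bragg_peak(grid)
    iz = peak.index[2]
    slab = grid.values[:, :, iz].astype(np.float64)
    if smooth_sigma_px > 0:
        slab = ndimage.gaussian_filter(slab, smooth_sigma_px)
    slab = slab / slab.max()
    return PlanarSlab(
        values=slab,
        u=grid.grid.axis_centers(0),
        v=grid.grid.axis_centers(1),
        depth=float(grid.grid.axis_centers(2)[iz]),
        pixel=(grid.grid.voxel[0], grid.grid.voxel[1]),
    )


def _half_widths(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Left and right half-widths at half maximum via linear interpolation."""
    imax = int(np.argmax(y))
    half = 0.5 * y[imax]
    left = right = math.nan
    for i in range(imax, 0, -1):
        if y[i - 1] < half <= y[i]:
            f = (y[i] - half) / (y[i] - y[i - 1])
            left = x[imax] - (x[i] + f * (x[i - 1] - x[i]))
            break
    for i in range(imax, len(y) - 1):
        if y[i + 1] < half <= y[i]:
            f = (y[i] - half) / (y[i] - y[i + 1])
            right = (x[i] + f * (x[i + 1] - x[i])) - x[imax]
            break
    return left, right


def fit_gaussian_1d(x: np.ndarray, y: np.ndarray) -> GaussianFit1D:
    """Least-squares Gaussian fit A*exp(-(x-mu)^2/(2 sigma^2)) of a profile."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 5:
        raise ValueError("need at least 5 samples")
    mass = y.sum()
    if mass <= 0:
        raise ValueError("profile has no positive mass")
    mu0 = float((x * y).sum() / mass)
    var0 = float((y * (x - mu0) ** 2).sum() / mass)
    sigma0 = math.sqrt(max(var0, (x[1] - x[0]) ** 2 / 12.0))

    def gauss(xx, a, mu, sig):
        return a * np.exp(-0.5 * ((xx - mu) / sig) ** 2)

    try:
        popt, _ = optimize.curve_fit(
            gauss, x, y, p0=[float(y.max()), mu0, sigma0], maxfev=10_000
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    amp, mu, sigma = float(popt[0]), float(popt[1]), float(abs(popt[2]))
    resid = y - gauss(x, *popt)
    rms = float(np.sqrt(np.mean(resid**2)) / abs(amp)) if amp else math.inf
    left, right = _half_widths(x, y)
    asym = 0.0
    if not (math.isnan(left) or math.isnan(right)) and (left + right) > 0:
        asym = (right - left) / (right + left)
    return GaussianFit1D(
        mean=mu, sigma=sigma, amplitude=amp, rms_residual=rms, halfwidth_asymmetry=asym
    )


def sigma_ratio(slab: PlanarSlab, profiles: str = "marginal") -> float:
    """Ratio sigma_u / sigma_v of the slab's 1D Gaussian fits.

    u is the bending axis, v the field axis; the ratio exceeds one when the
    Lorentz deflection broadens the in-plane distribution along u.  With
    ``profiles='marginal'`` (default) the 1D profiles are the slab sums over
    the orthogonal axis -- identical to central-axis cuts for a Gaussian
    spot but far less sensitive to sampling noise; ``profiles='central'``
    uses the single row/column through the peak pixel.
    """
    if profiles == "marginal":
        prof_u = slab.values.sum(axis=1)
        prof_v = slab.values.sum(axis=0)
    elif profiles == "central":
        iu, iv = np.unravel_index(int(np.argmax(slab.values)), slab.values.shape)
        prof_u = slab.values[:, iv]
        prof_v = slab.values[iu, :]
    else:
        raise ValueError("profiles must be 'marginal' or 'central'")
    fit_u = fit_gaussian_1d(slab.u, prof_u)
    fit_v = fit_gaussian_1d(slab.v, prof_v)
    return fit_u.sigma / fit_v.sigma


def isodose_contour(slab: PlanarSlab, level: float) -> np.ndarray:
    """Closed sub-pixel isodose contour (marching squares) around the peak.

    Returns an (n, 2) polyline in (u, v) cm, first point repeated last.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1) as a fraction of the maximum")
    contours = skmeasure.find_contours(slab.values, level)
    closed = [c for c in contours if np.allclose(c[0], c[-1])]
    if not closed:
        raise ContourError(f"no closed contour at level {level} (peak near slab edge?)")
    iu, iv = np.unravel_index(int(np.argmax(slab.values)), slab.values.shape)
    du, dv = slab.pixel

    def encloses_peak(c):
        path = c - np.array([iu, iv])
        angles = np.arctan2(path[:, 1], path[:, 0])
        winding = np.abs(np.unwrap(angles)[-1] - np.unwrap(angles)[0])
        return winding > math.pi
    best = None
    for c in closed:
        if encloses_peak(c):
            best = c
            break
    if best is None:
        raise ContourError(f"no closed contour at level {level} encloses the peak")
    out = np.empty_like(best)
    out[:, 0] = slab.u[0] + best[:, 0] * du
    out[:, 1] = slab.v[0] + best[:, 1] * dv
    return out


def fit_ic_ec(contour: np.ndarray, level: float = math.nan) -> IsodoseFit:
    """Fit shared-center inscribed and circumscribed circles to a contour.

    The center minimizes the annulus area pi*(r_ec^2 - r_ic^2); found by a
    coarse grid over the bounding box followed by Nelder-Mead refinement.
    """
    pts = np.asarray(contour, float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("contour must be an (n, 2) polyline")
    span = pts.max(axis=0) - pts.min(axis=0)
    if min(span) < 1e-9:
        raise ContourError("degenerate (collinear) contour")

    def annulus(c):
        d2 = (pts[:, 0] - c[0]) ** 2 + (pts[:, 1] - c[1]) ** 2
        return d2.max() - d2.min()

    lo = pts.min(axis=0)
    best, best_val = None, math.inf
    for cu in np.linspace(lo[0], lo[0] + span[0], 15):
        for cv in np.linspace(lo[1], lo[1] + span[1], 15):
            val = annulus((cu, cv))
            if val < best_val:
                best, best_val = (cu, cv), val
    res = optimize.minimize(
        annulus, best, method="Nelder-Mead", options={"xatol": 1e-5, "fatol": 1e-12}
    )
    center = (float(res.x[0]), float(res.x[1]))
    d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    return IsodoseFit(
        level=level, contour=pts, center=center, r_ic=float(d.min()), r_ec=float(d.max())
    )


def skewness_by_level(
    slab_b: PlanarSlab,
    slab_0: PlanarSlab,
    levels: Sequence[float] = (0.8, 0.5, 0.2),
) -> pd.DataFrame:
    """IC/EC radius differences with and without field, per isodose level.

    The standard radius is the field-free fitted circle radius at the same
    level; rows are sorted by it (ascending radius = descending dose level).
    """
    rows = []
    for level in levels:
        fit_b = fit_ic_ec(isodose_contour(slab_b, level), level)
        fit_0 = fit_ic_ec(isodose_contour(slab_0, level), level)
        rows.append(
            {
                "level": level,
                "radius_diff_field": fit_b.radius_diff,
                "radius_diff_nofield": fit_0.radius_diff,
                "standard_radius": fit_0.mean_radius,
            }
        )
    return pd.DataFrame(rows).sort_values("standard_radius").reset_index(drop=True)


def _line_fwhm(values, grid, peak, direction, sample_step) -> float:
    """FWHM of the trilinearly-interpolated dose along a line through the peak."""
    half_len = float(np.linalg.norm(grid.extent))
    t = np.arange(-half_len, half_len + sample_step, sample_step)
    pts = np.array([peak.x, peak.y, peak.z])[:, None] + np.outer(direction, t)
    coords = [
        (pts[a] - (grid.origin[a] + 0.5 * grid.voxel[a])) / grid.voxel[a] for a in range(3)
    ]
    prof = ndimage.map_coordinates(values, coords, order=1, mode="constant", cval=0.0)
    left, right = _half_widths(t, prof)
    if math.isnan(left) or math.isnan(right):
        raise ContourError("profile does not fall to half maximum inside the grid")
    return left + right


def fwhm_scan(
    grid: DoseGrid,
    plane: str = "bending",
    angle_step: float = 1.0,
    sample_step: Optional[float] = None,
) -> FwhmScan:
    """Rotating-line FWHM scan through the Bragg peak.

    Lines rotate from the beam (+z) axis within the chosen plane
    ('bending' = x-z, containing the deflection; 'field' = y-z) over
    [0, 180) degrees.  The scan reports the extremal widths and their
    angles; FWHM(0 deg) is the 'vertical' (beam-axis) width.
    """
    if not 0.0 < angle_step <= 10.0:
        raise ValueError("angle_step must lie in (0, 10] degrees")
    if plane not in ("bending", "field"):
        raise ValueError("plane must be 'bending' or 'field'")
    peak = find_bragg_peak(grid)
    if sample_step is None:
        sample_step = 0.5 * min(grid.grid.voxel)
    values = grid.values.astype(np.float64)
    angles = np.arange(0.0, 180.0, angle_step)
    fwhm = np.empty_like(angles)
    lateral_axis = 0 if plane == "bending" else 1
    for i, ang in enumerate(angles):
        rad = math.radians(ang)
        direction = np.zeros(3)
        direction[2] = math.cos(rad)
        direction[lateral_axis] = math.sin(rad)
        fwhm[i] = _line_fwhm(values, grid.grid, peak, direction, sample_step)
    imax, imin = int(np.argmax(fwhm)), int(np.argmin(fwhm))
    return FwhmScan(
        angles=angles,
        fwhm=fwhm,
        fwhm_max=float(fwhm[imax]),
        angle_max=float(angles[imax]),
        fwhm_min=float(fwhm[imin]),
        angle_min=float(angles[imin]),
        fwhm_vertical=float(fwhm[0]),
    )
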