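"""Desk-scale transport simulator for proton pencil beams in a magnetic field.

The engine integrates the curved central trajectory of a proton slowing in
water inside a uniform field, and scores 3D dose grids for a Gaussian spot
in two modes:

* ``pencil`` -- deterministic: the central track carries a lateral Gaussian
  whose variance grows with accumulated multiple Coulomb scattering
  (Highland angle, Fermi-Eyges style second moment), and the longitudinal
  deposition is convolved with a Gaussian range-straggling kernel;
* ``mc`` -- sampled: each history draws an entry position from the 2D
  Gaussian spot and a Gaussian range perturbation, and is transported with
  per-step scattering kicks, depositing continuous-slowing-down energy into
  the containing voxel.

Geometry convention: beam along +z, field along +y, bending confined to the
x-z plane.  The CSDA energy along the track is exact -- the trajectory is
parametrised by residual range, so step size only controls geometric
resolution, not energy-loss accuracy.

Nuclear interactions and secondary particles are not modelled; the entrance
region therefore lacks the build-up a full Monte Carlo code produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from . import __version__ as _pkg_version
from .errors import UnsupportedGeometryError
from .physics import WATER, StoppingModel, curvature, energy_from_range, range_from_energy

__all__ = [
    "BeamSpec",
    "FieldSpec",
    "PhantomGrid",
    "DoseGrid",
    "TrackPolyline",
    "integrate_central_track",
    "simulate_dose_grid",
    "scattering_sigma_increment",
    "estimate_uncertainty",
    "straggling_sigma",
]

#: Radiation length of water [cm], used by the Highland formula.
RADIATION_LENGTH_WATER = 36.08


@dataclass(frozen=True)
class BeamSpec:
    """Incident pencil beam: energy [MeV], Gaussian spot sigma [cm], entry point.

    The beam direction is +z by convention; ``entry_point`` is (x, y) on the
    z = 0 phantom face.
    """

    energy: float
    spot_sigma: float = 0.5
    entry_point: tuple[float, float] = (0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "energy", float(self.energy))
        if not 0.0 < self.energy <= 300.0:
            raise ValueError(f"energy must lie in (0, 300] MeV, got {self.energy}")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")
        d = np.asarray(self.direction, float)
        if not math.isclose(float(np.linalg.norm(d)), 1.0, rel_tol=1e-9):
            raise ValueError("direction must be a unit vector")


@dataclass(frozen=True)
class FieldSpec:
    """Uniform magnetic field: magnitude [T], direction +y by convention."""

    magnitude: float
    direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    uniform: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.magnitude <= 3.0:
            raise ValueError(f"field magnitude must lie in [0, 3] T, got {self.magnitude}")
        d = np.asarray(self.direction, float)
        if not math.isclose(float(np.linalg.norm(d)), 1.0, rel_tol=1e-9):
            raise ValueError("direction must be a unit vector")


@dataclass(frozen=True)
class PhantomGrid:
    """Voxelized water phantom: extent, voxel size and origin per axis [cm].

    Default: 20 x 20 x 35 cm (x, y, z) with 0.5 mm lateral and 1 mm depth
    voxels, centred laterally on the beam axis.
    """

    extent: tuple[float, float, float] = (20.0, 20.0, 35.0)
    voxel: tuple[float, float, float] = (0.05, 0.05, 0.1)
    origin: tuple[float, float, float] = (-10.0, -10.0, 0.0)

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extent) or any(v <= 0 for v in self.voxel):
            raise ValueError("extents and voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(e / v)) for e, v in zip(self.extent, self.voxel))

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel[axis]

    def contains_entry(self, beam: BeamSpec) -> bool:
        x, y = beam.entry_point
        return (
            self.origin[0] <= x <= self.origin[0] + self.extent[0]
            and self.origin[1] <= y <= self.origin[1] + self.extent[1]
        )


@dataclass
class TrackPolyline:
    """Central trajectory samples in the bending plane.

    Arrays are ordered along the arc: ``s`` arc length, ``x`` signed lateral
    position, ``z`` depth, ``energy`` residual kinetic energy (strictly
    decreasing).  ``bend_sign`` records the Lorentz deflection sense
    (-1: toward -x for +z beam in +y field); analyses use magnitudes.
    """

    s: np.ndarray
    x: np.ndarray
    z: np.ndarray
    energy: np.ndarray
    step: float
    bend_sign: int
    relativistic: bool

    @property
    def lateral_offset(self) -> float:
        """|x| at the track endpoint (the Bragg-peak lateral shift WD) [cm]."""
        return float(abs(self.x[-1]))

    @property
    def depth(self) -> float:
        """Depth z reached at the track endpoint [cm]."""
        return float(self.z[-1])


def integrate_central_track(
    beam: BeamSpec,
    field: FieldSpec,
    step: float = 0.01,
    model: StoppingModel = WATER,
    relativistic: bool = True,
) -> TrackPolyline:
    """Integrate the deflected CSDA central track.

    Per step the direction is rotated by kappa(E) * ds (exact circular arc),
    with the energy taken exactly from the residual range.  Terminates at
    the cutoff energy, where the residual is deposited locally.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if abs(float(np.dot(beam.direction, field.direction))) > 1e-9:
        raise UnsupportedGeometryError("beam must be perpendicular to the field")
    if tuple(beam.direction) != (0.0, 0.0, 1.0) or (
        field.magnitude > 0 and tuple(field.direction) != (0.0, 1.0, 0.0)
    ):
        raise UnsupportedGeometryError("supported geometry: beam +z, field +y")

    total_range = range_from_energy(beam.energy, model)
    cutoff_residual = model.alpha * model.cutoff_energy**model.p
    arc_total = total_range - cutoff_residual
    n_full = int(arc_total // step)
    ds_last = arc_total - n_full * step
    steps = [step] * n_full + ([ds_last] if ds_last > 1e-12 else [])

    s_list = [0.0]
    x_list = [0.0]
    z_list = [0.0]
    e_list = [beam.energy]
    theta = 0.0  # angle from +z toward the (unsigned) bending axis
    u, z, s = 0.0, 0.0, 0.0
    for ds in steps:
        e_mid = energy_from_range(total_range - (s + 0.5 * ds), model)
        kappa = curvature(e_mid, field.magnitude, relativistic=relativistic, model=model)
        if kappa > 0:
            u += (math.cos(theta) - math.cos(theta + kappa * ds)) / kappa
            z += (math.sin(theta + kappa * ds) - math.sin(theta)) / kappa
            theta += kappa * ds
        else:
            u += ds * math.sin(theta)
            z += ds * math.cos(theta)
        s += ds
        s_list.append(s)
        x_list.append(u)
        z_list.append(z)
        e_list.append(energy_from_range(max(total_range - s, cutoff_residual), model))

    bend_sign = -1  # q v x B for +z beam in +y field points toward -x
    return TrackPolyline(
        s=np.asarray(s_list),
        x=bend_sign * np.asarray(x_list),
        z=np.asarray(z_list),
        energy=np.asarray(e_list),
        step=step,
        bend_sign=bend_sign,
        relativistic=relativistic,
    )


def scattering_sigma_increment(
    energy: float, step: float, model: StoppingModel = WATER
) -> float:
    """Highland RMS multiple-scattering angle [rad] for one step in water.

    theta0 = (14.1 MeV / pv) * sqrt(t) * (1 + log10(t)/9), t = step/X0 in
    radiation lengths; the logarithmic factor is clamped at zero so the
    angle vanishes smoothly as the step does.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if energy <= model.cutoff_energy:
        raise ValueError("energy must exceed the transport cutoff")
    mc2 = model.rest_energy
    pc2 = energy**2 + 2.0 * mc2 * energy
    pv = pc2 / (energy + mc2)  # pc * beta, MeV
    t = step / RADIATION_LENGTH_WATER
    log_factor = max(0.0, 1.0 + math.log10(t) / 9.0)
    return 14.1 / pv * math.sqrt(t) * log_factor * model.charge_number


def straggling_sigma(range_cm: float) -> float:
    """Gaussian range-straggling sigma [cm], 0.012 * R^0.935 for water."""
    return 0.012 * range_cm**0.935


@dataclass
class DoseGrid:
    """Voxelized deposited energy [MeV] with full provenance.

    ``values`` is indexed (x, y, z).  ``provenance`` is a flat, JSON-ready
    dict complete enough to regenerate the grid bit-identically from the
    recorded seed.  ``uncertainty`` holds per-voxel relative standard errors
    when the simulation ran in batches.
    """

    values: np.ndarray
    grid: PhantomGrid
    provenance: dict = dc_field(default_factory=dict)
    uncertainty: Optional[np.ndarray] = None

    def total_energy(self) -> float:
        return float(self.values.sum(dtype=np.float64))


def _make_provenance(beam, field, grid, model, mode, histories, seed, step, truncated):
    return {
        "package_version": _pkg_version,
        "mode": mode,
        "energy_mev": beam.energy,
        "spot_sigma_cm": beam.spot_sigma,
        "entry_point_cm": list(beam.entry_point),
        "field_t": field.magnitude,
        "field_direction": list(field.direction),
        "grid_extent_cm": list(grid.extent),
        "grid_voxel_cm": list(grid.voxel),
        "grid_origin_cm": list(grid.origin),
        "histories": histories,
        "seed": seed,
        "step_cm": step,
        "alpha": model.alpha,
        "p": model.p,
        "rest_energy_mev": model.rest_energy,
        "cutoff_mev": model.cutoff_energy,
        "truncated_energy_mev": truncated,
    }


def _pencil_dose(beam, field, grid, step, model, relativistic=True):
    track = integrate_central_track(beam, field, step=step, model=model, relativistic=relativistic)
    total_range = range_from_energy(beam.energy, model)
    sig_r = straggling_sigma(total_range)
    # per-step deposited energy from the range law (sums exactly to E0)
    e_edges = track.energy
    w = e_edges[:-1] - e_edges[1:]
    w = np.append(w, 0.0)
    w[-1] += e_edges[-1]  # below-cutoff residual deposited at the endpoint

    s = track.s
    x_track = track.x
    z_track = track.z
    # direction cosine along z per sample (projects the straggling kernel)
    dzds = np.gradient(z_track, s)
    cos_th = np.clip(dzds, 0.1, 1.0)

    # accumulated scattering variance (second moment of the Highland kicks)
    ds = np.diff(s, append=s[-1])
    e_mid = np.sqrt(np.maximum(e_edges * np.roll(e_edges, -1), model.cutoff_energy**2))
    theta2 = np.array(
        [
            scattering_sigma_increment(max(e, model.cutoff_energy * 1.01), max(d, 1e-9), model) ** 2
            if d > 1e-9
            else 0.0
            for e, d in zip(e_mid, ds)
        ]
    )
    # var_x(s_n) = sum_j theta2_j * (s_n - s_j)^2, via expanded cumulative sums
    c0 = np.cumsum(theta2)
    c1 = np.cumsum(theta2 * s)
    c2 = np.cumsum(theta2 * s**2)
    var_scatter = s**2 * c0 - 2.0 * s * c1 + c2

    values = np.zeros(grid.shape, dtype=np.float32)
    ox, oy, oz = grid.origin
    dx, dy, dz = grid.voxel
    nx, ny, nz = grid.shape
    xc = grid.axis_centers(0)
    yc = grid.axis_centers(1)
    z_edges = oz + np.arange(nz + 1) * dz
    ex, ey = beam.entry_point
    truncated = 0.0
    sqrt2 = math.sqrt(2.0)
    for j in range(len(s)):
        if w[j] <= 0:
            continue
        sigma = math.sqrt(beam.spot_sigma**2 + var_scatter[j])
        cx = ex + x_track[j]
        cy = ey
        # longitudinal range straggling: spread this sample's deposit over
        # z-slabs with an analytic Gaussian kernel (per-slab erf integral),
        # sigma projected onto z by the local track direction
        sig_z = max(sig_r * cos_th[j], 1e-6)
        zj = z_track[j]
        kz0 = max(int((zj - 4.0 * sig_z - oz) / dz), 0)
        kz1 = min(int((zj + 4.0 * sig_z - oz) / dz) + 2, nz)
        if kz0 >= kz1:
            truncated += float(w[j])
            continue
        erfs = np.array(
            [math.erf((ze - zj) / (sqrt2 * sig_z)) for ze in z_edges[kz0 : kz1 + 1]]
        )
        wz = 0.5 * (erfs[1:] - erfs[:-1])
        lost_z = 1.0 - wz.sum()

        half = 4.0 * sigma
        ix0 = max(int((cx - half - ox) / dx), 0)
        ix1 = min(int((cx + half - ox) / dx) + 1, nx)
        iy0 = max(int((cy - half - oy) / dy), 0)
        iy1 = min(int((cy + half - oy) / dy) + 1, ny)
        if ix0 >= ix1 or iy0 >= iy1:
            truncated += float(w[j])
            continue
        gx = np.exp(-0.5 * ((xc[ix0:ix1] - cx) / sigma) ** 2)
        gy = np.exp(-0.5 * ((yc[iy0:iy1] - cy) / sigma) ** 2)
        norm = gx.sum() * gy.sum()
        if norm <= 0:
            continue
        patch = (w[j] / norm) * np.outer(gx, gy)
        values[ix0:ix1, iy0:iy1, kz0:kz1] += (
            patch[:, :, None] * wz[None, None, :]
        ).astype(np.float32)
        truncated += float(w[j] * max(lost_z, 0.0))
    return values, truncated


def _mc_batch(beam, field, grid, n_hist, rng, step, model, relativistic=True):
    """Transport one batch of histories; returns (dose array, truncated energy)."""
    total_range = range_from_energy(beam.energy, model)
    sig_r = straggling_sigma(total_range)
    cutoff_residual = model.alpha * model.cutoff_energy**model.p

    ranges = total_range + rng.normal(0.0, sig_r, n_hist)
    ranges = np.maximum(ranges, 10.0 * cutoff_residual)
    # scale each history's energy profile so it starts exactly at E0
    e_start = energy_from_range(ranges, model)
    scale = beam.energy / e_start

    pos = np.empty((n_hist, 3))
    pos[:, 0] = beam.entry_point[0] + rng.normal(0.0, beam.spot_sigma, n_hist)
    pos[:, 1] = beam.entry_point[1] + rng.normal(0.0, beam.spot_sigma, n_hist)
    pos[:, 2] = 0.0
    vel = np.zeros((n_hist, 3))
    vel[:, 2] = 1.0

    s = np.zeros(n_hist)
    energy = np.full(n_hist, float(beam.energy), dtype=np.float64)
    alive = np.ones(n_hist, dtype=bool)

    values = np.zeros(grid.shape, dtype=np.float32)
    flat = values.ravel()
    ox, oy, oz = grid.origin
    dx, dy, dz = grid.voxel
    nx, ny, nz = grid.shape
    truncated = 0.0
    b_axis = np.asarray(field.direction, float)

    while np.any(alive):
        idx = np.nonzero(alive)[0]
        remaining = ranges[idx] - s[idx] - cutoff_residual
        ds = np.minimum(step, remaining)
        last = remaining <= step

        e_here = energy[idx]
        res_next = np.maximum(ranges[idx] - (s[idx] + ds), cutoff_residual)
        e_next = energy_from_range(res_next, model) * scale[idx]
        e_next[last] = 0.0  # below-cutoff residual deposited locally
        de = e_here - e_next

        mid = pos[idx] + vel[idx] * (0.5 * ds)[:, None]
        ix = np.floor((mid[:, 0] - ox) / dx).astype(np.intp)
        iy = np.floor((mid[:, 1] - oy) / dy).astype(np.intp)
        iz = np.floor((mid[:, 2] - oz) / dz).astype(np.intp)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
        np.add.at(flat, (ix[inside] * ny + iy[inside]) * nz + iz[inside], de[inside].astype(np.float32))
        truncated += float(de[~inside].sum())

        pos[idx] += vel[idx] * ds[:, None]
        energy[idx] = e_next
        s[idx] += ds

        cont = idx[~last]
        alive[idx[last]] = False
        if cont.size:
            e_mid = np.sqrt(e_here[~last] * np.maximum(e_next[~last], model.cutoff_energy))
            dsc = ds[~last]
            # magnetic bending: rotate about the field axis (Rodrigues)
            if field.magnitude > 0:
                kappa = curvature(e_mid, field.magnitude, relativistic=relativistic, model=model)
                phi = -kappa * dsc  # bending sense: toward -x for +z beam, +y field
                v = vel[cont]
                cosp = np.cos(phi)[:, None]
                sinp = np.sin(phi)[:, None]
                bxv = np.cross(np.broadcast_to(b_axis, v.shape), v)
                bdotv = (v @ b_axis)[:, None]
                vel[cont] = v * cosp + bxv * sinp + b_axis * bdotv * (1.0 - cosp)
            # multiple-scattering kicks in the two transverse directions
            pv = (e_mid**2 + 2.0 * model.rest_energy * e_mid) / (e_mid + model.rest_energy)
            t = dsc / RADIATION_LENGTH_WATER
            theta0 = 14.1 / pv * np.sqrt(t) * np.maximum(0.0, 1.0 + np.log10(t) / 9.0)
            v = vel[cont]
            ref = np.where(np.abs(v[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
            e1 = np.cross(v, ref)
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
            e2 = np.cross(v, e1)
            a1 = rng.normal(0.0, theta0)[:, None]
            a2 = rng.normal(0.0, theta0)[:, None]
            v = v + e1 * a1 + e2 * a2
            vel[cont] = v / np.linalg.norm(v, axis=1, keepdims=True)
    return values, truncated


def simulate_dose_grid(
    beam: BeamSpec,
    field: FieldSpec,
    grid: PhantomGrid = PhantomGrid(),
    mode: str = "pencil",
    histories: int = 200_000,
    seed: Optional[int] = None,
    model: StoppingModel = WATER,
    step: Optional[float] = None,
    n_batches: int = 1,
    relativistic: bool = True,
) -> DoseGrid:
    """Score a 3D dose grid for one spot.

    ``mode='pencil'`` is deterministic; ``mode='mc'`` samples ``histories``
    protons and requires ``seed``.  With ``n_batches >= 2`` the mc dose is
    accumulated batch-wise and a per-voxel relative-error grid is attached.
    Energy deposited outside the grid is recorded in the provenance as
    ``truncated_energy_mev``.
    """
    if not grid.contains_entry(beam):
        raise ValueError("beam entry point lies outside the phantom entry face")
    if mode == "pencil":
        step = 0.05 if step is None else step
        values, truncated = _pencil_dose(beam, field, grid, step, model, relativistic)
        prov = _make_provenance(beam, field, grid, model, mode, None, None, step, truncated)
        prov["relativistic"] = relativistic
        return DoseGrid(values=values, grid=grid, provenance=prov)
    if mode != "mc":
        raise ValueError(f"unknown mode {mode!r}")
    if histories < 1:
        raise ValueError("mc mode needs at least one history")
    if seed is None:
        raise ValueError("mc mode requires an explicit seed")
    step = 0.1 if step is None else step

    rng = np.random.default_rng(seed)
    batch_sizes = [histories // n_batches] * n_batches
    batch_sizes[-1] += histories - sum(batch_sizes)
    batches = []
    truncated = 0.0
    for nb in batch_sizes:
        v, tr = _mc_batch(beam, field, grid, nb, rng, step, model, relativistic)
        truncated += tr
        batches.append(v)
    values = np.sum(batches, axis=0, dtype=np.float32) if n_batches > 1 else batches[0]
    uncertainty = estimate_uncertainty(batches)[0] if n_batches >= 2 else None
    prov = _make_provenance(beam, field, grid, model, mode, histories, seed, step, truncated)
    prov["n_batches"] = n_batches
    prov["relativistic"] = relativistic
    return DoseGrid(values=values, grid=grid, provenance=prov, uncertainty=uncertainty)


def estimate_uncertainty(batches) -> tuple[np.ndarray, dict]:
    """Per-voxel relative standard error of the mean from mc batches.

    Returns the relative-error grid (zero where no dose was scored) and a
    summary with the mean relative error in the peak region (voxels above
    half the global maximum) and in the low-dose region (below 10%).
    """
    batches = np.asarray(batches, dtype=np.float64)
    if batches.ndim < 2 or batches.shape[0] < 2:
        raise ValueError("uncertainty estimation needs at least two batches")
    n = batches.shape[0]
    mean = batches.mean(axis=0)
    sem = batches.std(axis=0, ddof=1) / math.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, sem / mean, 0.0)
    total = mean
    peak = total.max()
    peak_mask = total >= 0.5 * peak
    low_mask = (total > 0) & (total < 0.1 * peak)
    summary = {
        "peak_region_mean_rel_error": float(rel[peak_mask].mean()) if peak_mask.any() else 0.0,
        "low_dose_mean_rel_error": float(rel[low_mask].mean()) if low_mask.any() else 0.0,
        "n_batches": int(n),
    }
    return rel.astype(np.float32), summary
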