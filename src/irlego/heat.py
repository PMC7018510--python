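"""Heat diffusion around a focused IR laser in a homogeneous medium.

The focused 1,342 nm beam acts as a localized volumetric heat source.  The
temperature rise obeys conductive heat transfer,

    ρc ∂T/∂t = κ ∇²T + q(x),

solved two ways: closed-form Green's-function solutions for an ideal point
source (steady state Q/(4πκr) and transient with the erfc factor), and a
finite-difference solver on a uniform Cartesian grid with Dirichlet ambient
boundaries for extended sources (Gaussian deposition ball, or the
time-averaged source of a scanned beam).  The two routes cross-check each
other away from the source.

Convection in free water, which flattens thermal gradients relative to a
gel or tissue, is approximated by an optional effective-conductivity
multiplier on the medium — a deliberate simplification, not fluid dynamics.

Units: distances in µm at the API surface, powers in W, temperatures in °C
(rises in K); conversions to SI happen internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import fft as sp_fft
from scipy.special import erfc

__all__ = [
    "Medium",
    "BeamSource",
    "GridSpec",
    "TemperatureField",
    "water",
    "agarose3pct",
    "tissue",
    "steady_state_point_source",
    "transient_point_source",
    "analytic_point_field",
    "simulate_field",
    "radial_profile",
    "confinement_radius",
    "total_stored_energy",
]

UM = 1e-6  # m per µm


@dataclass(frozen=True)
class Medium:
    """Thermal properties of the heated medium.

    ``absorbed_power_fraction`` is the fraction of incident laser power
    deposited as heat at the focus.  It depends on the absorption
    coefficient at the laser wavelength and the focal geometry and is NOT
    tightly constrained here — the default 0.1 is a free parameter that
    scales every temperature rise linearly; calibrate it against a measured
    focal temperature before quantitative use.

    ``convection_multiplier`` scales the conductivity (and hence the
    diffusivity) to mimic convective stirring in free liquid; leave at 1 for
    gels and tissue.
    """

    thermal_conductivity: float  # W·m⁻¹·K⁻¹
    density: float               # kg·m⁻³
    specific_heat: float         # J·kg⁻¹·K⁻¹
    absorbed_power_fraction: float = 0.1
    label: str = "custom"
    convection_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if min(self.thermal_conductivity, self.density, self.specific_heat) <= 0:
            raise ValueError("thermal_conductivity, density and specific_heat must be > 0")
        if not 0.0 <= self.absorbed_power_fraction <= 1.0:
            raise ValueError("absorbed_power_fraction must lie in [0, 1]")
        if self.convection_multiplier < 1.0:
            raise ValueError("convection_multiplier must be >= 1")

    @property
    def effective_conductivity(self) -> float:
        return self.thermal_conductivity * self.convection_multiplier

    @property
    def diffusivity(self) -> float:
        """α = κ_eff/(ρc) in m²/s; derived, never stored independently."""
        return self.effective_conductivity / (self.density * self.specific_heat)


def water(convection_multiplier: float = 1.0, absorbed_power_fraction: float = 0.1) -> Medium:
    return Medium(0.60, 998.0, 4182.0, absorbed_power_fraction, "water", convection_multiplier)


def agarose3pct(absorbed_power_fraction: float = 0.1) -> Medium:
    """3 % agarose gel: a tissue phantom, conductivity close to soft tissue."""
    return Medium(0.50, 1030.0, 4000.0, absorbed_power_fraction, "agarose3pct")


def tissue(absorbed_power_fraction: float = 0.1) -> Medium:
    return Medium(0.49, 1050.0, 3600.0, absorbed_power_fraction, "tissue")


@dataclass(frozen=True)
class BeamSource:
    """The IR heating beam as a volumetric heat source.

    ``deposition_radius`` is the Gaussian standard deviation of the heat
    deposition ball in µm; the default matches a diffraction-limited focal
    spot of ~0.4 µm² area.  In scan mode the beam raster-scans a
    ``scan_extent`` region and the solver deposits the time-averaged source
    density uniformly over that lateral extent.
    """

    incident_power: float  # W
    mode: Literal["point", "scan"] = "point"
    scan_extent: tuple[float, float] = (8.0, 8.0)  # µm × µm
    duration: float = 32.0  # s
    focal_position: tuple[float, float, float] = (0.0, 0.0, 0.0)  # µm
    deposition_radius: float = 0.36  # µm (Gaussian sd)

    def __post_init__(self) -> None:
        if self.incident_power <= 0:
            raise ValueError("incident_power must be > 0")
        if self.mode not in ("point", "scan"):
            raise ValueError("mode must be 'point' or 'scan'")
        if self.mode == "scan" and min(self.scan_extent) <= 0:
            raise ValueError("scan mode requires a positive scan extent")
        if self.deposition_radius <= 0:
            raise ValueError("deposition_radius must be > 0")

    def absorbed_power(self, medium: Medium) -> float:
        return self.incident_power * medium.absorbed_power_fraction


@dataclass(frozen=True)
class GridSpec:
    """Uniform Cartesian grid on [−L, L]³ µm with Dirichlet boundary at ±L."""

    spacing: float = 1.0       # µm
    half_extent: float = 100.0  # µm

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.half_extent <= self.spacing:
            raise ValueError("need spacing > 0 and half_extent > spacing")

    @property
    def interior_coords(self) -> np.ndarray:
        """Interior node coordinates in µm (boundary nodes at ±L excluded)."""
        n = int(round(self.half_extent / self.spacing))
        return self.spacing * np.arange(-n + 1, n)


@dataclass(frozen=True)
class TemperatureField:
    """Gridded 3D temperature (°C) around the laser focus at one time point."""

    x: np.ndarray  # µm
    y: np.ndarray
    z: np.ndarray
    temperature: np.ndarray  # °C, shape (len(x), len(y), len(z))
    time: float  # s
    ambient: float = 23.0
    focal_position: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = (len(self.x), len(self.y), len(self.z))
        if self.temperature.shape != shape:
            raise ValueError(f"temperature shape {self.temperature.shape} != grid {shape}")
        if self.temperature.min() < self.ambient - 1e-9:
            raise ValueError("temperature below ambient with a nonnegative source")

    @property
    def rise(self) -> np.ndarray:
        return self.temperature - self.ambient

    def radii(self) -> np.ndarray:
        fx, fy, fz = self.focal_position
        return np.sqrt(
            (self.x[:, None, None] - fx) ** 2
            + (self.y[None, :, None] - fy) ** 2
            + (self.z[None, None, :] - fz) ** 2
        )


def steady_state_point_source(absorbed_power: float, medium: Medium, r):
    """Steady-state rise ΔT = Q/(4πκr) of an ideal point source, r in µm."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("r must be > 0 (the point-source solution is singular at r = 0)")
    dT = absorbed_power / (4.0 * np.pi * medium.effective_conductivity * r_arr * UM)
    return dT if dT.shape else float(dT)


def transient_point_source(absorbed_power: float, medium: Medium, r, t: float):
    """Transient rise ΔT(r, t) = Q/(4πκr)·erfc(r/(2√(αt))); zero at t = 0.

    The focal temperature reaches ~99 % of steady state within a second or
    two for water-like diffusivity — the source turns on effectively
    instantaneously on experimental time scales.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("r must be > 0")
    if t == 0:
        out = np.zeros_like(r_arr)
        return out if out.shape else 0.0
    steady = steady_state_point_source(absorbed_power, medium, r_arr)
    arg = (r_arr * UM) / (2.0 * np.sqrt(medium.diffusivity * t))
    dT = steady * erfc(arg)
    return dT if np.asarray(dT).shape else float(dT)


def analytic_point_field(
    medium: Medium,
    source: BeamSource,
    grid: GridSpec,
    t: float | None = None,
    ambient: float = 23.0,
) -> TemperatureField:
    """Evaluate the point-source solution on a grid (steady if ``t`` is None).

    The singular focal voxel is assigned the value at r = spacing/2.
    """
    coords = grid.interior_coords
    fx, fy, fz = source.focal_position
    r = np.sqrt(
        (coords[:, None, None] - fx) ** 2
        + (coords[None, :, None] - fy) ** 2
        + (coords[None, None, :] - fz) ** 2
    )
    r = np.maximum(r, grid.spacing / 2.0)
    q = source.absorbed_power(medium)
    if t is None:
        dT = steady_state_point_source(q, medium, r)
        t_out = np.inf
    else:
        dT = transient_point_source(q, medium, r, t)
        t_out = t
    return TemperatureField(coords, coords, coords, ambient + dT, t_out, ambient,
                            source.focal_position)


def _source_density(medium: Medium, source: BeamSource, grid: GridSpec) -> np.ndarray:
    """Volumetric heat source q (W/m³) on the interior grid, exactly normalized."""
    coords = grid.interior_coords
    dx = grid.spacing
    fx, fy, fz = source.focal_position
    a = source.deposition_radius
    if a < dx:
        raise ValueError(
            f"grid spacing {dx} µm does not resolve deposition_radius {a} µm; "
            "use spacing <= deposition_radius or a larger source"
        )
    gz = np.exp(-0.5 * ((coords - fz) / a) ** 2)
    if source.mode == "point":
        gx = np.exp(-0.5 * ((coords - fx) / a) ** 2)
        gy = np.exp(-0.5 * ((coords - fy) / a) ** 2)
    else:
        ex, ey = source.scan_extent
        if min(ex, ey) < 2 * dx:
            raise ValueError("grid spacing too coarse for the scan extent (need >= 2 cells)")
        gx = (np.abs(coords - fx) <= ex / 2.0).astype(float)
        gy = (np.abs(coords - fy) <= ey / 2.0).astype(float)
    shape = gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    total = shape.sum() * (dx * UM) ** 3
    if total <= 0:
        raise ValueError("source does not overlap the grid")
    return shape * (source.absorbed_power(medium) / total)


def _dst_eigenvalues(n: int, dx_m: float) -> np.ndarray:
    """Eigenvalues of the 1-D 3-point Laplacian with Dirichlet boundaries."""
    k = np.arange(1, n + 1)
    return (2.0 - 2.0 * np.cos(k * np.pi / (n + 1))) / dx_m**2


def simulate_field(
    medium: Medium,
    source: BeamSource,
    grid: GridSpec = GridSpec(),
    duration: float | None = None,
    *,
    scheme: Literal["explicit", "implicit"] = "implicit",
    dt: float | None = None,
    n_steps: int = 1000,
    output_times: Sequence[float] | None = None,
    ambient: float = 23.0,
) -> list[TemperatureField]:
    """Finite-difference solution of the heated medium, from a cold start.

    ``explicit`` is forward-time centered-space stepping with a CFL
    stability check (a violating ``dt`` is rejected with the corrected value
    suggested).  ``implicit`` is backward Euler, solved exactly per step by
    diagonalizing the 7-point Laplacian in a discrete sine basis (Dirichlet
    boundaries), so arbitrarily large steps are stable; with a constant
    source the whole trajectory collapses to a closed-form geometric series,
    making long simulated times cheap.

    Returns one :class:`TemperatureField` per requested output time (default:
    only the final time).  Output times are snapped to step multiples.
    """
    if duration is None:
        duration = source.duration
    if duration <= 0:
        raise ValueError("duration must be > 0")
    coords = grid.interior_coords
    n = coords.size
    dx_m = grid.spacing * UM
    alpha = medium.diffusivity
    rho_c = medium.density * medium.specific_heat
    q = _source_density(medium, source, grid)
    s = q / rho_c  # K/s heating rate density

    if output_times is None:
        output_times = [duration]
    output_times = sorted(float(t) for t in output_times)
    if output_times[-1] > duration + 1e-12:
        raise ValueError("output time beyond the simulated duration")

    fields: list[TemperatureField] = []

    if scheme == "explicit":
        if dt is None:
            dt = 0.9 * dx_m**2 / (6.0 * alpha)
        dt_max = dx_m**2 / (6.0 * alpha)
        if dt > dt_max:
            raise ValueError(
                f"explicit step dt={dt:g} s violates the stability bound "
                f"dx²/(6α) = {dt_max:g} s; use dt <= {dt_max:g} or the implicit scheme"
            )
        total_steps = int(np.ceil(duration / dt))
        snap_steps = {max(1, int(round(t / dt))): t for t in output_times}
        u = np.zeros((n, n, n))
        lap = np.empty_like(u)
        c = alpha * dt / dx_m**2
        for step in range(1, total_steps + 1):
            lap.fill(0.0)
            lap[:-1] += u[1:]
            lap[1:] += u[:-1]
            lap[:, :-1] += u[:, 1:]
            lap[:, 1:] += u[:, :-1]
            lap[:, :, :-1] += u[:, :, 1:]
            lap[:, :, 1:] += u[:, :, :-1]
            lap -= 6.0 * u
            u += c * lap + dt * s
            if step in snap_steps:
                fields.append(
                    TemperatureField(coords, coords, coords, ambient + u.copy(),
                                     step * dt, ambient, source.focal_position)
                )
        return fields

    if scheme != "implicit":
        raise ValueError("scheme must be 'explicit' or 'implicit'")

    if dt is None:
        dt = duration / n_steps
    lam1 = _dst_eigenvalues(n, dx_m)
    lam = lam1[:, None, None] + lam1[None, :, None] + lam1[None, None, :]
    s_hat = sp_fft.dstn(s, type=1, norm="ortho")
    a_fac = 1.0 / (1.0 + dt * alpha * lam)
    for t_out in output_times:
        n_t = max(1, int(round(t_out / dt)))
        # backward-Euler from u=0 with constant source: u_n = s(1 − Aⁿ)/(αλ)
        u_hat = s_hat * (1.0 - a_fac**n_t) / (alpha * lam)
        u = sp_fft.idstn(u_hat, type=1, norm="ortho")
        u = np.maximum(u, 0.0)  # clip O(ε) spectral ringing below the cold start
        fields.append(
            TemperatureField(coords, coords, coords, ambient + u,
                             n_t * dt, ambient, source.focal_position)
        )
    return fields


def radial_profile(
    field: TemperatureField, bin_width: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Angularly averaged temperature versus distance from the focus.

    Returns (bin-center radii µm, mean temperature °C per shell).
    """
    if bin_width is None:
        bin_width = float(field.x[1] - field.x[0])
    r = field.radii().ravel()
    t = field.temperature.ravel()
    idx = np.floor(r / bin_width).astype(int)
    sums = np.bincount(idx, weights=t)
    counts = np.bincount(idx)
    means = sums / counts
    centers = (np.arange(means.size) + 0.5) * bin_width
    return centers, means


def confinement_radius(field: TemperatureField, threshold: float) -> float:
    """Largest distance from the focus where the shell-mean temperature ≥ threshold.

    Linear interpolation between adjacent shells refines the crossing; 0 if
    even the innermost shell is below threshold.
    """
    if threshold <= field.ambient:
        raise ValueError("threshold must exceed the ambient temperature")
    centers, means = radial_profile(field)
    above = means >= threshold
    if not above.any():
        return 0.0
    last = int(np.max(np.nonzero(above)))
    if last == means.size - 1:
        return float(centers[last])
    r0, r1 = centers[last], centers[last + 1]
    t0, t1 = means[last], means[last + 1]
    if t1 == t0:
        return float(r0)
    return float(r0 + (threshold - t0) * (r1 - r0) / (t1 - t0))


def total_stored_energy(field: TemperatureField, medium: Medium) -> float:
    """Volume-integrated ρcΔT over the grid, in joules."""
    dx = float(field.x[1] - field.x[0]) * UM
    return float(medium.density * medium.specific_heat * field.rise.sum() * dx**3)
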