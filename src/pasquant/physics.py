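"""Aerosol microphysics and mesh-attenuation models.

Everything here is pure computation on SI quantities (meters, seconds,
pascals) except the projected-diameter helpers, which speak micrometers
because that is the unit of the imaging pipeline.  The three gamma model
variants (``mesh``, ``hybrid``, ``area``) encode how the protective mesh
cap of a flat passive sampler attenuates the deposition velocity of a
particle of given aerodynamic diameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ConvergenceError

# Physical constants (SI)
BOLTZMANN = 1.380649e-23  # J/K
GRAVITY = 9.80665  # m/s^2
UNIT_DENSITY = 1000.0  # kg/m^3, reference density defining aerodynamic diameter
SUTHERLAND_T = 110.4  # K, Sutherland constant for air
REF_TEMPERATURE = 293.15  # K
REF_PRESSURE = 101325.0  # Pa
REF_MEAN_FREE_PATH = 66.5e-9  # m at reference T, P
MOLAR_MASS_AIR = 0.0289647  # kg/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)

STOKES_LIMIT = 100e-6  # m; above this the Stokes settling law degrades

GAMMA_PREFACTOR = 5.95e-3
GAMMA_EXPONENT = -0.439
DEFAULT_OPEN_AREA_RATIO = 0.27


@dataclass(frozen=True)
class AirEnvironment:
    """Thermodynamic state of the air plus derived transport properties.

    ``dynamic_viscosity`` and ``mean_free_path`` may be pinned explicitly
    to reproduce any reference convention; otherwise they follow
    Sutherland's law and the standard T,P scaling of the mean free path.
    """

    temperature: float = REF_TEMPERATURE  # K
    pressure: float = REF_PRESSURE  # Pa
    viscosity_override: float | None = None  # Pa s
    mean_free_path_override: float | None = None  # m
    unit_density: float = UNIT_DENSITY  # kg/m^3

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.pressure <= 0:
            raise ValueError("temperature and pressure must be positive")
        if self.unit_density <= 0:
            raise ValueError("unit_density must be positive")

    @property
    def dynamic_viscosity(self) -> float:
        """Dynamic viscosity of air in Pa s (Sutherland's law)."""
        if self.viscosity_override is not None:
            return self.viscosity_override
        t = self.temperature
        return 1.458e-6 * t**1.5 / (t + SUTHERLAND_T)

    @property
    def air_mass_density(self) -> float:
        """Mass density of air in kg/m^3 (ideal gas)."""
        return self.pressure * MOLAR_MASS_AIR / (GAS_CONSTANT * self.temperature)

    @property
    def kinematic_viscosity(self) -> float:
        """Kinematic viscosity nu = mu / rho_air in m^2/s."""
        return self.dynamic_viscosity / self.air_mass_density

    @property
    def mean_free_path(self) -> float:
        """Gas mean free path in meters, scaled from the reference state."""
        if self.mean_free_path_override is not None:
            return self.mean_free_path_override
        t, p = self.temperature, self.pressure
        return (
            REF_MEAN_FREE_PATH
            * (REF_PRESSURE / p)
            * (t / REF_TEMPERATURE)
            * (1.0 + SUTHERLAND_T / REF_TEMPERATURE)
            / (1.0 + SUTHERLAND_T / t)
        )


@dataclass(frozen=True)
class MaterialProperties:
    """Bulk particle properties used in size and mass conversions."""

    density_g_cm3: float = 2.8
    volume_shape_factor: float = 1.6  # S_V; 1 recovers a sphere
    dynamic_shape_factor: float = 1.4  # chi; 1 recovers a sphere

    def __post_init__(self) -> None:
        if self.density_g_cm3 <= 0:
            raise ValueError("particle density must be positive")
        if self.volume_shape_factor <= 0:
            raise ValueError("volume shape factor must be positive")
        if self.dynamic_shape_factor < 1:
            raise ValueError("dynamic shape factor must be >= 1")

    @property
    def density_kg_m3(self) -> float:
        return self.density_g_cm3 * 1000.0


@dataclass(frozen=True)
class GammaModel:
    """Mesh-attenuation model choice.

    variant:
        ``mesh``   -- power-law attenuation gamma = 5.95e-3 * X**-0.439,
                      X = da * vt / nu (wind-tunnel derived);
        ``hybrid`` -- the same power law capped at the open-area ratio;
        ``area``   -- constant gamma equal to the open-area ratio.
    """

    variant: str = "hybrid"
    open_area_ratio: float = DEFAULT_OPEN_AREA_RATIO

    VARIANTS = ("mesh", "hybrid", "area")

    def __post_init__(self) -> None:
        if self.variant not in self.VARIANTS:
            raise ConfigurationError(
                f"unknown gamma model variant {self.variant!r}; "
                f"expected one of {self.VARIANTS}"
            )
        if not 0 < self.open_area_ratio <= 1:
            raise ConfigurationError("open_area_ratio must lie in (0, 1]")


@dataclass(frozen=True)
class DepositionSettings:
    """Parameters of the quiescent-air deposition velocity model."""

    boundary_layer_m: float = 1e-3
    include_diffusion: bool = True

    def __post_init__(self) -> None:
        if self.boundary_layer_m <= 0:
            raise ValueError("boundary layer thickness must be positive")


DEFAULT_ENVIRONMENT = AirEnvironment()
DEFAULT_DEPOSITION = DepositionSettings()


def _validate_positive(d, name: str):
    arr = np.asarray(d, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} must be positive and finite")
    return arr


def _scalar_like(value: np.ndarray, template) -> float | np.ndarray:
    if np.isscalar(template) or np.ndim(template) == 0:
        return float(value)
    return value


def slip_correction(d, env: AirEnvironment = DEFAULT_ENVIRONMENT):
    """Cunningham slip correction factor for a particle of diameter ``d`` (m).

    Uses the single-expression form
    Cc = 1 + (lambda/d) * (2.514 + 0.800 * exp(-0.55 * d/lambda)).
    """
    arr = _validate_positive(d, "diameter")
    lam = env.mean_free_path
    knud = lam / arr
    cc = 1.0 + knud * (2.514 + 0.800 * np.exp(-0.55 / knud))
    return _scalar_like(cc, d)


def settling_velocity(da, env: AirEnvironment = DEFAULT_ENVIRONMENT):
    """Terminal settling velocity (m/s) of the unit-density sphere of
    aerodynamic diameter ``da`` (m), Stokes regime with slip correction."""
    arr = _validate_positive(da, "aerodynamic diameter")
    if np.any(arr > STOKES_LIMIT):
        warnings.warn(
            "settling_velocity called above the Stokes validity range "
            f"(> {STOKES_LIMIT * 1e6:.0f} um); result extrapolated",
            stacklevel=2,
        )
    mu = env.dynamic_viscosity
    vt = env.unit_density * arr**2 * GRAVITY * slip_correction(arr, env) / (18.0 * mu)
    return _scalar_like(vt, da)


def diffusion_coefficient(d, env: AirEnvironment = DEFAULT_ENVIRONMENT):
    """Brownian diffusion coefficient (m^2/s), Stokes-Einstein with slip."""
    arr = _validate_positive(d, "diameter")
    mu = env.dynamic_viscosity
    dcoef = BOLTZMANN * env.temperature * slip_correction(arr, env) / (3.0 * np.pi * mu * arr)
    return _scalar_like(dcoef, d)


def deposition_velocity(
    da,
    env: AirEnvironment = DEFAULT_ENVIRONMENT,
    settings: DepositionSettings = DEFAULT_DEPOSITION,
):
    """Deposition velocity (m/s) onto an upward-facing surface in still air.

    Combines gravitational settling and Brownian diffusion through a
    boundary layer of thickness ``settings.boundary_layer_m``:

        v = vt / (1 - exp(-vt * delta / D))

    which tends to vt for large particles and to D/delta for small ones.
    With ``include_diffusion`` off it reduces to the bare settling velocity.
    """
    arr = _validate_positive(da, "aerodynamic diameter")
    vt = np.asarray(settling_velocity(arr, env))
    if not settings.include_diffusion:
        return _scalar_like(vt, da)
    dcoef = np.asarray(diffusion_coefficient(arr, env))
    x = vt * settings.boundary_layer_m / dcoef
    # -expm1(-x) is accurate for tiny x and saturates at 1 for large x,
    # so both analytic limits fall out without special-casing overflow.
    with np.errstate(over="ignore"):
        v = vt / (-np.expm1(-x))
    v = np.where(x > 700.0, vt, v)
    return _scalar_like(v, da)


def gamma_mesh(da, env: AirEnvironment = DEFAULT_ENVIRONMENT):
    """Wind-tunnel mesh attenuation factor: 5.95e-3 * (da*vt/nu)**-0.439."""
    arr = _validate_positive(da, "aerodynamic diameter")
    vt = np.asarray(settling_velocity(arr, env))
    x = arr * vt / env.kinematic_viscosity
    gamma = GAMMA_PREFACTOR * x**GAMMA_EXPONENT
    return _scalar_like(gamma, da)


def gamma_apply(
    da,
    env: AirEnvironment = DEFAULT_ENVIRONMENT,
    model: GammaModel = GammaModel(),
):
    """Evaluate the configured gamma model at aerodynamic diameter ``da`` (m)."""
    arr = _validate_positive(da, "aerodynamic diameter")
    if model.variant == "mesh":
        gamma = np.asarray(gamma_mesh(arr, env))
    elif model.variant == "hybrid":
        gamma = np.minimum(np.asarray(gamma_mesh(arr, env)), model.open_area_ratio)
    elif model.variant == "area":
        gamma = np.full_like(arr, model.open_area_ratio, dtype=float)
    else:  # pragma: no cover - guarded by GammaModel.__post_init__
        raise ConfigurationError(f"unknown gamma model variant {model.variant!r}")
    return _scalar_like(gamma, da)


def particle_mass(d_pa_um, mat: MaterialProperties):
    """Particle mass in picograms from projected-area diameter in um.

    Volume convention: V = (pi/6) * d_pa^3 / S_V, so S_V = 1 recovers a
    sphere.  1 g/cm^3 equals exactly 1 pg/um^3, so the arithmetic is done
    directly in image units.
    """
    arr = _validate_positive(d_pa_um, "projected-area diameter")
    mass = mat.density_g_cm3 * (np.pi / 6.0) * arr**3 / mat.volume_shape_factor
    return _scalar_like(mass, d_pa_um)


def _fixed_point_diameter(target, start_um, env, tol_um, max_iter):
    """Solve d^2 * Cc(d) = target (d in um, Cc evaluated in m) by iteration."""
    d = np.asarray(start_um, dtype=float).copy()
    for _ in range(max_iter):
        cc = np.asarray(slip_correction(d * 1e-6, env))
        d_new = np.sqrt(target / cc)
        if np.all(np.abs(d_new - d) < tol_um):
            return d_new
        d = d_new
    raise ConvergenceError(
        f"diameter fixed point did not converge within {max_iter} iterations"
    )


def projected_to_aerodynamic(
    d_pa_um,
    mat: MaterialProperties,
    env: AirEnvironment = DEFAULT_ENVIRONMENT,
    *,
    slip: bool = True,
    tol_um: float = 1e-6,
    max_iter: int = 100,
):
    """Convert projected-area diameter (um) to aerodynamic diameter (um).

    The volume-equivalent diameter is d_ve = d_pa * S_V**(-1/3); the
    aerodynamic diameter then satisfies

        da^2 * Cc(da) * rho0 = d_ve^2 * Cc(d_ve) * (rho_p / chi)

    solved by fixed-point iteration on da (with ``slip=False`` the
    slip-free closed form is returned directly).
    """
    arr = _validate_positive(d_pa_um, "projected-area diameter")
    d_ve = arr * mat.volume_shape_factor ** (-1.0 / 3.0)
    ratio = mat.density_kg_m3 / (mat.dynamic_shape_factor * env.unit_density)
    if not slip:
        return _scalar_like(d_ve * np.sqrt(ratio), d_pa_um)
    cc_ve = np.asarray(slip_correction(d_ve * 1e-6, env))
    target = d_ve**2 * cc_ve * ratio  # um^2 times dimensionless
    da = _fixed_point_diameter(target, d_ve * np.sqrt(ratio), env, tol_um, max_iter)
    return _scalar_like(da, d_pa_um)


def aerodynamic_to_projected(
    da_um,
    mat: MaterialProperties,
    env: AirEnvironment = DEFAULT_ENVIRONMENT,
    *,
    slip: bool = True,
    tol_um: float = 1e-6,
    max_iter: int = 100,
):
    """Inverse of :func:`projected_to_aerodynamic` (both in um)."""
    arr = _validate_positive(da_um, "aerodynamic diameter")
    ratio = mat.density_kg_m3 / (mat.dynamic_shape_factor * env.unit_density)
    if not slip:
        d_ve = arr / np.sqrt(ratio)
    else:
        cc_a = np.asarray(slip_correction(arr * 1e-6, env))
        target = arr**2 * cc_a / ratio
        d_ve = _fixed_point_diameter(target, arr / np.sqrt(ratio), env, tol_um, max_iter)
    return _scalar_like(d_ve * mat.volume_shape_factor ** (1.0 / 3.0), da_um)
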