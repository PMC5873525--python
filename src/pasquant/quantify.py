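"""Particle tables to blank-corrected mass concentrations and size
distributions.

The passive-sampling mass balance inverts the deposition flux: each
particle of mass m deposited on analyzed area A during time t implies an
airborne concentration contribution m / (gamma * v_dep * A * t), where
gamma is the mesh attenuation and v_dep the still-air deposition velocity
at the particle's aerodynamic diameter.

Note on coverage: ``analyzed_area_m2`` is the total area of the analyzed
images and is used directly; ``analyzed_fraction`` (the share of the
opening the images cover) is metadata only, because the expected flux per
unit area is uniform, so no rescaling by the covered fraction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import physics
from .errors import ConfigurationError
from .imaging import ParticleObservation

PG_TO_MG = 1e-9


@dataclass(frozen=True)
class SamplerConfig:
    """Geometry and timing of one sampler deployment."""

    duration_s: float = 8 * 3600.0
    analyzed_area_m2: float = 60 * 450e-6 * 600e-6  # 60 images of 450x600 um
    analyzed_fraction: float = 0.51  # metadata; not used in the mass balance
    substrate: str = ""

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.analyzed_area_m2 <= 0:
            raise ValueError("duration and analyzed area must be positive")
        if not 0 < self.analyzed_fraction <= 1:
            raise ValueError("analyzed_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class FractionConvention:
    """A size-selective sampling convention as a collection efficiency curve.

    curve shapes:
        ``step``              -- indicator(da <= cut);
        ``lognormal_sigmoid`` -- 1 - Phi(ln(da/cut) / ln(GSD)), a sharp
                                 impactor-like curve for small GSD;
        ``iso_respirable``    -- the standard analytic approximation of the
                                 respirable convention,
                                 0.5*(1+exp(-0.06 da))*(1-Phi(ln(da/4.25)/ln 1.5)),
                                 whose 50% point sits at 4 um.
    """

    name: str
    cut_um: float
    curve_shape: str = "lognormal_sigmoid"
    gsd: float = 1.1

    def __post_init__(self) -> None:
        if self.cut_um <= 0:
            raise ValueError("cut diameter must be positive")
        if self.curve_shape not in ("step", "lognormal_sigmoid", "iso_respirable"):
            raise ConfigurationError(f"unknown curve shape {self.curve_shape!r}")
        if self.curve_shape == "lognormal_sigmoid" and self.gsd <= 1:
            raise ValueError("GSD must exceed 1")


PM10 = FractionConvention("PM10", 10.0, "lognormal_sigmoid", 1.1)
PM25 = FractionConvention("PM2.5", 2.5, "lognormal_sigmoid", 1.1)
RESPIRABLE = FractionConvention("respirable", 4.0, "iso_respirable")

CONVENTIONS = {"pm10": PM10, "pm2.5": PM25, "respirable": RESPIRABLE}


@dataclass
class BlankGroup:
    """Field blank concentrations for a group of locations, per fraction."""

    label: str
    concentrations: dict[str, list[float]] = field(default_factory=dict)

    def mean(self, fraction: str) -> float:
        values = self.concentrations.get(fraction, [])
        if len(values) == 0:
            raise ConfigurationError(
                f"blank group {self.label!r} has no members for fraction {fraction!r}"
            )
        return float(np.mean(values))


@dataclass
class SizeDistribution:
    """Binned mass concentration with its log-width-normalized view."""

    bin_edges_um: np.ndarray  # aerodynamic, length n+1
    dM: np.ndarray  # mg/m^3 per bin, length n
    underflow: float = 0.0  # mass below the first edge
    overflow: float = 0.0  # mass above the last edge

    @property
    def dM_dlogda(self) -> np.ndarray:
        widths = np.diff(np.log10(self.bin_edges_um))
        return self.dM / widths

    @property
    def total(self) -> float:
        return float(self.dM.sum() + self.underflow + self.overflow)


@dataclass
class ConcentrationResult:
    """Total concentration plus per-particle audit quantities."""

    total_mg_m3: float
    contributions_mg_m3: np.ndarray  # one entry per particle
    da_um: np.ndarray
    model_variant: str


def _extract_dpa(particles) -> np.ndarray:
    if isinstance(particles, pd.DataFrame):
        return particles["d_pa_um"].to_numpy(dtype=float)
    return np.array([p.d_pa_um for p in particles], dtype=float)


def concentration_total(
    particles,
    model: physics.GammaModel,
    sampler: SamplerConfig,
    mat: physics.MaterialProperties,
    env: physics.AirEnvironment = physics.DEFAULT_ENVIRONMENT,
    settings: physics.DepositionSettings = physics.DEFAULT_DEPOSITION,
) -> ConcentrationResult:
    """Invert the deposition flux of a filtered particle table.

    ``particles`` is a list of :class:`ParticleObservation` or a DataFrame
    with a ``d_pa_um`` column.  Returns the total in mg/m^3 together with
    each particle's contribution for audit.
    """
    d_pa = _extract_dpa(particles)
    if d_pa.size == 0:
        warnings.warn("empty particle table: concentration is 0", stacklevel=2)
        return ConcentrationResult(0.0, np.empty(0), np.empty(0), model.variant)
    da = np.asarray(physics.projected_to_aerodynamic(d_pa, mat, env))
    mass_pg = np.asarray(physics.particle_mass(d_pa, mat))
    gamma = np.asarray(physics.gamma_apply(da * 1e-6, env, model))
    v_dep = np.asarray(physics.deposition_velocity(da * 1e-6, env, settings))
    if np.any(v_dep <= 0) or np.any(gamma <= 0):
        raise FloatingPointError("non-positive deposition velocity or gamma")
    denom = gamma * v_dep * sampler.analyzed_area_m2 * sampler.duration_s
    contributions = mass_pg * PG_TO_MG / denom
    return ConcentrationResult(float(contributions.sum()), contributions, da, model.variant)


def fraction_efficiency(da_um, conv: FractionConvention):
    """Collection efficiency of convention ``conv`` at aerodynamic diameter
    ``da_um`` (um); values in [0, 1], non-increasing in diameter."""
    da = np.asarray(da_um, dtype=float)
    if np.any(da <= 0):
        raise ValueError("aerodynamic diameter must be positive")
    if conv.curve_shape == "step":
        eff = (da <= conv.cut_um).astype(float)
    elif conv.curve_shape == "lognormal_sigmoid":
        eff = 1.0 - norm.cdf(np.log(da / conv.cut_um) / np.log(conv.gsd))
    else:  # iso_respirable
        eff = 0.5 * (1.0 + np.exp(-0.06 * da)) * (
            1.0 - norm.cdf(np.log(da / 4.25) / np.log(1.5))
        )
    if np.ndim(da_um) == 0:
        return float(eff)
    return eff


def fraction_concentration(
    particles,
    conv: FractionConvention,
    model: physics.GammaModel,
    sampler: SamplerConfig,
    mat: physics.MaterialProperties,
    env: physics.AirEnvironment = physics.DEFAULT_ENVIRONMENT,
    settings: physics.DepositionSettings = physics.DEFAULT_DEPOSITION,
) -> float:
    """Efficiency-weighted concentration (mg/m^3) for one size fraction."""
    result = concentration_total(particles, model, sampler, mat, env, settings)
    if result.da_um.size == 0:
        return 0.0
    eff = fraction_efficiency(result.da_um, conv)
    return float(np.sum(eff * result.contributions_mg_m3))


def blank_correct(values: dict[str, float], blanks: BlankGroup) -> dict[str, float]:
    """Subtract the group's mean blank per fraction; negatives preserved."""
    return {fraction: value - blanks.mean(fraction) for fraction, value in values.items()}


def size_distribution(
    particles,
    bin_edges_um,
    model: physics.GammaModel,
    sampler: SamplerConfig,
    mat: physics.MaterialProperties,
    env: physics.AirEnvironment = physics.DEFAULT_ENVIRONMENT,
    settings: physics.DepositionSettings = physics.DEFAULT_DEPOSITION,
) -> SizeDistribution:
    """Bin per-particle contributions by aerodynamic diameter.

    Particles outside the edges go to reported under/overflow totals so the
    binned distribution plus spill always conserves the total mass.
    """
    edges = np.asarray(bin_edges_um, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0) or edges[0] <= 0:
        raise ValueError("bin edges must be positive and strictly increasing")
    d_pa = _extract_dpa(particles)
    if d_pa.size == 0:
        return SizeDistribution(edges, np.zeros(edges.size - 1))
    result = concentration_total(particles, model, sampler, mat, env, settings)
    da, weights = result.da_um, result.contributions_mg_m3
    dM, _ = np.histogram(da, bins=edges, weights=weights)
    under = float(weights[da < edges[0]].sum())
    over = float(weights[da > edges[-1]].sum())
    return SizeDistribution(edges, dM, underflow=under, overflow=over)
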