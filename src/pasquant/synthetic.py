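"""Ground-truth-known generators for every pipeline stage.

``simulate_deposition`` forward-models the sampler: a lognormal mass-size
distribution deposits onto the analyzed area at gamma-attenuated,
size-dependent velocity, with Poisson particle counts and uniform
placement.  ``render_image`` rasterizes a particle table into the
grayscale micrographs the imaging module consumes, and ``simulate_study``
draws multi-occasion study tables with a known variance-component
structure.

Number concentrations per size bin are obtained by dividing the bin's mass
concentration by the single-particle mass at the bin-centre diameter; this
is the discrete equivalent of converting the mass lognormal to a count
lognormal via the Hatch-Choate shift ln(CMD) = ln(MMD) - 3 ln^2(GSD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import physics
from .errors import ConfigurationError
from .imaging import PARTICLE_COLUMNS, ImageCalibration
from .quantify import PG_TO_MG, SamplerConfig

MAX_EXPECTED_COUNT = 1e7


@dataclass(frozen=True)
class AerosolSpec:
    """A lognormal aerosol by mass."""

    mmad_um: float  # mass median aerodynamic diameter
    gsd: float
    total_mass_mg_m3: float
    material: physics.MaterialProperties = physics.MaterialProperties()

    def __post_init__(self) -> None:
        if self.mmad_um <= 0 or self.total_mass_mg_m3 < 0:
            raise ValueError("MMAD must be positive and mass non-negative")
        if self.gsd <= 1:
            raise ValueError("GSD must exceed 1")


@dataclass(frozen=True)
class StudySpec:
    """Design of a synthetic multi-occasion study."""

    n_locations: int = 4
    n_times: int = 3
    n_replicates: int = 10
    var_between: float = 0.01
    var_within: float = 0.01
    occasion_means: np.ndarray | None = None  # (n_locations, n_times)
    seed: int | None = None
    device: str = "passive"
    fraction: str = "PM10"

    def __post_init__(self) -> None:
        if min(self.n_locations, self.n_times, self.n_replicates) < 1:
            raise ValueError("design dimensions must be >= 1")
        if self.var_between < 0 or self.var_within < 0:
            raise ValueError("variances must be non-negative")


@dataclass
class DepositionTruth:
    """Ground truth accompanying a simulated particle table."""

    bin_edges_um: np.ndarray  # aerodynamic
    bin_da_um: np.ndarray  # bin centres (geometric mean)
    bin_d_pa_um: np.ndarray
    bin_mass_mg_m3: np.ndarray  # airborne mass concentration per bin
    expected_counts: np.ndarray  # Poisson means of deposited counts
    counts: np.ndarray  # realized counts
    expected_concentration: float  # sum of covered bin masses
    poisson_se: float  # SE of the flux-inverted total under Poisson counts
    model_variant: str


def simulate_deposition(
    aerosol: AerosolSpec,
    model: physics.GammaModel,
    sampler: SamplerConfig,
    env: physics.AirEnvironment = physics.DEFAULT_ENVIRONMENT,
    seed: int | None = None,
    settings: physics.DepositionSettings = physics.DEFAULT_DEPOSITION,
    calib: ImageCalibration = ImageCalibration(),
    n_bins: int = 80,
    span_log_sigmas: float = 4.0,
) -> tuple[pd.DataFrame, DepositionTruth]:
    """Simulate the particle table deposited during one deployment.

    Per log-spaced aerodynamic-diameter bin, the expected deposited count is
    (bin mass / particle mass) * gamma * v_dep * A * t; realized counts are
    Poisson, positions uniform over the analyzed images, and the projected
    diameter is the bin centre mapped back through the shape-factor chain.
    Returns the particle table (imaging CSV schema) and the ground truth.
    """
    rng = np.random.default_rng(seed)
    lo = aerosol.mmad_um * aerosol.gsd ** (-span_log_sigmas)
    hi = aerosol.mmad_um * aerosol.gsd ** (span_log_sigmas)
    edges = np.geomspace(lo, hi, n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])

    z = np.log(edges / aerosol.mmad_um) / np.log(aerosol.gsd)
    mass_frac = np.diff(norm.cdf(z))
    bin_mass = aerosol.total_mass_mg_m3 * mass_frac  # mg/m^3

    d_pa = np.asarray(
        physics.aerodynamic_to_projected(centers, aerosol.material, env)
    )
    mass_per_particle = np.asarray(physics.particle_mass(d_pa, aerosol.material)) * PG_TO_MG
    gamma = np.asarray(physics.gamma_apply(centers * 1e-6, env, model))
    v_dep = np.asarray(physics.deposition_velocity(centers * 1e-6, env, settings))
    number_conc = bin_mass / mass_per_particle  # per m^3
    expected = number_conc * gamma * v_dep * sampler.analyzed_area_m2 * sampler.duration_s

    total_expected = expected.sum()
    if total_expected > MAX_EXPECTED_COUNT:
        raise ConfigurationError(
            f"expected particle count {total_expected:.3g} exceeds the "
            f"{MAX_EXPECTED_COUNT:.0g} guard; reduce concentration or area"
        )

    counts = rng.poisson(expected)
    n_total = int(counts.sum())
    image_area_m2 = calib.image_width_um * calib.image_height_um * 1e-12
    n_images = max(1, int(round(sampler.analyzed_area_m2 / image_area_m2)))

    d_pa_particles = np.repeat(d_pa, counts)
    image_ids = rng.integers(0, n_images, size=n_total)
    x = rng.uniform(0.0, calib.image_width_um, size=n_total)
    y = rng.uniform(0.0, calib.image_height_um, size=n_total)
    r = d_pa_particles / 2.0
    touches = (
        (x < r)
        | (y < r)
        | (x > calib.image_width_um - r)
        | (y > calib.image_height_um - r)
    )
    frame = pd.DataFrame(
        {
            "image_id": [f"sim_{i:03d}" for i in image_ids],
            "particle_id": np.arange(1, n_total + 1),
            "area_um2": np.pi * (d_pa_particles / 2.0) ** 2,
            "d_pa_um": d_pa_particles,
            "x_um": x,
            "y_um": y,
            "touches_edge": touches,
        },
        columns=PARTICLE_COLUMNS,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = np.where(expected > 0, bin_mass**2 / np.where(expected > 0, expected, 1.0), 0.0)
    truth = DepositionTruth(
        bin_edges_um=edges,
        bin_da_um=centers,
        bin_d_pa_um=d_pa,
        bin_mass_mg_m3=bin_mass,
        expected_counts=expected,
        counts=counts,
        expected_concentration=float(bin_mass.sum()),
        poisson_se=float(np.sqrt(var_terms.sum())),
        model_variant=model.variant,
    )
    return frame, truth


def render_image(
    particles,
    calib: ImageCalibration = ImageCalibration(),
    noise_sd: float = 5.0,
    seed: int | None = None,
    foreground: int = 200,
    background: int = 20,
) -> np.ndarray:
    """Rasterize particles as filled discs on a noisy background (uint8).

    Each particle claims exactly round(area * px_density^2) pixels — the
    ones nearest its centre — so rasterized areas match the nominal
    projected areas to within half a pixel.  Discs overhanging the border
    are clipped (and thus recoverable as edge-touching components).
    """
    rng = np.random.default_rng(seed)
    nrows, ncols = calib.shape
    image = np.zeros((nrows, ncols), dtype=float)
    if isinstance(particles, pd.DataFrame):
        table = particles[["x_um", "y_um", "area_um2"]].to_numpy(dtype=float)
    else:
        table = np.array(
            [[p.centroid_x_um, p.centroid_y_um, p.projected_area_um2] for p in particles],
            dtype=float,
        ).reshape(-1, 3)
    ppm = calib.pixels_per_micron
    for x_um, y_um, area_um2 in table:
        n_px = max(1, int(round(area_um2 * ppm**2)))
        cx, cy = x_um * ppm, y_um * ppm  # column, row (pixel coordinates)
        r_px = np.sqrt(n_px / np.pi) + 2.0
        r0 = max(0, int(np.floor(cy - r_px)))
        r1 = min(nrows, int(np.ceil(cy + r_px)) + 1)
        c0 = max(0, int(np.floor(cx - r_px)))
        c1 = min(ncols, int(np.ceil(cx + r_px)) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rows, cols = np.mgrid[r0:r1, c0:c1]
        rows, cols = rows.ravel(), cols.ravel()
        dist2 = (rows + 0.5 - cy) ** 2 + (cols + 0.5 - cx) ** 2
        # candidates limited to the geometric disc (plus one pixel of slack)
        # so discs overhanging the border clip instead of bleeding inward
        inside = dist2 <= (np.sqrt(n_px / np.pi) + 1.0) ** 2
        rows, cols, dist2 = rows[inside], cols[inside], dist2[inside]
        order = np.lexsort((cols, rows, dist2))
        take = order[: min(n_px, order.size)]
        image[rows[take], cols[take]] = 1.0
    out = np.where(image > 0, float(foreground), float(background))
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def simulate_study(spec: StudySpec) -> pd.DataFrame:
    """Draw a long-format study table from the variance-component model
    value = occasion fixed mean + N(0, var_between) + N(0, var_within)."""
    rng = np.random.default_rng(spec.seed)
    L, T, n = spec.n_locations, spec.n_times, spec.n_replicates
    if spec.occasion_means is None:
        # additive fixed structure: distinct but arbitrary location/time levels
        loc_eff = np.linspace(0.0, 1.0, L)
        time_eff = np.linspace(0.0, 0.3, T)
        means = 0.5 + loc_eff[:, None] + time_eff[None, :]
    else:
        means = np.asarray(spec.occasion_means, dtype=float)
        if means.shape != (L, T):
            raise ValueError("occasion_means must have shape (n_locations, n_times)")
    occ_effect = rng.normal(0.0, np.sqrt(spec.var_between), size=(L, T))
    rows = []
    for i in range(L):
        for j in range(T):
            noise = rng.normal(0.0, np.sqrt(spec.var_within), size=n)
            values = means[i, j] + occ_effect[i, j] + noise
            for k in range(n):
                rows.append(
                    {
                        "location": f"L{i}",
                        "time": f"T{j}",
                        "occasion": f"L{i}:T{j}",
                        "device": spec.device,
                        "replicate_id": k,
                        "value": values[k],
                        "fraction": spec.fraction,
                    }
                )
    return pd.DataFrame(rows)
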