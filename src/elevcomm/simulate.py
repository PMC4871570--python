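"""Synthetic elevational community data.

Generates the three tables the analysis pipeline consumes — a plot
design, a plot x predictor environment table, and a plot x species
count matrix — with the statistical structure the downstream stages
assume: a stratified multi-subregion design (5 subregions x ~200 m
elevational zones x 3 plots), temperature falling with elevation at a
fixed lapse rate, a configurable set of inter-predictor correlations
induced through a Gaussian copula (notably r = 0.90 between historical
vegetation stability and precipitation seasonality), negative-binomial
counts whose log-mean rises with elevation, subregional endemics with
structural zeros outside their home subregion, and depauperate (often
all-zero) lowland plots.

Every generator is a pure function of its configuration: the config
seed is split deterministically into per-stage child seeds, so each
table is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SimConfig",
    "ZONE_SCHEME",
    "PREDICTORS",
    "PREDICTOR_GROUPS",
    "DEFAULT_PRIORITY",
    "generate_design",
    "generate_environment",
    "generate_community",
    "design_arithmetic",
]

# default stratified design: 5 subregions, 23 zones, 3 plots per zone
ZONE_SCHEME: dict[str, list[int]] = {
    "SU": [350, 600, 800, 1000],
    "AU": [100, 200, 400, 600, 800, 1000],
    "BK": [1000, 1200, 1400, 1600],
    "CU": [100, 400, 600, 800, 1000, 1200],
    "WU": [900, 1100, 1300],
}

SUBREGION_LATITUDE = {
    "SU": -18.95, "AU": -17.60, "BK": -17.27, "CU": -16.50, "WU": -16.25,
}

#: the 17 candidate predictors: 8 bioclimatic, 2 soil-moisture, 4 local
#: habitat descriptors, terrain aspect, historical vegetation stability,
#: plus elevation and latitude
PREDICTORS = [
    "Ave.T", "Seas.T", "Max.T", "Min.T",
    "Ann.P", "Seas.P", "P.Wet.Q", "P.Dry.Q",
    "AWC", "TWI", "Habitat", "Treefall", "Litter", "Aspect",
    "Hist.veg", "Elevation", "Latitude",
]

#: property groups for correlation screening.  Elevation sits in the
#: temperature group: at a fixed lapse rate temperature is a linear
#: function of elevation, so the pair is screened as one property.
PREDICTOR_GROUPS = {
    "Ave.T": "temperature", "Seas.T": "temperature",
    "Max.T": "temperature", "Min.T": "temperature",
    "Elevation": "temperature",
    "Ann.P": "precipitation", "Seas.P": "precipitation",
    "P.Wet.Q": "precipitation", "P.Dry.Q": "precipitation",
    "AWC": "soil", "TWI": "soil",
    "Habitat": "habitat", "Treefall": "habitat", "Litter": "habitat",
    "Aspect": "terrain", "Latitude": "terrain",
    "Hist.veg": "history",
}

#: keep-priority for screening, most valuable first: annual means and
#: seasonalities ahead of period extremes and of elevation per se
DEFAULT_PRIORITY = [
    "Ave.T", "Seas.T", "Ann.P", "Seas.P", "Hist.veg", "Latitude",
    "AWC", "TWI", "Habitat", "Treefall", "Litter", "Aspect",
]


@dataclass
class SimConfig:
    """Conditions for the synthetic community.

    ``elev_effect`` is the mean per-species log-link slope on elevation
    in km (positive: richness and abundance increase uphill);
    ``dispersion`` is the negative-binomial size theta; ``lapse_rate``
    is in degrees C per metre.  ``env_targets`` lists (predictor_i,
    predictor_j, Pearson r) correlations induced between the predictors'
    latent residuals.
    """

    seed: int = 0
    n_species: int = 43
    endemic_fraction: float = 0.33
    elev_effect: float = 4.2
    intercept_mean: float = -5.0
    intercept_sd: float = 1.0
    slope_sd: float = 0.75
    dispersion: float = 1.0
    env_targets: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("Hist.veg", "Seas.P", 0.90)]
    )
    lapse_rate: float = 1.0 / 200.0
    traps_per_plot: int = 3
    months: int = 12
    plots_per_zone: int = 3
    zones: dict[str, list[int]] = field(
        default_factory=lambda: {k: list(v) for k, v in ZONE_SCHEME.items()}
    )
    elev_jitter: float = 50.0
    lost_trap_months: int = 0  # optional thinning; 0 = off

    def __post_init__(self):
        if not 0.0 <= self.endemic_fraction <= 1.0:
            raise ConfigurationError("endemic_fraction must be in [0, 1]")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion theta must be > 0")
        for a, b, r in self.env_targets:
            if not abs(r) < 1:
                raise ConfigurationError(
                    f"target correlation |r({a},{b})| must be < 1"
                )
        if not self.zones or not any(self.zones.values()):
            raise ConfigurationError("zone scheme must be non-empty")

    def stage_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), stage])
        )

    def to_dict(self) -> dict:
        return asdict(self)


def generate_design(config: SimConfig) -> pd.DataFrame:
    """One row per plot: subregion, zone elevation, jittered actual
    elevation, latitude and plot id."""
    rng = config.stage_rng(0)
    rows = []
    for sub, zones in config.zones.items():
        if not zones:
            raise ConfigurationError(f"subregion {sub!r} has no zones")
        lat0 = SUBREGION_LATITUDE.get(sub, -17.5)
        for z in zones:
            for i in range(config.plots_per_zone):
                actual = z + rng.uniform(-config.elev_jitter, config.elev_jitter)
                rows.append(
                    {
                        "plot_id": f"{sub}-{z}-{i + 1}",
                        "subregion": sub,
                        "zone_elev": z,
                        "actual_elev": round(max(actual, 1.0), 1),
                        "latitude": round(lat0 + rng.uniform(-0.02, 0.02), 4),
                    }
                )
    plots = pd.DataFrame(rows).set_index("plot_id")
    if plots.index.has_duplicates:
        raise ConfigurationError("plot ids are not unique")
    return plots


def _residual_correlation(config: SimConfig) -> np.ndarray:
    """Latent residual correlation matrix from the configured targets."""
    p = len(PREDICTORS)
    R = np.eye(p)
    idx = {name: j for j, name in enumerate(PREDICTORS)}
    for a, b, r in config.env_targets:
        if a not in idx or b not in idx:
            raise ConfigurationError(f"unknown predictor in target ({a}, {b})")
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        pairs = ", ".join(f"({a}, {b}, r={r})" for a, b, r in config.env_targets)
        raise ConfigurationError(
            f"correlation targets are jointly infeasible "
            f"(not positive definite): {pairs}"
        ) from None
    return R


def generate_environment(plots: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Plot x predictor table with the configured structure.

    Temperature predictors fall with actual elevation at the lapse rate;
    precipitation rises with elevation (cloud stripping); the latent
    residuals carry the Gaussian-copula correlation targets.  Deterministic
    under the config seed.
    """
    if plots.empty:
        raise ConfigurationError("plot table is empty")
    rng = config.stage_rng(1)
    R = _residual_correlation(config)
    L = np.linalg.cholesky(R)
    n = len(plots)
    eps = pd.DataFrame(
        (L @ rng.standard_normal((len(PREDICTORS), n))).T,
        columns=PREDICTORS, index=plots.index,
    )

    elev = plots["actual_elev"].to_numpy(dtype=float)
    elev_km = elev / 1000.0
    lat = plots["latitude"].to_numpy(dtype=float)

    env = pd.DataFrame(index=plots.index)
    env["Ave.T"] = 25.5 - config.lapse_rate * elev + 0.3 * eps["Ave.T"]
    env["Max.T"] = env["Ave.T"] + 5.0 + 0.3 * eps["Max.T"]
    env["Min.T"] = env["Ave.T"] - 5.0 + 0.3 * eps["Min.T"]
    env["Seas.T"] = 1.5 - 0.3 * (elev_km - elev_km.mean()) + 0.5 * eps["Seas.T"]
    env["Ann.P"] = 2000.0 + 1200.0 * elev_km + 400.0 * eps["Ann.P"]
    env["P.Wet.Q"] = 0.55 * env["Ann.P"] + 120.0 * eps["P.Wet.Q"]
    env["P.Dry.Q"] = 0.12 * env["Ann.P"] + 30.0 * eps["P.Dry.Q"]
    env["Seas.P"] = 60.0 + 8.0 * eps["Seas.P"]
    env["Hist.veg"] = 0.5 + 0.15 * eps["Hist.veg"]
    env["AWC"] = 80.0 + 10.0 * eps["AWC"]
    env["TWI"] = 8.0 + 1.5 * eps["TWI"]
    env["Habitat"] = np.clip(2.0 + 0.8 * eps["Habitat"], 0.0, 4.0)
    env["Treefall"] = np.clip(
        1.5 - 0.5 * (elev_km - elev_km.mean()) + 0.8 * eps["Treefall"], 0.0, 4.0
    )
    env["Litter"] = np.clip(3.0 + 0.5 * elev_km + 0.8 * eps["Litter"], 0.0, None)
    env["Aspect"] = np.mod(180.0 + 100.0 * eps["Aspect"], 360.0)
    env["Elevation"] = elev
    env["Latitude"] = lat
    return env[PREDICTORS]


def generate_community(
    plots: pd.DataFrame, env: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Plot x species negative-binomial count matrix.

    Species s at plot p has log mean ``alpha_s + beta_s * elev_km`` with
    ``beta_s ~ N(elev_effect, slope_sd)``; endemic species (a configured
    fraction, each assigned one home subregion) have structural zeros
    everywhere else.  All-zero plots are valid output (and expected in
    the lowlands under the defaults).
    """
    if not plots.index.equals(env.index):
        raise ConfigurationError("environment rows misaligned with plots")
    rng = config.stage_rng(2)
    S = config.n_species
    subregions = list(config.zones.keys())

    alpha = rng.normal(config.intercept_mean, config.intercept_sd, S)
    beta = rng.normal(config.elev_effect, config.slope_sd, S)
    n_endemic = int(round(config.endemic_fraction * S))
    endemic_ids = rng.choice(S, size=n_endemic, replace=False)
    home = {int(s): subregions[rng.integers(len(subregions))] for s in endemic_ids}

    elev_km = plots["actual_elev"].to_numpy(dtype=float)[:, None] / 1000.0
    mu = np.exp(alpha[None, :] + beta[None, :] * elev_km)
    theta = config.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))

    for s, sub in home.items():
        counts[(plots["subregion"] != sub).to_numpy(), s] = 0

    if config.lost_trap_months > 0:
        # binomial thinning: each individual sits in one of the plot's
        # trap-months, a random subset of which is lost
        total = config.traps_per_plot * config.months
        lost_plots = rng.choice(
            len(plots),
            size=min(config.lost_trap_months, len(plots)),
            replace=False,
        )
        for pidx in lost_plots:
            lost = rng.integers(1, config.traps_per_plot + 1)
            keep = (total - lost) / total
            counts[pidx] = rng.binomial(counts[pidx], keep)

    species = [f"sp{j + 1:03d}" for j in range(S)]
    out = pd.DataFrame(counts, index=plots.index, columns=species)
    out.attrs["endemic_home"] = {species[s]: sub for s, sub in home.items()}
    return out


def design_arithmetic(config: SimConfig) -> dict[str, int]:
    """Exact design counts: zones, plots, trap-months."""
    n_zones = sum(len(z) for z in config.zones.values())
    n_plots = n_zones * config.plots_per_zone
    return {
        "zones": n_zones,
        "plots": n_plots,
        "trap_months": n_plots * config.traps_per_plot * config.months,
    }
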