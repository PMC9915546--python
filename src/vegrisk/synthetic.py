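"""Synthetic paired soil-vegetable data generator.

Emulates the statistical structure the analysis assumes: 51 paired samples
across 7 leafy-vegetable species; soil metal contents produced by a
two-latent-source log-linear mixing model (a smelter source loading Cd, Cr,
Cu, V and a mine source loading Pb, Zn), so that the planted structure shows
up as positive within-group correlations and a two-component PCA; and
vegetable contents produced through a log-linear bioaccumulation-factor
model whose pH, organic-matter, and free-Fe-oxide slopes are negative for Cd
and V and whose available-K slope is positive for Cd, Cr, V.

Soil metal content of sample i:

    C_mi = BV_m * exp(L_m1 * S1_i + L_m2 * S2_i + eps_mi),
    S_k ~ Normal(1, source_sigma_k),  eps_mi ~ Normal(0, noise_m)

with default own-source loadings L_m = ln(GM_m / BV_m) chosen so the
geometric means land on the regional survey values. Vegetable content is
BAF * C_soil with

    ln BAF_mi = alpha_m + sum_c beta_cm (x_ci - xbar_c) + offset(species_i)
                + eta_mi

and alpha_m solved analytically so the expected arithmetic-mean BAF equals
the study-reported grand mean for each metal.

All randomness flows from one seed through fixed-order substreams (one per
component and metal), so adding a metal leaves the other draws unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import (
    DEFAULT_SPECIES_PLAN,
    METALS,
    PairedDataset,
    SoilSample,
    VegetableSample,
    VegriskError,
)

#: Regional-survey geometric means the soil generator is calibrated to, mg/kg.
SOIL_GEOMEAN_TARGETS = {"Cd": 11.3, "Cr": 121.0, "Cu": 27.8, "Pb": 88.2,
                        "V": 409.0, "Zn": 329.0}

#: Grand-mean (arithmetic) bioaccumulation factors the vegetable generator
#: is calibrated to.
BAF_MEAN_TARGETS = {"Cd": 0.019, "Cu": 0.016, "Zn": 0.014, "Pb": 0.002,
                    "V": 0.001, "Cr": 0.0003}

SMELTER_METALS = ("Cd", "Cr", "Cu", "V")
MINE_METALS = ("Pb", "Zn")

_BACKGROUND = {"Cd": 0.41, "Cr": 33.9, "Cu": 8.56, "Pb": 32.7, "V": 95.6,
               "Zn": 118.0}


def _default_loadings() -> dict[str, tuple[float, float]]:
    out = {}
    for m in METALS:
        own = math.log(SOIL_GEOMEAN_TARGETS[m] / _BACKGROUND[m])
        out[m] = (own, 0.0) if m in SMELTER_METALS else (0.0, own)
    return out


def _default_covariates() -> dict[str, dict]:
    # Calibrated to the regional-survey magnitudes: pH ~ truncated normal,
    # the rest log-normal (gm = geometric mean, gsd = geometric SD).
    return {
        "pH": {"dist": "truncnorm", "mean": 5.84, "sd": 0.76,
               "low": 4.5, "high": 7.3},
        "som": {"dist": "lognormal", "gm": 26.7, "gsd": 1.21},
        "dcb_fe": {"dist": "lognormal", "gm": 1.55, "gsd": 1.5},
        "dcb_al": {"dist": "lognormal", "gm": 0.66, "gsd": 1.5},
        "avail_n": {"dist": "truncnorm", "mean": 59.4, "sd": 17.1,
                    "low": 20.0, "high": 100.0},
        "avail_p": {"dist": "lognormal", "gm": 0.03, "gsd": 2.0},
        "avail_k": {"dist": "lognormal", "gm": 65.5, "gsd": 1.92},
    }


def _default_baf_slopes() -> dict[str, dict[str, float]]:
    # beta per (metal, covariate) on the ln-BAF scale; units 1/covariate-unit.
    # Negative pH/SOM/DCB-Fe effects for Cd and V; positive avail-K effect
    # for Cd, Cr, V; everything else flat.
    slopes = {m: {"pH": 0.0, "som": 0.0, "dcb_fe": 0.0, "avail_k": 0.0}
              for m in METALS}
    for m in ("Cd", "V"):
        slopes[m].update({"pH": -0.6, "som": -0.05, "dcb_fe": -0.4})
    for m in ("Cd", "Cr", "V"):
        slopes[m]["avail_k"] = 0.004
    return slopes


def _default_species_offsets() -> dict[str, float]:
    # ln-BAF additive offsets; the high accumulators of the study design
    # (garland chrysanthemum, pak choi, coriander) sit highest.
    return {
        "asparagus lettuce": -0.3,
        "pak choi": 0.4,
        "coriander": 0.4,
        "flowering Chinese cabbage": 0.0,
        "garland chrysanthemum": 0.4,
        "garlic sprout": -0.3,
        "lettuce": 0.0,
    }


def _plan_for(n: int) -> tuple[tuple[str, int], ...]:
    """Round-robin species plan for a site count other than the default 51."""
    species = [s for s, _ in DEFAULT_SPECIES_PLAN]
    counts = {s: 0 for s in species}
    for i in range(n):
        counts[species[i % len(species)]] += 1
    return tuple((s, c) for s, c in counts.items() if c > 0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-data generator; defaults ARE the study design."""

    n_sites: int = 51
    species_plan: tuple[tuple[str, int], ...] | None = None
    background: dict[str, float] = field(default_factory=lambda: dict(_BACKGROUND))
    source_loadings: dict[str, tuple[float, float]] = field(
        default_factory=_default_loadings
    )
    source_sigma: tuple[float, float] = (0.5, 0.5)
    metal_noise_sigma: dict[str, float] = field(
        default_factory=lambda: {m: 0.3 for m in METALS}
    )
    covariates: dict[str, dict] = field(default_factory=_default_covariates)
    baf_targets: dict[str, float] = field(
        default_factory=lambda: dict(BAF_MEAN_TARGETS)
    )
    baf_slopes: dict[str, dict[str, float]] = field(
        default_factory=_default_baf_slopes
    )
    species_offsets: dict[str, float] = field(
        default_factory=_default_species_offsets
    )
    baf_residual_sigma: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise VegriskError("n_sites must be >= 0")
        if self.species_plan is None:
            plan = (DEFAULT_SPECIES_PLAN if self.n_sites == 51
                    else _plan_for(self.n_sites))
            object.__setattr__(self, "species_plan", plan)
        if sum(c for _, c in self.species_plan) != self.n_sites:
            raise VegriskError("species_plan counts must sum to n_sites")
        if any(c <= 0 for _, c in self.species_plan):
            raise VegriskError("species_plan counts must be positive")
        if any(s < 0 for s in self.source_sigma):
            raise VegriskError("source_sigma must be >= 0")
        if any(v < 0 for v in self.metal_noise_sigma.values()):
            raise VegriskError("metal_noise_sigma must be >= 0")
        if self.baf_residual_sigma < 0:
            raise VegriskError("baf_residual_sigma must be >= 0")


def _covariate_moments(spec: dict) -> tuple[float, float]:
    """Analytic (mean, variance) of a covariate distribution spec."""
    if spec["dist"] == "truncnorm":
        # close enough to the untruncated moments for calibration purposes
        return spec["mean"], spec["sd"] ** 2
    if spec["dist"] == "lognormal":
        s = math.log(spec["gsd"])
        mean = spec["gm"] * math.exp(s * s / 2.0)
        var = mean * mean * math.expm1(s * s)
        return mean, var
    raise VegriskError(f"unknown covariate distribution {spec['dist']!r}")


def _draw_covariate(spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec["dist"] == "truncnorm":
        a = (spec["low"] - spec["mean"]) / spec["sd"]
        b = (spec["high"] - spec["mean"]) / spec["sd"]
        if a >= b:
            raise VegriskError("infeasible truncation bounds for covariate")
        return stats.truncnorm.rvs(
            a, b, loc=spec["mean"], scale=spec["sd"], size=n, random_state=rng
        )
    if spec["dist"] == "lognormal":
        return rng.lognormal(math.log(spec["gm"]), math.log(spec["gsd"]), size=n)
    raise VegriskError(f"unknown covariate distribution {spec['dist']!r}")


def _substreams(seed: int) -> list[np.random.SeedSequence]:
    # fixed spawn order: 0 covariates, 1 latent sources, 2-7 soil metal
    # noise (panel order), 8-13 ln-BAF residuals (panel order)
    return np.random.SeedSequence(seed).spawn(2 + 2 * len(METALS))


def generate_soils(config: GeneratorConfig, seed: int | None = None) -> list[SoilSample]:
    """Draw soil covariates and two-source metal contents for every site."""
    seed = config.seed if seed is None else seed
    streams = _substreams(seed)
    n = config.n_sites
    rng_cov = np.random.default_rng(streams[0])
    cov_values = {
        name: _draw_covariate(spec, n, rng_cov)
        for name, spec in config.covariates.items()
    }
    rng_src = np.random.default_rng(streams[1])
    s1 = rng_src.normal(1.0, config.source_sigma[0], size=n)
    s2 = rng_src.normal(1.0, config.source_sigma[1], size=n)
    metals_matrix = {}
    for k, m in enumerate(METALS):
        rng_m = np.random.default_rng(streams[2 + k])
        eps = rng_m.normal(0.0, config.metal_noise_sigma[m], size=n)
        l1, l2 = config.source_loadings[m]
        metals_matrix[m] = config.background[m] * np.exp(l1 * s1 + l2 * s2 + eps)
    soils = []
    for i in range(n):
        soils.append(
            SoilSample(
                sample_id=f"S{i + 1:03d}",
                ph=float(cov_values["pH"][i]),
                som=float(cov_values["som"][i]),
                dcb_fe=float(cov_values["dcb_fe"][i]),
                dcb_al=float(cov_values["dcb_al"][i]),
                avail_n=float(cov_values["avail_n"][i]),
                avail_p=float(cov_values["avail_p"][i]),
                avail_k=float(cov_values["avail_k"][i]),
                metals={m: float(metals_matrix[m][i]) for m in METALS},
            )
        )
    return soils


def _baf_intercepts(config: GeneratorConfig) -> dict[str, float]:
    """Solve alpha_m so the expected arithmetic-mean BAF hits its target.

    E[BAF] = exp(alpha + V/2) * sum_s w_s exp(offset_s) with V the ln-BAF
    variance contributed by covariate slopes and the residual; hence
    alpha = ln(target) - ln(sum_s w_s e^{offset_s}) - V/2.
    """
    n = max(config.n_sites, 1)
    weights = {s: c / n for s, c in config.species_plan} or {"all": 1.0}
    offset_term = sum(
        w * math.exp(config.species_offsets.get(s, 0.0))
        for s, w in weights.items()
    )
    alphas = {}
    for m in METALS:
        v = config.baf_residual_sigma**2
        for cov, beta in config.baf_slopes[m].items():
            _, var = _covariate_moments(config.covariates[cov])
            v += beta * beta * var
        alphas[m] = (
            math.log(config.baf_targets[m]) - math.log(offset_term) - v / 2.0
        )
    return alphas


def generate_vegetables(
    soils: list[SoilSample], config: GeneratorConfig, seed: int | None = None
) -> list[VegetableSample]:
    """Draw one vegetable per site through the log-linear BAF model."""
    seed = config.seed if seed is None else seed
    if len(soils) != config.n_sites:
        raise VegriskError("species plan inconsistent with available sites")
    streams = _substreams(seed)
    species_seq: list[str] = []
    for sp, count in config.species_plan:
        species_seq.extend([sp] * count)
    cov_means = {
        name: _covariate_moments(spec)[0]
        for name, spec in config.covariates.items()
    }
    alphas = _baf_intercepts(config)
    vegetables = []
    n = len(soils)
    ln_baf = {}
    for k, m in enumerate(METALS):
        rng_m = np.random.default_rng(streams[2 + len(METALS) + k])
        eta = rng_m.normal(0.0, config.baf_residual_sigma, size=n)
        vals = np.full(n, alphas[m]) + eta
        for i, (soil, sp) in enumerate(zip(soils, species_seq)):
            x = {"pH": soil.ph, "som": soil.som, "dcb_fe": soil.dcb_fe,
                 "avail_k": soil.avail_k}
            vals[i] += sum(
                beta * (x[cov] - cov_means[cov])
                for cov, beta in config.baf_slopes[m].items()
            )
            vals[i] += config.species_offsets.get(sp, 0.0)
        ln_baf[m] = vals
    for i, (soil, sp) in enumerate(zip(soils, species_seq)):
        metals = {
            m: float(math.exp(ln_baf[m][i]) * soil.metals[m]) for m in METALS
        }
        vegetables.append(
            VegetableSample(
                sample_id=f"V{i + 1:03d}",
                species=sp,
                soil_id=soil.sample_id,
                metals=metals,
            )
        )
    return vegetables


def generate_dataset(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> PairedDataset:
    """Generate a reproducible paired dataset from (config, seed)."""
    config = config or GeneratorConfig()
    soils = generate_soils(config, seed=seed)
    vegetables = generate_vegetables(soils, config, seed=seed)
    return PairedDataset(soils=tuple(soils), vegetables=tuple(vegetables))
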