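"""Non-carcinogenic ingestion risk, deterministic and Monte Carlo.

Chronic daily intake for the vegetable-ingestion pathway:

    CDI = IR_veg(kg/day) * C_veg(fw) * EF * ED / (BW * AT)       [mg/kg/day]
    HQ  = CDI / RfD
    HI  = sum_m HQ_m

HQ > 1 (per metal) and HI >= 1 (summed) flag potential concern. With the
non-carcinogenic default AT = ED * 365, ED cancels and the dose constant
reduces to IR * EF / (BW * 365).

The Monte Carlo engine draws vegetable contents from per-metal log-normal
distributions fitted by method of moments to (mean, SD) and truncated by
rejection to the observed [min, max], then propagates each draw through
CDI -> HQ -> HI. Metals are sampled independently within an iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import METALS, ExposureScenario, VegriskError


def cdi(c_veg_fw: float, scenario: ExposureScenario) -> float:
    """Chronic daily intake, mg/kg body weight per day.

    ``scenario.ir_veg`` is in g/day and is converted to kg/day so that the
    mg/kg fresh-weight content yields a dose in mg.
    """
    if c_veg_fw < 0:
        raise VegriskError("cdi: content must be >= 0")
    ir_kg = scenario.ir_veg / 1000.0
    return ir_kg * c_veg_fw * scenario.ef * scenario.ed / (scenario.bw * scenario.at)


def hq(cdi_value: float, rfd: float) -> float:
    """Hazard quotient CDI/RfD; values above 1 flag potential concern."""
    if rfd <= 0:
        raise VegriskError("hq: reference dose must be > 0")
    return cdi_value / rfd


def hi(hq_values) -> float:
    """Hazard index: the sum of per-metal hazard quotients."""
    x = np.asarray(list(hq_values), dtype=float)
    if np.any(x < 0):
        raise VegriskError("hi: hazard quotients must be >= 0")
    return float(np.sum(x))


def is_safe(hi_value: float) -> bool:
    """HI < 1 is interpreted as safe for ingestion."""
    return hi_value < 1.0


def fit_lognormal(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments log-normal fit from arithmetic mean and SD.

    ``sigma^2 = ln(1 + (sd/mean)^2)``, ``mu = ln(mean) - sigma^2 / 2``; the
    fitted distribution's analytic mean and SD reproduce the inputs exactly.
    ``sd = 0`` gives the degenerate point mass at ``mean``.
    """
    if mean <= 0:
        raise VegriskError("fit_lognormal: mean must be > 0")
    if sd < 0:
        raise VegriskError("fit_lognormal: sd must be >= 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class ContentDistribution:
    """Fitted fresh-weight content distribution for one metal in one species.

    ``mu``/``sigma`` are the log-space location and scale from the
    method-of-moments fit; sampling truncates to [minimum, maximum].
    """

    metal: str
    species: str
    mean: float
    sd: float
    minimum: float
    maximum: float
    mu: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.minimum <= self.maximum):
            raise VegriskError(
                f"ContentDistribution {self.species}/{self.metal}: "
                "need 0 < minimum <= maximum"
            )
        mu, sigma = fit_lognormal(self.mean, self.sd)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @classmethod
    def from_values(cls, metal: str, species: str, values) -> "ContentDistribution":
        x = np.asarray(values, dtype=float)
        if x.size == 0 or np.any(x <= 0):
            raise VegriskError("from_values: need positive contents")
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        return cls(metal=metal, species=species, mean=float(np.mean(x)), sd=sd,
                   minimum=float(np.min(x)), maximum=float(np.max(x)))


def sample_contents(
    dist: ContentDistribution, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw truncated log-normal contents by rejection resampling.

    Rejection preserves the log-normal shape inside the bounds. If fewer
    than 1 in 10,000 proposals land inside [minimum, maximum], the bounds
    are treated as inconsistent with the moments and an error is raised.
    """
    if n < 1:
        raise VegriskError("sample_contents: n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dist.sigma == 0.0:
        return np.full(n, min(max(dist.mean, dist.minimum), dist.maximum))
    out = np.empty(n)
    filled = 0
    proposed = 0
    while filled < n:
        draw = rng.lognormal(dist.mu, dist.sigma, size=max(n - filled, 1000))
        proposed += draw.size
        keep = draw[(draw >= dist.minimum) & (draw <= dist.maximum)]
        take = min(keep.size, n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
        if proposed >= 10_000 and filled / proposed < 1e-4:
            raise VegriskError(
                f"sample_contents {dist.species}/{dist.metal}: acceptance "
                "probability < 1e-4; check the truncation bounds against the "
                "fitted moments"
            )
    return out


@dataclass(frozen=True)
class RiskDistribution:
    """Monte Carlo hazard-quotient draws for one receptor x species."""

    receptor: str
    species: str
    hq_draws: pd.DataFrame  # iterations x metals
    hi_draws: np.ndarray
    n_iter: int
    seed: int


@dataclass(frozen=True)
class RiskSummary:
    receptor: str
    species: str
    hq_percentile: dict[str, float]
    hi_percentile: float
    percentile: float
    contribution: dict[str, float]  # mean HQ_m / mean HI; sums to 1
    safe: bool


def _dose_constant(scenario: ExposureScenario) -> float:
    """Content-independent part of CDI: IR(kg/d) * EF * ED / (BW * AT)."""
    return (scenario.ir_veg / 1000.0) * scenario.ef * scenario.ed / (
        scenario.bw * scenario.at
    )


def deterministic_risk(
    contents: dict[str, float], scenario: ExposureScenario, species: str = "all"
) -> RiskSummary:
    """Point-estimate HQ/HI from fixed (e.g. mean) contents."""
    hqs = {m: hq(cdi(contents[m], scenario), scenario.rfd[m]) for m in METALS}
    total = hi(hqs.values())
    contrib = {m: (hqs[m] / total if total > 0 else 0.0) for m in METALS}
    return RiskSummary(
        receptor=scenario.receptor, species=species, hq_percentile=hqs,
        hi_percentile=total, percentile=1.0, contribution=contrib,
        safe=is_safe(total),
    )


def mc_risk(
    dists: list[ContentDistribution],
    scenario: ExposureScenario,
    n_iter: int = 10_000,
    seed: int = 0,
) -> RiskDistribution:
    """Monte Carlo HQ/HI for one receptor and one species.

    Each iteration draws all metal contents independently and computes
    CDI -> HQ per metal -> HI. Metal substreams are spawned from ``seed`` in
    fixed panel order, so results are reproducible and adding a metal does
    not perturb the draws of the others.
    """
    if n_iter < 1:
        raise VegriskError("mc_risk: n_iter must be >= 1")
    by_metal = {d.metal: d for d in dists}
    missing = [m for m in METALS if m not in by_metal]
    if missing:
        raise VegriskError(f"mc_risk: no content distribution for {', '.join(missing)}")
    missing_rfd = [m for m in METALS if m not in scenario.rfd]
    if missing_rfd:
        raise VegriskError(f"mc_risk: scenario lacks RfD for {', '.join(missing_rfd)}")
    species = {d.species for d in dists}
    if len(species) > 1:
        raise VegriskError("mc_risk: distributions must share one species label")
    const = _dose_constant(scenario)
    streams = np.random.SeedSequence(seed).spawn(len(METALS))
    hq_cols = {}
    for m, ss in zip(METALS, streams):
        contents = sample_contents(by_metal[m], n_iter, np.random.default_rng(ss))
        hq_cols[m] = const * contents / scenario.rfd[m]
    hq_draws = pd.DataFrame(hq_cols, columns=list(METALS))
    return RiskDistribution(
        receptor=scenario.receptor,
        species=species.pop(),
        hq_draws=hq_draws,
        hi_draws=hq_draws.to_numpy().sum(axis=1),
        n_iter=n_iter,
        seed=seed,
    )


def summarize_risk(dist: RiskDistribution, percentile: float = 0.9) -> RiskSummary:
    """Empirical percentile (linear interpolation) of HI and each HQ.

    The per-metal contribution is ``mean(HQ_m) / mean(HI)``, which sums to 1
    by construction.
    """
    if not (0 < percentile < 1):
        raise VegriskError("summarize_risk: percentile must be in (0, 1)")
    q = percentile * 100.0
    hq_p = {m: float(np.percentile(dist.hq_draws[m], q)) for m in METALS}
    hi_p = float(np.percentile(dist.hi_draws, q))
    mean_hi = float(np.mean(dist.hi_draws))
    contrib = {
        m: (float(np.mean(dist.hq_draws[m])) / mean_hi if mean_hi > 0 else 0.0)
        for m in METALS
    }
    return RiskSummary(
        receptor=dist.receptor, species=dist.species, hq_percentile=hq_p,
        hi_percentile=hi_p, percentile=percentile, contribution=contrib,
        safe=is_safe(hi_p),
    )


def risk_summary_frame(summaries: list[RiskSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"receptor": s.receptor, "species": s.species,
               "percentile": s.percentile, "hi": s.hi_percentile, "safe": s.safe}
        for m in METALS:
            row[f"hq_{m}"] = s.hq_percentile[m]
        for m in METALS:
            row[f"contrib_{m}"] = s.contribution[m]
        rows.append(row)
    return pd.DataFrame(rows)
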