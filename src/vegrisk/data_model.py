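"""Domain types shared by all pipeline stages.

Concentrations are stored unrounded: mg/kg dry weight for soils, mg/kg fresh
weight for vegetable edible parts. Display rounding happens only when report
tables are written.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Fixed metal panel and its canonical ordering for all tabular output.
METALS: tuple[str, ...] = ("Cd", "Cr", "Cu", "Pb", "V", "Zn")

#: The seven leafy-vegetable species of the study design, with sample counts.
DEFAULT_SPECIES_PLAN: tuple[tuple[str, int], ...] = (
    ("asparagus lettuce", 11),
    ("pak choi", 6),
    ("coriander", 5),
    ("flowering Chinese cabbage", 11),
    ("garland chrysanthemum", 5),
    ("garlic sprout", 8),
    ("lettuce", 5),
)


class VegriskError(Exception):
    """Base class for all package errors."""


class LoadError(VegriskError):
    """Raised when an input table fails validation; names row and field."""


class ConfigError(VegriskError):
    """Raised when a configuration file is incomplete or inconsistent."""


def _check_panel(metals: dict[str, float], owner: str) -> dict[str, float]:
    """Validate a metal panel: all six metals present, finite, > 0."""
    missing = [m for m in METALS if m not in metals]
    if missing:
        raise LoadError(f"{owner}: missing metal(s) {', '.join(missing)}")
    out: dict[str, float] = {}
    for m in METALS:
        v = float(metals[m])
        if not math.isfinite(v) or v <= 0:
            raise LoadError(
                f"{owner}: non-positive concentration for {m} ({metals[m]!r})"
            )
        out[m] = v
    return out


@dataclass(frozen=True)
class SoilSample:
    """One topsoil record: physicochemical covariates + total-metal panel.

    pH is dimensionless; som (soil organic matter), dcb_fe, dcb_al
    (dithionite-citrate-bicarbonate extractable Fe/Al oxides) are g/kg;
    available N/P/K are mg/kg; metals are total contents in mg/kg dry weight.
    """

    sample_id: str
    ph: float
    som: float
    dcb_fe: float
    dcb_al: float
    avail_n: float
    avail_p: float
    avail_k: float
    metals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.ph < 14):
            raise LoadError(f"soil {self.sample_id}: pH {self.ph} outside (0, 14)")
        for name in ("som", "dcb_fe", "dcb_al", "avail_n", "avail_p", "avail_k"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise LoadError(f"soil {self.sample_id}: {name} = {v} is negative")
        object.__setattr__(
            self, "metals", _check_panel(self.metals, f"soil {self.sample_id}")
        )


@dataclass(frozen=True)
class VegetableSample:
    """One edible-part record: species, fresh-weight metal panel, paired soil id."""

    sample_id: str
    species: str
    soil_id: str
    metals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "metals", _check_panel(self.metals, f"vegetable {self.sample_id}")
        )


@dataclass(frozen=True)
class PairedDataset:
    """A validated collection of soils plus vegetables referencing them."""

    soils: tuple[SoilSample, ...]
    vegetables: tuple[VegetableSample, ...]

    def __post_init__(self) -> None:
        soil_ids = [s.sample_id for s in self.soils]
        if len(set(soil_ids)) != len(soil_ids):
            dup = sorted({i for i in soil_ids if soil_ids.count(i) > 1})
            raise LoadError(f"duplicate soil sample_id(s): {', '.join(dup)}")
        veg_ids = [v.sample_id for v in self.vegetables]
        if len(set(veg_ids)) != len(veg_ids):
            dup = sorted({i for i in veg_ids if veg_ids.count(i) > 1})
            raise LoadError(f"duplicate vegetable sample_id(s): {', '.join(dup)}")
        known = set(soil_ids)
        for v in self.vegetables:
            if v.soil_id not in known:
                raise LoadError(
                    f"vegetable {v.sample_id}: soil_id {v.soil_id!r} "
                    "not present in the soil table"
                )

    def soil_for(self, veg: VegetableSample) -> SoilSample:
        return self.soil_index()[veg.soil_id]

    def soil_index(self) -> dict[str, SoilSample]:
        return {s.sample_id: s for s in self.soils}


@dataclass(frozen=True)
class ReferenceTables:
    """Regulatory/geochemical reference values.

    background: geochemical background value (BV) per metal, mg/kg soil.
    screening: soil screening value (SV) per metal, mg/kg (agricultural-land
        risk standard; vanadium uses the Canadian soil-quality guideline).
    veg_mpl: maximum permissible level in vegetables, mg/kg fresh weight,
        defined only for metals with a food-safety limit.
    igeo_classes: ordered (upper_bound, label) ladder for the
        geo-accumulation index; bounds strictly increasing, last bound may be
        +inf.
    sv_notes: optional provenance flag per metal (e.g. "canadian_guideline").
    """

    background: dict[str, float]
    screening: dict[str, float]
    veg_mpl: dict[str, float]
    igeo_classes: tuple[tuple[float, str], ...]
    sv_notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table_name, table in (
            ("background", self.background),
            ("screening", self.screening),
        ):
            missing = [m for m in METALS if m not in table]
            if missing:
                raise ConfigError(
                    f"reference table {table_name!r} missing metal(s): "
                    + ", ".join(missing)
                )
            for m, v in table.items():
                if not v > 0:
                    raise ConfigError(f"{table_name}[{m}] = {v} must be > 0")
        for m, v in self.veg_mpl.items():
            if not v > 0:
                raise ConfigError(f"veg_mpl[{m}] = {v} must be > 0")
        bounds = [b for b, _ in self.igeo_classes]
        if not bounds:
            raise ConfigError("igeo_classes must be non-empty")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ConfigError("igeo class bounds must be strictly increasing")


@dataclass(frozen=True)
class ExposureScenario:
    """Receptor exposure parameters for the vegetable-ingestion pathway.

    ir_veg: vegetable intake, g/day fresh weight (converted to kg/day inside
        dose formulas, since contents are mg per kg).
    ef: exposure frequency, days/year; ed: exposure duration, years;
    bw: body weight, kg; at: averaging time, days (defaults to ed*365 for
        non-carcinogenic effects when not given); rfd: oral reference dose
        per metal, mg/kg/day.
    """

    receptor: str
    ir_veg: float
    ef: float
    ed: float
    bw: float
    rfd: dict[str, float]
    at: float | None = None

    def __post_init__(self) -> None:
        if self.at is None:
            object.__setattr__(self, "at", self.ed * 365.0)
        for name in ("ir_veg", "ef", "ed", "bw", "at"):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigError(
                    f"scenario {self.receptor!r}: {name} = {v} must be > 0"
                )
        missing = [m for m in METALS if m not in self.rfd]
        if missing:
            raise ConfigError(
                f"scenario {self.receptor!r}: rfd table missing metal(s): "
                + ", ".join(missing)
            )
        for m, v in self.rfd.items():
            if not v > 0:
                raise ConfigError(f"scenario {self.receptor!r}: rfd[{m}] must be > 0")


def dry_to_fresh(c_dry: float, moisture_fraction: float) -> float:
    """Convert a dry-weight content to fresh weight.

    ``c_fresh = c_dry * (1 - moisture_fraction)``. Never applied implicitly:
    vegetable inputs are taken as fresh-weight concentrations.
    """
    if not (0 <= moisture_fraction < 1):
        raise ValueError("moisture_fraction must be in [0, 1)")
    return c_dry * (1.0 - moisture_fraction)
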