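"""Shipped default configuration.

Reference values (background BV, screening SV, vegetable maximum permissible
levels) are the regional/regulatory values of the study setting: agricultural
soils around vanadium-bearing stone-coal smelters in western Hunan, the
GB 15618-2018 agricultural-land screening standard (Canadian soil-quality
guideline for V, which GB 15618 does not cover), and GB 2762-2017 food limits.

Exposure parameters and oral reference doses are NOT study-reported values:
they are standard exposure-handbook / US-EPA defaults, flagged
``provenance: non-paper`` in the emitted config, chosen so that the
child/adult dose ratio (IR/BW) of ~1.76 matches what published
receptor-stratified hazard-quotient tables for this pathway imply.
"""

from __future__ import annotations

import copy
import math
from typing import Any

import yaml

from .data_model import ExposureScenario, ReferenceTables

# Müller geo-accumulation ladder; bounds are upper bounds of half-open
# intervals (lower < Igeo <= upper), last class open above.
IGEO_LADDER: tuple[tuple[float, str], ...] = (
    (0.0, "unpolluted"),
    (1.0, "unpolluted to moderately contaminated"),
    (2.0, "moderately contaminated"),
    (3.0, "moderately to heavily contaminated"),
    (4.0, "heavily contaminated"),
    (5.0, "heavily to extremely contaminated"),
    (math.inf, "extremely contaminated"),
)

DEFAULT_CONFIG: dict[str, Any] = {
    "references": {
        # Regional geochemical background values, mg/kg dry soil.
        "background": {"Cd": 0.41, "Cr": 33.9, "Cu": 8.56, "Pb": 32.7,
                       "V": 95.6, "Zn": 118.0},
        # Soil screening values, mg/kg dry soil.
        "screening": {"Cd": 0.30, "Cr": 150.0, "Cu": 50.0, "Pb": 90.0,
                      "V": 130.0, "Zn": 200.0},
        "screening_notes": {"V": "canadian_guideline"},
        # Food-safety maximum permissible levels, mg/kg fresh weight;
        # only Cd, Pb, Cr carry limits for leafy vegetables.
        "veg_mpl": {"Cd": 0.20, "Pb": 0.30, "Cr": 1.0},
    },
    "scenarios": {
        "adult": {
            "ir_veg": 345.0,   # g/day fresh weight
            "ef": 365.0,       # days/year
            "ed": 30.0,        # years
            "bw": 61.8,        # kg
            "rfd": {"Cd": 1.0e-3, "Cr": 3.0e-3, "Cu": 4.0e-2,
                    "Pb": 3.5e-3, "V": 7.0e-3, "Zn": 0.3},
            "provenance": "non-paper",
        },
        "child": {
            "ir_veg": 231.5,
            "ef": 365.0,
            "ed": 6.0,
            "bw": 23.6,
            "rfd": {"Cd": 1.0e-3, "Cr": 3.0e-3, "Cu": 4.0e-2,
                    "Pb": 3.5e-3, "V": 7.0e-3, "Zn": 0.3},
            "provenance": "non-paper",
        },
    },
}


def default_config() -> dict[str, Any]:
    """A deep copy of the shipped default configuration mapping."""
    return copy.deepcopy(DEFAULT_CONFIG)


def default_references() -> ReferenceTables:
    refs = DEFAULT_CONFIG["references"]
    return ReferenceTables(
        background=dict(refs["background"]),
        screening=dict(refs["screening"]),
        veg_mpl=dict(refs["veg_mpl"]),
        igeo_classes=IGEO_LADDER,
        sv_notes=dict(refs.get("screening_notes", {})),
    )


def default_scenarios() -> list[ExposureScenario]:
    out = []
    for name, sc in DEFAULT_CONFIG["scenarios"].items():
        out.append(
            ExposureScenario(
                receptor=name,
                ir_veg=sc["ir_veg"],
                ef=sc["ef"],
                ed=sc["ed"],
                bw=sc["bw"],
                rfd=dict(sc["rfd"]),
                at=sc.get("at"),
            )
        )
    return out


def dump_default_config(path: str) -> None:
    """Write the shipped defaults as a YAML file a user can edit."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(default_config(), fh, sort_keys=False)
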