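"""Delimited-table readers/writers and configuration loading.

Tables are comma-separated, UTF-8, "." decimal, mandatory header row.
Soil columns: ``sample_id, pH, som, dcb_fe, dcb_al, avail_n, avail_p,
avail_k, Cd, Cr, Cu, Pb, V, Zn``.  Vegetable columns: ``sample_id, species,
soil_id, Cd, Cr, Cu, Pb, V, Zn``.
"""

from __future__ import annotations

import logging
import os
from typing import Any

import pandas as pd
import yaml

from .data_model import (
    METALS,
    ConfigError,
    ExposureScenario,
    LoadError,
    PairedDataset,
    ReferenceTables,
    SoilSample,
    VegetableSample,
)
from .defaults import IGEO_LADDER, default_config

log = logging.getLogger(__name__)

SOIL_COVARIATES = ("pH", "som", "dcb_fe", "dcb_al", "avail_n", "avail_p", "avail_k")
SOIL_COLUMNS = ("sample_id",) + SOIL_COVARIATES + METALS
VEG_COLUMNS = ("sample_id", "species", "soil_id") + METALS


def _read_table(path: str, required: tuple[str, ...], kind: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise LoadError(f"{kind} table not found: {path}")
    df = pd.read_csv(path, dtype={"sample_id": str, "soil_id": str, "species": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{kind} table {path}: missing column(s) {', '.join(missing)}")
    return df


def _numeric(row: pd.Series, col: str, kind: str, row_id: str) -> float:
    try:
        return float(row[col])
    except (TypeError, ValueError) as exc:
        raise LoadError(
            f"{kind} row {row_id!r}, field {col!r}: unparseable numeric "
            f"{row[col]!r}"
        ) from exc


def read_paired_dataset(soil_path: str, veg_path: str) -> PairedDataset:
    """Load and cross-validate a paired soil-vegetable dataset.

    Every vegetable's ``soil_id`` must resolve to exactly one soil record;
    ids must be unique within each table; all concentrations must be > 0.
    Errors name the offending row and field.
    """
    soil_df = _read_table(soil_path, SOIL_COLUMNS, "soil")
    veg_df = _read_table(veg_path, VEG_COLUMNS, "vegetable")

    soils = []
    for _, row in soil_df.iterrows():
        sid = str(row["sample_id"])
        soils.append(
            SoilSample(
                sample_id=sid,
                ph=_numeric(row, "pH", "soil", sid),
                som=_numeric(row, "som", "soil", sid),
                dcb_fe=_numeric(row, "dcb_fe", "soil", sid),
                dcb_al=_numeric(row, "dcb_al", "soil", sid),
                avail_n=_numeric(row, "avail_n", "soil", sid),
                avail_p=_numeric(row, "avail_p", "soil", sid),
                avail_k=_numeric(row, "avail_k", "soil", sid),
                metals={m: _numeric(row, m, "soil", sid) for m in METALS},
            )
        )
    vegetables = []
    for _, row in veg_df.iterrows():
        vid = str(row["sample_id"])
        vegetables.append(
            VegetableSample(
                sample_id=vid,
                species=str(row["species"]),
                soil_id=str(row["soil_id"]),
                metals={m: _numeric(row, m, "vegetable", vid) for m in METALS},
            )
        )
    return PairedDataset(soils=tuple(soils), vegetables=tuple(vegetables))


def soils_frame(dataset: PairedDataset) -> pd.DataFrame:
    rows = [
        {
            "sample_id": s.sample_id,
            "pH": s.ph,
            "som": s.som,
            "dcb_fe": s.dcb_fe,
            "dcb_al": s.dcb_al,
            "avail_n": s.avail_n,
            "avail_p": s.avail_p,
            "avail_k": s.avail_k,
            **{m: s.metals[m] for m in METALS},
        }
        for s in dataset.soils
    ]
    return pd.DataFrame(rows, columns=list(SOIL_COLUMNS))


def vegetables_frame(dataset: PairedDataset) -> pd.DataFrame:
    rows = [
        {
            "sample_id": v.sample_id,
            "species": v.species,
            "soil_id": v.soil_id,
            **{m: v.metals[m] for m in METALS},
        }
        for v in dataset.vegetables
    ]
    return pd.DataFrame(rows, columns=list(VEG_COLUMNS))


def write_paired_dataset(dataset: PairedDataset, soil_path: str, veg_path: str) -> None:
    """Write soil and vegetable tables at full precision (round-trip safe)."""
    # pandas' default float repr is shortest-round-trip, so values survive
    soils_frame(dataset).to_csv(soil_path, index=False)
    vegetables_frame(dataset).to_csv(veg_path, index=False)


def load_config(path: str | None = None) -> tuple[ReferenceTables, list[ExposureScenario]]:
    """Load reference tables and exposure scenarios from a YAML config.

    With ``path=None`` the shipped defaults are returned. A user config is
    merged over the defaults section-by-section, so a partial file that
    only overrides, say, ``scenarios.child.bw`` is valid.
    """
    cfg = default_config()
    if path is not None:
        if not os.path.exists(path):
            raise ConfigError(f"config file not found: {path}")
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config {path}: top level must be a mapping")
        _deep_merge(cfg, user)

    refs_cfg = cfg.get("references", {})
    for table in ("background", "screening"):
        got = refs_cfg.get(table, {})
        missing = [m for m in METALS if m not in got]
        if missing:
            raise ConfigError(
                f"references.{table}: missing metal(s) {', '.join(missing)}"
            )
    ladder = refs_cfg.get("igeo_classes")
    if ladder is None:
        igeo_classes = IGEO_LADDER
    else:
        igeo_classes = tuple(
            (float("inf") if str(b).lower() in ("inf", ".inf") else float(b), str(lbl))
            for b, lbl in (tuple(entry) for entry in ladder)
        )
    references = ReferenceTables(
        background={m: float(refs_cfg["background"][m]) for m in METALS},
        screening={m: float(refs_cfg["screening"][m]) for m in METALS},
        veg_mpl={m: float(v) for m, v in refs_cfg.get("veg_mpl", {}).items()},
        igeo_classes=igeo_classes,
        sv_notes=dict(refs_cfg.get("screening_notes", {})),
    )

    scenarios = []
    for name, sc in cfg.get("scenarios", {}).items():
        for key in ("ir_veg", "ef", "ed", "bw", "rfd"):
            if key not in sc:
                raise ConfigError(f"scenarios.{name}: missing key {key!r}")
        rfd = sc["rfd"]
        missing = [m for m in METALS if m not in rfd]
        if missing:
            raise ConfigError(
                f"scenarios.{name}.rfd: missing metal(s) {', '.join(missing)}"
            )
        scenarios.append(
            ExposureScenario(
                receptor=str(name),
                ir_veg=float(sc["ir_veg"]),
                ef=float(sc["ef"]),
                ed=float(sc["ed"]),
                bw=float(sc["bw"]),
                rfd={m: float(rfd[m]) for m in METALS},
                at=float(sc["at"]) if sc.get("at") is not None else None,
            )
        )
    if not scenarios:
        raise ConfigError("config defines no exposure scenarios")
    return references, scenarios


def _deep_merge(base: dict[str, Any], override: dict[str, Any]) -> None:
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_merge(base[key], value)
        else:
            base[key] = value


def write_report_tables(results: dict[str, pd.DataFrame], out_dir: str) -> list[str]:
    """Write one CSV per result family into ``out_dir``.

    Keys of ``results`` become file names (``<key>.csv``). Column order is
    preserved as given; rounding, if any, is the caller's concern. Empty
    frames are written headers-only with a warning.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for family, frame in results.items():
        path = os.path.join(out_dir, f"{family}.csv")
        if frame.empty:
            log.warning("result family %r is empty; writing headers only", family)
        frame.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    return written
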