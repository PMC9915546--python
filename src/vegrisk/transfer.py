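"""Soil-to-vegetable transfer.

Bioaccumulation factors (BAF = fresh-weight edible-part content over paired
soil total content), species-level aggregation, food-limit screening, and
Pearson correlation of BAFs with soil covariates and soil totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    METALS,
    PairedDataset,
    ReferenceTables,
    VegetableSample,
    VegriskError,
)

#: Soil covariates a BAF can be correlated against, plus the pseudo-covariate
#: "soil_total" (the soil content of the same metal).
BAF_COVARIATES = ("pH", "som", "dcb_fe", "dcb_al", "avail_n", "avail_p",
                  "avail_k", "soil_total")


@dataclass(frozen=True)
class BafRecord:
    vegetable_id: str
    species: str
    metal: str
    baf: float
    c_veg_fw: float
    c_soil: float


@dataclass(frozen=True)
class BafSummary:
    species: str  # "all" for the pooled grand mean
    metal: str
    mean_baf: float
    n: int
    singleton: bool = False  # n == 1 groups are carried but flagged


@dataclass(frozen=True)
class BafCorrelation:
    metal: str
    covariate: str
    r: float
    p: float


def compute_baf(dataset: PairedDataset) -> list[BafRecord]:
    """One BAF record per vegetable x metal; the ratio is exact."""
    soil_index = dataset.soil_index()
    records = []
    for veg in dataset.vegetables:
        soil = soil_index[veg.soil_id]
        for m in METALS:
            records.append(
                BafRecord(
                    vegetable_id=veg.sample_id,
                    species=veg.species,
                    metal=m,
                    baf=veg.metals[m] / soil.metals[m],
                    c_veg_fw=veg.metals[m],
                    c_soil=soil.metals[m],
                )
            )
    return records


def summarize_baf(
    records: list[BafRecord], by_species: bool = False, geometric: bool = False
) -> list[BafSummary]:
    """Mean BAF per metal, pooled or per species.

    The default aggregate is the arithmetic mean; ``geometric=True`` gives
    the geometric mean (BAF distributions are right-skewed).
    """
    if not records:
        raise VegriskError("summarize_baf: no records")
    mean = (lambda v: float(np.exp(np.mean(np.log(v))))) if geometric else (
        lambda v: float(np.mean(v))
    )
    groups: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        key = (rec.species if by_species else "all", rec.metal)
        groups.setdefault(key, []).append(rec.baf)
    return [
        BafSummary(species=sp, metal=m, mean_baf=mean(v), n=len(v),
                   singleton=len(v) == 1)
        for (sp, m), v in groups.items()
    ]


def mpl_exceedance(
    vegetables: list[VegetableSample], references: ReferenceTables
) -> dict[str, float | None]:
    """Strict-exceedance fraction of vegetable contents over each food limit.

    Metals with no maximum permissible level are reported as ``None``
    (undefined), never as zero.
    """
    if not vegetables:
        raise VegriskError("mpl_exceedance: no vegetable samples")
    out: dict[str, float | None] = {}
    for m in METALS:
        mpl = references.veg_mpl.get(m)
        if mpl is None:
            out[m] = None
            continue
        contents = np.array([v.metals[m] for v in vegetables])
        out[m] = float(np.mean(contents > mpl))
    return out


def baf_property_correlation(
    dataset: PairedDataset,
    records: list[BafRecord],
    log_baf: bool = False,
    species: str | None = None,
) -> list[BafCorrelation]:
    """Pearson r of per-metal BAFs against soil covariates and soil totals.

    Pools all species by default; pass ``species`` to stratify. Computed on
    untransformed BAFs unless ``log_baf``. Zero-variance covariates give
    NaN r (undefined), not an error.
    """
    soil_index = dataset.soil_index()
    veg_index = {v.sample_id: v for v in dataset.vegetables}
    out = []
    for m in METALS:
        recs = [r for r in records if r.metal == m
                and (species is None or r.species == species)]
        if len(recs) < 3:
            raise VegriskError(
                f"baf_property_correlation: need >= 3 paired records for {m}"
            )
        baf = np.array([r.baf for r in recs])
        if log_baf:
            baf = np.log(baf)
        soils = [soil_index[veg_index[r.vegetable_id].soil_id] for r in recs]
        covs = {
            "pH": [s.ph for s in soils],
            "som": [s.som for s in soils],
            "dcb_fe": [s.dcb_fe for s in soils],
            "dcb_al": [s.dcb_al for s in soils],
            "avail_n": [s.avail_n for s in soils],
            "avail_p": [s.avail_p for s in soils],
            "avail_k": [s.avail_k for s in soils],
            "soil_total": [s.metals[m] for s in soils],
        }
        for cov_name in BAF_COVARIATES:
            x = np.asarray(covs[cov_name], dtype=float)
            # ptp==0 is the exact-constancy test (std can round to ~1e-16)
            if np.ptp(x) == 0 or np.ptp(baf) == 0:
                out.append(BafCorrelation(m, cov_name, np.nan, np.nan))
                continue
            res = stats.pearsonr(baf, x)
            out.append(
                BafCorrelation(m, cov_name, float(res.statistic), float(res.pvalue))
            )
    return out


def baf_records_frame(records: list[BafRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def baf_summary_frame(summaries: list[BafSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def baf_correlation_frame(correlations: list[BafCorrelation]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in correlations])
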