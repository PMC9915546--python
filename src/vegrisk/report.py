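"""Report-table construction and the end-to-end pipeline.

Each stage returns tidy :class:`pandas.DataFrame` families keyed by a stable
name; :func:`vegrisk.io.write_report_tables` turns them into CSVs. The
``run_all`` sequence mirrors the study workflow: soil summary -> Igeo and
guideline exceedance -> source statistics -> bioaccumulation -> deterministic
and Monte Carlo risk for every configured receptor.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__, contamination, risk, transfer
from .data_model import (
    METALS,
    ExposureScenario,
    PairedDataset,
    ReferenceTables,
)

log = logging.getLogger(__name__)


def summary_tables(dataset: PairedDataset) -> dict[str, pd.DataFrame]:
    return {"summary_soil": contamination.summarize_soils(dataset.soils)}


def igeo_tables(
    dataset: PairedDataset, references: ReferenceTables
) -> dict[str, pd.DataFrame]:
    results = contamination.igeo_results(list(dataset.soils), references)
    per_sample = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in dataset.soils],
            **{r.metal: r.igeo_values for r in results},
        }
    )
    per_metal = pd.DataFrame(
        [
            {
                "metal": r.metal,
                "mean_igeo": r.mean_igeo,
                "mean_class": contamination.classify_igeo(
                    r.mean_igeo, references.igeo_classes
                ),
                **{f"frac[{label}]": r.class_fractions.get(label, 0.0)
                   for _, label in references.igeo_classes},
            }
            for r in results
        ]
    )
    exceed = pd.DataFrame(
        [
            {
                "metal": m,
                "screening_value": references.screening[m],
                "note": references.sv_notes.get(m, ""),
                "exceedance_fraction": contamination.exceedance_fraction(
                    [s.metals[m] for s in dataset.soils], references.screening[m]
                ),
            }
            for m in METALS
        ]
    )
    return {"igeo_samples": per_sample, "igeo_metals": per_metal,
            "soil_exceedance": exceed}


def source_tables(dataset: PairedDataset, n_components: int = 2,
                  log_scale: bool = False) -> dict[str, pd.DataFrame]:
    stats_ = contamination.metal_pca(
        list(dataset.soils), n_components=n_components, log_scale=log_scale
    )
    corr = stats_.correlation.reset_index(names="metal")
    pvals = stats_.p_values.reset_index(names="metal")
    comps = list(stats_.loadings.columns)
    pca = stats_.loadings.reset_index(names="metal")
    pca = pca.merge(
        stats_.contributions.add_prefix("contrib_").reset_index(names="metal"),
        on="metal",
    )
    variance = pd.DataFrame(
        {"component": comps, "explained_variance_pct": stats_.explained_variance}
    )
    return {"metal_correlation": corr, "metal_correlation_p": pvals,
            "pca_loadings": pca, "pca_variance": variance}


def baf_tables(
    dataset: PairedDataset, references: ReferenceTables, log_baf: bool = False
) -> dict[str, pd.DataFrame]:
    records = transfer.compute_baf(dataset)
    mpl = transfer.mpl_exceedance(list(dataset.vegetables), references)
    mpl_frame = pd.DataFrame(
        [
            {
                "metal": m,
                "mpl": references.veg_mpl.get(m, np.nan),
                "exceedance_fraction": np.nan if mpl[m] is None else mpl[m],
                "defined": mpl[m] is not None,
            }
            for m in METALS
        ]
    )
    return {
        "baf_records": transfer.baf_records_frame(records),
        "baf_summary": transfer.baf_summary_frame(
            transfer.summarize_baf(records, by_species=False)
        ),
        "baf_summary_species": transfer.baf_summary_frame(
            transfer.summarize_baf(records, by_species=True)
        ),
        "mpl_exceedance": mpl_frame,
        "baf_correlation": transfer.baf_correlation_frame(
            transfer.baf_property_correlation(dataset, records, log_baf=log_baf)
        ),
    }


def risk_tables(
    dataset: PairedDataset,
    scenarios: list[ExposureScenario],
    n_iter: int = 10_000,
    seed: int = 0,
    percentile: float = 0.9,
) -> dict[str, pd.DataFrame]:
    """Deterministic (mean-content) and Monte Carlo risk per receptor x species.

    Content distributions are fitted per species from the raw vegetable
    records (method-of-moments log-normal, truncated at the observed
    min/max). Content draws are shared across receptors: the same seed is
    used for every scenario, so receptors differ only through their exposure
    constants.
    """
    species_groups: dict[str, list] = {}
    for v in dataset.vegetables:
        species_groups.setdefault(v.species, []).append(v)
    det_rows, mc_rows = [], []
    for scenario in scenarios:
        for sp, vegs in sorted(species_groups.items()):
            dists = [
                risk.ContentDistribution.from_values(
                    m, sp, [v.metals[m] for v in vegs]
                )
                for m in METALS
            ]
            mean_contents = {m: d.mean for m, d in zip(METALS, dists)}
            det_rows.append(risk.deterministic_risk(mean_contents, scenario, sp))
            mc = risk.mc_risk(dists, scenario, n_iter=n_iter, seed=seed)
            mc_rows.append(risk.summarize_risk(mc, percentile=percentile))
    return {
        "risk_deterministic": risk.risk_summary_frame(det_rows),
        "risk_mc": risk.risk_summary_frame(mc_rows),
    }


def write_manifest(
    out_dir: str, seed: int | None, config_path: str | None
) -> str:
    """Write the run manifest (command line, config hash, seed, version)."""
    cfg_hash = ""
    if config_path and os.path.exists(config_path):
        with open(config_path, "rb") as fh:
            cfg_hash = hashlib.sha256(fh.read()).hexdigest()
    manifest = {
        "command_line": " ".join(sys.argv),
        "config_hash": cfg_hash,
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def run_all(
    dataset: PairedDataset,
    references: ReferenceTables,
    scenarios: list[ExposureScenario],
    n_iter: int = 10_000,
    seed: int = 0,
    percentile: float = 0.9,
) -> dict[str, pd.DataFrame]:
    """Execute every stage and return all report families."""
    tables: dict[str, pd.DataFrame] = {}
    for stage, builder in (
        ("summarize", lambda: summary_tables(dataset)),
        ("igeo", lambda: igeo_tables(dataset, references)),
        ("sources", lambda: source_tables(dataset)),
        ("baf", lambda: baf_tables(dataset, references)),
        ("risk", lambda: risk_tables(dataset, scenarios, n_iter=n_iter,
                                     seed=seed, percentile=percentile)),
    ):
        log.info("running stage %s", stage)
        try:
            tables.update(builder())
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return tables
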