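"""Soil contamination assessment.

Summary statistics, the geo-accumulation index with its contamination-class
ladder, guideline-exceedance screening, and source-apportionment statistics
(Pearson correlation matrix and PCA of the soil metal panel).

The geo-accumulation index compares a measured soil content against 1.5x the
geochemical background:

    Igeo = log2( C_soil / (1.5 * B_soil) )

where the factor 1.5 absorbs natural fluctuation of the background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .data_model import METALS, ReferenceTables, SoilSample, VegriskError


@dataclass(frozen=True)
class SummaryStats:
    """Per-variable summary: order statistics, arithmetic and geometric moments.

    ``mean_geo = exp(mean(ln x))``; ``sd_geo = exp(sd(ln x))`` is the
    dimensionless multiplicative geometric SD; ``cv = sd_arith / mean_arith``.
    """

    n: int
    minimum: float
    median: float
    maximum: float
    mean_arith: float
    sd_arith: float
    mean_geo: float
    sd_geo: float
    cv: float


@dataclass(frozen=True)
class IgeoResult:
    metal: str
    igeo_values: np.ndarray
    mean_igeo: float
    class_fractions: dict[str, float]


@dataclass(frozen=True)
class SourceStats:
    """Correlation matrix with p-values plus PCA decomposition of soil metals."""

    correlation: pd.DataFrame
    p_values: pd.DataFrame
    explained_variance: np.ndarray  # percent per component, non-increasing
    loadings: pd.DataFrame          # metals x components
    contributions: pd.DataFrame     # percent, columns sum to 100


def summarize(values) -> SummaryStats:
    """Summary statistics of strictly positive concentrations (or pH values).

    SDs are sample standard deviations (ddof=1); with n=1 both SDs are 0 and
    the geometric SD is 1.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise VegriskError("summarize: empty input")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise VegriskError("summarize: all values must be finite and > 0")
    logs = np.log(x)
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    sd_log = float(np.std(logs, ddof=1)) if x.size > 1 else 0.0
    mean = float(np.mean(x))
    return SummaryStats(
        n=int(x.size),
        minimum=float(np.min(x)),
        median=float(np.median(x)),
        maximum=float(np.max(x)),
        mean_arith=mean,
        sd_arith=sd,
        mean_geo=float(np.exp(np.mean(logs))),
        sd_geo=float(np.exp(sd_log)),
        cv=sd / mean,
    )


def igeo(c_soil, bv: float):
    """Geo-accumulation index, ``log2(c_soil / (1.5 * bv))``.

    Accepts a scalar or array of soil contents; both must be > 0.
    """
    c = np.asarray(c_soil, dtype=float)
    if np.any(c <= 0) or bv <= 0:
        raise VegriskError("igeo: soil content and background value must be > 0")
    out = np.log2(c / (1.5 * bv))
    return float(out) if np.isscalar(c_soil) else out


def classify_igeo(value: float, ladder=None) -> str:
    """Map an index value to its contamination class.

    Classes are half-open intervals (lower < Igeo <= upper); values above the
    last finite bound take the top label. Total over the reals.
    """
    if ladder is None:
        from .defaults import IGEO_LADDER as ladder  # noqa: N811
    for upper, label in ladder:
        if value <= upper:
            return label
    return ladder[-1][1]


def igeo_results(
    soils: list[SoilSample], references: ReferenceTables
) -> list[IgeoResult]:
    """Per-metal Igeo values, mean Igeo, and class fractions over a dataset."""
    out = []
    for m in METALS:
        vals = igeo(np.array([s.metals[m] for s in soils]), references.background[m])
        labels = [classify_igeo(v, references.igeo_classes) for v in vals]
        fractions = {
            label: labels.count(label) / len(labels)
            for _, label in references.igeo_classes
            if label in labels
        }
        out.append(
            IgeoResult(
                metal=m,
                igeo_values=vals,
                mean_igeo=float(np.mean(vals)),
                class_fractions=fractions,
            )
        )
    return out


def exceedance_fraction(values, threshold: float) -> float:
    """Fraction of values strictly greater than the threshold (ties comply)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise VegriskError("exceedance_fraction: empty input")
    if threshold <= 0:
        raise VegriskError("exceedance_fraction: threshold must be > 0")
    return float(np.mean(x > threshold))


def _pairwise_pearson(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    cols = list(frame.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            xa, xb = frame[a].to_numpy(), frame[b].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                rij, pij = np.nan, np.nan  # zero-variance column: undefined r
            else:
                res = stats.pearsonr(xa, xb)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p


def metal_correlation(
    soils: list[SoilSample], log_scale: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r (and two-sided p) between soil metal contents.

    Computed on raw concentrations by default; ``log_scale=True`` uses
    ln-transformed contents. Zero-variance columns yield NaN, not an error.
    """
    if len(soils) < 3:
        raise VegriskError("metal_correlation: need at least 3 samples")
    frame = pd.DataFrame({m: [s.metals[m] for s in soils] for m in METALS})
    if log_scale:
        frame = np.log(frame)
    return _pairwise_pearson(frame)


def metal_pca(
    soils: list[SoilSample], n_components: int = 2, log_scale: bool = False
) -> SourceStats:
    """PCA of z-score-standardized soil metal contents.

    Loadings are the principal-axis weights (rows of the rotation matrix);
    the per-metal contribution to a component is its squared loading as a
    percentage of that component's squared-loading total, so each component's
    contributions sum to 100.
    """
    if len(soils) < n_components + 1:
        raise VegriskError("metal_pca: need n >= n_components + 1 samples")
    frame = pd.DataFrame({m: [s.metals[m] for s in soils] for m in METALS})
    if log_scale:
        frame = np.log(frame)
    sd = frame.std(ddof=1)
    constant = [m for m in METALS if np.ptp(frame[m].to_numpy()) == 0]
    if constant:
        raise VegriskError(f"metal_pca: constant column(s): {', '.join(constant)}")
    z = (frame - frame.mean()) / sd
    pca = PCA(n_components=n_components)
    pca.fit(z.to_numpy())
    comps = [f"PC{i + 1}" for i in range(n_components)]
    loadings = pd.DataFrame(pca.components_.T, index=list(METALS), columns=comps)
    sq = loadings**2
    contributions = 100.0 * sq / sq.sum(axis=0)
    corr, pvals = metal_correlation(soils, log_scale=log_scale)
    return SourceStats(
        correlation=corr,
        p_values=pvals,
        explained_variance=100.0 * pca.explained_variance_ratio_,
        loadings=loadings,
        contributions=contributions,
    )


def summarize_soils(soils: list[SoilSample]) -> pd.DataFrame:
    """Table-style summary of covariates and metal contents across a dataset."""
    rows = []
    variables = [("pH", lambda s: s.ph), ("som", lambda s: s.som),
                 ("dcb_fe", lambda s: s.dcb_fe), ("dcb_al", lambda s: s.dcb_al),
                 ("avail_n", lambda s: s.avail_n), ("avail_p", lambda s: s.avail_p),
                 ("avail_k", lambda s: s.avail_k)]
    variables += [(m, lambda s, m=m: s.metals[m]) for m in METALS]
    for name, getter in variables:
        st = summarize([getter(s) for s in soils])
        rows.append(
            {
                "variable": name, "n": st.n, "minimum": st.minimum,
                "median": st.median, "maximum": st.maximum,
                "mean_arith": st.mean_arith, "sd_arith": st.sd_arith,
                "mean_geo": st.mean_geo, "sd_geo": st.sd_geo, "cv": st.cv,
            }
        )
    return pd.DataFrame(rows)
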