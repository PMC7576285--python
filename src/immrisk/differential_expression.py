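"""Tumor-vs-normal differential expression of ICPR genes and lncRNAs.

Each feature gets a two-sided Welch (unequal-variance) t-test between the
tumor and normal sample groups.  ICPR genes are called tumor-specific at
``p < p_gene`` (default 0.05), lncRNAs at the stricter ``p < p_lnc``
(default 0.01); direction is up when the tumor mean exceeds the normal
mean.  The test is feature-level: a gene shared by two populations receives
the same statistic in both.

Benjamini-Hochberg adjusted p-values are computed and stored alongside the
raw ones but do not drive the significance flag by default; the raw
class-specific thresholds do.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import (
    GENE,
    LNCRNA,
    NORMAL,
    TUMOR,
    ExpressionMatrix,
    ImmuneGeneSets,
    PipelineConfig,
)

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class DifferentialResult:
    feature_id: str
    feature_class: str
    mean_tumor: float
    mean_normal: float
    t_stat: float
    p_value: float
    p_adjusted: float
    direction: str
    significant: bool


def test_feature(values_tumor: Sequence[float], values_normal: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch t-test for one feature.

    Degenerate case: when both groups have zero variance the test is defined
    rather than an error -- equal means give ``(0.0, 1.0)``, unequal means an
    infinite statistic with p = 0.
    """
    a = np.asarray(values_tumor, dtype=float)
    b = np.asarray(values_normal, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _welch_all(x: ExpressionMatrix) -> pd.DataFrame:
    """Vectorized Welch test over every feature of the matrix."""
    tumor = x.group_values(TUMOR).to_numpy()
    normal = x.group_values(NORMAL).to_numpy()
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("each sample group needs at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
    mt = tumor.mean(axis=1)
    mn = normal.mean(axis=1)
    # zero variance in both groups: define instead of propagating NaN
    nan = ~np.isfinite(p)
    if nan.any():
        equal = nan & (mt == mn)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        diff = nan & (mt != mn)
        t = np.where(diff, np.sign(mt - mn) * np.inf, t)
        p = np.where(diff, 0.0, p)
    return pd.DataFrame(
        {"mean_tumor": mt, "mean_normal": mn, "t": t, "p": p}, index=x.values.index
    )


def call_specific_features(
    x: ExpressionMatrix,
    sets: ImmuneGeneSets,
    cfg: PipelineConfig | None = None,
) -> tuple[dict[str, list[DifferentialResult]], list[DifferentialResult]]:
    """Call tumor-specific ICPR genes per population and tumor-specific lncRNAs.

    Returns ``(per_population, lnc_results)``: for each population, one
    result per set member present in the matrix (flagged at ``p_gene``), and
    one result per lncRNA in the matrix (flagged at ``p_lnc``).  Direction is
    ``up`` iff the tumor mean strictly exceeds the normal mean (exact ties
    labeled ``down``; such features are never significant anyway).
    """
    cfg = cfg or PipelineConfig()
    stats_df = _welch_all(x)
    sets = sets.restrict_to(x.features_of(GENE))

    gene_ids = sorted({g for genes in sets.populations.values() for g in genes})
    lnc_ids = x.features_of(LNCRNA)

    adj = pd.Series(np.nan, index=stats_df.index)
    for ids in (gene_ids, lnc_ids):
        if ids:
            adj.loc[ids] = multipletests(stats_df.loc[ids, "p"], method="fdr_bh")[1]

    def make(fid: str, fclass: str, alpha: float) -> DifferentialResult:
        row = stats_df.loc[fid]
        return DifferentialResult(
            feature_id=fid,
            feature_class=fclass,
            mean_tumor=float(row["mean_tumor"]),
            mean_normal=float(row["mean_normal"]),
            t_stat=float(row["t"]),
            p_value=float(row["p"]),
            p_adjusted=float(adj.loc[fid]),
            direction=UP if row["mean_tumor"] > row["mean_normal"] else DOWN,
            significant=bool(row["p"] < alpha),
        )

    per_population: dict[str, list[DifferentialResult]] = {}
    for name, genes in sets.populations.items():
        if not genes:
            logger.warning("population %r has no mappable genes", name)
            per_population[name] = []
            continue
        per_population[name] = [make(g, GENE, cfg.p_gene) for g in genes]
    lnc_results = [make(l, LNCRNA, cfg.p_lnc) for l in lnc_ids]
    return per_population, lnc_results


def significant_ids(results: Sequence[DifferentialResult]) -> list[str]:
    return [r.feature_id for r in results if r.significant]


def directions(per_population: Mapping[str, Sequence[DifferentialResult]],
               lnc_results: Sequence[DifferentialResult]) -> dict[str, str]:
    """Feature -> up/down map pooled over all results (feature-level, so a
    feature repeated across populations is consistent by construction)."""
    out: dict[str, str] = {}
    for results in list(per_population.values()) + [list(lnc_results)]:
        for r in results:
            out[r.feature_id] = r.direction
    return out


def population_summary(per_population: Mapping[str, Sequence[DifferentialResult]]) -> pd.DataFrame:
    """Per-population counts: tested, significant, fraction, up/down split."""
    rows = []
    for name, results in per_population.items():
        sig = [r for r in results if r.significant]
        rows.append(
            {
                "population": name,
                "n_tested": len(results),
                "n_significant": len(sig),
                "frac_significant": len(sig) / len(results) if results else float("nan"),
                "n_up": sum(r.direction == UP for r in sig),
                "n_down": sum(r.direction == DOWN for r in sig),
            }
        )
    return pd.DataFrame(rows).set_index("population")


def results_table(
    per_population: Mapping[str, Sequence[DifferentialResult]],
    lnc_results: Sequence[DifferentialResult],
) -> pd.DataFrame:
    """Long-format table of all results (population column, lncRNAs pooled)."""
    rows = []
    for pop, results in per_population.items():
        for r in results:
            rows.append((r.feature_id, r.feature_class, pop, r.mean_tumor, r.mean_normal,
                         r.t_stat, r.p_value, r.p_adjusted, r.direction, r.significant))
    for r in lnc_results:
        rows.append((r.feature_id, r.feature_class, "lncRNA", r.mean_tumor, r.mean_normal,
                     r.t_stat, r.p_value, r.p_adjusted, r.direction, r.significant))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "class", "population", "mean_tumor", "mean_normal",
                 "t", "p", "p_adj", "direction", "significant"],
    )
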