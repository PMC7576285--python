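"""Rank-based per-patient immune-risk scoring and three-group stratification.

The scoring works entirely on tumor patients and on the features (genes and
lncRNAs) of the per-population co-expression networks:

1. For each network feature, patients are ranked by its expression from
   high to low.  A patient carries an *up*-regulated feature as a risk
   feature when ranked in the last 70% (i.e. outside the top 30% block),
   and a *down*-regulated feature when ranked in the top 30% block.  The
   top block holds ``ceil(down_risk_frac * N)`` patients; expression ties
   are broken by patient id so the call is deterministic.
2. A population is a risk population for a patient when strictly more than
   ``pop_risk_frac`` (default 50%) of its network features are risk
   features for that patient.
3. Patients are stratified by their risk-population count into min-immune
   (0..group_bounds[0]), media-immune (..group_bounds[1]) and multi-immune
   groups.

Populations whose network is empty are skipped and excluded from the
population total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import TUMOR, ExpressionMatrix, PipelineConfig

logger = logging.getLogger(__name__)

MIN_IMMUNE = "min_immune"
MEDIA_IMMUNE = "media_immune"
MULTI_IMMUNE = "multi_immune"
GROUPS = (MIN_IMMUNE, MEDIA_IMMUNE, MULTI_IMMUNE)


@dataclass(frozen=True)
class RiskCall:
    patient_id: str
    population: str
    n_risk_features: int
    n_features: int
    is_risk: bool


@dataclass(frozen=True)
class RiskProfile:
    patient_id: str
    risk_population_count: int
    group: str


def _top_block_size(frac: float, n: int) -> int:
    # ceil of frac*n in exact arithmetic; the round() guards against float
    # artifacts like 0.3 * 20 -> 6.000000000000001
    return math.ceil(round(frac * n, 9))


def call_risk_features(
    x: ExpressionMatrix,
    network_features: Mapping[str, Iterable[str]],
    directions: Mapping[str, str],
    cfg: PipelineConfig | None = None,
) -> dict[str, dict[str, frozenset[str]]]:
    """Per (population, patient) risk-feature sets from expression ranks.

    ``network_features`` maps each population to the nodes of its network;
    ``directions`` gives each feature's tumor-vs-normal direction
    (``up``/``down``).  Only tumor samples are ranked.  Returns
    ``{population: {patient_id: frozenset(risk features)}}``.
    """
    cfg = cfg or PipelineConfig()
    tumor = x.group_values(TUMOR)
    patients = np.array(tumor.columns)
    n = len(patients)
    if n < 2:
        raise ValueError("need at least 2 tumor patients to rank")
    k = _top_block_size(cfg.down_risk_frac, n)

    all_features = sorted({f for feats in network_features.values() for f in feats})
    missing_dir = [f for f in all_features if f not in directions]
    if missing_dir:
        raise ValueError(f"features without a direction: {missing_dir[:10]}")
    missing_expr = [f for f in all_features if f not in tumor.index]
    if missing_expr:
        raise ValueError(f"network features absent from the matrix: {missing_expr[:10]}")

    # per feature: the set of patients carrying it as a risk feature
    risk_patients: dict[str, set[str]] = {}
    pid_order = np.argsort(patients)  # lexicographic tie-break material
    for f in all_features:
        v = tumor.loc[f].to_numpy(dtype=float)
        # order patients by expression descending, ties by patient id ascending
        order = np.lexsort((patients, -v))
        top_block = patients[order[:k]]
        if directions[f] == "up":
            risk_patients[f] = set(patients[order[k:]])
        elif directions[f] == "down":
            risk_patients[f] = set(top_block)
        else:
            raise ValueError(f"invalid direction {directions[f]!r} for feature {f!r}")

    out: dict[str, dict[str, frozenset[str]]] = {}
    for pop, feats in network_features.items():
        feats = sorted(set(feats))
        if not feats:
            logger.warning("population %r has an empty network; skipped from scoring", pop)
            continue
        per_patient: dict[str, set[str]] = {p: set() for p in patients}
        for f in feats:
            for p in risk_patients[f]:
                per_patient[p].add(f)
        out[pop] = {p: frozenset(s) for p, s in per_patient.items()}
    return out


def call_risk_populations(
    risk_features: Mapping[str, Mapping[str, frozenset[str]]],
    network_features: Mapping[str, Iterable[str]],
    cfg: PipelineConfig | None = None,
) -> list[RiskCall]:
    """One RiskCall per (patient, non-empty population).

    ``is_risk`` uses the strict majority rule: the risk-feature count must
    exceed ``pop_risk_frac`` of the population network's feature count.
    """
    cfg = cfg or PipelineConfig()
    calls: list[RiskCall] = []
    for pop in risk_features:
        n_features = len(set(network_features[pop]))
        threshold = round(cfg.pop_risk_frac * n_features, 9)
        for patient in sorted(risk_features[pop]):
            n_risk = len(risk_features[pop][patient])
            calls.append(
                RiskCall(
                    patient_id=patient,
                    population=pop,
                    n_risk_features=n_risk,
                    n_features=n_features,
                    is_risk=n_risk > threshold,
                )
            )
    return calls


def population_risk_fractions(calls: Sequence[RiskCall]) -> pd.Series:
    """Fraction of patients for which each population is a risk population."""
    df = pd.DataFrame([(c.population, c.is_risk) for c in calls], columns=["population", "is_risk"])
    return df.groupby("population")["is_risk"].mean()


def risk_matrix(calls: Sequence[RiskCall]) -> pd.DataFrame:
    """Patients x populations 0/1 indicator matrix of risk populations."""
    df = pd.DataFrame(
        [(c.patient_id, c.population, int(c.is_risk)) for c in calls],
        columns=["patient_id", "population", "is_risk"],
    )
    return df.pivot(index="patient_id", columns="population", values="is_risk")


def assign_group(risk_population_count: int, cfg: PipelineConfig | None = None,
                 n_populations: int = 17) -> str:
    """Map a risk-population count to min/media/multi-immune."""
    cfg = cfg or PipelineConfig()
    lo, hi = cfg.group_bounds
    if hi >= n_populations:
        raise ValueError("group_bounds exceed the number of populations")
    if not 0 <= risk_population_count <= n_populations:
        raise ValueError(
            f"risk-population count {risk_population_count} outside 0..{n_populations}"
        )
    if risk_population_count <= lo:
        return MIN_IMMUNE
    if risk_population_count <= hi:
        return MEDIA_IMMUNE
    return MULTI_IMMUNE


def build_profiles(calls: Sequence[RiskCall], cfg: PipelineConfig | None = None) -> list[RiskProfile]:
    """Aggregate RiskCalls into one profile per patient.

    The population total (for range checking) is the number of populations
    actually scored, i.e. those with non-empty networks.
    """
    cfg = cfg or PipelineConfig()
    n_pops = len({c.population for c in calls})
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.patient_id] = counts.get(c.patient_id, 0) + int(c.is_risk)
    return [
        RiskProfile(
            patient_id=p,
            risk_population_count=counts[p],
            group=assign_group(counts[p], cfg, n_populations=max(n_pops, cfg.group_bounds[1] + 1)),
        )
        for p in sorted(counts)
    ]


def two_group_split(profiles: Sequence[RiskProfile], boundary: int) -> tuple[list[str], list[str]]:
    """Split patients at a risk-count boundary: (count < boundary, count >= boundary).

    Supports the two-group sensitivity analyses at boundaries 6 and 7.  An
    empty side is legal but logged; survival comparison should be skipped.
    """
    if boundary <= 0:
        raise ValueError("boundary must be positive")
    low = [p.patient_id for p in profiles if p.risk_population_count < boundary]
    high = [p.patient_id for p in profiles if p.risk_population_count >= boundary]
    if not low or not high:
        logger.warning("two-group split at %d leaves one side empty", boundary)
    return low, high


def profiles_table(profiles: Sequence[RiskProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.patient_id, p.risk_population_count, p.group) for p in profiles],
        columns=["patient_id", "risk_population_count", "group"],
    )
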