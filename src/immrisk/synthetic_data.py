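"""Synthetic tumor/normal expression studies with full ground truth.

The generator emulates the statistical structure the pipeline assumes:

* a feature universe of ICPR genes (partitioned among immune cell
  populations) and lncRNAs, i.i.d. normal on the log2 scale;
* planted differentially expressed features with a mean shift of
  ``de_effect`` log2 units in tumor (direction recorded);
* planted gene-lncRNA pairs per population whose correlation is
  ``+r_planted`` in tumor and ``r_normal`` (default ``-r_planted``) in
  normal samples, with a hub-skewed assignment of pairs to genes; all
  non-planted pairs are uncorrelated;
* survival times exponential with hazard
  ``baseline_hazard * hazard_multiplier ** risk_count``, where the risk
  count is the patient's true risk-population count under the planted
  networks, with independent censoring.

Ground truth (directions, planted pairs, per-patient risk counts and
expected groups) is returned alongside the data so every pipeline stage can
be scored against what was planted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import immune_risk
from .expression_io import (
    GENE,
    LNCRNA,
    NORMAL,
    TUMOR,
    ExpressionMatrix,
    ImmuneGeneSets,
    PipelineConfig,
    write_expression,
)

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the generator.

    Defaults mirror a tumor-heavy bulk cohort: 369 tumors vs 50 adjacent
    normals, 17 immune cell populations of 24 marker genes each, 400
    lncRNAs, moderate differential expression (half the background features
    shifted by 1.5 log2 units at unit residual noise), 8 planted
    differential-coexpression pairs per population at |r| = 0.9, and a
    survival effect in which each additional risk population multiplies the
    hazard by ``hazard_multiplier`` (default 0.8: more risk populations,
    better prognosis).
    """

    n_tumor: int = 369
    n_normal: int = 50
    n_populations: int = 17
    genes_per_population: int = 24
    n_lncs: int = 400
    frac_de: float = 0.5
    de_effect: float = 1.5
    n_diffcoex_pairs: int = 8
    r_planted: float = 0.9
    r_normal: float | None = None  # None -> -r_planted
    noise_sd: float = 1.0
    base_mean: float = 6.0
    hazard_multiplier: float = 0.8
    baseline_hazard: float = 1.0 / 1500.0  # per day; median ~ 1000 days at count 0
    censor_rate: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 3 or self.n_normal < 3:
            raise ValueError("need at least 3 samples per group")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if not 0.0 < self.r_planted < 1.0:
            raise ValueError("r_planted must be in (0, 1)")
        if self.r_normal is not None and not -1.0 < self.r_normal < 1.0:
            raise ValueError("r_normal must be in (-1, 1)")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        if self.hazard_multiplier <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")
        if self.n_diffcoex_pairs > self.genes_per_population:
            raise ValueError("more planted pairs than genes per population")
        if self.n_diffcoex_pairs * self.n_populations > self.n_lncs:
            raise ValueError("more planted pairs than available lncRNAs")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**dict(d))  # type: ignore[arg-type]


@dataclass
class PlantedPair:
    population: str
    gene_id: str
    lnc_id: str
    r_tumor: float
    r_normal: float


@dataclass
class SimTruth:
    """Everything that was planted, for scoring pipeline output."""

    de_directions: dict[str, str]  # feature -> up/down, all truly DE features
    planted_pairs: list[PlantedPair]
    networks: dict[str, list[str]]  # population -> planted network nodes
    risk_counts: dict[str, int]  # tumor patient -> true risk-population count
    expected_group: dict[str, str]


def _conditional_partner(rng: np.random.Generator, g: np.ndarray, r: float) -> np.ndarray:
    """Unit-variance vector with population correlation r against ``g``."""
    return r * g + np.sqrt(1.0 - r * r) * rng.standard_normal(g.size)


def simulate_expression(cfg: SimConfig) -> tuple[ExpressionMatrix, ImmuneGeneSets, SimTruth]:
    """Generate the expression matrix (log2 scale), gene sets and truth."""
    rng = np.random.default_rng(cfg.seed)
    n_genes = cfg.n_populations * cfg.genes_per_population
    gene_ids = [f"GENE{i:04d}" for i in range(n_genes)]
    lnc_ids = [f"LNC{i:04d}" for i in range(cfg.n_lncs)]
    pop_names = [f"population_{i + 1:02d}" for i in range(cfg.n_populations)]
    tumor_ids = [f"T{i:03d}" for i in range(cfg.n_tumor)]
    normal_ids = [f"N{i:03d}" for i in range(cfg.n_normal)]

    populations = {
        pop: gene_ids[i * cfg.genes_per_population : (i + 1) * cfg.genes_per_population]
        for i, pop in enumerate(pop_names)
    }
    sets = ImmuneGeneSets(populations)

    feats = gene_ids + lnc_ids
    n_feat = len(feats)
    n_samp = cfg.n_tumor + cfg.n_normal
    values = rng.standard_normal((n_feat, n_samp))
    row = {f: i for i, f in enumerate(feats)}
    tumor_cols = slice(0, cfg.n_tumor)
    normal_cols = slice(cfg.n_tumor, n_samp)

    # planted differential-coexpression pairs: per population, pair j is
    # assigned to gene floor(log2(j+1)) -- a hub-skewed map so networks have
    # degree diversity (one gene acquires several lncRNA partners, as hub
    # genes do in real co-expression networks); each pair's lncRNA is drawn
    # conditionally on the gene so correlation is r_planted in tumor and
    # r_normal in normal while pairs sharing a gene stay non-differential
    r_t = cfg.r_planted
    r_n = -cfg.r_planted if cfg.r_normal is None else cfg.r_normal
    planted_pairs: list[PlantedPair] = []
    networks: dict[str, list[str]] = {}
    lnc_cursor = 0
    planted_features: set[str] = set()
    for pop in pop_names:
        nodes: set[str] = set()
        for j in range(cfg.n_diffcoex_pairs):
            g_id = populations[pop][int(np.log2(j + 1))]
            l_id = lnc_ids[lnc_cursor]
            lnc_cursor += 1
            g_row = values[row[g_id]]
            values[row[l_id], tumor_cols] = _conditional_partner(rng, g_row[tumor_cols], r_t)
            values[row[l_id], normal_cols] = _conditional_partner(rng, g_row[normal_cols], r_n)
            planted_pairs.append(PlantedPair(pop, g_id, l_id, r_t, r_n))
            planted_features.update((g_id, l_id))
            nodes.update((g_id, l_id))
        networks[pop] = sorted(nodes)

    # differential expression: planted-pair features are always DE with
    # alternating direction (so population networks mix up and down);
    # each remaining feature is DE with probability frac_de, direction random
    de_directions: dict[str, str] = {}
    for i, f in enumerate(sorted(planted_features)):
        de_directions[f] = UP if i % 2 == 0 else DOWN
    for f in feats:
        if f in de_directions:
            continue
        if rng.random() < cfg.frac_de:
            de_directions[f] = UP if rng.random() < 0.5 else DOWN

    values *= cfg.noise_sd
    values += cfg.base_mean
    for f, d in de_directions.items():
        shift = cfg.de_effect if d == UP else -cfg.de_effect
        values[row[f], tumor_cols] += shift

    x = ExpressionMatrix(
        values=pd.DataFrame(values, index=feats, columns=tumor_ids + normal_ids),
        feature_class=pd.Series([GENE] * n_genes + [LNCRNA] * cfg.n_lncs, index=feats),
        sample_group=pd.Series(
            [TUMOR] * cfg.n_tumor + [NORMAL] * cfg.n_normal, index=tumor_ids + normal_ids
        ),
        log_scale=True,
    )

    # true risk counts: the rank-based risk algorithm applied to the planted
    # networks with the planted directions -- consistent with the emitted
    # matrix by construction
    pipe_cfg = PipelineConfig()
    rf = immune_risk.call_risk_features(x, networks, de_directions, pipe_cfg)
    calls = immune_risk.call_risk_populations(rf, networks, pipe_cfg)
    profiles = immune_risk.build_profiles(calls, pipe_cfg)
    risk_counts = {p.patient_id: p.risk_population_count for p in profiles}
    expected_group = {p.patient_id: p.group for p in profiles}

    truth = SimTruth(
        de_directions=de_directions,
        planted_pairs=planted_pairs,
        networks=networks,
        risk_counts=risk_counts,
        expected_group=expected_group,
    )
    return x, sets, truth


def simulate_survival(
    risk_counts: Mapping[str, int], cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Clinical table with hazard multiplicative in the true risk count.

    Event times are exponential with rate
    ``baseline_hazard * hazard_multiplier ** count``.  A fraction
    ``censor_rate`` of records is censored independently at a uniform time
    before the drawn event time.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    ids = sorted(risk_counts)
    rows = []
    for pid in ids:
        rate = cfg.baseline_hazard * cfg.hazard_multiplier ** risk_counts[pid]
        t = rng.exponential(1.0 / rate)
        if rng.random() < cfg.censor_rate:
            rows.append((pid, t * rng.random(), 0))
        else:
            rows.append((pid, t, 1))
    return pd.DataFrame(
        {"time": [r[1] for r in rows], "event": [r[2] for r in rows]},
        index=pd.Index(ids, name="sample_id"),
    )


def write_study(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a full synthetic study to disk in the pipeline's input formats.

    The expression matrix is written on the raw scale (``2**v - 1``) so the
    standard preprocessing (zero filter + log2(x+1)) reproduces the
    generated log2 values exactly.  Also writes the class map, gene sets
    (GMT), clinical table, and a truth JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    x, sets, truth = simulate_expression(cfg)
    clinical = simulate_survival(truth.risk_counts, cfg)

    raw = ExpressionMatrix(
        values=np.exp2(x.values) - 1.0,
        feature_class=x.feature_class,
        sample_group=x.sample_group,
        log_scale=False,
    )
    paths = {
        "expression": out / "expression.tsv",
        "class_map": out / "class_map.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.json",
    }
    write_expression(raw, paths["expression"], class_map=paths["class_map"])
    with open(paths["gene_sets"], "w") as fh:
        for name, genes in sets.populations.items():
            fh.write("\t".join([name, "simulated"] + genes) + "\n")
    pd.DataFrame(
        {
            "sample_id": clinical.index,
            "time_days": clinical["time"].to_numpy(),
            "event": clinical["event"].to_numpy(),
        }
    ).to_csv(paths["clinical"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "de_directions": truth.de_directions,
                "planted_pairs": [dataclasses.asdict(p) for p in truth.planted_pairs],
                "networks": truth.networks,
                "risk_counts": truth.risk_counts,
                "expected_group": truth.expected_group,
            },
            fh,
            indent=1,
        )
    return paths
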