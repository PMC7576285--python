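"""End-to-end orchestration: preprocess -> DE -> co-expression networks ->
immune-risk scoring -> survival, with every intermediate persisted and a
run manifest that fully determines a rerun."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__, differential_coexpression as dc, differential_expression as de
from . import immune_risk, survival
from .expression_io import (
    ExpressionMatrix,
    ImmuneGeneSets,
    PipelineConfig,
    preprocess,
    read_clinical,
    read_expression,
    read_gene_sets,
)

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """All stage outputs of one pipeline run."""

    cfg: PipelineConfig
    x: ExpressionMatrix
    de_per_population: dict[str, list[de.DifferentialResult]]
    de_lncs: list[de.DifferentialResult]
    pairs: list[dc.CoexPair]
    networks: dict[str, dc.CoexNetwork]  # per population + "integrated"
    power_law: dc.PowerLawFit | None
    risk_calls: list[immune_risk.RiskCall]
    profiles: list[immune_risk.RiskProfile]
    km_curves: dict[str, survival.KMCurve]
    log_rank: survival.LogRankResult | None
    two_group: dict[int, survival.LogRankResult]

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in immune_risk.GROUPS}
        for p in self.profiles:
            sizes[p.group] += 1
        return sizes


def run_study(
    x: ExpressionMatrix,
    sets: ImmuneGeneSets,
    clinical: pd.DataFrame | None,
    cfg: PipelineConfig | None = None,
    two_group_boundaries: tuple[int, ...] = (6, 7),
) -> StudyResult:
    """Run every analysis stage on an in-memory, log-scale matrix."""
    cfg = cfg or PipelineConfig()
    if not x.log_scale:
        x = preprocess(x, cfg)

    per_pop, lncs = de.call_specific_features(x, sets, cfg)
    specific_genes = {pop: de.significant_ids(res) for pop, res in per_pop.items()}
    specific_lncs = de.significant_ids(lncs)

    pairs = dc.screen_pairs(x, specific_genes, specific_lncs, cfg)
    networks: dict[str, dc.CoexNetwork] = {}
    for pop in specific_genes:
        networks[pop] = dc.build_network(pairs, cfg, scope=pop)
    networks[dc.INTEGRATED] = dc.build_network(pairs, cfg, scope=dc.INTEGRATED)

    power_law: dc.PowerLawFit | None = None
    try:
        power_law = dc.fit_power_law(networks[dc.INTEGRATED])
    except ValueError as exc:
        logger.warning("power-law fit skipped: %s", exc)

    network_features = {
        pop: net.nodes for pop, net in networks.items()
        if pop != dc.INTEGRATED and len(net) > 0
    }
    dirs = de.directions(per_pop, lncs)
    profiles: list[immune_risk.RiskProfile] = []
    risk_calls: list[immune_risk.RiskCall] = []
    if network_features:
        rf = immune_risk.call_risk_features(x, network_features, dirs, cfg)
        risk_calls = immune_risk.call_risk_populations(rf, network_features, cfg)
        profiles = immune_risk.build_profiles(risk_calls, cfg)
    else:
        logger.warning("all population networks empty; no risk scoring performed")

    km_curves: dict[str, survival.KMCurve] = {}
    lr: survival.LogRankResult | None = None
    two_group: dict[int, survival.LogRankResult] = {}
    if clinical is not None and profiles:
        group_of = {p.patient_id: p.group for p in profiles}
        try:
            km_curves, lr = survival.compare_groups(clinical, group_of)
        except ValueError as exc:
            logger.warning("three-group survival comparison skipped: %s", exc)
        for b in two_group_boundaries:
            low, high = immune_risk.two_group_split(profiles, b)
            if low and high:
                labels = {p: ("low" if p in set(low) else "high") for p in low + high}
                try:
                    _, two_group[b] = survival.compare_groups(clinical, labels)
                except ValueError as exc:
                    logger.warning("two-group comparison at %d skipped: %s", b, exc)
    return StudyResult(
        cfg=cfg, x=x, de_per_population=per_pop, de_lncs=lncs, pairs=pairs,
        networks=networks, power_law=power_law, risk_calls=risk_calls,
        profiles=profiles, km_curves=km_curves, log_rank=lr, two_group=two_group,
    )


# ---------------------------------------------------------------------------
# file-based run with manifest
# ---------------------------------------------------------------------------

def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def persist_study(res: StudyResult, out_dir: str | Path) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        p = out / name
        df.to_csv(p, sep="\t", lineterminator="\n", **kw)
        written[name] = str(p)

    save(de.results_table(res.de_per_population, res.de_lncs), "differential_expression.tsv", index=False)
    save(de.population_summary(res.de_per_population), "de_population_summary.tsv")
    save(dc.pairs_table(res.pairs), "screened_pairs.tsv", index=False)
    edge_rows = []
    for name, net in res.networks.items():
        for p in net.edges:
            edge_rows.append((name, p.gene_id, p.lnc_id, p.pcc_tumor, p.pcc_normal, p.delta, p.pattern))
    save(
        pd.DataFrame(edge_rows, columns=["network", "gene_id", "lnc_id", "pcc_tumor",
                                         "pcc_normal", "delta", "pattern"]),
        "network_edges.tsv", index=False,
    )
    dc.write_sif(res.networks[dc.INTEGRATED], out / "integrated_network.sif")
    written["integrated_network.sif"] = str(out / "integrated_network.sif")
    deg_rows = [
        (name, node, d)
        for name, net in res.networks.items()
        for node, d in sorted(net.degree.items())
    ]
    save(pd.DataFrame(deg_rows, columns=["network", "node", "degree"]), "degrees.tsv", index=False)
    if res.power_law is not None:
        with open(out / "power_law.json", "w") as fh:
            json.dump(dataclasses.asdict(res.power_law), fh, indent=1)
        written["power_law.json"] = str(out / "power_law.json")
    if res.risk_calls:
        save(immune_risk.risk_matrix(res.risk_calls), "risk_matrix.tsv")
        save(immune_risk.profiles_table(res.profiles), "risk_profiles.tsv", index=False)
    for label, curve in res.km_curves.items():
        save(survival.km_table(curve), f"km_{label}.tsv", index=False)
    if res.log_rank is not None:
        payload = {"three_group": dataclasses.asdict(res.log_rank)}
        payload.update({f"two_group_boundary_{b}": dataclasses.asdict(r) for b, r in res.two_group.items()})
        with open(out / "log_rank.json", "w") as fh:
            json.dump(payload, fh, indent=1)
        written["log_rank.json"] = str(out / "log_rank.json")
    return written


def run_pipeline(config: str | Path | Mapping, out_dir: str | Path | None = None) -> dict:
    """File-based all-in-one run from a YAML/JSON config.

    The config holds the input paths (``expression``, ``class_map``,
    ``gene_sets``, ``clinical``), an optional ``out`` directory, an optional
    ``expression_is_log`` flag, and any :class:`PipelineConfig` field under
    ``thresholds``.  Returns the run manifest (also written to
    ``manifest.json``); identical config + inputs give identical manifests.
    """
    if isinstance(config, (str, Path)):
        cfg_dict = load_config(config)
    else:
        cfg_dict = dict(config)
    cfg = PipelineConfig.from_dict(cfg_dict.get("thresholds", {}))
    out = Path(out_dir or cfg_dict.get("out", "immrisk_out"))

    paths = {k: cfg_dict[k] for k in ("expression", "class_map", "gene_sets") if k in cfg_dict}
    if "expression" not in paths or "class_map" not in paths or "gene_sets" not in paths:
        raise ValueError("config must name expression, class_map and gene_sets inputs")
    x = read_expression(paths["expression"], paths["class_map"])
    if cfg_dict.get("expression_is_log", False):
        x.log_scale = True
    sets = read_gene_sets(paths["gene_sets"])
    clinical = None
    if "clinical" in cfg_dict:
        paths["clinical"] = cfg_dict["clinical"]
        clinical = read_clinical(paths["clinical"])

    res = run_study(x, sets, clinical, cfg)
    written = persist_study(res, out)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in paths.items()},
        "counts": {
            "features": len(res.x.feature_ids),
            "features_dropped": res.x.n_dropped,
            "significant_genes": sum(
                len(de.significant_ids(r)) for r in res.de_per_population.values()
            ),
            "significant_lncs": len(de.significant_ids(res.de_lncs)),
            "pairs_screened": len(res.pairs),
            "network_edges": {name: len(net) for name, net in res.networks.items()},
            "patients_scored": len(res.profiles),
            "group_sizes": res.group_sizes,
        },
        "outputs": written,
    }
    if res.log_rank is not None:
        manifest["log_rank"] = dataclasses.asdict(res.log_rank)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
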