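"""Differential co-expression of gene-lncRNA pairs between tumor and normal.

For each immune cell population, Pearson correlation coefficients (PCCs) of
every tumor-specific ICPR gene against every tumor-specific lncRNA are
computed separately in tumor and normal samples.  The screening statistic is
the absolute change ``delta = |pcc_tumor - pcc_normal|``: pairs with delta
strictly above ``delta_screen`` are retained, and only the stronger changes
above ``delta_network`` become edges of the per-population bipartite
networks.  Each retained pair is classified by how its correlation changed
(sign flip in either direction, or same-sign strengthening/weakening).

Degree analysis of the networks includes an ordinary least-squares power-law
fit of log10(degree frequency) on log10(degree), the usual scale-free check.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import (
    GENE,
    LNCRNA,
    NORMAL,
    TUMOR,
    ExpressionMatrix,
    PipelineConfig,
)

logger = logging.getLogger(__name__)

NEG_TO_POS = "negative_to_positive"
POS_TO_NEG = "positive_to_negative"
STRENGTHENED = "same_sign_strengthened"
WEAKENED = "same_sign_weakened"

INTEGRATED = "integrated"


@dataclass(frozen=True)
class CoexPair:
    population: str
    gene_id: str
    lnc_id: str
    pcc_tumor: float
    pcc_normal: float
    p_tumor: float
    p_normal: float
    delta: float
    pattern: str


@dataclass
class CoexNetwork:
    """Bipartite gene-lncRNA network of strong correlation changes."""

    population: str
    graph: nx.Graph
    edges: list[CoexPair]

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    @property
    def genes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == GENE)

    @property
    def lncs(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == LNCRNA)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def pcc(u: Sequence[float], v: Sequence[float]) -> tuple[float, float]:
    """Pearson r with a two-sided p-value from the t distribution (n-2 df)."""
    a = np.asarray(u, dtype=float)
    b = np.asarray(v, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("constant vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def classify_pattern(pcc_normal: float, pcc_tumor: float) -> str:
    """Qualitative change of a pair's correlation from normal to tumor."""
    if pcc_normal < 0 <= pcc_tumor:
        return NEG_TO_POS
    if pcc_normal > 0 >= pcc_tumor:
        return POS_TO_NEG
    return STRENGTHENED if abs(pcc_tumor) > abs(pcc_normal) else WEAKENED


def _corr_with_p(feats: np.ndarray, lncs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson correlations of two matrices sharing sample columns.

    Returns (R, P) of shape (n_feats, n_lncs).  Rows must be non-constant.
    """
    n = feats.shape[1]
    fz = feats - feats.mean(axis=1, keepdims=True)
    lz = lncs - lncs.mean(axis=1, keepdims=True)
    fn = np.sqrt((fz**2).sum(axis=1, keepdims=True))
    ln = np.sqrt((lz**2).sum(axis=1, keepdims=True))
    r = (fz / fn) @ (lz / ln).T
    np.clip(r, -1.0, 1.0, out=r)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(t)] = 0.0  # |r| == 1
    return r, p


def screen_pairs(
    x: ExpressionMatrix,
    specific_genes: Mapping[str, Sequence[str]],
    specific_lncs: Sequence[str],
    cfg: PipelineConfig | None = None,
) -> list[CoexPair]:
    """All gene x lncRNA pairs per population with ``delta > delta_screen``.

    Only tumor-specific features should enter.  Features constant within
    either sample group cannot be correlated and are dropped with a warning.
    """
    cfg = cfg or PipelineConfig()
    tumor = x.group_values(TUMOR)
    normal = x.group_values(NORMAL)
    if tumor.shape[1] < 3 or normal.shape[1] < 3:
        raise ValueError("each sample group needs at least 3 samples for correlations")

    def usable(ids: Sequence[str]) -> list[str]:
        ids = [i for i in ids if i in x.values.index]
        tv = tumor.loc[ids].to_numpy()
        nv = normal.loc[ids].to_numpy()
        ok = (tv.std(axis=1) > 0) & (nv.std(axis=1) > 0)
        dropped = [i for i, k in zip(ids, ok) if not k]
        if dropped:
            logger.warning("dropping %d constant features from correlation: %s",
                           len(dropped), dropped[:5])
        return [i for i, k in zip(ids, ok) if k]

    lnc_ids = usable(list(specific_lncs))
    pairs: list[CoexPair] = []
    if not lnc_ids:
        logger.warning("no usable tumor-specific lncRNAs; no pairs screened")
        return pairs
    lt = tumor.loc[lnc_ids].to_numpy()
    ln = normal.loc[lnc_ids].to_numpy()

    for pop in specific_genes:
        gene_ids = usable(list(specific_genes[pop]))
        if not gene_ids:
            logger.warning("population %r has no usable tumor-specific genes", pop)
            continue
        gt = tumor.loc[gene_ids].to_numpy()
        gn = normal.loc[gene_ids].to_numpy()
        rt, pt = _corr_with_p(gt, lt)
        rn, pn = _corr_with_p(gn, ln)
        delta = np.abs(rt - rn)
        keep = delta > cfg.delta_screen
        if cfg.pair_p_max is not None:
            keep &= (pt <= cfg.pair_p_max) & (pn <= cfg.pair_p_max)
        gi, li = np.nonzero(keep)
        for g, l in zip(gi, li):
            pairs.append(
                CoexPair(
                    population=pop,
                    gene_id=gene_ids[g],
                    lnc_id=lnc_ids[l],
                    pcc_tumor=float(rt[g, l]),
                    pcc_normal=float(rn[g, l]),
                    p_tumor=float(pt[g, l]),
                    p_normal=float(pn[g, l]),
                    delta=float(delta[g, l]),
                    pattern=classify_pattern(float(rn[g, l]), float(rt[g, l])),
                )
            )
    return pairs


def delta_histogram(pairs: Sequence[CoexPair], start: float = 0.3, width: float = 0.1) -> pd.Series:
    """Counts of pairs per |dPCC| bin (start-start+width, ...), pooled over
    populations with recurrences of the same gene-lncRNA pair counted."""
    deltas = np.array([p.delta for p in pairs])
    top = max(2.0, start + width)
    edges = np.arange(start, top + width, width)
    counts, _ = np.histogram(deltas, bins=edges)
    labels = [f"{a:.1f}-{b:.1f}" for a, b in zip(edges[:-1], edges[1:])]
    return pd.Series(counts, index=labels, name="n_pairs")


def build_network(
    pairs: Sequence[CoexPair],
    cfg: PipelineConfig | None = None,
    scope: str = INTEGRATED,
) -> CoexNetwork:
    """Bipartite network of pairs with ``delta > delta_network``.

    ``scope`` is a population name (edges restricted to it) or
    ``"integrated"`` (edges pooled over all populations; a gene-lncRNA edge
    recurring in several populations is collapsed keeping the max delta).
    """
    cfg = cfg or PipelineConfig()
    if scope == INTEGRATED:
        selected: dict[tuple[str, str], CoexPair] = {}
        for p in pairs:
            if p.delta > cfg.delta_network:
                key = (p.gene_id, p.lnc_id)
                if key not in selected or p.delta > selected[key].delta:
                    selected[key] = p
        edges = list(selected.values())
    else:
        edges = [p for p in pairs if p.population == scope and p.delta > cfg.delta_network]
        seen = {(p.gene_id, p.lnc_id) for p in edges}
        if len(seen) != len(edges):
            raise ValueError(f"duplicate gene-lncRNA pairs within population {scope!r}")
    g = nx.Graph()
    for p in edges:
        g.add_node(p.gene_id, kind=GENE)
        g.add_node(p.lnc_id, kind=LNCRNA)
        g.add_edge(p.gene_id, p.lnc_id, delta=p.delta, pattern=p.pattern)
    if not edges:
        logger.warning("network %r is empty at delta > %.2f", scope, cfg.delta_network)
    return CoexNetwork(population=scope, graph=g, edges=edges)


def fit_power_law(net: CoexNetwork | Mapping[int, int] | Iterable[int]) -> PowerLawFit:
    """OLS fit of log10(frequency) on log10(degree) over the network's
    degree distribution (degrees >= 1 with nonzero frequency).

    Accepts a network, a degree -> frequency mapping, or a raw degree
    sequence.  Requires at least 3 distinct degree values.
    """
    if isinstance(net, CoexNetwork):
        freq: Mapping[int, int] = Counter(net.degree.values())
    elif isinstance(net, Mapping):
        freq = net
    else:
        freq = Counter(net)
    pts = [(d, f) for d, f in freq.items() if d >= 1 and f > 0]
    if len(pts) < 3:
        raise ValueError("insufficient degree diversity: need >= 3 distinct degrees")
    d = np.log10([p[0] for p in pts])
    f = np.log10([p[1] for p in pts])
    fit = stats.linregress(d, f)
    return PowerLawFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(pts),
    )


def hub_report(net: CoexNetwork, top_k: int = 10) -> pd.DataFrame:
    """Top-degree genes and lncRNAs, ranked separately per node kind.

    Sorted by degree descending with lexicographic tie-break, so the report
    is deterministic.
    """
    deg = net.degree
    rows = []
    for kind, nodes in ((GENE, net.genes), (LNCRNA, net.lncs)):
        ranked = sorted(nodes, key=lambda n: (-deg[n], n))[:top_k]
        rows += [{"node": n, "kind": kind, "degree": deg[n]} for n in ranked]
    return pd.DataFrame(rows, columns=["node", "kind", "degree"])


def pairs_table(pairs: Sequence[CoexPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.population, p.gene_id, p.lnc_id, p.pcc_tumor, p.pcc_normal,
             p.p_tumor, p.p_normal, p.delta, p.pattern)
            for p in pairs
        ],
        columns=["population", "gene_id", "lnc_id", "pcc_tumor", "pcc_normal",
                 "p_tumor", "p_normal", "delta", "pattern"],
    )


def pairs_from_table(df: pd.DataFrame) -> list[CoexPair]:
    return [
        CoexPair(
            population=str(r.population), gene_id=str(r.gene_id), lnc_id=str(r.lnc_id),
            pcc_tumor=float(r.pcc_tumor), pcc_normal=float(r.pcc_normal),
            p_tumor=float(r.p_tumor), p_normal=float(r.p_normal),
            delta=float(r.delta), pattern=str(r.pattern),
        )
        for r in df.itertuples(index=False)
    ]


def write_sif(net: CoexNetwork, path) -> None:
    """Simple interaction format for graph viewers: gene <coex> lncRNA."""
    with open(path, "w") as fh:
        for p in net.edges:
            fh.write(f"{p.gene_id}\tcoex\t{p.lnc_id}\n")
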