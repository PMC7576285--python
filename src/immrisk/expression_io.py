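"""Expression-matrix, gene-set and clinical-table I/O plus preprocessing.

The pipeline's central container is :class:`ExpressionMatrix`: a features x
samples matrix where every feature is classed ``gene`` or ``lncRNA`` and
every sample is grouped ``tumor`` or ``normal``.  Raw matrices are
preprocessed by removing features with too many zero values and applying
``log2(x + pseudocount)``; all downstream statistics (t-tests, Pearson
correlations, expression ranks) operate on the log2 scale.

File formats are deliberately plain: tab-separated matrices (first column
``feature_id``), a two-column id/label map covering both features and
samples, standard GMT gene sets, and a clinical TSV with columns
``sample_id``, ``time_days``, ``event``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE = "gene"
LNCRNA = "lncRNA"
TUMOR = "tumor"
NORMAL = "normal"

FEATURE_CLASSES = (GENE, LNCRNA)
SAMPLE_GROUPS = (TUMOR, NORMAL)


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the analysis, in one place.

    Parameters
    ----------
    p_gene, p_lnc
        Significance thresholds for calling tumor-specific ICPR genes
        (default 0.05) and lncRNAs (default 0.01) from the two-sample t-test.
    delta_screen, delta_network
        |dPCC| thresholds: pairs with absolute tumor-vs-normal correlation
        change strictly above ``delta_screen`` (default 0.3) are screened in;
        only changes strictly above ``delta_network`` (default 0.7) become
        network edges.
    up_risk_frac, down_risk_frac
        Rank fractions of the risk-feature rule: patients ranked in the last
        70% for an up-regulated feature, or in the top 30% for a
        down-regulated feature, carry it as a risk feature.  The two are
        complements; a single boundary index ``ceil(down_risk_frac * N)``
        governs both.
    pop_risk_frac
        A population is a risk population for a patient when strictly more
        than this fraction (default 0.50) of its network features are risk
        features for that patient.
    group_bounds
        Inclusive upper counts for the min-immune and media-immune groups
        (default ``(4, 9)``: 0-4 min, 5-9 media, 10+ multi).
    zero_filter_frac
        Maximum tolerated fraction of zero values per feature before the
        feature is removed in preprocessing.  The default 0.0 removes any
        feature containing a zero.
    pseudocount
        Added before the log2 transform (default 1.0).
    pair_p_max
        Optional cap on the per-group correlation p-values of screened pairs;
        ``None`` (default) applies no p filter.
    seed
        Seed for stochastic components.
    """

    p_gene: float = 0.05
    p_lnc: float = 0.01
    delta_screen: float = 0.3
    delta_network: float = 0.7
    up_risk_frac: float = 0.70
    down_risk_frac: float = 0.30
    pop_risk_frac: float = 0.50
    group_bounds: tuple[int, int] = (4, 9)
    zero_filter_frac: float = 0.0
    pseudocount: float = 1.0
    pair_p_max: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("up_risk_frac", "down_risk_frac", "pop_risk_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v!r}")
        for name in ("p_gene", "p_lnc"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {v!r}")
        for name in ("delta_screen", "delta_network"):
            v = getattr(self, name)
            if not 0.0 < v <= 2.0:
                raise ValidationError(f"{name} must be in (0, 2], got {v!r}")
        lo, hi = self.group_bounds
        if not (0 <= lo < hi):
            raise ValidationError(f"group_bounds must satisfy 0 <= lo < hi, got {self.group_bounds!r}")
        if not 0.0 <= self.zero_filter_frac < 1.0:
            raise ValidationError("zero_filter_frac must be in [0, 1)")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "group_bounds" in d:
            d["group_bounds"] = tuple(d["group_bounds"])  # type: ignore[arg-type]
        return cls(**d)  # type: ignore[arg-type]


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with feature class and sample group.

    ``values`` is a DataFrame indexed by feature id with sample ids as
    columns; ``feature_class`` and ``sample_group`` are Series aligned to the
    index and columns respectively.  ``log_scale`` records whether
    :func:`preprocess` (or an equivalent transform) has been applied.
    """

    values: pd.DataFrame
    feature_class: pd.Series
    sample_group: pd.Series
    log_scale: bool = False
    n_dropped: int = 0

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate feature ids: {dups[:10]}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dups[:10]}")
        self.feature_class = self.feature_class.reindex(idx)
        if self.feature_class.isna().any():
            missing = list(idx[self.feature_class.isna()])
            raise ValidationError(f"features without class: {missing[:10]}")
        bad = ~self.feature_class.isin(FEATURE_CLASSES)
        if bad.any():
            raise ValidationError(
                f"invalid feature classes: {sorted(self.feature_class[bad].unique())}"
            )
        self.sample_group = self.sample_group.reindex(cols)
        if self.sample_group.isna().any():
            missing = list(cols[self.sample_group.isna()])
            raise ValidationError(f"samples without group: {missing[:10]}")
        bad = ~self.sample_group.isin(SAMPLE_GROUPS)
        if bad.any():
            raise ValidationError(
                f"invalid sample groups: {sorted(self.sample_group[bad].unique())}"
            )
        for grp in SAMPLE_GROUPS:
            if not (self.sample_group == grp).any():
                raise ValidationError(f"group has no samples: {grp!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("expression values must be finite")

    # -- convenience accessors -------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.sample_group.index[self.sample_group == group])

    def features_of(self, cls: str) -> list[str]:
        return list(self.feature_class.index[self.feature_class == cls])

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix restricted to one sample group."""
        return self.values.loc[:, self.samples_in(group)]

    def subset_features(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(ids)
        missing = [f for f in ids if f not in self.values.index]
        if missing:
            raise ValidationError(f"unknown features: {missing[:10]}")
        return ExpressionMatrix(
            values=self.values.loc[ids],
            feature_class=self.feature_class.loc[ids],
            sample_group=self.sample_group,
            log_scale=self.log_scale,
        )


@dataclass
class ImmuneGeneSets:
    """Ordered collection of named immune-cell-population marker sets."""

    populations: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.populations.items():
            if not genes:
                raise ValidationError(f"empty gene set: {name!r}")
            seen: set[str] = set()
            deduped = []
            for g in genes:
                if g not in seen:
                    seen.add(g)
                    deduped.append(g)
            if len(deduped) != len(genes):
                logger.info(
                    "gene set %r: dropped %d duplicate symbols", name, len(genes) - len(deduped)
                )
                self.populations[name] = deduped

    @property
    def names(self) -> list[str]:
        return list(self.populations)

    def __len__(self) -> int:
        return len(self.populations)

    def __getitem__(self, name: str) -> list[str]:
        return self.populations[name]

    def restrict_to(self, feature_ids: Iterable[str]) -> "ImmuneGeneSets":
        """Drop symbols absent from the given feature universe.

        Marker catalogs always exceed any one platform, so missing symbols
        are dropped with a logged count rather than raised.  Populations left
        empty are retained as empty lists here and skipped downstream.
        """
        universe = set(feature_ids)
        out: dict[str, list[str]] = {}
        n_dropped = 0
        for name, genes in self.populations.items():
            kept = [g for g in genes if g in universe]
            n_dropped += len(genes) - len(kept)
            out[name] = kept
        if n_dropped:
            logger.info("dropped %d gene-set symbols absent from the matrix", n_dropped)
        obj = object.__new__(ImmuneGeneSets)
        obj.populations = out  # bypass the non-empty check: empty-after-restrict is legal
        return obj


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_class_map(path: str | Path) -> tuple[pd.Series, pd.Series]:
    """Split a two-column id/label TSV into feature classes and sample groups."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "label"], dtype=str, comment="#")
    if df["id"].duplicated().any():
        dups = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise ValidationError(f"duplicate ids in class map: {dups[:10]}")
    is_feat = df["label"].isin(FEATURE_CLASSES)
    is_samp = df["label"].isin(SAMPLE_GROUPS)
    bad = df.loc[~(is_feat | is_samp), "label"].unique()
    if len(bad):
        raise ValidationError(f"unknown labels in class map: {sorted(bad)[:10]}")
    feats = df[is_feat].set_index("id")["label"]
    samps = df[is_samp].set_index("id")["label"]
    return feats, samps


def read_expression(path: str | Path, class_map: str | Path) -> ExpressionMatrix:
    """Read a raw-scale expression TSV plus its id/label map.

    The matrix file is tab-separated with first column ``feature_id`` and a
    header row of sample ids; missing values are not permitted.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        raise ValidationError("missing values are not permitted in the expression matrix")
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"duplicate feature ids: {dups[:10]}")
    feats, samps = _read_class_map(class_map)
    missing_f = [f for f in df.index if f not in feats.index]
    if missing_f:
        raise ValidationError(f"features missing from class map: {missing_f[:10]}")
    missing_s = [s for s in df.columns if s not in samps.index]
    if missing_s:
        raise ValidationError(f"samples missing from class map: {missing_s[:10]}")
    return ExpressionMatrix(
        values=df.astype(float),
        feature_class=feats.reindex(df.index),
        sample_group=samps.reindex(df.columns),
    )


def write_expression(x: ExpressionMatrix, path: str | Path, class_map: str | Path | None = None) -> None:
    """Write the matrix (and optionally its class map) in the TSV dialect of
    :func:`read_expression`; a write/read round-trip is bit-identical."""
    out = x.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", lineterminator="\n")
    if class_map is not None:
        with open(class_map, "w") as fh:
            for fid, cls in x.feature_class.items():
                fh.write(f"{fid}\t{cls}\n")
            for sid, grp in x.sample_group.items():
                fh.write(f"{sid}\t{grp}\n")


def preprocess(x: ExpressionMatrix, cfg: PipelineConfig | None = None) -> ExpressionMatrix:
    """Zero-filter features and log2-transform a raw-scale matrix.

    Features whose fraction of zero values strictly exceeds
    ``cfg.zero_filter_frac`` are removed (the default 0.0 removes features
    containing any zero, the strictest reading of the filter and the one
    that makes a pseudocount immaterial for retained features).  Remaining
    values become ``log2(value + pseudocount)``.
    """
    cfg = cfg or PipelineConfig()
    if x.log_scale:
        raise ValidationError("matrix is already on the log scale")
    vals = x.values
    zero_frac = (vals == 0).mean(axis=1)
    keep = zero_frac <= cfg.zero_filter_frac
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValidationError("zero filter removed all features")
    if n_dropped:
        logger.info("zero filter dropped %d of %d features", n_dropped, len(keep))
    transformed = np.log2(vals.loc[keep] + cfg.pseudocount)
    if not np.isfinite(transformed.to_numpy()).all():
        raise ValidationError("non-finite values after log2 transform; check pseudocount")
    return ExpressionMatrix(
        values=transformed,
        feature_class=x.feature_class.loc[keep],
        sample_group=x.sample_group,
        log_scale=True,
        n_dropped=n_dropped,
    )


def read_gene_sets(path: str | Path) -> ImmuneGeneSets:
    """Read a GMT file: per line, set name, description, then gene symbols."""
    populations: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"GMT line {lineno}: expected name, description, >=1 symbol")
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if name in populations:
                raise ValidationError(f"duplicate gene-set name: {name!r}")
            if not genes:
                raise ValidationError(f"empty gene set: {name!r}")
            populations[name] = genes
    if not populations:
        raise ValidationError("GMT file contains no gene sets")
    return ImmuneGeneSets(populations)


def load_default_gene_sets() -> ImmuneGeneSets:
    """Bundled 17-immune-cell-population marker collection.

    A synthetic stand-in: the population names follow the standard 17-way
    catalog (B cells, eosinophils, macrophages, mast cells, NK CD56bright,
    NK CD56dim, neutrophils, T helper cells, Tcm, Tem, Tfh, aDCs, iDCs,
    activated CD8 T cells, gamma delta T cells, Tregs, cytotoxic cells) with
    representative marker symbols, not a published curation.
    """
    ref = resources.files("immrisk").joinpath("data/immune_populations_synthetic.gmt")
    with resources.as_file(ref) as p:
        return read_gene_sets(p)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV with columns sample_id, time_days, event.

    Returns a validated DataFrame indexed by sample id with columns ``time``
    (days, >= 0) and ``event`` (1 = death observed, 0 = censored).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise ValidationError(f"duplicate sample ids in clinical table: {dups[:10]}")
    out = pd.DataFrame(
        {"time": df["time_days"].astype(float).to_numpy(), "event": df["event"].astype(int).to_numpy()},
        index=pd.Index(df["sample_id"], name="sample_id"),
    )
    if (out["time"] < 0).any():
        raise ValidationError("survival times must be >= 0")
    if not out["event"].isin((0, 1)).all():
        raise ValidationError("event indicator must be 0 or 1")
    return out
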