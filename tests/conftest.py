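import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from immrisk.expression_io import ExpressionMatrix, PipelineConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def cfg():
    return PipelineConfig()


def make_matrix(values, feature_class, sample_group, log_scale=True):
    """Build an ExpressionMatrix from plain dicts/arrays."""
    df = pd.DataFrame(values)
    return ExpressionMatrix(
        values=df,
        feature_class=pd.Series(feature_class),
        sample_group=pd.Series(sample_group),
        log_scale=log_scale,
    )


@pytest.fixture
def toy_matrix():
    """3 features x 4 samples, log scale, 2 tumor + 2 normal."""
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.normal(6, 1, (3, 4)),
        index=["G1", "G2", "L1"],
        columns=["T1", "T2", "N1", "N2"],
    )
    return ExpressionMatrix(
        values=vals,
        feature_class=pd.Series({"G1": "gene", "G2": "gene", "L1": "lncRNA"}),
        sample_group=pd.Series({"T1": "tumor", "T2": "tumor", "N1": "normal", "N2": "normal"}),
        log_scale=True,
    )


@pytest.fixture
def raw_files(tmp_path):
    """Raw-scale 3x4 expression TSV plus class map on disk."""
    expr = tmp_path / "expr.tsv"
    expr.write_text(
        "feature_id\tT1\tT2\tN1\tN2\n"
        "G1\t3.0\t7.0\t1.0\t2.0\n"
        "G2\t5.0\t6.0\t4.0\t3.0\n"
        "L1\t1.0\t2.0\t8.0\t9.0\n"
    )
    cmap = tmp_path / "cmap.tsv"
    cmap.write_text(
        "G1\tgene\nG2\tgene\nL1\tlncRNA\n"
        "T1\ttumor\nT2\ttumor\nN1\tnormal\nN2\tnormal\n"
    )
    return expr, cmap
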