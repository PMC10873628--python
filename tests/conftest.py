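import numpy as np
import pandas as pd
import pytest

from curtainkit.formats_io import (ColumnMap, DifferentialTable,
                                   RawQuantMatrix, SampleAnnotation)
from curtainkit.synthetic_fixtures import (PTMSimParams, ProteomeSimParams,
                                           gen_proteome, gen_ptm)


@pytest.fixture
def colmap_linear():
    return ColumnMap(primary_id_col="id", fc_col="FC", sig_col="pval",
                     fc_scale="linear", sig_scale="raw_p", gene_col="gene",
                     comparison_label="treated_vs_control")


@pytest.fixture
def small_table():
    """Four features, one per volcano class at cutoffs (1.0, 1.301)."""
    df = pd.DataFrame({
        "primary_id": ["P1", "P2", "P3", "P4"],
        "gene": ["GeneA", "GeneB", "GeneC", "Rab10"],
        "log2_fc": [2.0, 0.1, -3.0, 0.0],
        "neglog10_sig": [3.0, 2.5, 0.5, 0.1],
        "comparison": "cmp",
    })
    return DifferentialTable(data=df)


@pytest.fixture
def annotations4():
    return [
        SampleAnnotation("ctrl_r1", "ctrl", 1, 0),
        SampleAnnotation("ctrl_r2", "ctrl", 2, 1),
        SampleAnnotation("treat_r1", "treat", 1, 2),
        SampleAnnotation("treat_r2", "treat", 2, 3),
    ]


@pytest.fixture
def small_matrix(annotations4):
    df = pd.DataFrame(
        [[8.0, 2.0, 4.0, 16.0],
         [1.0, np.nan, 2.0, 4.0],
         [32.0, 16.0, 8.0, 4.0]],
        index=pd.Index(["P1", "P2", "P3"], name="feature_id"),
        columns=[a.sample_name for a in annotations4])
    return RawQuantMatrix(intensities=df, samples=annotations4)


@pytest.fixture(scope="session")
def ptm_fixture():
    return gen_ptm(PTMSimParams(seed=11))


@pytest.fixture(scope="session")
def proteome_fixture():
    return gen_proteome(ProteomeSimParams(seed=5))
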