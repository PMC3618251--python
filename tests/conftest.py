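import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pmpscan.simulate import SynthConfig, generate_methylome

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


#: GEO-series shape of the 501-sample compendium: (series, tissue,
#: n_somatic_normal, n_tumor, n_germline)
TABLE1_SERIES = (
    ("GSE26990", "breast", 42, 47, 0),
    ("GSE26126", "prostate", 98, 95, 0),
    ("GSE17648", "colorectal", 22, 22, 0),
    ("GSE25062", "colorectal", 29, 125, 0),
    ("GSE26974", "sperm", 0, 0, 21),
)


def build_table1_sheet() -> pd.DataFrame:
    rows = []
    for sid, tissue, nn, nt, ng in TABLE1_SERIES:
        for i in range(nn):
            rows.append((f"{sid}_N{i:03d}", sid, tissue, "SOMATIC_NORMAL"))
        for i in range(nt):
            rows.append((f"{sid}_T{i:03d}", sid, tissue, "TUMOR"))
        for i in range(ng):
            rows.append((f"{sid}_G{i:03d}", sid, tissue, "GERMLINE"))
    return pd.DataFrame(rows, columns=["sample_id", "series_id",
                                       "tissue", "cls"])


@pytest.fixture(scope="session")
def table1_samples() -> pd.DataFrame:
    return build_table1_sheet()


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic methylome shared by read-only tests."""
    return generate_methylome(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def default_sim(default_dataset):
    from pmpscan import build_pmp_vector, pmp_sim
    vec = build_pmp_vector(default_dataset.matrix, default_dataset.samples)
    return pmp_sim(default_dataset.matrix, vec)


@pytest.fixture
def tiny_matrix_files(tmp_path):
    """2-locus x 3-sample TSV pair with one empty (missing) cell."""
    mat = tmp_path / "matrix.tsv"
    mat.write_text("locus_id\ts1\ts2\ts3\n"
                   "cg01\t0.1\t0.9\t0.5\n"
                   "cg02\t0.2\t\t0.4\n")
    sheet = tmp_path / "samples.tsv"
    sheet.write_text("sample_id\tseries_id\ttissue\tcls\n"
                     "s1\tA\tbreast\tTUMOR\n"
                     "s2\tA\tbreast\tSOMATIC_NORMAL\n"
                     "s3\tB\tsperm\tGERMLINE\n")
    return mat, sheet
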