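import numpy as np
import pandas as pd
import pytest

from spatialpgx.io import GeneList
from spatialpgx.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scale simulated dataset shared across read-only tests."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def het_dataset():
    """Heterogeneity-only planting (no DE), so within-tumor spread is the
    sole planted signal being measured."""
    return simulate_dataset(SimulationConfig(seed=11, n_de=0))


@pytest.fixture(scope="session")
def de_dataset():
    """DE-only planting (no heterogeneity mixture), so the tumor/non-tumor
    mean shift is the sole planted signal being measured."""
    return simulate_dataset(SimulationConfig(seed=11, n_het=0))


@pytest.fixture(scope="session")
def default_panel(default_dataset):
    gt = default_dataset.truth.gene_table
    return GeneList(symbols=list(gt.loc[gt.is_panel, "gene"]))


@pytest.fixture
def tiny_sample_dir(tmp_path):
    """Hand-written 10x-style triplet: 3 genes x 4 spots, plus annotations."""
    d = tmp_path / "sample_t1"
    d.mkdir()
    (d / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate integer general\n"
        "3 4 5\n"
        "1 1 4\n"
        "1 2 2\n"
        "2 3 1\n"
        "3 1 7\n"
        "3 4 3\n"
    )
    (d / "features.tsv").write_text(
        "ENSG01\tGPX9\tGene Expression\n"
        "ENSG02\tSOD9\tGene Expression\n"
        "ENSG03\tCYP999\tGene Expression\n"
    )
    (d / "barcodes.tsv").write_text("BC1-1\nBC2-1\nBC3-1\nBC4-1\n")
    (d / "annotations.csv").write_text(
        "Barcode,Annotation\nBC1-1,DCIS\nBC2-1,stroma\nBC3-1,mixed\nBC4-1,normal\n"
    )
    (d / "tissue_positions.csv").write_text(
        "barcode,in_tissue,array_row,array_col,pxl_row,pxl_col\n"
        "BC1-1,1,0,0,50,50\nBC2-1,1,0,1,50,150\nBC3-1,1,1,0,150,50\nBC4-1,1,1,1,150,150\n"
    )
    return d


def brute_force_quantile(values, p):
    """Independent oracle: sort and linearly interpolate at (n-1)*p."""
    v = sorted(float(x) for x in values)
    n = len(v)
    if n == 1:
        return v[0]
    pos = (n - 1) * p
    lo = int(np.floor(pos))
    frac = pos - lo
    if lo + 1 >= n:
        return v[-1]
    return v[lo] + (v[lo + 1] - v[lo]) * frac


def brute_force_iqr(values):
    return (
        brute_force_quantile(values, 0.25),
        brute_force_quantile(values, 0.75),
        brute_force_quantile(values, 0.75) - brute_force_quantile(values, 0.25),
    )


@pytest.fixture
def go_fixture():
    """Constructed GO annotation table with known keyword matches."""
    return pd.DataFrame(
        [
            # keyword-matching terms
            ("GPX9", "GO:X1", "cellular response to oxidative stress"),
            ("SOD9", "GO:X2", "response to reactive oxygen species"),
            ("NAT9", "GO:X3", "oxygen transport"),
            ("CYP999", "GO:X3", "oxygen transport"),      # excluded by family
            ("ABC999", "GO:X1", "cellular response to oxidative stress"),  # excluded
            ("UGT9", "GO:X4", "stress-activated cascade"),
            # non-matching terms
            ("GPX9", "GO:N1", "glutathione metabolic process"),
            ("SLC99", "GO:N2", "transmembrane transport"),
        ],
        columns=["gene", "go_id", "term_name"],
    )


@pytest.fixture
def go_panel():
    return GeneList(symbols=["GPX9", "SOD9", "NAT9", "CYP999", "ABC999", "UGT9", "SLC99", "NOANN1"])
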