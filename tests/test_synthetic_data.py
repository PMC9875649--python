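import numpy as np
import pandas as pd
import pytest

from spatialpgx.errors import ConfigurationError, ValidationError
from spatialpgx.io import read_annotations, read_count_matrix
from spatialpgx.synthetic_data import (
    SimulationConfig,
    _label_budgets,
    grow_regions,
    simulate_dataset,
    write_fixture,
)


def small_config(**kw):
    base = dict(
        n_samples=2, spots_per_sample=100, grid=(10, 10), n_genes=60,
        n_pharmacogenes=30, n_panel_absent=2, n_het=5, n_de=5, seed=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_grid_too_small_rejected(self):
        with pytest.raises(ConfigurationError, match="grid"):
            simulate_dataset(small_config(grid=(5, 5)))

    def test_null_simulation_allowed(self):
        ds = simulate_dataset(small_config(f_het=1.0, f_de=1.0, library_sigma=0.0))
        assert ds.truth.het_genes == [] and ds.truth.de_genes == []
        # all regions share the same expected means
        rm = ds.truth.region_means
        for col in rm.columns:
            np.testing.assert_array_equal(rm[col], rm.iloc[:, 0])

    def test_bad_proportions_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_dataset(small_config(region_proportions={"tumor": 0.5}))


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        for run in ("a", "b"):
            write_fixture(simulate_dataset(small_config(seed=7)), tmp_path / run)
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                other = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == other.read_bytes(), f.name

    def test_different_seed_different_counts(self):
        a = simulate_dataset(small_config(seed=1))
        b = simulate_dataset(small_config(seed=2))
        assert (a.matrices["sample_01"].dense() != b.matrices["sample_01"].dense()).any()


class TestCountModel:
    def test_poisson_limit_mean(self):
        """phi -> inf: counts are Poisson; sample mean within 3 SE of mu."""
        cfg = SimulationConfig(
            n_samples=1, spots_per_sample=10000, grid=(100, 100), n_genes=2,
            n_pharmacogenes=1, n_het=0, n_de=0, dispersion=np.inf,
            library_sigma=0.0, baseline_log_mean=np.log(5.0), baseline_log_sigma=0.0,
            seed=5,
        )
        counts = simulate_dataset(cfg).matrices["sample_01"].dense()
        se = np.sqrt(5.0 / 10000)
        assert abs(counts[:, 0].mean() - 5.0) < 3 * se

    def test_nb_mean_variance_law(self):
        """Empirical variance over 1e4 spots within 10% of m + m^2/phi."""
        phi, m = 5.0, 4.0
        cfg = SimulationConfig(
            n_samples=1, spots_per_sample=10000, grid=(100, 100), n_genes=2,
            n_pharmacogenes=1, n_het=0, n_de=0, dispersion=phi,
            library_sigma=0.0, baseline_log_mean=np.log(m), baseline_log_sigma=0.0,
            seed=6,
        )
        counts = simulate_dataset(cfg).matrices["sample_01"].dense()[:, 0]
        expected = m + m**2 / phi
        assert abs(counts.var(ddof=1) - expected) / expected < 0.10

    def test_planted_het_genes_have_larger_tumor_iqr(self, default_dataset):
        """f_het=4, p_hi=0.5: every H gene's tumor IQR beats its own NB noise
        floor, and H genes dominate matched non-H genes on average."""
        ds = default_dataset
        truth = ds.truth
        H = set(truth.het_genes)
        genes = ds.matrices["sample_01"].genes
        region = truth.spot_table.set_index(["sample", "barcode"])["region"]
        tumor_blocks = []
        for sid, m in ds.matrices.items():
            mask = np.array([region[(sid, bc)] == "tumor" for bc in m.barcodes])
            tumor_blocks.append(m.dense()[mask])
        tumor = np.vstack(tumor_blocks)
        q25, q75 = np.quantile(tumor, [0.25, 0.75], axis=0)
        iqr = dict(zip(genes, q75 - q25))
        panel = list(truth.gene_table.loc[truth.gene_table.is_panel, "gene"])
        h_iqr = np.mean([iqr[g] for g in panel if g in H])
        non_h_iqr = np.mean([iqr[g] for g in panel if g not in H])
        assert h_iqr > 2 * non_h_iqr


class TestRegionGeometry:
    def test_budgets_are_exact_largest_remainder(self):
        budgets = _label_budgets({"a": 0.5, "b": 0.3, "c": 0.2}, 10)
        assert budgets == {"a": 5, "b": 3, "c": 2}

    def test_label_counts_match_proportions_exactly(self):
        rng = np.random.default_rng(0)
        labels = grow_regions((10, 10), 100, {"tumor": 0.6, "stroma": 0.4}, rng)
        assert labels.count("tumor") == 60 and labels.count("stroma") == 40

    def test_labels_are_spatially_coherent(self):
        """Most spots share their label with at least one grid neighbor."""
        rng = np.random.default_rng(1)
        rows = cols = 20
        labels = grow_regions((rows, cols), rows * cols,
                              {"tumor": 0.5, "stroma": 0.3, "normal": 0.2}, rng)
        grid = np.array(labels).reshape(rows, cols)
        same = 0
        for r in range(rows):
            for c in range(cols):
                nbs = [grid[r + dr, c + dc] for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                       if 0 <= r + dr < rows and 0 <= c + dc < cols]
                same += any(n == grid[r, c] for n in nbs)
        assert same / (rows * cols) > 0.9


class TestFixtureRoundTrip:
    def test_write_then_read_back_equal(self, tmp_path):
        ds = simulate_dataset(small_config())
        write_fixture(ds, tmp_path / "fx")
        for sid, m in ds.matrices.items():
            back = read_count_matrix(
                tmp_path / "fx" / sid / "matrix.mtx",
                tmp_path / "fx" / sid / "features.tsv",
                tmp_path / "fx" / sid / "barcodes.tsv",
                sid,
            )
            np.testing.assert_array_equal(back.dense(), m.dense())
            assert back.genes == m.genes and back.barcodes == m.barcodes
            ann = read_annotations(tmp_path / "fx" / sid / "annotations.csv", sample_id=sid)
            assert ann.regions() == ds.annotations[sid].regions()

    def test_truth_lists_planted_sets(self, tmp_path):
        ds = simulate_dataset(small_config())
        write_fixture(ds, tmp_path / "fx")
        truth = pd.read_csv(tmp_path / "fx" / "truth_genes.tsv", sep="\t")
        assert truth["in_het"].sum() == 5
        assert truth["in_de"].sum() == 5
        assert set(truth.loc[truth.in_het, "gene"]) == set(ds.truth.het_genes)

    def test_annotation_csv_counts_match_proportions(self, tmp_path):
        ds = simulate_dataset(small_config())
        write_fixture(ds, tmp_path / "fx")
        ann = pd.read_csv(tmp_path / "fx" / "sample_01" / "annotations.csv")
        counts = ann.iloc[:, 1].value_counts()
        budgets = _label_budgets(ds.config.region_proportions, ds.config.spots_per_sample)
        for label, n in budgets.items():
            assert counts.get(label, 0) == n

    def test_refuses_nonempty_dir_without_force(self, tmp_path):
        out = tmp_path / "fx"
        out.mkdir()
        (out / "existing.txt").write_text("x")
        ds = simulate_dataset(small_config())
        with pytest.raises(ValidationError):
            write_fixture(ds, out)
        write_fixture(ds, out, force=True)  # with force it proceeds
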