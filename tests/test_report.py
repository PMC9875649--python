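import math

import numpy as np
import pandas as pd
import pytest

from spatialpgx.core import build_grouping
from spatialpgx.heterogeneity import heterogeneity_table
from spatialpgx.io import SpotPositions, read_table
from spatialpgx.report import boxplot_ranked, intensity_map, s_plot, spatial_map

from test_core import make_annotation, make_matrix


@pytest.fixture
def het_fixture():
    m = make_matrix(
        [[0, 0, 0, 5], [4, 2, 0, 5], [8, 4, 0, 5], [12, 6, 0, 5]],
        genes=["A", "B", "C", "D"],
    )
    anns = {"s1": make_annotation(["tumor"] * 4, "s1")}
    grouping = build_grouping(anns, "combined")
    het = heterogeneity_table({"s1": m}, grouping)
    return {"s1": m}, grouping, het


class TestBoxplotRanked:
    def test_iqr_positive_genes_in_descending_order(self, het_fixture, tmp_path):
        matrices, grouping, het = het_fixture
        bundle = boxplot_ranked(matrices, grouping, het, "tumor", 10, tmp_path)
        assert list(dict.fromkeys(bundle.data["gene"])) == ["A", "B"]
        # sidecar holds every plotted spot value
        assert bundle.data.query("gene == 'A'")["value"].tolist() == [0, 4, 8, 12]
        assert bundle.sidecar_path.is_file()

    def test_top_n_limits_boxes(self, het_fixture, tmp_path):
        matrices, grouping, het = het_fixture
        bundle = boxplot_ranked(matrices, grouping, het, "tumor", 1, tmp_path)
        assert set(bundle.data["gene"]) == {"A"}

    def test_empty_selection_warns_not_fails(self, tmp_path):
        m = make_matrix([[5], [5], [5], [5]], genes=["A"])
        anns = {"s1": make_annotation(["tumor"] * 4, "s1")}
        grouping = build_grouping(anns, "combined")
        het = heterogeneity_table({"s1": m}, grouping)
        bundle = boxplot_ranked({"s1": m}, grouping, het, "tumor", 5, tmp_path)
        assert bundle.data.empty


class TestIntensityMap:
    def test_matrix_shape_and_zero_rows_dropped(self, het_fixture, tmp_path):
        _, _, het = het_fixture
        bundle = intensity_map(het, "sample", normalized=False, out_dir=tmp_path)
        # C (all-zero IQR) and D (constant) are dropped; A and B remain
        assert bundle.data["gene"].tolist() == ["A", "B"]
        assert list(bundle.data.columns) == ["gene", "tumor"]

    def test_sidecar_is_the_plotted_matrix(self, het_fixture, tmp_path):
        _, _, het = het_fixture
        bundle = intensity_map(het, "sample", normalized=False, out_dir=tmp_path)
        back = read_table(bundle.sidecar_path)
        a_iqr = het.loc[het.gene == "A", "iqr"].iloc[0]
        assert back.loc[back.gene == "A", "tumor"].iloc[0] == pytest.approx(a_iqr)


class TestSPlot:
    def de_frame(self):
        return pd.DataFrame(
            {
                "gene": ["A", "A", "B", "B"],
                "sample": ["s1", "s2"] * 2,
                "log2fc": [-1.0, -2.0, 1.0, -math.inf],
                "p_raw": [0.01, 0.02, 0.5, 0.001],
                "p_bonferroni": [0.04, 0.08, 1.0, 0.004],
            }
        )

    def test_infinite_records_form_separate_layer(self, tmp_path):
        bundle = s_plot(self.de_frame(), tmp_path)
        inf_rows = bundle.data[bundle.data["is_infinite"]]
        assert len(inf_rows) == 1
        # placed below the lower reference bar: -(max finite |l2fc| + 1)
        assert inf_rows["y_plot"].iloc[0] == -3.0

    def test_all_finite_has_no_infinity_layer(self, tmp_path):
        de = self.de_frame()
        de.loc[3, "log2fc"] = -0.5
        bundle = s_plot(de, tmp_path)
        assert not bundle.data["is_infinite"].any()

    def test_point_count_preserved_under_mirroring(self, tmp_path):
        de = self.de_frame()
        mirrored = de.assign(log2fc=-de["log2fc"])
        assert len(s_plot(de, tmp_path / "a").data) == len(
            s_plot(mirrored, tmp_path / "b").data
        )


class TestSpatialMap:
    def positions(self, barcodes):
        n = len(barcodes)
        return SpotPositions(
            sample_id="s1",
            table=pd.DataFrame(
                {
                    "in_tissue": True,
                    "array_row": range(n),
                    "array_col": 0,
                    "pxl_row": np.arange(n) * 10.0,
                    "pxl_col": 5.0,
                },
                index=pd.Index(barcodes, name="barcode"),
            ),
        )

    def test_zero_sum_spots_omitted_from_plot_layer(self, tmp_path):
        m = make_matrix([[0, 0], [1, 2], [0, 0]], genes=["A", "B"])
        ann = make_annotation(["tumor", "stroma", "normal"])
        bundle = spatial_map(m, self.positions(m.barcodes), ann, ["A", "B"], tmp_path)
        assert (bundle.data["value"] > 0).sum() == 1
        assert bundle.data.loc[bundle.data.value > 0, "barcode"].iloc[0] == "BC1"

    def test_tumor_outline_set_matches_annotation(self, tmp_path, default_dataset, default_panel):
        ds = default_dataset
        sid = "sample_01"
        fam_abc = [g for g in default_panel.symbols if g.startswith("ABC")]
        bundle = spatial_map(
            ds.matrices[sid], ds.positions[sid], ds.annotations[sid], fam_abc, tmp_path
        )
        truth = ds.truth.spot_table.query("sample == @sid").set_index("barcode")["region"]
        plotted = bundle.data.set_index("barcode")["region"]
        assert (plotted == truth.reindex(plotted.index)).all()

    def test_sidecar_bytes_stable_across_runs(self, tmp_path):
        m = make_matrix([[1, 2], [3, 4]], genes=["A", "B"])
        ann = make_annotation(["tumor", "stroma"])
        b1 = spatial_map(m, self.positions(m.barcodes), ann, ["A"], tmp_path / "r1")
        b2 = spatial_map(m, self.positions(m.barcodes), ann, ["A"], tmp_path / "r2")
        assert b1.sidecar_path.read_bytes() == b2.sidecar_path.read_bytes()
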