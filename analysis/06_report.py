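"""Render the presentation surfaces from the pipeline tables.

Ranked tumor boxplots, per-sample and per-region IQR intensity maps (raw and
normalized), the DE S-plot with its infinity layer, and a spatial map of ABC
transporter expression for the first sample.  Figures (PNG+SVG) and their
sidecar TSVs go under results/figures/.
"""

import argparse
from pathlib import Path

from spatialpgx.categorize import assign_families
from spatialpgx.core import build_grouping, filter_genes
from spatialpgx.heterogeneity import heterogeneity_table
from spatialpgx.io import read_gene_list, read_table
from spatialpgx.pipeline import load_fixture_dir
from spatialpgx.report import boxplot_ranked, intensity_map, s_plot, spatial_map

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixture", type=Path, default=ROOT / "results" / "fixture")
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    het = read_table(args.results / "heterogeneity.tsv")
    de = read_table(args.results / "de.tsv")
    matrices, annotations, positions = load_fixture_dir(args.fixture)
    panel = read_gene_list(args.fixture / "panel.tsv")
    raw = {sid: filter_genes(m, panel)[0] for sid, m in matrices.items()}
    grouping = build_grouping(annotations, "combined")

    figs = args.results / "figures"
    bundles = [
        boxplot_ranked(
            raw, grouping,
            het[(het.grouping_mode == "combined") & (~het.normalized)],
            "tumor", 35, figs,
        ),
        intensity_map(het[het.grouping_mode == "sample"], "sample", False, figs),
        intensity_map(het[het.grouping_mode == "sample"], "sample", True, figs),
        intensity_map(het[het.grouping_mode == "region"], "region", False, figs),
        intensity_map(het[het.grouping_mode == "region"], "region", True, figs),
        s_plot(de, figs),
    ]
    families = assign_families(panel)
    abc = [g for g in panel.symbols if families.families.get(g) == "ABC"]
    sid = sorted(matrices)[0]
    if abc and sid in positions:
        bundles.append(
            spatial_map(raw[sid], positions[sid], annotations[sid], abc, figs,
                        name=f"spatial_map_abc_{sid}")
        )
    for b in bundles:
        print(f"{b.name}: {len(b.data)} sidecar rows -> {b.sidecar_path}")


if __name__ == "__main__":
    main()
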