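"""Load the fixture, normalize per spot, and filter to the pharmacogene panel.

Reports per-sample spot totals, zero-total spots dropped, and how many panel
symbols were absent from the matrices (the 298-style panel loaded against
the matrix keeps 286 here).  Writes results/preprocess_summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from spatialpgx.core import filter_genes, normalize_per_spot
from spatialpgx.io import read_gene_list, write_table
from spatialpgx.pipeline import load_fixture_dir

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixture", type=Path, default=ROOT / "results" / "fixture")
    args = ap.parse_args()

    matrices, annotations, _ = load_fixture_dir(args.fixture)
    panel = read_gene_list(args.fixture / "panel.tsv")

    rows = []
    missing = []
    for sid, m in matrices.items():
        norm = normalize_per_spot(m)
        filtered, missing = filter_genes(m, panel)
        rows.append(
            {
                "sample": sid,
                "n_spots": m.n_spots,
                "n_genes": m.n_genes,
                "median_umi_per_spot": float(pd.Series(m.total_counts()).median()),
                "n_zero_total_dropped": len(norm.dropped_barcodes),
                "n_panel_genes_present": filtered.n_genes,
            }
        )
    summary = pd.DataFrame(rows)
    write_table(summary, ROOT / "results" / "preprocess_summary.tsv")
    print(summary.to_string(index=False))
    print(f"panel: {len(panel)} symbols, {len(panel) - len(missing)} present, "
          f"{len(missing)} absent from the matrices: {missing}")


if __name__ == "__main__":
    main()
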