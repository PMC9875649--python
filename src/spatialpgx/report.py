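"""Presentation surfaces: ranked boxplots, IQR intensity maps, DE S-plots,
and spatial intensity maps.

Every figure is a best-effort visual analog; the tested contract is the
sidecar TSV written next to it, which contains exactly the plotted numbers
and is byte-stable given identical inputs.  No statistic is computed here —
this module only arranges tables produced upstream.

Infinite log2 fold changes are drawn as a separate layer at
+/-(max finite |log2fc| + 1), with reference bars at +/-max finite |log2fc|,
so zero-vs-nonzero comparisons sit visibly above/below the bars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import NormalizedMatrix, SpotGrouping, group_values
from .errors import ValidationError
from .io import AnnotationTable, GeneList, SpotPositions, UMICountMatrix, write_table

logger = logging.getLogger(__name__)


@dataclass
class FigureBundle:
    """A rendered figure plus the sidecar holding exactly its numbers."""

    name: str
    figure_paths: list[Path]
    sidecar_path: Path
    data: pd.DataFrame


def _render(fig: plt.Figure, out_dir: Path, name: str, data: pd.DataFrame) -> FigureBundle:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ext in ("png", "svg"):
        p = out_dir / f"{name}.{ext}"
        fig.savefig(p, dpi=120, metadata={"Date": None} if ext == "svg" else None)
        paths.append(p)
    plt.close(fig)
    sidecar = out_dir / f"{name}.sidecar.tsv"
    write_table(data, sidecar)
    return FigureBundle(name=name, figure_paths=paths, sidecar_path=sidecar, data=data)


def boxplot_ranked(
    matrices: Mapping[str, UMICountMatrix | NormalizedMatrix],
    grouping: SpotGrouping,
    het: pd.DataFrame,
    group: str,
    top_n: int,
    out_dir: str | Path,
    name: str = "boxplot_ranked",
) -> FigureBundle:
    """Boxplots of spot-level values for IQR>0 genes, descending-IQR order.

    The sidecar holds one row per (gene, spot value) in plotted order.
    """
    sub = het[(het["group"] == group) & (het["iqr"] > 0)]
    sub = sub.sort_values(["iqr", "gene"], ascending=[False, True], kind="mergesort")
    genes = list(sub["gene"].head(top_n))
    if not genes:
        logger.warning("boxplot_ranked: no IQR>0 genes in group %s", group)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.set_title(f"{group}: no genes with IQR > 0")
        return _render(fig, Path(out_dir), name, pd.DataFrame(columns=["gene", "value"]))

    if group not in grouping.groups:
        raise ValidationError(f"group {group!r} absent from grouping")
    block = group_values(matrices, grouping.groups[group])
    first = next(iter(matrices.values()))
    gene_idx = {g: i for i, g in enumerate(first.genes)}
    series = {g: block[:, gene_idx[g]] for g in genes}

    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(genes)), 4))
    ax.boxplot([series[g] for g in genes], tick_labels=genes)
    ax.set_ylabel("expression per spot")
    ax.set_title(f"{group}: genes with IQR > 0 (descending)")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()

    data = pd.DataFrame(
        [(g, float(v)) for g in genes for v in series[g]], columns=["gene", "value"]
    )
    return _render(fig, Path(out_dir), name, data)


def intensity_map(
    het: pd.DataFrame,
    axis: str,
    normalized: bool,
    out_dir: str | Path,
    name: str | None = None,
) -> FigureBundle:
    """Gene x group heatmap of IQR values; rows with all-zero IQR dropped.

    ``axis`` is descriptive only (``sample`` or ``region``): the columns are
    the groups present in the supplied table, which the caller builds with
    the matching grouping mode.  The sidecar is the plotted matrix.
    """
    sub = het[het["normalized"] == normalized]
    if sub.empty:
        raise ValidationError(f"intensity_map: no records with normalized={normalized}")
    pivot = sub.pivot_table(index="gene", columns="group", values="iqr", aggfunc="first")
    pivot = pivot.fillna(0.0)
    pivot = pivot.loc[(pivot > 0).any(axis=1)]
    pivot = pivot.sort_index().sort_index(axis=1)

    fig, ax = plt.subplots(figsize=(max(4, 0.5 * pivot.shape[1] + 2), max(3, 0.18 * len(pivot))))
    if pivot.size:
        im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis")
        fig.colorbar(im, ax=ax, label="IQR")
        ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(pivot)), pivot.index, fontsize=5)
    kind = "normalized" if normalized else "raw"
    ax.set_title(f"IQR per gene per {axis} ({kind})")
    fig.tight_layout()

    data = pivot.rename_axis("gene").reset_index()
    return _render(fig, Path(out_dir), name or f"intensity_map_{axis}_{kind}", data)


def s_plot(de: pd.DataFrame, out_dir: str | Path, name: str = "s_plot") -> FigureBundle:
    """Per-(gene, sample) log2 fold changes, ascending by per-gene mean.

    Infinite values are a separate layer beyond the reference bars; the
    sidecar carries the plotted y position and an ``is_infinite`` column.
    """
    if de.empty:
        raise ValidationError("s_plot: empty DE table")
    plot = de[de["log2fc"].notna()].copy()  # both-zero records have nothing to plot
    finite = plot["log2fc"][np.isfinite(plot["log2fc"])]
    bar = float(np.abs(finite).max()) if len(finite) else 1.0
    inf_y = bar + 1.0

    gene_order = {g: i for i, g in enumerate(dict.fromkeys(plot["gene"]))}
    plot["x"] = plot["gene"].map(gene_order)
    plot["is_infinite"] = ~np.isfinite(plot["log2fc"])
    plot["y_plot"] = np.where(
        plot["is_infinite"], np.sign(plot["log2fc"]) * inf_y, plot["log2fc"]
    )

    fig, ax = plt.subplots(figsize=(8, 4))
    fin = plot[~plot["is_infinite"]]
    inf = plot[plot["is_infinite"]]
    ax.scatter(fin["x"], fin["y_plot"], s=8, c=-np.log10(fin["p_bonferroni"].clip(lower=1e-300)),
               cmap="plasma")
    if len(inf):
        ax.scatter(inf["x"], inf["y_plot"], s=8, c="tab:red", marker="^")
    if len(finite):
        ax.axhline(bar, color="black")
        ax.axhline(-bar, color="black")
    ax.set_xlabel("genes (ascending mean fold change)")
    ax.set_ylabel("log2 fold change (tumor vs non-tumor)")
    fig.tight_layout()

    data = plot[["gene", "sample", "log2fc", "p_bonferroni", "x", "y_plot", "is_infinite"]]
    data = data.reset_index(drop=True)
    return _render(fig, Path(out_dir), name, data)


def spatial_map(
    matrix: UMICountMatrix | NormalizedMatrix,
    positions: SpotPositions,
    annotations: AnnotationTable,
    gene_set: GeneList | Sequence[str],
    out_dir: str | Path,
    name: str = "spatial_map",
) -> FigureBundle:
    """Per-spot summed expression over ``gene_set`` at spot coordinates.

    Zero-sum spots are omitted; tumor-annotated spots get a black outline.
    The sidecar holds the per-spot sums with coordinates and region.
    """
    symbols = list(gene_set.symbols if isinstance(gene_set, GeneList) else gene_set)
    gene_idx = {g: i for i, g in enumerate(matrix.genes)}
    cols = [gene_idx[g] for g in symbols if g in gene_idx]
    arr = matrix.counts if isinstance(matrix, UMICountMatrix) else matrix.values
    sums = (
        np.asarray(arr[:, cols].sum(axis=1)).ravel()
        if cols
        else np.zeros(matrix.n_spots)
    )

    coords = positions.coords(matrix.barcodes)
    missing = coords["pxl_row"].isna()
    if missing.any():
        logger.warning(
            "spatial_map: %d barcode(s) missing coordinates; dropped", int(missing.sum())
        )
    regions = annotations.regions()
    rows = []
    for bc, total, (_, pos) in zip(matrix.barcodes, sums, coords.iterrows()):
        if np.isnan(pos["pxl_row"]):
            continue
        rows.append(
            {
                "barcode": bc,
                "pxl_row": float(pos["pxl_row"]),
                "pxl_col": float(pos["pxl_col"]),
                "value": float(total),
                "region": regions.get(bc, "unannotated"),
            }
        )
    data = pd.DataFrame(rows, columns=["barcode", "pxl_row", "pxl_col", "value", "region"])
    shown = data[data["value"] > 0]

    fig, ax = plt.subplots(figsize=(5, 5))
    if len(shown):
        tumor = shown["region"] == "tumor"
        ax.scatter(
            shown.loc[tumor, "pxl_col"], shown.loc[tumor, "pxl_row"],
            c=shown.loc[tumor, "value"], cmap="viridis", s=30,
            edgecolors="black", linewidths=0.8,
        )
        sc = ax.scatter(
            shown.loc[~tumor, "pxl_col"], shown.loc[~tumor, "pxl_row"],
            c=shown.loc[~tumor, "value"], cmap="viridis", s=30,
        )
        fig.colorbar(sc, ax=ax, label="summed expression")
    ax.invert_yaxis()
    ax.set_title(f"{matrix.sample_id}: {len(symbols)} gene(s), tumor outlined")
    ax.set_aspect("equal")
    fig.tight_layout()
    return _render(fig, Path(out_dir), name, data)
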