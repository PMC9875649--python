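"""Interquartile-range heterogeneity of spot-level expression.

Heterogeneity of a gene within a group of spots is scored as the
interquartile range (75th minus 25th percentile) of its per-spot expression.
The IQR characterises spread without being dominated by outlier spots, and —
deliberately — no log transform is applied, so the score is in count (or
expression-fraction) units.

Quantiles use linear interpolation at position (n-1)*p between order
statistics, the common default in mainstream statistical environments; the
convention is recorded in the output so results are auditable.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .core import NormalizedMatrix, SpotGrouping, group_values
from .errors import ValidationError
from .io import GeneList, UMICountMatrix

logger = logging.getLogger(__name__)

#: Quantile convention recorded in table metadata.
QUANTILE_METHOD = "linear"

#: Groups smaller than this get a low-n flag (quantiles are still defined).
LOW_N = 4


def iqr(values) -> tuple[float, float, float]:
    """Return (Q25, Q75, IQR) of ``values`` with linear interpolation.

    IQR = Q75 - Q25 >= 0.  Raises on empty input.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("iqr: empty input")
    q25, q75 = np.quantile(arr, [0.25, 0.75], method=QUANTILE_METHOD)
    return float(q25), float(q75), float(q75 - q25)


def heterogeneity_table(
    matrices: Mapping[str, UMICountMatrix | NormalizedMatrix] | UMICountMatrix | NormalizedMatrix,
    grouping: SpotGrouping,
    normalized: bool | None = None,
) -> pd.DataFrame:
    """Per-(gene, group) IQR records, ranked by descending IQR within group.

    Columns: gene, group, n_spots, q25, q75, iqr, normalized, low_n, rank.
    Ties on IQR rank lexicographically by gene symbol so output is
    deterministic across runs and platforms.
    """
    if isinstance(matrices, (UMICountMatrix, NormalizedMatrix)):
        matrices = {matrices.sample_id: matrices}
    first = next(iter(matrices.values()))
    genes = list(first.genes)
    for m in matrices.values():
        if list(m.genes) != genes:
            raise ValidationError("heterogeneity_table: samples have differing gene lists")
    if normalized is None:
        normalized = isinstance(first, NormalizedMatrix)

    records = []
    for label in sorted(grouping.groups):
        members = grouping.groups[label]
        block = group_values(matrices, members)
        n = block.shape[0]
        if n == 0:
            logger.warning("heterogeneity: group %s has no spots; skipped", label)
            continue
        if n < LOW_N:
            logger.warning("heterogeneity: group %s has only %d spot(s)", label, n)
        q25, q75 = np.quantile(block, [0.25, 0.75], axis=0, method=QUANTILE_METHOD)
        sub = pd.DataFrame(
            {
                "gene": genes,
                "group": label,
                "n_spots": n,
                "q25": q25,
                "q75": q75,
                "iqr": q75 - q25,
                "normalized": bool(normalized),
                "low_n": n < LOW_N,
            }
        )
        sub = sub.sort_values(["iqr", "gene"], ascending=[False, True], kind="mergesort")
        sub["rank"] = np.arange(1, len(sub) + 1)
        records.append(sub)
    if not records:
        return pd.DataFrame(
            columns=["gene", "group", "n_spots", "q25", "q75", "iqr",
                     "normalized", "low_n", "rank"]
        )
    return pd.concat(records, ignore_index=True)


def select_iqr_positive(table: pd.DataFrame, group: str) -> GeneList:
    """Genes with IQR > 0 in ``group``, in descending-IQR order.

    This selection (IQR strictly above zero on raw counts, in the tumor
    group) is the export surface for downstream gene-set analyses.
    """
    if group not in set(table["group"]):
        raise ValidationError(f"group {group!r} not present in heterogeneity table")
    sub = table[(table["group"] == group) & (table["iqr"] > 0)]
    sub = sub.sort_values(["iqr", "gene"], ascending=[False, True], kind="mergesort")
    return GeneList(symbols=list(sub["gene"]))
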