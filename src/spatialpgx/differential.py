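"""Tumor-per-sample vs combined-non-tumor differential expression.

For every pharmacogene and every sample, the tumor spots of that sample are
compared against the non-tumor spots (normal + lymphocytes + stroma) pooled
across ALL samples, on per-spot expression fractions.  Three deliberately
unusual contracts:

* **Infinity retention.**  log2 fold changes where exactly one group mean is
  zero are kept as signed infinity rather than discarded or pseudocounted —
  a zero group mean is informative (no detected expression) and the
  comparison is reported as +inf (tumor-only expression) or -inf
  (non-tumor-only).  Both means zero yields no fold change and no test.
* **Welch's t on the same values as the fold change**, zeros included as
  data points; zeros are only special for the mean-ratio infinity rule.
* **Bonferroni over tests actually performed**: corrected p = min(1, p * M)
  where M counts records where a test was carried out, not all gene x sample
  combinations.

Degenerate variance (both sample variances zero) with equal means gives
t = 0, p = 1; with unequal means the t statistic is undefined, the record is
flagged ``degenerate_variance`` with p = NA and it does not count toward M —
silently returning p = 0 would fabricate significance.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .core import NONTUMOR_REGIONS, NormalizedMatrix, group_values
from .errors import ValidationError
from .io import AnnotationTable

logger = logging.getLogger(__name__)

#: Minimal group size for which Welch's test is defined (sample variances).
MIN_GROUP = 2

FLAG_POS_INF = "pos_inf"
FLAG_NEG_INF = "neg_inf"
FLAG_BOTH_ZERO = "both_zero"
FLAG_DEGENERATE = "degenerate_variance"
FLAG_LOW_N = "low_n"


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sided t-test: returns (t, nu, p).

    t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny) with unbiased sample
    variances; degrees of freedom nu by Welch–Satterthwaite; p two-sided
    from the t distribution.  Requires >= 2 observations per group.

    Both variances zero: returns (0, nx+ny-2, 1) when the means are equal,
    and (nan, nan, nan) otherwise — the caller flags such records.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < MIN_GROUP or y.size < MIN_GROUP:
        raise ValidationError(
            f"welch_t: need >= {MIN_GROUP} observations per group, got {x.size}, {y.size}"
        )
    nx, ny = x.size, y.size
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return 0.0, float(nx + ny - 2), 1.0
        return math.nan, math.nan, math.nan
    t = (mx - my) / math.sqrt(se2)
    nu = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(scipy.stats.t.sf(abs(t), nu))
    return float(t), float(nu), min(p, 1.0)


def log2_fold_change(mean_tumor: float, mean_nontumor: float) -> float:
    """log2(m_T / m_N) on the extended reals; NaN when both means are zero."""
    if mean_tumor == 0.0 and mean_nontumor == 0.0:
        return math.nan
    if mean_nontumor == 0.0:
        return math.inf
    if mean_tumor == 0.0:
        return -math.inf
    return math.log2(mean_tumor / mean_nontumor)


def de_table(
    matrices: Mapping[str, NormalizedMatrix],
    annotations: Mapping[str, AnnotationTable],
) -> pd.DataFrame:
    """One record per (gene, sample): fold change, Welch test, Bonferroni.

    Columns: gene, sample, n_tumor, n_nontumor, mean_tumor, mean_nontumor,
    log2fc, t, df, p_raw, p_bonferroni, flags.  Samples without tumor spots
    are omitted with a warning.  Rows are sorted by per-gene mean finite
    log2 fold change (ascending), then gene, then sample.
    """
    first = next(iter(matrices.values()))
    genes = list(first.genes)
    for m in matrices.values():
        if list(m.genes) != genes:
            raise ValidationError("de_table: samples have differing gene lists")

    nontumor_members = [
        (sid, bc)
        for sid, ann in annotations.items()
        for bc, region in ann.regions().items()
        if region in NONTUMOR_REGIONS
    ]
    y = group_values(matrices, nontumor_members)
    if y.shape[0] < MIN_GROUP:
        raise ValidationError(
            f"combined non-tumor group has {y.shape[0]} spot(s); need >= {MIN_GROUP}"
        )
    ny = y.shape[0]
    my = y.mean(axis=0)
    vy = y.var(axis=0, ddof=1)

    records = []
    for sid in sorted(matrices):
        ann = annotations[sid]
        tumor_members = [
            (sid, bc) for bc, region in ann.regions().items() if region == "tumor"
        ]
        x = group_values({sid: matrices[sid]}, tumor_members)
        nx = x.shape[0]
        if nx == 0:
            logger.warning("de_table: sample %s has no tumor spots; omitted", sid)
            continue
        mx = x.mean(axis=0)
        vx = x.var(axis=0, ddof=1) if nx >= 2 else np.full(len(genes), np.nan)

        for i, gene in enumerate(genes):
            flags = []
            l2fc = log2_fold_change(float(mx[i]), float(my[i]))
            if math.isnan(l2fc):
                flags.append(FLAG_BOTH_ZERO)
            elif l2fc == math.inf:
                flags.append(FLAG_POS_INF)
            elif l2fc == -math.inf:
                flags.append(FLAG_NEG_INF)

            t = df = p = math.nan
            if math.isnan(l2fc):
                pass  # both means zero: no comparison, no test
            elif nx < MIN_GROUP:
                flags.append(FLAG_LOW_N)
            else:
                se2 = vx[i] / nx + vy[i] / ny
                if se2 == 0.0:
                    if mx[i] == my[i]:
                        t, df, p = 0.0, float(nx + ny - 2), 1.0
                    else:
                        flags.append(FLAG_DEGENERATE)
                else:
                    t = float((mx[i] - my[i]) / np.sqrt(se2))
                    df = float(
                        se2**2
                        / ((vx[i] / nx) ** 2 / (nx - 1) + (vy[i] / ny) ** 2 / (ny - 1))
                    )
                    p = min(2.0 * float(scipy.stats.t.sf(abs(t), df)), 1.0)

            records.append(
                {
                    "gene": gene,
                    "sample": sid,
                    "n_tumor": nx,
                    "n_nontumor": ny,
                    "mean_tumor": float(mx[i]),
                    "mean_nontumor": float(my[i]),
                    "log2fc": l2fc,
                    "t": t,
                    "df": df,
                    "p_raw": p,
                    "p_bonferroni": math.nan,
                    "flags": ";".join(flags),
                }
            )

    table = pd.DataFrame(records)
    if table.empty:
        raise ValidationError("de_table: no sample contributed tumor spots")

    n_tests = int(table["p_raw"].notna().sum())
    table["p_bonferroni"] = np.minimum(1.0, table["p_raw"] * n_tests)
    logger.info("de_table: %d records, %d tests performed (Bonferroni M)", len(table), n_tests)

    # S-plot order: ascending per-gene mean finite fold change.
    order = _gene_order(table)
    table["_o"] = table["gene"].map(order)
    table = (
        table.sort_values(["_o", "gene", "sample"], kind="mergesort")
        .drop(columns="_o")
        .reset_index(drop=True)
    )
    table.attrs["n_tests"] = n_tests
    return table


def _gene_order(table: pd.DataFrame) -> dict[str, int]:
    """Rank genes ascending by mean finite log2fc; all-infinite genes last."""
    finite = table[np.isfinite(table["log2fc"])]
    means = finite.groupby("gene")["log2fc"].mean()
    keys = sorted(
        table["gene"].unique(),
        key=lambda g: (0, means[g], g) if g in means else (1, 0.0, g),
    )
    return {g: i for i, g in enumerate(keys)}


def summarize_global(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene roll-up of the DE table, ascending by mean finite log2fc.

    Columns: gene, n_samples, mean_log2fc (finite records only; NA when
    every record is infinite or absent), n_pos_inf, n_neg_inf, n_inf,
    min_p_bonferroni, down_in_all — the latter fires when every sample's
    record is significant at ``alpha`` with a negative fold change
    (-inf counts as negative).
    """
    if table.empty:
        raise ValidationError("summarize_global: empty DE table")
    rows = []
    for gene, sub in table.groupby("gene", sort=False):
        l2 = sub["log2fc"]
        finite = l2[np.isfinite(l2)]
        n_pos = int((l2 == np.inf).sum())
        n_neg = int((l2 == -np.inf).sum())
        tested = sub["p_raw"].notna()
        down_in_all = bool(
            len(sub)
            and (tested & (sub["p_bonferroni"] < alpha) & (l2 < 0)).all()
        )
        rows.append(
            {
                "gene": gene,
                "n_samples": len(sub),
                "mean_log2fc": float(finite.mean()) if len(finite) else math.nan,
                "n_pos_inf": n_pos,
                "n_neg_inf": n_neg,
                "n_inf": n_pos + n_neg,
                "min_p_bonferroni": float(sub["p_bonferroni"].min())
                if tested.any()
                else math.nan,
                "down_in_all": down_in_all,
            }
        )
    out = pd.DataFrame(rows)
    out["_na"] = out["mean_log2fc"].isna()
    out = (
        out.sort_values(["_na", "mean_log2fc", "gene"], kind="mergesort")
        .drop(columns="_na")
        .reset_index(drop=True)
    )
    return out
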