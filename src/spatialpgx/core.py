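"""Shared preprocessing: per-spot normalization, panel filtering, grouping.

Normalization divides each spot's counts by that spot's total UMI count
(TPM-like, without the x1e6 rescale), so each retained spot's values sum to
one.  The denominator is the total over ALL genes — normalising against
panel-only totals would reintroduce composition artifacts.  The pipeline
normalises on the full matrix first and filters to the pharmacogene panel
afterwards; a test pins that order.

Spot grouping supports the three categorizations the analyses need:
per-sample-within-region, per-region-across-samples, and all tumor spots
combined.  Mixed and unannotated spots appear in no group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError
from .io import (
    EXCLUDED_REGIONS,
    AnnotationTable,
    GeneList,
    UMICountMatrix,
)

logger = logging.getLogger(__name__)

#: Grouping modes.
MODE_SAMPLE = "sample"      # per-sample-within-region
MODE_REGION = "region"      # per-region-across-samples
MODE_COMBINED = "combined"  # all tumor spots, one group
GROUPING_MODES = (MODE_SAMPLE, MODE_REGION, MODE_COMBINED)

#: Regions that enter statistics (tumor composite already applied upstream).
INCLUDED_REGIONS = ("tumor", "stroma", "lymphocytes", "normal")

#: The combined non-tumor comparator for differential expression.
NONTUMOR_REGIONS = ("stroma", "lymphocytes", "normal")


@dataclass
class NormalizedMatrix:
    """Spot x gene matrix of per-spot expression fractions r_ij = c_ij / T_j."""

    sample_id: str
    barcodes: list[str]
    genes: list[str]
    values: sp.csr_matrix  # spots x genes, float
    dropped_barcodes: list[str] = field(default_factory=list)

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def barcode_index(self) -> dict[str, int]:
        return {bc: j for j, bc in enumerate(self.barcodes)}

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class SpotGrouping:
    """Disjoint groups of (sample, barcode) pairs under one grouping mode."""

    mode: str
    groups: dict[str, list[tuple[str, str]]]

    def sizes(self) -> dict[str, int]:
        return {g: len(m) for g, m in self.groups.items()}

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for label, members in self.groups.items():
            overlap = seen.intersection(members)
            if overlap:
                raise ValidationError(
                    f"grouping mode {self.mode}: group {label} overlaps earlier "
                    f"groups on {len(overlap)} spot(s)"
                )
            seen.update(members)


def normalize_per_spot(matrix: UMICountMatrix) -> NormalizedMatrix:
    """Divide each spot's counts by its total UMI count.

    Spots with a zero total are dropped and their barcodes reported on the
    returned object and in the log.
    """
    totals = matrix.total_counts().astype(float)
    keep = totals > 0
    dropped = [bc for bc, k in zip(matrix.barcodes, keep) if not k]
    if dropped:
        logger.warning(
            "sample %s: dropped %d zero-total spot(s): %s",
            matrix.sample_id, len(dropped), dropped[:5],
        )
    counts = matrix.counts[keep]
    inv = sp.diags(1.0 / totals[keep])
    values = sp.csr_matrix(inv @ counts.astype(float))
    return NormalizedMatrix(
        sample_id=matrix.sample_id,
        barcodes=[bc for bc, k in zip(matrix.barcodes, keep) if k],
        genes=list(matrix.genes),
        values=values,
        dropped_barcodes=dropped,
    )


def filter_genes(
    matrix: UMICountMatrix | NormalizedMatrix, panel: GeneList
) -> tuple[UMICountMatrix | NormalizedMatrix, list[str]]:
    """Restrict columns to panel symbols present in the matrix.

    Panel order is preserved.  Returns the filtered matrix and the list of
    panel symbols not found.  Zero panel genes present is an error: the
    pipeline cannot proceed.
    """
    gene_idx = {g: i for i, g in enumerate(matrix.genes)}
    present = [g for g in panel.symbols if g in gene_idx]
    missing = [g for g in panel.symbols if g not in gene_idx]
    if not present:
        raise ValidationError(
            f"sample {matrix.sample_id}: none of the {len(panel)} panel genes "
            "are present in the matrix"
        )
    cols = [gene_idx[g] for g in present]
    if isinstance(matrix, UMICountMatrix):
        return (
            UMICountMatrix(
                sample_id=matrix.sample_id,
                barcodes=list(matrix.barcodes),
                genes=present,
                counts=sp.csr_matrix(matrix.counts[:, cols]),
            ),
            missing,
        )
    return (
        NormalizedMatrix(
            sample_id=matrix.sample_id,
            barcodes=list(matrix.barcodes),
            genes=present,
            values=sp.csr_matrix(matrix.values[:, cols]),
            dropped_barcodes=list(matrix.dropped_barcodes),
        ),
        missing,
    )


def build_grouping(
    annotations: Mapping[str, AnnotationTable],
    mode: str,
    regions: Sequence[str] | None = None,
) -> SpotGrouping:
    """Group included (non-mixed, annotated) spots per the requested mode.

    ``regions`` optionally restricts which composite regions form groups
    (e.g. tumor only).  A requested group ending up empty is emitted empty
    with a warning, never an error.
    """
    if mode not in GROUPING_MODES:
        raise ValidationError(f"unknown grouping mode {mode!r}; use one of {GROUPING_MODES}")
    wanted = tuple(regions) if regions is not None else INCLUDED_REGIONS
    for r in wanted:
        if r in EXCLUDED_REGIONS:
            raise ValidationError(f"region {r!r} is excluded from all statistics")

    groups: dict[str, list[tuple[str, str]]] = {}
    if mode == MODE_COMBINED:
        groups["tumor"] = []
    elif mode == MODE_REGION:
        for r in wanted:
            groups[r] = []
    else:
        for sid in annotations:
            for r in wanted:
                groups[f"{sid}:{r}"] = []

    for sid, ann in annotations.items():
        for bc, region in ann.regions().items():
            if region in EXCLUDED_REGIONS:
                continue
            if mode == MODE_COMBINED:
                if region == "tumor":
                    groups["tumor"].append((sid, bc))
            elif mode == MODE_REGION:
                if region in wanted:
                    groups[region].append((sid, bc))
            else:
                if region in wanted:
                    groups[f"{sid}:{region}"].append((sid, bc))

    for label, members in groups.items():
        if not members:
            logger.warning("grouping mode %s: group %s is empty", mode, label)
    logger.info("grouping %s: sizes %s", mode, {g: len(m) for g, m in groups.items()})
    return SpotGrouping(mode=mode, groups=groups)


def group_values(
    matrices: Mapping[str, UMICountMatrix | NormalizedMatrix],
    members: Sequence[tuple[str, str]],
) -> np.ndarray:
    """Stack the (spots-in-group) x genes value block across samples.

    Barcodes dropped during normalization (zero totals) are skipped.
    """
    blocks = []
    for sid, mat in matrices.items():
        idx = mat.barcode_index()
        rows = [idx[bc] for s, bc in members if s == sid and bc in idx]
        if rows:
            arr = mat.counts if isinstance(mat, UMICountMatrix) else mat.values
            blocks.append(np.asarray(arr[rows].todense(), dtype=float))
    if not blocks:
        n_genes = next(iter(matrices.values())).n_genes
        return np.empty((0, n_genes))
    return np.vstack(blocks)
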