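"""Readers and writers for the on-disk formats the pipeline consumes and emits.

Input side: 10x-Genomics-style per-sample triplets (MatrixMarket counts +
features/barcodes TSVs), tissue-position CSVs, Loupe-style annotation CSVs
(barcode -> pathologist label), and pharmacogene panel lists.  Output side:
plain TSV tables in which ``inf``/``-inf`` are first-class values (zero-vs-
nonzero fold changes are retained as signed infinity downstream) and missing
values are written as ``NA``.

All text readers accept plain or gzip files transparently.  On disk the count
matrix follows the 10x convention (genes as MTX rows); in memory every matrix
is spot-major (spots x genes).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Enumerated composite regions every raw pathologist label maps into.
REGIONS = ("tumor", "stroma", "lymphocytes", "normal", "mixed", "unannotated")

#: Regions excluded from every statistic.
EXCLUDED_REGIONS = frozenset({"mixed", "unannotated"})

#: Composite-region mapping: tumor subtypes (DCIS, cellular tumor,
#: desmoplastic tumor) collapse into the tumor region; keys are lowercase.
DEFAULT_REGION_MAPPING: dict[str, str] = {
    "tumor": "tumor",
    "dcis": "tumor",
    "cellular tumor": "tumor",
    "desmoplastic tumor": "tumor",
    "stroma": "stroma",
    "lymphocytes": "lymphocytes",
    "normal": "normal",
    "mixed": "mixed",
}


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class UMICountMatrix:
    """Sparse nonnegative-integer spot x gene UMI count matrix for one sample.

    ``counts[j, i]`` is the deduplicated transcript (UMI) count of gene ``i``
    in spot ``j``.
    """

    sample_id: str
    barcodes: list[str]
    genes: list[str]
    counts: sp.csr_matrix  # spots x genes

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError(f"duplicate barcodes in sample {self.sample_id}")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"duplicate gene symbols in sample {self.sample_id}")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValidationError(
                f"sample {self.sample_id}: counts must be nonnegative integers"
            )

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def barcode_index(self) -> dict[str, int]:
        return {bc: j for j, bc in enumerate(self.barcodes)}

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def total_counts(self) -> np.ndarray:
        """Per-spot total UMI count T_j over all genes."""
        return np.asarray(self.counts.sum(axis=1)).ravel()


@dataclass
class AnnotationTable:
    """Barcode -> pathologist label for one sample, plus the composite map.

    ``raw_labels`` keeps the free-text export verbatim; ``region(barcode)``
    resolves through the composite mapping, sending tumor subtypes to
    ``tumor`` and unknown labels to ``unannotated``.
    """

    sample_id: str
    raw_labels: dict[str, str]
    mapping: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_REGION_MAPPING))

    def region_of_label(self, raw_label: str) -> str:
        return self.mapping.get(raw_label.strip().lower(), "unannotated")

    def region(self, barcode: str) -> str:
        raw = self.raw_labels.get(barcode)
        if raw is None:
            return "unannotated"
        return self.region_of_label(raw)

    def regions(self) -> dict[str, str]:
        return {bc: self.region_of_label(lbl) for bc, lbl in self.raw_labels.items()}

    def is_excluded(self, barcode: str) -> bool:
        return self.region(barcode) in EXCLUDED_REGIONS

    def included_barcodes(self) -> list[str]:
        return [bc for bc in self.raw_labels if not self.is_excluded(bc)]

    def region_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for reg in self.regions().values():
            counts[reg] = counts.get(reg, 0) + 1
        return counts


@dataclass
class SpotPositions:
    """Spot array/pixel coordinates for one sample (tissue_positions CSV)."""

    sample_id: str
    table: pd.DataFrame  # index barcode; columns in_tissue, array_row, array_col, pxl_row, pxl_col

    def __post_init__(self) -> None:
        required = {"in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"positions table missing columns {sorted(missing)}")
        coords = self.table[["array_row", "array_col", "pxl_row", "pxl_col"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValidationError("positions contain non-finite coordinates")

    def coords(self, barcodes: Sequence[str]) -> pd.DataFrame:
        return self.table.reindex(barcodes)


@dataclass
class GeneList:
    """Ordered panel of gene symbols with optional symbol -> family labels."""

    symbols: list[str]
    families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValidationError("gene list symbols are not unique")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def family(self, symbol: str) -> str:
        return self.families.get(symbol, "other")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def dedup_symbols(symbols: Iterable[str]) -> list[str]:
    """Disambiguate repeated symbols with an ``_k`` suffix in load order.

    (A, B, A) -> (A, B, A_1).  Summing duplicate columns instead would corrupt
    per-gene IQR statistics, so both columns are kept.
    """
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        k = seen.get(s, 0)
        out.append(s if k == 0 else f"{s}_{k}")
        seen[s] = k + 1
    return out


def read_count_matrix(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    sample_id: str,
) -> UMICountMatrix:
    """Load a 10x-style MTX triplet as a spot-major UMI count matrix.

    The MTX file stores genes as rows and spots as columns; the reader
    transposes.  Gene symbols come from the second column of the features
    file (first column if only one is present); duplicates are suffixed.
    """
    with _open_text(matrix_path, "rb") as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:  # noqa: BLE001 - annotate file in message
            raise FormatError(f"{matrix_path}: not valid MatrixMarket ({exc})") from exc
    mat = sp.coo_matrix(mat)
    if mat.data.size and (np.any(mat.data < 0) or np.any(mat.data != np.round(mat.data))):
        raise ValidationError(f"{matrix_path}: entries must be nonnegative integers")

    with _open_text(features_path) as fh:
        feature_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    with _open_text(barcodes_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    if len(feature_rows) != mat.shape[0]:
        raise FormatError(
            f"{features_path}: {len(feature_rows)} features but MTX header declares "
            f"{mat.shape[0]} rows"
        )
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but MTX header declares "
            f"{mat.shape[1]} columns"
        )

    symbols = [row[1] if len(row) > 1 else row[0] for row in feature_rows]
    genes = dedup_symbols(symbols)
    counts = sp.csr_matrix(mat.T.astype(np.int64))
    return UMICountMatrix(sample_id=sample_id, barcodes=barcodes, genes=genes, counts=counts)


def read_annotations(
    path: str | Path,
    mapping: Mapping[str, str] | None = None,
    sample_id: str = "",
    strip_barcode_suffix: bool = False,
) -> AnnotationTable:
    """Read a Loupe-style annotation export (barcode, label) CSV.

    Labels absent from the composite mapping become ``unannotated`` and are
    summarised in a log line.  ``strip_barcode_suffix`` removes a trailing
    ``-<digit>`` GEM-well suffix when the matrix barcodes lack it.
    """
    mapping = dict(DEFAULT_REGION_MAPPING) if mapping is None else dict(mapping)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: annotation CSV needs >= 2 columns (barcode, label)")
    barcodes = df.iloc[:, 0].str.strip()
    labels = df.iloc[:, 1].str.strip()
    if strip_barcode_suffix:
        barcodes = barcodes.str.replace(r"-\d+$", "", regex=True)

    raw_labels: dict[str, str] = {}
    conflicts: list[str] = []
    for bc, lbl in zip(barcodes, labels):
        if bc in raw_labels and raw_labels[bc] != lbl:
            conflicts.append(bc)
        raw_labels[bc] = lbl
    if conflicts:
        raise ValidationError(
            f"{path}: conflicting labels for barcodes {sorted(set(conflicts))[:10]}"
        )

    table = AnnotationTable(sample_id=sample_id, raw_labels=raw_labels, mapping=mapping)
    unknown = sorted({l for l in raw_labels.values() if l.strip().lower() not in mapping})
    if unknown:
        logger.warning(
            "sample %s: %d label(s) not in composite mapping -> unannotated: %s",
            sample_id, len(unknown), unknown,
        )
    return table


def read_positions(path: str | Path, sample_id: str = "") -> SpotPositions:
    """Read a tissue_positions CSV (barcode, in_tissue, array/pixel coords)."""
    df = pd.read_csv(path)
    cols = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"]
    if df.shape[1] < 6:
        raise FormatError(f"{path}: tissue positions CSV needs 6 columns, got {df.shape[1]}")
    df = df.iloc[:, :6]
    df.columns = cols
    df["in_tissue"] = df["in_tissue"].astype(bool)
    df = df.set_index("barcode")
    return SpotPositions(sample_id=sample_id, table=df)


def read_gene_list(path: str | Path) -> GeneList:
    """Read a pharmacogene panel: one symbol per line or symbol<TAB>family."""
    symbols: list[str] = []
    families: dict[str, str] = {}
    n_dups = 0
    with _open_text(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if not parts or not parts[0]:
                continue
            sym = parts[0].strip()
            if sym in symbols:
                n_dups += 1
                continue
            symbols.append(sym)
            if len(parts) > 1 and parts[1].strip():
                families[sym] = parts[1].strip()
    if not symbols:
        raise ValidationError(f"{path}: gene list is empty")
    if n_dups:
        logger.warning("%s: dropped %d duplicate symbol(s)", path, n_dups)
    return GeneList(symbols=symbols, families=families)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

_NA_REP = "NA"


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with header; NaN -> ``NA``, infinities -> ``inf``/``-inf``.

    The serialisation is deterministic for a given frame (fixed column order,
    repr-roundtrip floats), so repeated runs on identical inputs are
    byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False, na_rep=_NA_REP)


def read_table(path: str | Path) -> pd.DataFrame:
    """Re-read a TSV written by :func:`write_table`; inverse up to dtypes."""
    return pd.read_csv(
        path, sep="\t", na_values=[_NA_REP], keep_default_na=False
    )
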