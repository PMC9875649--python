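"""Seeded Visium-like multi-sample simulator with planted signal.

The generator emits, for each of several samples, a spot x gene UMI count
matrix on a spatial grid, a pathologist-style annotation CSV whose region
labels form contiguous blobs, tissue positions, and a ground-truth table —
in exactly the on-disk layout the ``io`` module reads.  It exists so every
downstream statistic can be exercised and power-checked with no external
data.

Count model
-----------
Counts are negative binomial: gene ``i`` in spot ``j`` has mean
``L_j * mu_{i,region(j)}`` and dispersion ``phi`` (variance m + m^2/phi),
where ``L_j`` is a log-normal library-size factor with unit mean — the
standard overdispersion model for UMI data, and it gives per-spot
normalization something real to remove.  ``phi = inf`` selects the Poisson
limit.

Planted signal (tumor spots only):

* genes in ``H`` (heterogeneous): each tumor spot's mean is drawn from the
  two-component mixture {mu_i, f_het * mu_i} with weight ``p_hi`` on the
  high component — a bimodal within-tumor expression pattern;
* genes in ``D`` (differential): all tumor-spot means are scaled by
  ``f_de``.

``f_het = 1`` (or ``n_het = 0``) and ``f_de = 1`` give exchangeable
regions — the null simulation used for type-I-error calibration.

Region geometry is seeded multi-source region growing: each raw label gets
an exact spot budget and grows blob-wise from random seeds, re-seeding a new
blob if enclosed, so label counts match the configured proportions exactly
(largest-remainder rounding) while remaining spatially coherent.

Determinism: one (config, seed) pair, one byte stream.  The generator is
numpy's PCG64 ``default_rng``; the algorithm name is recorded in the emitted
metadata.  Reproducibility is promised within this implementation, not
across languages.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .errors import ConfigurationError, ValidationError
from .io import (
    DEFAULT_REGION_MAPPING,
    AnnotationTable,
    SpotPositions,
    UMICountMatrix,
)

logger = logging.getLogger(__name__)

RNG_ALGORITHM = "numpy-default_rng-PCG64"

#: Raw pathologist labels and their default spot-share per sample, patterned
#: on the published tumor/stroma/normal/lymphocyte/mixed proportions.
DEFAULT_REGION_PROPORTIONS: dict[str, float] = {
    "tumor": 0.33,
    "DCIS": 0.10,
    "cellular tumor": 0.11,
    "desmoplastic tumor": 0.10,
    "stroma": 0.26,
    "normal": 0.03,
    "lymphocytes": 0.01,
    "mixed": 0.06,
}

#: Family prefixes used for synthetic panel gene symbols (weights roughly
#: reflect an ADME panel's family composition).
PANEL_FAMILIES = ("CYP", "SLC", "ABC", "GST", "UGT", "NAT", "ADME")
PANEL_FAMILY_WEIGHTS = (0.25, 0.20, 0.15, 0.10, 0.08, 0.04, 0.18)


@dataclass
class SimulationConfig:
    """All knobs of the simulator; defaults are the desk-scale study design.

    6 samples x 400 spots (20x20 grid) x 600 genes with a 286-gene
    pharmacogene panel; the emitted panel file additionally lists
    ``n_panel_absent`` symbols absent from the matrix, mirroring a panel
    filtered down on load.  Baseline per-gene means are log-normal around
    3 UMI/spot with modest spread (a curated, mid-expressed panel);
    dispersion phi = 5; library factors log-normal with sigma 0.3.
    """

    n_samples: int = 6
    spots_per_sample: int = 400
    grid: tuple[int, int] = (20, 20)
    n_genes: int = 600
    n_pharmacogenes: int = 286
    n_panel_absent: int = 12
    baseline_log_mean: float = float(np.log(3.0))
    baseline_log_sigma: float = 0.2
    dispersion: float = 5.0
    library_sigma: float = 0.3
    n_het: int = 20
    f_het: float = 4.0
    p_hi: float = 0.5
    n_de: int = 20
    f_de: float = 0.5
    region_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_PROPORTIONS)
    )
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.grid
        if rows * cols < self.spots_per_sample:
            raise ConfigurationError(
                f"grid {rows}x{cols} holds {rows * cols} spots < "
                f"spots_per_sample={self.spots_per_sample}"
            )
        if min(self.n_samples, self.spots_per_sample, self.n_genes,
               self.n_pharmacogenes) < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.n_pharmacogenes > self.n_genes:
            raise ConfigurationError("n_pharmacogenes cannot exceed n_genes")
        if self.f_het < 1.0:
            raise ConfigurationError("f_het must be >= 1 (1 = no planted heterogeneity)")
        if self.f_de <= 0.0:
            raise ConfigurationError("f_de must be > 0")
        if self.n_het > 0 and self.f_het > 1.0 and not (0.0 < self.p_hi < 1.0):
            raise ConfigurationError("p_hi must lie in (0, 1)")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive (inf = Poisson)")
        if self.library_sigma < 0:
            raise ConfigurationError("library_sigma must be >= 0")
        if not self.region_proportions:
            raise ConfigurationError("region_proportions must be non-empty")
        if any(v < 0 for v in self.region_proportions.values()):
            raise ConfigurationError("region proportions must be >= 0")
        if abs(sum(self.region_proportions.values()) - 1.0) > 1e-6:
            raise ConfigurationError("region proportions must sum to 1")
        if max(self.n_het, self.n_de) > self.n_pharmacogenes:
            raise ConfigurationError("planted sets cannot exceed the panel size")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        d["rng_algorithm"] = RNG_ALGORITHM
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d.pop("rng_algorithm", None)
        if "grid" in d:
            d["grid"] = tuple(d["grid"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated dataset."""

    seed: int
    het_genes: list[str]               # H
    de_genes: list[str]                # D
    gene_table: pd.DataFrame           # gene, is_panel, in_het, in_de, mu_baseline, mu_tumor_expected
    spot_table: pd.DataFrame           # sample, barcode, raw_label, region, library_factor
    region_means: pd.DataFrame         # gene x region expected means (no library factor)

    def region_spot_counts(self) -> pd.DataFrame:
        return (
            self.spot_table.groupby(["sample", "region"]).size().rename("n_spots").reset_index()
        )


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    matrices: dict[str, UMICountMatrix]
    annotations: dict[str, AnnotationTable]
    positions: dict[str, SpotPositions]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Region geometry
# ---------------------------------------------------------------------------


def _label_budgets(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder rounding of proportions to exact integer budgets."""
    labels = list(proportions)
    raw = np.array([proportions[l] * n for l in labels])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for k in order[:rem]:
        base[k] += 1
    return {l: int(b) for l, b in zip(labels, base) if b > 0}


def grow_regions(
    grid: tuple[int, int],
    n_spots: int,
    proportions: Mapping[str, float],
    rng: np.random.Generator,
) -> list[str]:
    """Assign a raw label to each of the first ``n_spots`` grid cells.

    Multi-source region growing: each label claims cells adjacent to its
    current territory; a label with budget left but no free frontier seeds a
    fresh blob, so budgets are always met exactly and labels stay blob-like.
    """
    rows, cols = grid
    cells = [(r, c) for r in range(rows) for c in range(cols)][:n_spots]
    cell_set = set(cells)
    budgets = _label_budgets(proportions, n_spots)
    labels = {}
    frontier: dict[str, list[tuple[int, int]]] = {l: [] for l in budgets}
    remaining = dict(budgets)

    def neighbors(cell):
        r, c = cell
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = (r + dr, c + dc)
            if nb in cell_set and nb not in labels:
                yield nb

    unassigned = list(cells)
    rng.shuffle(unassigned)

    def claim(label, cell):
        labels[cell] = label
        remaining[label] -= 1
        frontier[label].append(cell)
        if cell in unassigned_set:
            unassigned_set.remove(cell)

    unassigned_set = set(unassigned)
    active = [l for l in budgets if remaining[l] > 0]
    while active:
        # grow the label furthest from its budget first, with random ties
        weights = np.array([remaining[l] for l in active], dtype=float)
        label = active[rng.choice(len(active), p=weights / weights.sum())]
        grown = False
        while frontier[label]:
            cell = frontier[label][-1]
            free = [nb for nb in neighbors(cell)]
            if free:
                claim(label, free[rng.integers(len(free))])
                grown = True
                break
            frontier[label].pop()
        if not grown:
            # enclosed (or fresh): seed a new blob on any unassigned cell
            pool = sorted(unassigned_set)
            if not pool:
                break
            claim(label, pool[rng.integers(len(pool))])
        active = [l for l in budgets if remaining[l] > 0]

    return [labels[c] for c in cells]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _gene_symbols(config: SimulationConfig, rng: np.random.Generator) -> tuple[list[str], list[str], dict[str, str]]:
    """Synthetic symbols: panel genes get family prefixes, rest are GENE####."""
    fam_idx = rng.choice(
        len(PANEL_FAMILIES), size=config.n_pharmacogenes, p=PANEL_FAMILY_WEIGHTS
    )
    panel = [f"{PANEL_FAMILIES[k]}{i + 1:03d}" for i, k in enumerate(fam_idx)]
    families = {s: PANEL_FAMILIES[k] for s, k in zip(panel, fam_idx)}
    background = [f"GENE{i + 1:04d}" for i in range(config.n_genes - config.n_pharmacogenes)]
    genes = panel + background
    absent = [f"PANELONLY{i + 1:02d}" for i in range(config.n_panel_absent)]
    return genes, panel + absent, families


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean m, dispersion phi): var = m + m^2/phi; phi=inf is Poisson."""
    if np.isinf(phi):
        return rng.poisson(mean)
    p = phi / (phi + mean)
    return rng.negative_binomial(phi, p)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full multi-sample dataset plus ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes, panel_symbols, families = _gene_symbols(config, rng)
    mu = rng.lognormal(config.baseline_log_mean, config.baseline_log_sigma, config.n_genes)

    panel_present = genes[: config.n_pharmacogenes]
    effect_on = config.f_het > 1.0 and config.n_het > 0
    het_genes = sorted(map(str, rng.choice(panel_present, size=config.n_het, replace=False))) if effect_on else []
    de_on = config.f_de != 1.0 and config.n_de > 0
    de_genes = sorted(map(str, rng.choice(panel_present, size=config.n_de, replace=False))) if de_on else []
    het_idx = np.array([genes.index(g) for g in het_genes], dtype=int)
    de_idx = np.array([genes.index(g) for g in de_genes], dtype=int)
    overlap = sorted(set(het_genes) & set(de_genes))
    if overlap:
        logger.info("planted sets overlap on %d gene(s): %s", len(overlap), overlap)

    # expected per-region means (library factor excluded); tumor means carry
    # the DE scaling and the heterogeneity-mixture expectation
    regions = sorted({DEFAULT_REGION_MAPPING[l.lower()] for l in config.region_proportions})
    mu_tumor = mu.copy()
    mu_tumor[de_idx] *= config.f_de
    if effect_on:
        mu_tumor[het_idx] *= 1.0 + config.p_hi * (config.f_het - 1.0)
    region_means = pd.DataFrame({r: (mu_tumor if r == "tumor" else mu) for r in regions}, index=genes)

    matrices: dict[str, UMICountMatrix] = {}
    annotations: dict[str, AnnotationTable] = {}
    positions: dict[str, SpotPositions] = {}
    spot_rows = []

    rows, cols = config.grid
    for s in range(config.n_samples):
        sid = f"sample_{s + 1:02d}"
        n = config.spots_per_sample
        raw_labels = grow_regions(config.grid, n, config.region_proportions, rng)
        region = [DEFAULT_REGION_MAPPING[l.lower()] for l in raw_labels]
        is_tumor = np.array([r == "tumor" for r in region])

        lib = (
            rng.lognormal(-config.library_sigma**2 / 2.0, config.library_sigma, n)
            if config.library_sigma > 0
            else np.ones(n)
        )

        mean = np.outer(np.ones(n), mu)
        if de_idx.size:
            mean[np.ix_(is_tumor.nonzero()[0], de_idx)] *= config.f_de
        if effect_on and het_idx.size:
            t_rows = is_tumor.nonzero()[0]
            hi = rng.random((t_rows.size, het_idx.size)) < config.p_hi
            mult = np.where(hi, config.f_het, 1.0)
            mean[np.ix_(t_rows, het_idx)] *= mult
        mean *= lib[:, None]

        counts = _nb_draw(rng, mean, config.dispersion).astype(np.int64)

        barcodes = [f"{sid}-BC{j + 1:04d}-1" for j in range(n)]
        matrices[sid] = UMICountMatrix(
            sample_id=sid, barcodes=barcodes, genes=list(genes),
            counts=sp.csr_matrix(counts),
        )
        annotations[sid] = AnnotationTable(
            sample_id=sid,
            raw_labels=dict(zip(barcodes, raw_labels)),
            mapping=dict(DEFAULT_REGION_MAPPING),
        )
        grid_rc = [(j // cols, j % cols) for j in range(n)]
        positions[sid] = SpotPositions(
            sample_id=sid,
            table=pd.DataFrame(
                {
                    "in_tissue": True,
                    "array_row": [r for r, _ in grid_rc],
                    "array_col": [c for _, c in grid_rc],
                    "pxl_row": [100 * r + 50 for r, _ in grid_rc],
                    "pxl_col": [100 * c + 50 for _, c in grid_rc],
                },
                index=pd.Index(barcodes, name="barcode"),
            ),
        )
        spot_rows.extend(
            {
                "sample": sid, "barcode": bc, "raw_label": lbl,
                "region": reg, "library_factor": float(L),
            }
            for bc, lbl, reg, L in zip(barcodes, raw_labels, region, lib)
        )

    gene_table = pd.DataFrame(
        {
            "gene": genes,
            "is_panel": [g in set(panel_present) for g in genes],
            "in_het": [g in set(het_genes) for g in genes],
            "in_de": [g in set(de_genes) for g in genes],
            "mu_baseline": mu,
            "mu_tumor_expected": mu_tumor,
        }
    )
    truth = SyntheticTruth(
        seed=config.seed,
        het_genes=list(het_genes),
        de_genes=list(de_genes),
        gene_table=gene_table,
        spot_table=pd.DataFrame(spot_rows),
        region_means=region_means,
    )
    dataset = SyntheticDataset(
        config=config,
        matrices=matrices,
        annotations=annotations,
        positions=positions,
        truth=truth,
    )
    dataset.panel_symbols = panel_symbols  # type: ignore[attr-defined]
    dataset.families = families  # type: ignore[attr-defined]
    return dataset


# ---------------------------------------------------------------------------
# GO annotation fixture (synthetic)
# ---------------------------------------------------------------------------

#: Synthetic GO-style term names; the first four contain the ROS keywords
#: (oxidative / stress / oxygen / reactive), the rest do not.
_SYNTH_ROS_TERMS = [
    ("GO:S000001", "cellular response to oxidative stress"),
    ("GO:S000002", "response to reactive oxygen species"),
    ("GO:S000003", "oxygen transport"),
    ("GO:S000004", "stress-activated signaling cascade"),
]
_SYNTH_NEUTRAL_TERMS = [
    ("GO:S000101", "xenobiotic metabolic process"),
    ("GO:S000102", "transmembrane transport"),
    ("GO:S000103", "glutathione metabolic process"),
    ("GO:S000104", "lipid metabolic process"),
]


def simulate_go_annotations(
    panel_genes: list[str], rng: np.random.Generator, ros_fraction: float = 0.2
) -> pd.DataFrame:
    """Synthetic gene -> GO-term-name table for the ROS categorization stage.

    A seeded fraction of panel genes receives one or two keyword-bearing
    terms; every gene receives one neutral term.  This is a stand-in fixture
    for an MGI-style batch-query export, not real GO data.
    """
    rows = []
    n_ros = max(1, int(round(ros_fraction * len(panel_genes))))
    ros_members = set(rng.choice(panel_genes, size=n_ros, replace=False))
    for g in panel_genes:
        gid, name = _SYNTH_NEUTRAL_TERMS[rng.integers(len(_SYNTH_NEUTRAL_TERMS))]
        rows.append({"gene": g, "go_id": gid, "term_name": name})
        if g in ros_members:
            k = 1 + int(rng.integers(2))
            for t in rng.choice(len(_SYNTH_ROS_TERMS), size=k, replace=False):
                gid, name = _SYNTH_ROS_TERMS[int(t)]
                rows.append({"gene": g, "go_id": gid, "term_name": name})
    return pd.DataFrame(rows).drop_duplicates(ignore_index=True)


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------


def write_fixture(dataset: SyntheticDataset, out_dir: str | Path, force: bool = False) -> None:
    """Emit the dataset in the exact layout the io module reads.

    Per-sample directories with matrix.mtx / features.tsv / barcodes.tsv /
    annotations.csv / tissue_positions.csv, plus panel.tsv, a synthetic
    go_annotations.tsv, truth tables, and sim_config.yaml at the root.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(f"{out}: directory is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)

    for sid, mat in dataset.matrices.items():
        d = out / sid
        d.mkdir(exist_ok=True)
        # 10x convention on disk: genes as MTX rows
        scipy.io.mmwrite(
            str(d / "matrix.mtx"), sp.coo_matrix(mat.counts.T), field="integer"
        )
        with open(d / "features.tsv", "w") as fh:
            for g in mat.genes:
                fh.write(f"{g}\t{g}\tGene Expression\n")
        with open(d / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(mat.barcodes) + "\n")
        ann = dataset.annotations[sid]
        pd.DataFrame(
            {"Barcode": mat.barcodes, "Annotation": [ann.raw_labels[b] for b in mat.barcodes]}
        ).to_csv(d / "annotations.csv", index=False)
        dataset.positions[sid].table.reset_index().to_csv(
            d / "tissue_positions.csv", index=False
        )

    families = getattr(dataset, "families", {})
    with open(out / "panel.tsv", "w") as fh:
        for g in getattr(dataset, "panel_symbols", list(dataset.truth.gene_table["gene"])):
            fh.write(f"{g}\t{families.get(g, 'other')}\n")

    go_rng = np.random.default_rng(dataset.config.seed + 104729)
    panel_present = [
        g for g in dataset.truth.gene_table.loc[dataset.truth.gene_table.is_panel, "gene"]
    ]
    simulate_go_annotations(panel_present, go_rng).to_csv(
        out / "go_annotations.tsv", sep="\t", index=False
    )

    dataset.truth.gene_table.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    dataset.truth.spot_table.to_csv(out / "truth_spots.tsv", sep="\t", index=False)
    dataset.truth.region_means.rename_axis("gene").reset_index().to_csv(
        out / "truth_region_means.tsv", sep="\t", index=False
    )
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    logger.info("wrote fixture with %d sample(s) to %s", len(dataset.matrices), out)
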