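"""End-to-end orchestration: simulate/load -> preprocess -> heterogeneity ->
differential expression -> categorization -> report, with a run manifest.

The run is driven by a single declarative :class:`RunConfig` (one source of
truth; CLI flags are overrides).  The manifest records input hashes, the
config, library versions, per-region spot counts per sample, and per-stage
wall time, so identical inputs give identical outputs (hash-stable, aside
from the timing fields).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .categorize import (
    DEFAULT_ROS_EXCLUDED_FAMILIES,
    DEFAULT_ROS_KEYWORDS,
    assign_families,
    read_go_annotations,
    ros_genes,
)
from .core import (
    MODE_COMBINED,
    MODE_REGION,
    MODE_SAMPLE,
    build_grouping,
    filter_genes,
    normalize_per_spot,
)
from .differential import de_table, summarize_global
from .errors import ConfigurationError
from .heterogeneity import heterogeneity_table, select_iqr_positive
from .io import (
    read_annotations,
    read_count_matrix,
    read_gene_list,
    read_positions,
    write_table,
)
from .report import boxplot_ranked, intensity_map, s_plot, spatial_map
from .synthetic_data import SimulationConfig, simulate_dataset, write_fixture

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    input_dir: str | Path | None = None     # fixture root with per-sample subdirs
    out_dir: str | Path = "results/run"
    panel_path: str | Path | None = None    # default: <input_dir>/panel.tsv
    go_annotations_path: str | Path | None = None
    blocklist_path: str | Path | None = None
    alpha: float = 0.05
    top_n_boxplot: int = 35
    seed: int = 0
    simulate: dict | None = None            # SimulationConfig overrides; None = load only
    ros_keywords: tuple[str, ...] = DEFAULT_ROS_KEYWORDS
    ros_excluded_families: tuple[str, ...] = DEFAULT_ROS_EXCLUDED_FAMILIES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.simulate is None:
            if self.input_dir is None:
                raise ConfigurationError("need either input_dir or a simulate block")
            if not Path(self.input_dir).is_dir():
                raise ConfigurationError(f"input_dir {self.input_dir} does not exist")
        panel = self.resolved_panel_path()
        if panel is not None and self.simulate is None and not Path(panel).is_file():
            raise ConfigurationError(f"panel file {panel} does not exist")

    def resolved_panel_path(self) -> Path | None:
        if self.panel_path is not None:
            return Path(self.panel_path)
        if self.input_dir is not None:
            return Path(self.input_dir) / "panel.tsv"
        return None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_fixture_dir(input_dir: str | Path):
    """Load every per-sample directory under a fixture root."""
    input_dir = Path(input_dir)
    matrices, annotations, positions = {}, {}, {}
    sample_dirs = sorted(d for d in input_dir.iterdir() if (d / "matrix.mtx").is_file())
    if not sample_dirs:
        raise ConfigurationError(f"{input_dir}: no sample directories with matrix.mtx")
    for d in sample_dirs:
        sid = d.name
        matrices[sid] = read_count_matrix(
            d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv", sample_id=sid
        )
        annotations[sid] = read_annotations(d / "annotations.csv", sample_id=sid)
        pos = d / "tissue_positions.csv"
        if pos.is_file():
            positions[sid] = read_positions(pos, sample_id=sid)
    return matrices, annotations, positions


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": _jsonable(dataclasses.asdict(config)),
        "versions": _versions(),
        "stages": {},
        "inputs": {},
        "outputs": [],
    }
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_

            def __exit__(self_, *exc):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                logger.info("stage %s: done in %.2fs", name, timings[name])
                return False

        return _T()

    # -- simulate (optional) -------------------------------------------------
    if config.simulate is not None:
        with stage("simulate"):
            sim_cfg = SimulationConfig.from_dict({"seed": config.seed, **config.simulate})
            dataset = simulate_dataset(sim_cfg)
            fixture_dir = Path(config.input_dir) if config.input_dir else out / "fixture"
            write_fixture(dataset, fixture_dir, force=True)
            config = dataclasses.replace(config, input_dir=fixture_dir)
            manifest["config"]["input_dir"] = str(fixture_dir)

    input_dir = Path(config.input_dir)

    # -- load ---------------------------------------------------------------
    with stage("load"):
        matrices, annotations, positions = load_fixture_dir(input_dir)
        panel = read_gene_list(config.resolved_panel_path())
        for f in sorted(input_dir.rglob("*")):
            if f.is_file() and f.suffix in {".mtx", ".tsv", ".csv", ".yaml"}:
                manifest["inputs"][str(f.relative_to(input_dir))] = _sha256(f)

    spot_counts = {
        sid: dict(sorted(ann.region_counts().items())) for sid, ann in sorted(annotations.items())
    }
    manifest["spot_counts_per_region_per_sample"] = spot_counts

    # -- preprocess ----------------------------------------------------------
    with stage("preprocess"):
        normalized_full = {sid: normalize_per_spot(m) for sid, m in matrices.items()}
        raw_panel, norm_panel, missing = {}, {}, []
        for sid in matrices:
            raw_panel[sid], missing = filter_genes(matrices[sid], panel)
            norm_panel[sid], _ = filter_genes(normalized_full[sid], panel)
        manifest["panel"] = {
            "n_panel": len(panel),
            "n_present": len(panel) - len(missing),
            "missing_symbols": missing,
        }

    # -- heterogeneity -------------------------------------------------------
    with stage("heterogeneity"):
        g_combined = build_grouping(annotations, MODE_COMBINED)
        g_sample = build_grouping(annotations, MODE_SAMPLE, regions=("tumor",))
        g_region = build_grouping(annotations, MODE_REGION)
        het_tables = []
        for mats, normalized in ((raw_panel, False), (norm_panel, True)):
            for grouping in (g_combined, g_sample, g_region):
                t = heterogeneity_table(mats, grouping, normalized=normalized)
                t.insert(2, "grouping_mode", grouping.mode)
                het_tables.append(t)
        het = pd.concat(het_tables, ignore_index=True)
        write_table(het, out / "heterogeneity.tsv")
        het_combined_raw = het[
            (het["grouping_mode"] == MODE_COMBINED) & (~het["normalized"])
        ]
        iqr_pos = select_iqr_positive(het_combined_raw, "tumor")
        pd.DataFrame({"gene": iqr_pos.symbols}).to_csv(
            out / "tumor_iqr_positive_genes.tsv", sep="\t", index=False
        )
        manifest["stages"]["heterogeneity"] = {
            "n_records": int(len(het)),
            "n_tumor_iqr_positive_raw": len(iqr_pos.symbols),
        }

    # -- differential expression --------------------------------------------
    with stage("differential"):
        de = de_table(norm_panel, annotations)
        write_table(de, out / "de.tsv")
        de_summary = summarize_global(de, alpha=config.alpha)
        write_table(de_summary, out / "de_summary.tsv")
        manifest["stages"]["differential"] = {
            "n_records": int(len(de)),
            "n_tests": int(de.attrs["n_tests"]),
            "n_infinite": int(np.isinf(de["log2fc"]).sum()),
            "n_down_in_all": int(de_summary["down_in_all"].sum()),
        }

    # -- categorize ----------------------------------------------------------
    with stage("categorize"):
        families = assign_families(panel)
        go_path = config.go_annotations_path or (input_dir / "go_annotations.tsv")
        ros = None
        if Path(go_path).is_file():
            blocklist = []
            if config.blocklist_path and Path(config.blocklist_path).is_file():
                blocklist = [
                    l.strip() for l in Path(config.blocklist_path).read_text().splitlines()
                    if l.strip()
                ]
            ros = ros_genes(
                read_go_annotations(go_path),
                panel,
                keywords=config.ros_keywords,
                excluded_families=config.ros_excluded_families,
                blocklist=blocklist,
                family_assignment=families,
            )
            write_table(ros.to_frame(), out / "categories.tsv")
            manifest["stages"]["categorize"] = {
                "n_ros": len(ros.ros_genes()),
                "n_matched_terms": len(ros.matched_term_set()),
            }
        else:
            write_table(families.to_frame(), out / "categories.tsv")
            logger.warning("no GO annotation table at %s; ROS stage skipped", go_path)

    # -- report --------------------------------------------------------------
    with stage("report"):
        figs = out / "figures"
        bundles = [
            boxplot_ranked(
                raw_panel, g_combined, het_combined_raw, "tumor",
                config.top_n_boxplot, figs,
            ),
            intensity_map(
                het[het["grouping_mode"] == MODE_SAMPLE], "sample", False, figs
            ),
            intensity_map(
                het[het["grouping_mode"] == MODE_SAMPLE], "sample", True, figs
            ),
            intensity_map(
                het[het["grouping_mode"] == MODE_REGION], "region", False, figs
            ),
            intensity_map(
                het[het["grouping_mode"] == MODE_REGION], "region", True, figs
            ),
            s_plot(de, figs),
        ]
        abc_set = [g for g in panel.symbols if families.families.get(g) == "ABC"]
        if abc_set and positions:
            sid = sorted(positions)[0]
            bundles.append(
                spatial_map(
                    raw_panel[sid], positions[sid], annotations[sid], abc_set,
                    figs, name=f"spatial_map_abc_{sid}",
                )
            )
        manifest["outputs"] = sorted(
            str(b.sidecar_path.relative_to(out)) for b in bundles
        ) + ["heterogeneity.tsv", "de.tsv", "de_summary.tsv", "categories.tsv"]

    manifest["timings_s"] = timings
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _versions() -> dict[str, str]:
    import matplotlib
    import numpy
    import scipy

    return {
        "spatialpgx": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "matplotlib": matplotlib.__version__,
    }


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
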