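"""End-to-end runs: simulate -> (segment) -> analyze -> report.

Every stage writes its outputs before the next reads them, so each number
in the final report is recomputable from the intermediate CSVs alone.
Runs are deterministic given the configuration and master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .analytics import (
    ControlSeparation,
    FeatureMatrix,
    HitTable,
    call_hits,
    control_separation,
    cumulative_variance,
    filter_dead_wells,
    pca_morphospace,
)
from .imaging import SegmentationParams, measurements_to_frame, process_well_image
from .layout import PlateLayout, default_384_layout, normalize_well
from .simulate import SyntheticScreenConfig, simulate_screen

logger = logging.getLogger(__name__)

#: Accepted header aliases for externally produced feature tables.
DEFAULT_ALIASES: Mapping[str, str] = {
    "plate": "plate_id",
    "plate_name": "plate_id",
    "well_id": "well",
    "well_position": "well",
    "median_area": "median_colony_area",
    "median colony area": "median_colony_area",
    "percent_colonies_with_lumens": "pct_colonies_with_lumens",
    "pct_lumens": "pct_colonies_with_lumens",
    "percent colonies with lumens": "pct_colonies_with_lumens",
    "count": "colony_count",
    "n_colonies": "colony_count",
    "treatment": "compound_id",
    "concentration": "concentration_um",
}

REQUIRED_GATING = ("median_colony_area", "pct_colonies_with_lumens")


def load_feature_table(
    path,
    aliases: Optional[Mapping[str, str]] = None,
    layout: Optional[PlateLayout] = None,
) -> FeatureMatrix:
    """Read a per-well feature CSV into a :class:`FeatureMatrix`.

    Column aliases (case-insensitive) are applied, well names normalized,
    and roles inferred from ``layout`` when a ``role`` column is absent.
    Missing gating columns are a hard error; a missing ``colony_count``
    only disables dead-well filtering downstream (with a warning).
    """
    df = pd.read_csv(path)
    amap = dict(DEFAULT_ALIASES)
    amap.update({k.lower(): v for k, v in (aliases or {}).items()})
    df = df.rename(columns=lambda c: amap.get(c.strip().lower(), c.strip()))
    for col in ("plate_id", "well"):
        if col not in df.columns:
            raise ValueError(f"feature table {path} missing required column: {col}")
    if "role" not in df.columns:
        if layout is None:
            layout = default_384_layout()
        logger.warning("no role column: inferring roles from plate layout")
        df["role"] = [layout.role_of(w) for w in df["well"]]
    missing = [c for c in REQUIRED_GATING if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing gating columns: {missing}")
    if "colony_count" not in df.columns:
        logger.warning("no colony_count column: dead-well filtering disabled")
    return FeatureMatrix(df)


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    out_dir: Path = Path("morphoscreen_run")
    seed: int = 0
    stages: Tuple[str, ...] = ("simulate", "analyze")
    features_path: Optional[Path] = None  # input for analyze-only runs
    screen: SyntheticScreenConfig = field(default_factory=SyntheticScreenConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    percent: float = 5.0
    dead_fraction: Optional[float] = 0.5
    n_pca_components: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.percent < 100:
            raise ValueError("percent must be in (0, 100)")
        self.out_dir = Path(self.out_dir)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["features_path"] = None if self.features_path is None else str(self.features_path)
        d["version"] = __version__
        return d


@dataclass
class ReportBundle:
    """Everything a run produced, plus the metadata to reproduce it."""

    features: FeatureMatrix
    hit_table: Optional[HitTable]
    qc: Optional[ControlSeparation]
    pca_scores: Optional[pd.DataFrame]
    pca_loadings: Optional[pd.DataFrame]
    excluded_dead: Optional[pd.DataFrame]
    metadata: dict


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, default=str))


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the configured stages and write all outputs to ``out_dir``.

    A QC failure (positive controls not separating from DMSO) marks the
    report but does not abort the run.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    metadata: dict = {"config": config.snapshot()}

    if "simulate" in config.stages:
        screen_cfg = dataclasses.replace(config.screen, seed=config.seed)
        fm, truth = simulate_screen(screen_cfg)
        fm.to_csv(out / "features.csv")
        truth.to_json(out / "ground_truth.json")
        metadata["n_wells"] = len(fm)
    elif config.features_path is not None:
        fm = load_feature_table(config.features_path)
    else:
        raise ValueError("analyze-only runs need features_path")

    hit_table = qc = None
    scores = loadings = excluded = None
    if "analyze" in config.stages:
        try:
            qc = control_separation(fm)
            if not qc.passed:
                logger.warning("QC failure: positive controls do not separate from DMSO")
        except ValueError as exc:
            logger.warning("control-separation QC skipped: %s", exc)

        dead_fraction = config.dead_fraction
        if dead_fraction is not None and "colony_count" not in fm.data.columns:
            logger.warning("dead-well filtering disabled: no colony_count column")
            dead_fraction = None
        hit_table = call_hits(fm, percent=config.percent, dead_fraction=dead_fraction)
        excluded = hit_table.table[hit_table.table["excluded_dead"]][["plate_id", "well"]]

        analyzable = fm
        if dead_fraction is not None:
            analyzable, _ = filter_dead_wells(fm, dead_fraction)
        try:
            pca = pca_morphospace(analyzable, config.n_pca_components)
            scores = pca.scores.reset_index()
            scores = pd.concat(
                [scores, analyzable.data.set_index(["plate_id", "well"]).loc[
                    pca.scores.index, ["role"]
                ].reset_index(drop=True)],
                axis=1,
            )
            loadings = pca.loadings
            metadata["pca"] = {
                "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
                "cumulative_variance": [
                    cumulative_variance(pca, k)
                    for k in range(1, len(pca.explained_variance_ratio) + 1)
                ],
            }
        except ValueError as exc:
            logger.warning("PCA skipped: %s", exc)

        hit_table.table.to_csv(out / "hit_table.csv", index=False)
        hit_table.compound_rollup.to_csv(out / "hit_compounds.csv", index=False)
        if scores is not None:
            scores.to_csv(out / "pca_scores.csv", index=False)
            loadings.to_csv(out / "pca_loadings.csv")
        summary = {
            "thresholds": hit_table.thresholds,
            "gating_params": hit_table.params,
            "n_hit_wells": int(hit_table.table["is_hit"].sum()),
            "n_hit_compounds": int(len(hit_table.compound_rollup)),
            "n_excluded_dead": int(hit_table.table["excluded_dead"].sum()),
            "qc_passed": None if qc is None else qc.passed,
            "qc": None if qc is None else qc.metrics,
        }
        _write_json(out / "hits_summary.json", summary)
        metadata["summary"] = summary

    _write_json(out / "run_metadata.json", metadata)
    return ReportBundle(fm, hit_table, qc, scores, loadings, excluded, metadata)


def segment_image_file(
    image_path, params: SegmentationParams, out_dir: Optional[Path] = None
) -> Tuple[pd.DataFrame, dict]:
    """Segment one well image file; optionally write masks and tables.

    Returns the per-colony measurement table and the well summary dict.
    Masks are written as 16-bit label TIFFs next to the CSVs.
    """
    import tifffile

    image = tifffile.imread(image_path)
    colony_mask, lumen_mask, assignment, measurements, summary = process_well_image(
        image, params
    )
    table = measurements_to_frame(measurements)
    summary_d = dataclasses.asdict(summary)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = Path(image_path).stem
        tifffile.imwrite(out_dir / f"{stem}_colonies.tif", colony_mask.astype(np.uint16))
        tifffile.imwrite(out_dir / f"{stem}_lumens.tif", lumen_mask.astype(np.uint16))
        table.to_csv(out_dir / f"{stem}_colonies.csv", index=False)
        _write_json(out_dir / f"{stem}_summary.json", summary_d)
    return table, summary_d
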