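"""End-to-end orchestration: annotations -> areas -> models -> statistics.

``run_cohort_analysis`` executes the full analysis for one reader
cohort: pool positive marks, build suspicious areas, hierarchically
cluster readers and exclude outer-branch outliers (per error branch),
label areas easy/difficult by median split, extract the 201-feature
radiomic vector per area, run the nested-CV random-forest difficulty
model per view, and compare the discriminative features between
difficulty groups. ``run_demo`` wires a synthetic cohort into the same
path so the whole pipeline can be exercised without the (non-public)
study data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import radiomics
from .annotations import (PipelineThresholds, areas_to_frame,
                          assign_difficulty, build_response_matrix,
                          build_suspicious_areas)
from .model import ModelConfig, ModelResult, nested_cv, result_table
from .prep import extract_roi, normalize_intensity, quantize, resample, \
    rescale_bbox
from .readers import (cluster_readers, exclude_outliers, identify_outliers,
                      outlier_report)
from .stats import compare_discriminative_features, comparison_table
from .synthetic import SyntheticCaseSet, SyntheticConfig, generate_case_set, \
    reader_ids, simulate_readers

logger = logging.getLogger(__name__)

ERROR_BRANCHES = {"FP": "normal", "FN": "cancer"}


@dataclass
class StudyConfig:
    """Configuration of one cohort analysis run."""

    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)
    model: ModelConfig = field(default_factory=ModelConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    target_spacing: Optional[float] = None  # None: keep native spacing
    views: tuple = ("CC", "MLO")
    cohort_id: str = "A"
    seed: int = 0


@dataclass
class BranchResult:
    """Outcome of one error branch (FP or FN)."""

    error_type: str
    dendrogram: object
    outliers: list
    outlier_table: pd.DataFrame
    roster: list
    areas: list
    area_table: pd.DataFrame
    models: dict  # view -> ModelResult or None
    feature_tables: dict  # view -> DataFrame (original feature values)
    comparisons: dict  # view -> list[FeatureComparison]


@dataclass
class ReportBundle:
    """Everything one cohort run produces."""

    branches: dict  # "FP"/"FN" -> BranchResult
    performance: pd.DataFrame
    manifest: dict

    def save(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.performance.to_csv(out_dir / "performance.csv", index=False)
        (out_dir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str))
        for etype, br in self.branches.items():
            br.area_table.to_csv(out_dir / f"areas_{etype}.csv", index=False)
            br.outlier_table.to_csv(out_dir / f"outliers_{etype}.csv",
                                    index=False)
            (out_dir / f"dendrogram_{etype}.nwk").write_text(
                br.dendrogram.to_newick())
            for view, comps in br.comparisons.items():
                if comps:
                    comparison_table(comps, etype).to_csv(
                        out_dir / f"features_{etype}_{view}.csv", index=False)
        return out_dir


def _prepare_view_images(images: dict, spacing: float,
                         target_spacing: Optional[float]):
    """Resample (optional) then normalize every view image once."""
    prepared = {}
    for key, arr in images.items():
        if target_spacing is not None and abs(target_spacing - spacing) > 1e-12:
            prep = resample(arr, spacing, target_spacing)
            prep = normalize_intensity(prep.array, prep.spacing)
            prep.provenance["original_spacing"] = spacing
        else:
            prep = normalize_intensity(arr, spacing)
            prep.provenance["original_spacing"] = spacing
        prepared[key] = prep
    return prepared


def _area_features(areas, prepared, spacing, target_spacing, bank):
    """201-feature table over areas (rows indexed by area_id)."""
    rois = []
    ids = []
    for area in areas:
        prep = prepared[(area.case_id, area.view, area.side)]
        bbox = area.bbox
        if target_spacing is not None and abs(target_spacing - spacing) > 1e-12:
            bbox = rescale_bbox(bbox, spacing, target_spacing)
        rows, cols = prep.array.shape
        bbox = (max(bbox[0], 0), max(bbox[1], 0),
                min(bbox[2], cols - 1), min(bbox[3], rows - 1))
        rois.append(extract_roi(prep, bbox))
        ids.append(area.area_id)
    return radiomics.extract_table(rois, ids=ids, rfs_bank=bank)


def run_cohort_analysis(images: dict, spacing: float,
                        annotations: pd.DataFrame, lesions: pd.DataFrame,
                        roster: list, config: StudyConfig) -> ReportBundle:
    """Run the full error analysis for one cohort.

    ``images`` maps ``(case_id, view, side)`` to grey-scale arrays at
    ``spacing`` mm/pixel. Models run separately per error branch
    (false positives on normal areas, false negatives on
    cancer-containing areas) and per view; a branch/view with fewer
    than two areas in either difficulty class is skipped with a log
    message rather than failing the run.
    """
    image_size = next(iter(images.values())).shape if images else None
    areas = build_suspicious_areas(annotations, lesions, spacing,
                                   config.thresholds, image_size)
    prepared = _prepare_view_images(images, spacing, config.target_spacing)
    bank = radiomics.build_rfs_bank()
    branches = {}
    all_results = []
    for etype, kind in ERROR_BRANCHES.items():
        sub = [a for a in areas if a.kind == kind]
        if len(sub) == 0:
            logger.warning("no %s areas; skipping %s branch", kind, etype)
            continue
        matrix = build_response_matrix(sub, roster, annotations,
                                       config.thresholds.positive_rating_cutoff)
        dendro = cluster_readers(matrix)
        outliers = identify_outliers(dendro)
        ann2, sub2, roster2 = exclude_outliers(annotations, sub, outliers,
                                               roster)
        matrix2 = build_response_matrix(sub2, roster2, ann2,
                                        config.thresholds.positive_rating_cutoff)
        assign_difficulty(sub2, matrix2)
        models, ftables, comps = {}, {}, {}
        for view in config.views:
            va = [a for a in sub2 if a.view == view]
            labels = np.array([1 if a.difficulty == "difficult" else 0
                               for a in va])
            if len(va) < 4 or len(np.unique(labels)) < 2 \
                    or min(np.bincount(labels)) < 2:
                logger.warning("%s/%s: too few areas per class, skipping "
                               "model", etype, view)
                models[view] = None
                comps[view] = []
                continue
            ft = _area_features(va, prepared, spacing,
                                config.target_spacing, bank)
            ftables[view] = ft
            # stable per-(branch, view) seed fan-out
            offset = (0 if etype == "FP" else 1) * len(config.views) \
                + list(config.views).index(view) + 1
            mcfg = ModelConfig(**{**asdict(config.model),
                                  "seed": config.model.seed + 101 * offset})
            res = nested_cv(ft.to_numpy(), labels, mcfg,
                            feature_names=list(ft.columns),
                            error_type=etype, view=view,
                            cohort=config.cohort_id)
            models[view] = res
            comps[view] = compare_discriminative_features(
                ft.reset_index(drop=True), labels, res.top_features)
            all_results.append(res)
        branches[etype] = BranchResult(
            error_type=etype, dendrogram=dendro, outliers=outliers,
            outlier_table=outlier_report(matrix, outliers), roster=roster2,
            areas=sub2, area_table=areas_to_frame(sub2), models=models,
            feature_tables=ftables, comparisons=comps)
    manifest = {"cohort": config.cohort_id, "seed": config.seed,
                "spacing_mm": spacing,
                "target_spacing_mm": config.target_spacing,
                "thresholds": asdict(config.thresholds),
                "model": asdict(config.model),
                "n_areas": len(areas), "roster": list(roster)}
    return ReportBundle(branches=branches,
                        performance=result_table(all_results),
                        manifest=manifest)


def run_demo(seed: int = 0, config: Optional[StudyConfig] = None,
             out_dir=None) -> ReportBundle:
    """Synthetic end-to-end run: generate a cohort, analyse it fully."""
    config = config or StudyConfig()
    config.seed = seed
    config.synthetic.seed = seed
    case_set = generate_case_set(config.synthetic)
    sim = simulate_readers(case_set, config.synthetic)
    roster = reader_ids(config.synthetic.n_readers)
    bundle = run_cohort_analysis(case_set.images, case_set.pixel_spacing,
                                 sim.annotations, case_set.lesion_truths,
                                 roster, config)
    bundle.manifest["synthetic"] = asdict(config.synthetic)
    bundle.manifest["planted_outliers"] = sorted(
        sim.reader_truth.loc[sim.reader_truth["is_outlier"],
                             "reader_id"].tolist())
    if out_dir is not None:
        bundle.save(out_dir)
    return bundle


def demo_case_set(seed: int = 0,
                  config: Optional[SyntheticConfig] = None) -> SyntheticCaseSet:
    cfg = config or SyntheticConfig()
    cfg.seed = seed
    return generate_case_set(cfg)
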