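"""From raw reader annotations to labelled suspicious areas.

Implements the error-analysis front end: pooling positive marks
(ratings >= 3 on the 1-5 RANZCR suspicion scale), complete-linkage
clustering of marks so that no two marks in a cluster are more than a
threshold apart (250 px by default), rectangular bounding boxes with a
10 px margin, lesion hit-testing at the lesion radius (12.5 mm by
default), per-reader binary false-response matrices, and the
median-split easy/difficult labelling of areas.

Coordinates are 0-based pixels; bounding boxes are inclusive at both
ends; each (case, view, side) combination is treated as an independent
image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["reader_id", "case_id", "view", "side",
                      "x_px", "y_px", "rating"]
LESION_COLUMNS = ["case_id", "view", "side", "x_px", "y_px",
                  "radius_mm", "subtype"]


@dataclass
class PipelineThresholds:
    """Constants of the error analysis; defaults follow the study design."""

    positive_rating_cutoff: int = 3
    cluster_max_distance: float = 250.0  # pixels, original-image frame
    bbox_margin: int = 10  # pixels
    lesion_hit_radius_mm: float = 12.5
    difficulty_rule: str = "median"  # strict-greater -> difficult

    def __post_init__(self) -> None:
        if (self.positive_rating_cutoff <= 0 or self.cluster_max_distance <= 0
                or self.bbox_margin < 0 or self.lesion_hit_radius_mm <= 0):
            raise ValueError("thresholds must be positive")
        if self.difficulty_rule != "median":
            raise ValueError("only the median difficulty rule is implemented")


@dataclass
class SuspiciousArea:
    """A clustered group of positive marks (or a seeded lesion area)."""

    area_id: str
    case_id: str
    view: str
    side: str
    kind: str  # "normal" | "cancer"
    bbox: tuple[int, int, int, int]  # x_min, y_min, x_max, y_max inclusive
    member_annotations: pd.DataFrame
    matched_lesion: Optional[pd.Series] = None
    responses: dict = field(default_factory=dict)  # reader_id -> 0/1
    difficulty: Optional[str] = None  # "easy" | "difficult"

    @property
    def false_response_count(self) -> int:
        return int(sum(self.responses.values()))


@dataclass
class ResponseMatrix:
    """Readers x areas binary matrix; 1 flags a false response."""

    reader_ids: list
    area_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.reader_ids), len(self.area_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("response values must be binary")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.reader_ids,
                            columns=self.area_ids)


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    bad = ~annotations["rating"].between(1, 5)
    if bad.any():
        raise ValueError("ratings must lie in the 1-5 RANZCR range")
    return annotations


def pool_positive_annotations(annotations: pd.DataFrame,
                              cutoff: int = 3) -> pd.DataFrame:
    """Keep the positive annotations (rating >= cutoff), order-preserving."""
    validate_annotations(annotations)
    return annotations[annotations["rating"] >= cutoff].copy()


def cluster_annotations(points: Sequence[tuple[float, float]],
                        max_distance: float) -> list[list[int]]:
    """Partition points into complete-linkage clusters of bounded diameter.

    Complete-linkage agglomerative clustering cut so that every
    within-cluster pairwise Euclidean distance is <= ``max_distance``
    (complete-linkage merge heights are exactly cluster diameters, so
    cutting the tree at the threshold guarantees the constraint).
    Returns index lists; stable under input permutation up to
    relabelling.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return []
    if n == 1:
        return [[0]]
    z = linkage(pdist(pts), method="complete")
    labels = fcluster(z, t=max_distance, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    # deterministic order: by smallest member index
    return sorted(clusters.values(), key=lambda c: min(c))


def make_bounding_box(cluster: Sequence[tuple[float, float]],
                      margin: int = 10,
                      image_size: Optional[tuple[int, int]] = None
                      ) -> tuple[int, int, int, int]:
    """Axis-aligned box extending ``margin`` px beyond the extreme marks.

    ``image_size`` is (rows, cols); the box is clipped to image bounds
    and returned as inclusive (x_min, y_min, x_max, y_max).
    """
    if len(cluster) == 0:
        raise ValueError("cannot box an empty cluster")
    pts = np.asarray(cluster, dtype=float)
    x_min = int(np.floor(pts[:, 0].min())) - margin
    y_min = int(np.floor(pts[:, 1].min())) - margin
    x_max = int(np.ceil(pts[:, 0].max())) + margin
    y_max = int(np.ceil(pts[:, 1].max())) + margin
    if image_size is not None:
        rows, cols = image_size
        x_min, x_max = max(x_min, 0), min(x_max, cols - 1)
        y_min, y_max = max(y_min, 0), min(y_max, rows - 1)
    return (x_min, y_min, x_max, y_max)


def point_in_bbox(x: float, y: float, bbox: tuple[int, int, int, int]) -> bool:
    x_min, y_min, x_max, y_max = bbox
    return x_min <= x <= x_max and y_min <= y <= y_max


def match_annotation_to_lesion(x: float, y: float, lesions: pd.DataFrame,
                               spacing: float,
                               hit_radius_mm: float = 12.5) -> Optional[int]:
    """Index of the nearest lesion whose centre lies within the hit radius.

    Distances are computed in mm via ``spacing`` (mm/pixel); the radius
    test is inclusive. Ties beyond floating precision are broken by
    table order (logged).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if len(lesions) == 0:
        return None
    d_mm = np.hypot(lesions["x_px"].to_numpy(dtype=float) - x,
                    lesions["y_px"].to_numpy(dtype=float) - y) * spacing
    within = np.flatnonzero(d_mm <= hit_radius_mm + 1e-9)
    if len(within) == 0:
        return None
    if len(within) > 1:
        order = within[np.argsort(d_mm[within], kind="stable")]
        if abs(d_mm[order[0]] - d_mm[order[1]]) < 1e-9:
            logger.info("lesion-match tie at (%.1f, %.1f); "
                        "breaking by table order", x, y)
        return int(order[0])
    return int(within[0])


def build_suspicious_areas(annotations: pd.DataFrame,
                           lesions: pd.DataFrame,
                           spacing: float,
                           thresholds: PipelineThresholds = None,
                           image_size: Optional[tuple[int, int]] = None
                           ) -> list[SuspiciousArea]:
    """Construct suspicious areas per (case, view, side).

    Positive marks matched to a lesion (centre within the hit radius)
    join that lesion's cancer area; all remaining positive marks are
    clustered with the bounded-diameter rule into normal areas. Cancer
    areas are seeded from lesion truths even when no reader marked them
    (an all-reader miss must still yield a row downstream).
    """
    thresholds = thresholds or PipelineThresholds()
    positives = pool_positive_annotations(
        annotations, thresholds.positive_rating_cutoff)
    areas: list[SuspiciousArea] = []
    keys = set()
    for df in (positives, lesions):
        for _, r in df.iterrows():
            keys.add((r["case_id"], r["view"], r["side"]))
    for case_id, view, side in sorted(keys):
        sel = positives[(positives["case_id"] == case_id)
                        & (positives["view"] == view)
                        & (positives["side"] == side)]
        les = lesions[(lesions["case_id"] == case_id)
                      & (lesions["view"] == view)
                      & (lesions["side"] == side)].reset_index(drop=True)
        lesion_members: dict[int, list] = {i: [] for i in range(len(les))}
        free_idx = []
        for idx, ann in sel.iterrows():
            li = match_annotation_to_lesion(
                ann["x_px"], ann["y_px"], les, spacing,
                thresholds.lesion_hit_radius_mm)
            if li is None:
                free_idx.append(idx)
            else:
                lesion_members[li].append(idx)
        # cancer areas: one per lesion truth, marked or not
        for li in range(len(les)):
            members = sel.loc[lesion_members[li]]
            pts = list(zip(members["x_px"], members["y_px"]))
            pts.append((float(les.loc[li, "x_px"]), float(les.loc[li, "y_px"])))
            bbox = make_bounding_box(pts, thresholds.bbox_margin, image_size)
            areas.append(SuspiciousArea(
                area_id=f"{case_id}_{view}_{side}_cancer{li}",
                case_id=case_id, view=view, side=side, kind="cancer",
                bbox=bbox, member_annotations=members,
                matched_lesion=les.loc[li]))
        # normal areas from the unmatched positive marks
        free = sel.loc[free_idx]
        pts = list(zip(free["x_px"], free["y_px"]))
        for ci, cluster in enumerate(
                cluster_annotations(pts, thresholds.cluster_max_distance)):
            members = free.iloc[cluster]
            bbox = make_bounding_box(
                list(zip(members["x_px"], members["y_px"])),
                thresholds.bbox_margin, image_size)
            areas.append(SuspiciousArea(
                area_id=f"{case_id}_{view}_{side}_normal{ci}",
                case_id=case_id, view=view, side=side, kind="normal",
                bbox=bbox, member_annotations=members))
    return areas


def build_response_matrix(areas: Iterable[SuspiciousArea],
                          readers: Sequence[str],
                          annotations: pd.DataFrame,
                          cutoff: int = 3) -> ResponseMatrix:
    """Binary false-response matrix over a reader roster.

    Normal area: entry 1 iff the reader has at least one positive mark
    inside the box (a false positive). Cancer area: entry 1 iff the
    reader has NO positive mark inside the box (a false negative — a
    negative mark or no mark at all). The per-area response dicts are
    filled in place as a side effect.
    """
    validate_annotations(annotations)
    readers = list(readers)
    unknown = set(annotations["reader_id"]) - set(readers)
    if unknown:
        raise ValueError(f"annotations from readers outside roster: "
                         f"{sorted(unknown)}")
    areas = list(areas)
    values = np.zeros((len(readers), len(areas)), dtype=int)
    positives = annotations[annotations["rating"] >= cutoff]
    for j, area in enumerate(areas):
        sel = positives[(positives["case_id"] == area.case_id)
                        & (positives["view"] == area.view)
                        & (positives["side"] == area.side)]
        mask = np.fromiter((point_in_bbox(x, y, area.bbox)
                            for x, y in zip(sel["x_px"], sel["y_px"])),
                           dtype=bool, count=len(sel))
        inside = sel[mask]
        marked = set(inside["reader_id"])
        for i, reader in enumerate(readers):
            hit = reader in marked
            false_resp = hit if area.kind == "normal" else not hit
            values[i, j] = int(false_resp)
        area.responses = {r: int(values[i, j])
                          for i, r in enumerate(readers)}
    return ResponseMatrix(reader_ids=readers,
                          area_ids=[a.area_id for a in areas],
                          values=values)


def assign_difficulty(areas: Iterable[SuspiciousArea],
                      responses: ResponseMatrix) -> list[SuspiciousArea]:
    """Median-split difficulty labels, normal and cancer areas separately.

    Per area kind: false-response count strictly greater than the
    kind's median -> "difficult"; count <= median -> "easy". If all
    counts within a kind are equal the labelling degenerates to all
    easy (warned).
    """
    areas = list(areas)
    counts = responses.values.sum(axis=0)
    count_by_id = dict(zip(responses.area_ids, counts))
    for kind in ("normal", "cancer"):
        group = [a for a in areas if a.kind == kind]
        if not group:
            continue
        kcounts = np.array([count_by_id[a.area_id] for a in group])
        med = float(np.median(kcounts))
        if np.ptp(kcounts) == 0:
            logger.warning("degenerate difficulty labelling: all %s-area "
                           "false-response counts equal %d", kind, kcounts[0])
        for a, c in zip(group, kcounts):
            a.difficulty = "difficult" if c > med else "easy"
    return areas


def areas_to_frame(areas: Iterable[SuspiciousArea]) -> pd.DataFrame:
    """Tidy per-area table (bbox, kind, false-response count, label)."""
    rows = []
    for a in areas:
        rows.append({
            "area_id": a.area_id, "case_id": a.case_id, "view": a.view,
            "side": a.side, "kind": a.kind,
            "x_min": a.bbox[0], "y_min": a.bbox[1],
            "x_max": a.bbox[2], "y_max": a.bbox[3],
            "n_members": len(a.member_annotations),
            "false_response_count": a.false_response_count,
            "difficulty": a.difficulty,
        })
    return pd.DataFrame(rows)
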