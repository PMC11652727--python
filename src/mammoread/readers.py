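"""Hierarchical clustering of readers by error agreement, with outlier exclusion.

Readers are rows of a binary false-response matrix; Euclidean distance
between rows measures reading-behaviour dissimilarity and Ward's
minimum-variance linkage builds the dendrogram. Readers sitting in the
outer branch(es) — those joining the remainder of the tree at the
greatest merge heights — are flagged as outliers and excluded from the
false-positive modelling branch, along with the normal areas that only
they marked. The false-negative branch keeps the full roster.

The source analysis identified outer branches by consensus among
researchers; here the cut is made algorithmic and configurable: the
outermost branch is peeled while the height gap separating it from the
rest of the tree exceeds ``gap_factor`` times the median merge height,
up to ``max_outliers`` readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram as _scipy_dendrogram
from scipy.cluster.hierarchy import linkage, leaves_list

from .annotations import ResponseMatrix, SuspiciousArea

logger = logging.getLogger(__name__)


@dataclass
class ReaderDendrogram:
    """Ward/Euclidean hierarchy over readers."""

    reader_ids: list
    linkage_matrix: np.ndarray  # scipy linkage records

    def __post_init__(self) -> None:
        n = len(self.reader_ids)
        z = np.asarray(self.linkage_matrix, dtype=float)
        if z.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 merge records")
        heights = z[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")
        self.linkage_matrix = z

    @property
    def leaf_order(self) -> list:
        return [self.reader_ids[i]
                for i in leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        """Newick text with merge heights as branch lengths."""
        n = len(self.reader_ids)
        height = {i: 0.0 for i in range(n)}
        text = {i: self.reader_ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node = n + k
            text[node] = f"({text[a]}:{la:.6g},{text[b]}:{lb:.6g})"
            height[node] = h
        return text[2 * n - 2] + ";"


def cluster_readers(matrix: ResponseMatrix) -> ReaderDendrogram:
    """Agglomerate readers with Euclidean distance and Ward linkage."""
    if len(matrix.reader_ids) < 2:
        raise ValueError("need at least 2 readers to cluster")
    z = linkage(matrix.values.astype(float), method="ward",
                metric="euclidean")
    return ReaderDendrogram(reader_ids=list(matrix.reader_ids),
                            linkage_matrix=z)


def _subtree_leaves(z: np.ndarray, node: int, n: int) -> list[int]:
    if node < n:
        return [node]
    a, b = int(z[node - n, 0]), int(z[node - n, 1])
    return _subtree_leaves(z, a, n) + _subtree_leaves(z, b, n)


def _node_height(z: np.ndarray, node: int, n: int) -> float:
    return 0.0 if node < n else float(z[node - n, 2])


def identify_outliers(dendro: ReaderDendrogram,
                      max_outliers: int | None = None,
                      gap_factor: float = 0.25) -> list[str]:
    """Readers in outer branches separated by a large height gap.

    Starting from the root merge, the smaller child branch is peeled as
    outliers while the height gap separating it from the rest of the
    tree is large *relative to that remaining subtree*:
    (root height − remaining-subtree height) > ``gap_factor`` x
    remaining-subtree height. The rule then recurses into the
    remaining subtree; peeling stops when the gap criterion fails or
    ``max_outliers`` (default: 25% of the roster) would be exceeded.
    An empty list is a valid outcome (a tree whose top merges all sit
    at comparable heights has no outer branch).
    """
    z = dendro.linkage_matrix
    n = len(dendro.reader_ids)
    if max_outliers is None:
        max_outliers = n // 4
    if max_outliers <= 0:
        return []
    outliers: list[int] = []
    node = 2 * n - 2  # root
    while node >= n:
        a, b = int(z[node - n, 0]), int(z[node - n, 1])
        la, lb = _subtree_leaves(z, a, n), _subtree_leaves(z, b, n)
        small, big = (la, b) if len(la) <= len(lb) else (lb, a)
        h_root = _node_height(z, node, n)
        h_rest = _node_height(z, big, n)
        if h_root <= 0 or h_root - h_rest <= gap_factor * h_rest:
            break
        if len(outliers) + len(small) > max_outliers:
            break
        outliers.extend(small)
        node = big
    names = [dendro.reader_ids[i] for i in sorted(outliers)]
    if names:
        logger.info("outer-branch outliers: %s", names)
    return names


def exclude_outliers(annotations: pd.DataFrame,
                     areas: list[SuspiciousArea],
                     outliers: list[str],
                     roster: list[str]):
    """Drop outlier readers and the normal areas only they marked.

    Returns ``(annotations, areas, roster)`` filtered for the
    false-positive pipeline. Cancer areas are always retained (the
    exclusion applies to false-positive modelling; false-negative
    analysis keeps the full roster and is run on the unfiltered
    inputs). Normal areas whose every positive mark came from outliers
    are removed.
    """
    unknown = set(outliers) - set(roster)
    if unknown:
        raise ValueError(f"outliers not in roster: {sorted(unknown)}")
    kept_roster = [r for r in roster if r not in set(outliers)]
    if not kept_roster:
        raise ValueError("cannot exclude every reader")
    if not outliers:
        return annotations, list(areas), list(roster)
    kept_ann = annotations[~annotations["reader_id"].isin(outliers)].copy()
    kept_areas = []
    for area in areas:
        if area.kind == "cancer":
            kept_areas.append(area)
            continue
        members = area.member_annotations
        if (~members["reader_id"].isin(outliers)).any():
            kept_areas.append(area)
        else:
            logger.info("dropping area %s: marked only by outliers",
                        area.area_id)
    return kept_ann, kept_areas, kept_roster


def outlier_report(matrix: ResponseMatrix, outliers: list[str]) -> pd.DataFrame:
    """Per-reader false-response counts against the cohort median."""
    counts = matrix.values.sum(axis=1)
    median = float(np.median(counts))
    return pd.DataFrame({
        "reader_id": matrix.reader_ids,
        "false_response_count": counts,
        "cohort_median": median,
        "is_outlier": [r in set(outliers) for r in matrix.reader_ids],
    })


def plot_dendrogram(dendro: ReaderDendrogram, ax=None, **kwargs):
    """Render the reader dendrogram (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    _scipy_dendrogram(dendro.linkage_matrix, labels=dendro.reader_ids,
                      ax=ax, **kwargs)
    ax.set_ylabel("Ward merge height")
    return ax
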