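"""Annotation pooling, clustering, boxing, hit-testing and labelling."""

import numpy as np
import pandas as pd
import pytest

from mammoread.annotations import (PipelineThresholds, assign_difficulty,
                                   build_response_matrix,
                                   build_suspicious_areas,
                                   cluster_annotations, make_bounding_box,
                                   match_annotation_to_lesion,
                                   pool_positive_annotations)

from .oracles import complete_linkage_bruteforce


def ann_frame(rows):
    return pd.DataFrame(rows, columns=["reader_id", "case_id", "view",
                                       "side", "x_px", "y_px", "rating"])


def simple_annotations(ratings, x0=10.0):
    return ann_frame([(f"R{i:02d}", "case001", "CC", "L", x0 + i, 20.0, r)
                      for i, r in enumerate(ratings)])


class TestPooling:
    def test_cutoff_three_keeps_ratings_three_and_higher(self):
        out = pool_positive_annotations(simple_annotations([1, 2, 3, 4, 5]))
        assert len(out) == 3
        assert (out["rating"] >= 3).all()

    def test_empty_and_all_negative_inputs(self):
        assert len(pool_positive_annotations(simple_annotations([]))) == 0
        assert len(pool_positive_annotations(
            simple_annotations([2, 2, 2]))) == 0

    def test_order_preserved(self):
        out = pool_positive_annotations(simple_annotations([5, 1, 3, 4]))
        assert list(out["x_px"]) == [10.0, 12.0, 13.0]

    def test_invalid_rating_rejected(self):
        with pytest.raises(ValueError):
            pool_positive_annotations(simple_annotations([6]))


class TestClustering:
    def test_threshold_splits_far_point(self):
        clusters = cluster_annotations([(0, 0), (100, 0), (400, 0)], 250.0)
        assert clusters == [[0, 1], [2]]

    def test_singleton_and_coincident_points(self):
        assert cluster_annotations([(5, 5)], 250.0) == [[0]]
        assert cluster_annotations([(5, 5), (5, 5)], 250.0) == [[0, 1]]
        assert cluster_annotations([], 250.0) == []

    def test_matches_bruteforce_complete_linkage(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 8))
            pts = rng.uniform(0, 600, size=(n, 2))
            t = float(rng.uniform(50, 400))
            ours = cluster_annotations([tuple(p) for p in pts], t)
            oracle = complete_linkage_bruteforce(pts, t)
            assert sorted(ours) == oracle

    def test_diameter_constraint_always_holds(self, rng):
        pts = rng.uniform(0, 1000, size=(40, 2))
        for cluster in cluster_annotations([tuple(p) for p in pts], 250.0):
            for i in cluster:
                for j in cluster:
                    assert np.hypot(*(pts[i] - pts[j])) <= 250.0 + 1e-9

    def test_permutation_invariance(self, rng):
        pts = [tuple(p) for p in rng.uniform(0, 500, size=(12, 2))]
        base = cluster_annotations(pts, 200.0)
        perm = rng.permutation(len(pts))
        clusters = cluster_annotations([pts[i] for i in perm], 200.0)
        remapped = sorted(sorted(int(perm[i]) for i in c) for c in clusters)
        assert remapped == sorted(sorted(c) for c in base)


class TestBoundingBox:
    def test_single_point_margin(self):
        assert make_bounding_box([(50, 60)], 10) == (40, 50, 60, 70)

    def test_clipping_at_image_edge(self):
        bbox = make_bounding_box([(0, 0), (30, 40)], 10, image_size=(100, 100))
        assert bbox == (0, 0, 40, 50)

    def test_zero_margin_is_tight(self):
        assert make_bounding_box([(3, 4), (7, 9)], 0) == (3, 4, 7, 9)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            make_bounding_box([], 10)


class TestLesionMatching:
    lesions = pd.DataFrame({"case_id": ["c"], "view": ["CC"], "side": ["L"],
                            "x_px": [100.0], "y_px": [100.0],
                            "radius_mm": [12.5], "subtype": ["stellate"]})

    def test_within_radius_matches(self):
        # 10 mm away at 0.1 mm/px = 100 px
        assert match_annotation_to_lesion(200.0, 100.0, self.lesions,
                                          spacing=0.1) == 0

    def test_boundary_is_inclusive(self):
        assert match_annotation_to_lesion(225.0, 100.0, self.lesions,
                                          spacing=0.1) == 0  # exactly 12.5 mm

    def test_beyond_radius_returns_none(self):
        assert match_annotation_to_lesion(226.0, 100.0, self.lesions,
                                          spacing=0.1) is None

    def test_no_lesions_returns_none(self):
        empty = self.lesions.iloc[:0]
        assert match_annotation_to_lesion(0, 0, empty, spacing=0.1) is None

    def test_nearest_of_two_wins(self):
        two = pd.concat([self.lesions, self.lesions]).reset_index(drop=True)
        two.loc[1, "x_px"] = 140.0
        assert match_annotation_to_lesion(130.0, 100.0, two, spacing=0.1) == 1


class TestResponseMatrix:
    def build(self, areas, readers, ann):
        return build_response_matrix(areas, readers, ann)

    def make_areas(self, ann, lesions):
        return build_suspicious_areas(ann, lesions, spacing=0.1,
                                      thresholds=PipelineThresholds(
                                          cluster_max_distance=50))

    def test_false_positive_and_negative_coding(self):
        lesions = pd.DataFrame(
            {"case_id": ["c1"], "view": ["CC"], "side": ["L"],
             "x_px": [500.0], "y_px": [500.0], "radius_mm": [12.5],
             "subtype": ["discrete mass"]})
        ann = ann_frame([
            ("A", "c1", "CC", "L", 100.0, 100.0, 4),  # FP mark, normal area
            ("B", "c1", "CC", "L", 505.0, 500.0, 5),  # hit on the lesion
            ("C", "c1", "CC", "L", 502.0, 498.0, 2),  # negative mark on lesion
        ])
        areas = self.make_areas(ann, lesions)
        kinds = {a.kind for a in areas}
        assert kinds == {"normal", "cancer"}
        matrix = self.build(areas, ["A", "B", "C"], ann)
        df = matrix.to_frame()
        normal_id = next(a.area_id for a in areas if a.kind == "normal")
        cancer_id = next(a.area_id for a in areas if a.kind == "cancer")
        assert df.loc["A", normal_id] == 1  # positive mark on normal: FP
        assert df.loc["B", normal_id] == 0
        assert df.loc["B", cancer_id] == 0  # true positive
        assert df.loc["C", cancer_id] == 1  # negative mark only: FN
        assert df.loc["A", cancer_id] == 1  # no mark at all: FN

    def test_unknown_reader_rejected(self):
        ann = ann_frame([("X", "c1", "CC", "L", 10.0, 10.0, 4)])
        areas = self.make_areas(ann, ann.iloc[:0].reindex(
            columns=["case_id", "view", "side", "x_px", "y_px", "radius_mm",
                     "subtype"]))
        with pytest.raises(ValueError, match="outside roster"):
            self.build(areas, ["A"], ann)

    def test_unmarked_lesion_still_becomes_area(self):
        lesions = pd.DataFrame(
            {"case_id": ["c1"], "view": ["CC"], "side": ["L"],
             "x_px": [50.0], "y_px": [50.0], "radius_mm": [12.5],
             "subtype": ["stellate"]})
        ann = ann_frame([])
        areas = self.make_areas(ann, lesions)
        assert len(areas) == 1 and areas[0].kind == "cancer"
        matrix = self.build(areas, ["A", "B"], ann)
        assert matrix.values.sum() == 2  # everyone missed it


class TestDifficulty:
    def label(self, counts):
        """Run assign_difficulty on synthetic single-kind areas."""
        from mammoread.annotations import ResponseMatrix, SuspiciousArea

        n_readers = max(counts) + 1
        areas = []
        values = np.zeros((n_readers, len(counts)), dtype=int)
        for j, c in enumerate(counts):
            values[:c, j] = 1
            areas.append(SuspiciousArea(
                area_id=f"a{j}", case_id="c", view="CC", side="L",
                kind="normal", bbox=(0, 0, 1, 1),
                member_annotations=pd.DataFrame()))
        matrix = ResponseMatrix([f"R{i}" for i in range(n_readers)],
                                [a.area_id for a in areas], values)
        assign_difficulty(areas, matrix)
        return [a.difficulty for a in areas]

    def test_median_split_even_count(self):
        assert self.label([1, 1, 2, 3]) == ["easy", "easy", "difficult",
                                            "difficult"]

    def test_median_split_odd_count(self):
        assert self.label([1, 2, 3]) == ["easy", "easy", "difficult"]

    def test_all_equal_counts_degenerate_to_easy(self):
        assert self.label([1, 1, 1]) == ["easy"] * 3

    def test_kinds_labelled_separately_and_conserved(self, rng):
        from mammoread.synthetic import SyntheticConfig, generate_case_set, \
            simulate_readers, reader_ids

        cfg = SyntheticConfig(n_normal_cases=6, n_cancer_cases=3,
                              image_size=(192, 192), seed=11)
        cs = generate_case_set(cfg)
        sim = simulate_readers(cs, cfg)
        areas = build_suspicious_areas(
            sim.annotations, cs.lesion_truths, cs.pixel_spacing,
            PipelineThresholds(cluster_max_distance=60), cfg.image_size)
        matrix = build_response_matrix(areas, reader_ids(cfg.n_readers),
                                       sim.annotations)
        assign_difficulty(areas, matrix)
        for kind in ("normal", "cancer"):
            group = [a for a in areas if a.kind == kind]
            assert all(a.difficulty in ("easy", "difficult") for a in group)
        # normal areas exist only where someone marked: count >= 1
        counts = matrix.values.sum(axis=0)
        for a, c in zip(areas, counts):
            if a.kind == "normal":
                assert 1 <= c <= cfg.n_readers


def test_area_building_invariant_to_annotation_order(rng):
    from mammoread.synthetic import SyntheticConfig, generate_case_set, \
        simulate_readers, reader_ids

    cfg = SyntheticConfig(n_normal_cases=5, n_cancer_cases=2,
                          image_size=(192, 192), seed=21)
    cs = generate_case_set(cfg)
    sim = simulate_readers(cs, cfg)
    thresholds = PipelineThresholds(cluster_max_distance=60)
    roster = reader_ids(cfg.n_readers)

    def run(ann):
        areas = build_suspicious_areas(ann, cs.lesion_truths,
                                       cs.pixel_spacing, thresholds,
                                       cfg.image_size)
        matrix = build_response_matrix(areas, roster, ann)
        return {a.area_id: a.bbox for a in areas}, \
            matrix.to_frame().sort_index(axis=1)

    boxes1, resp1 = run(sim.annotations)
    shuffled = sim.annotations.sample(frac=1.0, random_state=3)
    boxes2, resp2 = run(shuffled)
    assert set(boxes1.values()) == set(boxes2.values())
    pd.testing.assert_frame_equal(resp1, resp2)
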