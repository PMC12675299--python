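"""Geometry and proximity classification tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plaquemap import (
    Plaque,
    RegionPolygon,
    canonical_quadrilateral,
    classify_proximity,
    compute_proximity,
    distance_to_plaque_edge,
    nearest_plaque,
    point_in_polygon,
    polygon_area,
    summarize_proximity,
)
from plaquemap.spatial import DegenerateGeometryError, plaques_from_frame, plaques_to_frame
from plaquemap.containers import InputError

UNIT_SQUARE = [(0, 0), (1, 0), (1, 1), (0, 1)]


def _is_simple_quad(pts):
    """Segment-intersection test for quadrilateral simplicity."""

    def seg_cross(p, q, r, s):
        def orient(a, b, c):
            return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

        return orient(p, q, r) != orient(p, q, s) and orient(r, s, p) != orient(r, s, q)

    edges = [(pts[i], pts[(i + 1) % 4]) for i in range(4)]
    # non-adjacent edge pairs: (0,2) and (1,3)
    return not seg_cross(*edges[0], *edges[2]) and not seg_cross(*edges[1], *edges[3])


class TestCanonicalQuadrilateral:
    def test_bowtie_input_reordered_to_simple_square(self):
        ordered = canonical_quadrilateral(np.array([(0, 0), (1, 1), (1, 0), (0, 1)]))
        assert _is_simple_quad(ordered)
        assert {tuple(p) for p in ordered} == {(0, 0), (1, 0), (1, 1), (0, 1)}

    def test_clockwise_input_becomes_counter_clockwise(self):
        ordered = canonical_quadrilateral(np.array([(0, 1), (1, 1), (1, 0), (0, 0)]))
        # shoelace signed area positive for CCW
        x, y = ordered[:, 0], ordered[:, 1]
        signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert signed > 0

    @pytest.mark.parametrize(
        "pts",
        [
            [(0, 0), (1, 1), (2, 2), (3, 3)],  # collinear
            [(0, 0), (0, 0), (1, 0), (0, 1)],  # duplicate
        ],
    )
    def test_degenerate_points_raise(self, pts):
        with pytest.raises(DegenerateGeometryError):
            canonical_quadrilateral(np.array(pts, dtype=float))

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_point_sets_always_simple(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, size=(4, 2))
        try:
            ordered = canonical_quadrilateral(pts)
        except DegenerateGeometryError:
            return  # genuinely degenerate draws are allowed to fail
        assert _is_simple_quad(ordered)


class TestPointInPolygon:
    @pytest.mark.parametrize(
        "point, expected",
        [((0.5, 0.5), True), ((2.0, 2.0), False), ((0.0, 0.0), True), ((0.5, 0.0), True)],
    )
    def test_unit_square_with_boundary_inside(self, point, expected):
        assert point_in_polygon(point, UNIT_SQUARE) is expected


class TestPolygonArea:
    @pytest.mark.parametrize(
        "poly, expected",
        [
            (UNIT_SQUARE, 1.0),
            ([(0, 0), (4, 0), (0, 3)], 6.0),
            (list(reversed(UNIT_SQUARE)), 1.0),  # orientation-independent
        ],
    )
    def test_shoelace_values(self, poly, expected):
        assert polygon_area(poly) == pytest.approx(expected)


class TestDistanceToPlaqueEdge:
    SQUARE_PM1 = Plaque.from_points(1, [(-1, -1), (1, -1), (1, 1), (-1, 1)])

    def test_interior_point_distance_zero(self):
        assert distance_to_plaque_edge((0, 0), self.SQUARE_PM1) == 0.0

    def test_perpendicular_to_edge(self):
        assert distance_to_plaque_edge((3, 0), self.SQUARE_PM1) == pytest.approx(2.0)

    def test_nearest_corner(self):
        sq = Plaque.from_points(1, [(0, 0), (4, 0), (4, 4), (0, 4)])
        assert distance_to_plaque_edge((6, 6), sq) == pytest.approx(np.sqrt(8.0))

    def test_boundary_point_distance_zero(self):
        assert distance_to_plaque_edge((1, 0), self.SQUARE_PM1) == 0.0

    def test_matches_dense_boundary_sampling_oracle(self):
        """Shapely distances agree with a brute-force boundary-sampled minimum."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            c = rng.uniform(40, 60, 2)
            ang = np.deg2rad([0, 90, 180, 270]) + rng.uniform(-0.5, 0.5, 4)
            r = rng.uniform(5, 15, 4)
            plq = Plaque.from_points(1, np.column_stack([c[0] + r * np.cos(ang), c[1] + r * np.sin(ang)]))
            p = rng.uniform(0, 100, 2)
            per = plq.perimeter
            samples = np.vstack([np.linspace(per[i], per[(i + 1) % 4], 20_000) for i in range(4)])
            brute = float(np.min(np.hypot(samples[:, 0] - p[0], samples[:, 1] - p[1])))
            d = distance_to_plaque_edge(p, plq)
            if d == 0.0:
                continue  # interior by convention
            assert d == pytest.approx(brute, abs=1e-3)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 30, size=(4, 2))
        plq = Plaque.from_points(1, pts)
        p = rng.uniform(-20, 50, 2)
        d0 = distance_to_plaque_edge(p, plq)
        theta, shift = 0.83, np.array([12.5, -40.0])
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        plq2 = Plaque.from_points(1, pts @ rot.T + shift)
        d1 = distance_to_plaque_edge(rot @ p + shift, plq2)
        assert d1 == pytest.approx(d0, rel=1e-9)


class TestNearestPlaque:
    def test_picks_closer_plaque(self):
        plaques = [
            Plaque.from_points(1, [(0, 0), (2, 0), (2, 2), (0, 2)]),
            Plaque.from_points(2, [(10, 0), (12, 0), (12, 2), (10, 2)]),
        ]
        pid, d = nearest_plaque((4, 1), plaques)
        assert pid == 1 and d == pytest.approx(2.0)

    def test_exact_tie_goes_to_smaller_id(self):
        plaques = [
            Plaque.from_points(2, [(10, 0), (12, 0), (12, 2), (10, 2)]),
            Plaque.from_points(1, [(0, 0), (2, 0), (2, 2), (0, 2)]),
        ]
        pid, _ = nearest_plaque((6, 1), plaques)  # 4 um from both
        assert pid == 1

    def test_no_plaques_requires_explicit_distal_mode(self):
        with pytest.raises(InputError):
            nearest_plaque((0, 0), [])

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_result_bounded_by_every_individual_distance(self, seed):
        rng = np.random.default_rng(seed)
        plaques = []
        for pid in range(1, 4):
            c = rng.uniform(0, 100, 2)
            ang = np.deg2rad([0, 90, 180, 270]) + rng.uniform(-0.4, 0.4, 4)
            r = rng.uniform(3, 8, 4)
            plaques.append(
                Plaque.from_points(pid, np.column_stack([c[0] + r * np.cos(ang), c[1] + r * np.sin(ang)]))
            )
        p = rng.uniform(0, 100, 2)
        _, d = nearest_plaque(p, plaques)
        for plq in plaques:
            assert d <= distance_to_plaque_edge(p, plq) + 1e-12


class TestClassifyProximity:
    @pytest.mark.parametrize(
        "distance, expected",
        [(14.9, "plaque_associated"), (15.0, "plaque_associated"), (15.01, "distal"), (0.0, "plaque_associated")],
    )
    def test_cutoff_boundary_inclusive(self, distance, expected):
        assert classify_proximity(distance) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(InputError):
            classify_proximity(-0.1)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0, 100, allow_nan=False), st.floats(0, 50), st.floats(0, 50))
    def test_growing_cutoff_never_demotes_to_distal(self, d, c1, c2):
        lo, hi = sorted((c1, c2))
        if classify_proximity(d, lo) == "plaque_associated":
            assert classify_proximity(d, hi) == "plaque_associated"


class TestProximityRecords:
    def test_rule_scene_labels_distances_and_ids(self, rule_scene):
        exp = rule_scene["expected"]
        rec = compute_proximity(rule_scene["cells"], rule_scene["plaques"], rule_scene["region"]).set_index("cell_id")
        for cid, label in exp["labels"].items():
            assert rec.loc[cid, "label"] == label, cid
        for cid, pid in exp["nearest"].items():
            assert rec.loc[cid, "nearest_plaque_id"] == pid, cid
        for cid, d in exp["distances"].items():
            assert rec.loc[cid, "distance_um"] == pytest.approx(d, abs=1e-12), cid
        for cid in exp["out_of_region"]:
            assert not rec.loc[cid, "in_region"]
            assert pd.isna(rec.loc[cid, "label"])

    def test_truth_label_recovery_on_simulated_scene(self, small_dataset):
        """Classification at the generative cutoff reproduces the truth labels."""
        ds = small_dataset
        rec = compute_proximity(ds.cells, ds.plaques, region=None, cutoff=ds.config.proximity_cutoff_um)
        got = pd.Series(rec["label"].to_numpy(dtype=object), index=pd.Index(rec["cell_id"]))
        truth = ds.truth.true_proximity_label
        assert (got.loc[truth.index] == truth).all()

    def test_summary_counts_and_plaque_free_density(self, rule_scene):
        exp = rule_scene["expected"]
        cells = rule_scene["cells"]
        survivors = cells[cells["cell_id"].isin(exp["survivors"])]
        rec = compute_proximity(survivors, rule_scene["plaques"], rule_scene["region"])
        summary = summarize_proximity(rec, rule_scene["plaques"], rule_scene["region"])
        assert summary["per_plaque_counts"] == exp["per_plaque_counts"]
        assert summary["n_distal"] == exp["n_distal"]
        free = exp["region_area"] - exp["plaque_area_total"]
        assert summary["distal_density_per_um2"] == pytest.approx(exp["n_distal"] / free)

    def test_per_plaque_counts_reconcile_with_records(self, small_dataset):
        ds = small_dataset
        rec = compute_proximity(ds.cells, ds.plaques, ds.region_polygon)
        summary = summarize_proximity(rec, ds.plaques, ds.region_polygon)
        assoc = rec[(rec["in_region"]) & (rec["label"] == "plaque_associated")]
        assert sum(summary["per_plaque_counts"].values()) == len(assoc)

    def test_region_smaller_than_plaques_rejected(self, rule_scene):
        tiny = RegionPolygon("tiny", np.array([(0, 0), (10, 0), (10, 10), (0, 10)]))
        rec = compute_proximity(rule_scene["cells"], rule_scene["plaques"], tiny)
        with pytest.raises(InputError):
            summarize_proximity(rec, rule_scene["plaques"], tiny)


class TestPlaqueTableRoundTrip:
    def test_frame_round_trip_preserves_geometry(self, small_dataset):
        frame = plaques_to_frame(small_dataset.plaques)
        back = plaques_from_frame(frame)
        for a, b in zip(small_dataset.plaques, back):
            assert a.plaque_id == b.plaque_id
            np.testing.assert_allclose(a.perimeter, b.perimeter)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(InputError):
            plaques_from_frame(pd.DataFrame({"plaque_id": [1], "x1": [0], "y1": [0], "x2": [1]}))
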