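"""Tests for trajectory segment extraction, linearization and exemplars."""

import numpy as np
import pytest

from evodfnc.errors import (
    DegenerateExemplarError,
    DegenerateSegmentError,
    InvalidParameterError,
    NotFoundError,
    SubjectTooShortError,
)
from evodfnc.exemplars import (
    ContinuousSegment,
    Exemplar,
    cluster_linear_segments,
    compute_slope_bound,
    exemplar_membership_occupancy,
    extract_segments,
    linearize_segment,
    orient_exemplar,
    sample_exemplar_points,
)

from _helpers import make_embedding


def make_segment(points, subject="a", start=0):
    return ContinuousSegment(subject, start, np.asarray(points, dtype=float))


class TestExtractSegments:
    def test_boundary_single_segment(self, rng):
        emb = make_embedding(rng.normal(size=(10, 2)))
        segs = extract_segments(emb, "a", tau=10)
        assert len(segs) == 1
        assert segs[0].points.shape == (10, 2)

    def test_count_formula(self, rng):
        emb = make_embedding(rng.normal(size=(137, 2)))
        segs = extract_segments(emb, "a", tau=44)
        assert len(segs) == 94
        assert [s.start for s in segs] == list(range(94))

    def test_too_short_subject(self, rng):
        emb = make_embedding(rng.normal(size=(10, 2)))
        with pytest.raises(SubjectTooShortError):
            extract_segments(emb, "a", tau=11)


class TestLinearizeSegment:
    def test_collinear_points(self):
        x = np.linspace(0, 4, 9)
        seg = make_segment(np.column_stack([x, 2 * x]))
        lin = linearize_segment(seg, slope_bound=10.0)
        assert np.isclose(lin.slope, 2.0)
        assert np.allclose(lin.midpoint, [2.0, 4.0])
        assert np.isclose(lin.length, np.hypot(4.0, 8.0))

    def test_vertical_segment_takes_positive_bound(self):
        seg = make_segment([[1.0, y] for y in range(5)])
        lin = linearize_segment(seg, slope_bound=7.5)
        assert lin.slope == 7.5

    def test_three_four_five_length(self):
        t = np.linspace(0, 1, 50)
        seg = make_segment(np.column_stack([3 * t, 4 * t]))
        lin = linearize_segment(seg, slope_bound=100.0)
        assert np.isclose(lin.length, 5.0)

    def test_random_segment_matches_closed_forms(self, rng):
        pts = rng.normal(size=(10, 2))
        seg = make_segment(pts)
        lin = linearize_segment(seg, slope_bound=np.inf)
        x, y = pts[:, 0], pts[:, 1]
        expected_slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert np.isclose(lin.slope, expected_slope, atol=1e-12)
        # O(tau^2) enumeration for the length
        best = max(
            np.hypot(*(pts[i] - pts[j]))
            for i in range(10)
            for j in range(10)
        )
        assert np.isclose(lin.length, best)

    def test_slope_clipping(self, rng):
        pts = np.column_stack([np.linspace(0, 0.01, 8), np.linspace(0, 5, 8)])
        lin = linearize_segment(make_segment(pts), slope_bound=3.0)
        assert lin.slope == 3.0

    def test_degenerate_segment_rejected(self):
        with pytest.raises(DegenerateSegmentError):
            linearize_segment(make_segment(np.ones((5, 2))), slope_bound=1.0)


class TestSlopeBound:
    def test_max_abs_coordinate(self):
        emb = make_embedding([[-3, 1], [5, -2], [0, 3]])
        assert compute_slope_bound(emb) == 5.0

    def test_unit_circle(self):
        t = np.linspace(0, 2 * np.pi, 100)
        emb = make_embedding(np.column_stack([np.cos(t), np.sin(t)]))
        assert np.isclose(compute_slope_bound(emb), 1.0)

    def test_matches_brute_scan(self, rng):
        coords = rng.normal(scale=4, size=(50, 2))
        emb = make_embedding(coords)
        assert compute_slope_bound(emb) == max(abs(v) for v in coords.ravel())


class TestClusterLinearSegments:
    def _planted_segments(self, rng):
        # 4 well-separated (x, y, slope) clouds of straight mini-trajectories
        planted = [(-10, -10, 0.0), (10, -10, 1.5), (-10, 10, -1.5), (10, 10, 0.5)]
        segments, labels = [], []
        for lbl, (cx, cy, m) in enumerate(planted):
            for i in range(25):
                jx, jy = rng.normal(scale=0.2, size=2)
                t = np.linspace(-0.5, 0.5, 6)
                pts = np.column_stack([cx + jx + t, cy + jy + m * t])
                segments.append(linearize_segment(make_segment(pts, start=i), slope_bound=20.0))
                labels.append(lbl)
        return segments, np.array(labels), planted

    def test_planted_clusters_recovered(self, rng):
        segments, labels, planted = self._planted_segments(rng)
        exset = cluster_linear_segments(segments, K=4, seed=0, n_init=20)
        for g in range(4):
            assert len(set(exset.labels[labels == g])) == 1
        # centroid midpoints and slopes near the planted values
        for cx, cy, m in planted:
            d = [
                abs(e.midpoint[0] - cx) + abs(e.midpoint[1] - cy) + abs(e.slope - m)
                for e in exset.exemplars
            ]
            assert min(d) < 0.5

    def test_exemplar_length_within_member_range(self, rng):
        segments, _, _ = self._planted_segments(rng)
        exset = cluster_linear_segments(segments, K=4, seed=0, n_init=20)
        for k, ex in enumerate(exset.exemplars):
            lengths = [segments[i].length for i in np.flatnonzero(exset.labels == k)]
            assert min(lengths) - 1e-12 <= ex.length <= max(lengths) + 1e-12

    def test_reproducible_per_seed(self, rng):
        segments, _, _ = self._planted_segments(rng)
        a = cluster_linear_segments(segments, K=4, seed=3, n_init=10)
        b = cluster_linear_segments(segments, K=4, seed=3, n_init=10)
        assert np.array_equal(a.labels, b.labels)
        assert all(
            np.array_equal(x.midpoint, y.midpoint) and x.slope == y.slope
            for x, y in zip(a.exemplars, b.exemplars)
        )

    def test_k_exceeding_segments_rejected(self, rng):
        segments, _, _ = self._planted_segments(rng)
        with pytest.raises(InvalidParameterError):
            cluster_linear_segments(segments[:3], K=10, seed=0)


class TestOrientExemplar:
    def test_left_to_right_members(self):
        members = [make_segment([[0, 0], [1, 0], [2, 0]]) for _ in range(3)]
        assert orient_exemplar(0.0, members) == 1

    def test_reversed_members(self):
        members = [make_segment([[2, 0], [1, 0], [0, 0]]) for _ in range(3)]
        assert orient_exemplar(0.0, members) == -1

    def test_mixed_members_follow_mean_displacement(self):
        members = [
            make_segment([[0, 0], [3, 0]]),   # +3 displacement
            make_segment([[1, 0], [0, 0]]),   # -1
        ]
        assert orient_exemplar(0.0, members) == 1  # mean displacement +1 along +x

    def test_perpendicular_displacement_defaults_positive(self):
        members = [make_segment([[0, 0], [0, 5]])]
        assert orient_exemplar(0.0, members) == 1


class TestSampleExemplarPoints:
    def test_tau_two_gives_endpoints(self):
        ex = Exemplar(0, np.array([0.0, 0.0]), 0.0, 4.0, 1)
        pts = sample_exemplar_points(ex, tau=2)
        assert np.allclose(pts, [[-2, 0], [2, 0]])

    def test_mean_is_midpoint(self, rng):
        ex = Exemplar(0, rng.normal(size=2), 1.3, 2.7, -1)
        pts = sample_exemplar_points(ex, tau=9)
        assert np.allclose(pts.mean(axis=0), ex.midpoint, atol=1e-12)

    def test_spacing_arithmetic(self):
        ex = Exemplar(0, np.array([0.0, 0.0]), 0.0, 4.3, 1)
        pts = sample_exemplar_points(ex, tau=44)
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.allclose(gaps, 0.1)
        assert np.isclose(pts[0, 0], -2.15) and np.isclose(pts[-1, 0], 2.15)

    def test_direction_flips_order(self):
        fwd = Exemplar(0, np.zeros(2), 0.5, 2.0, 1)
        rev = Exemplar(0, np.zeros(2), 0.5, 2.0, -1)
        assert np.allclose(
            sample_exemplar_points(fwd, 7), sample_exemplar_points(rev, 7)[::-1]
        )

    def test_zero_length_rejected(self):
        ex = Exemplar(0, np.zeros(2), 0.0, 0.0, 1)
        with pytest.raises(DegenerateExemplarError):
            sample_exemplar_points(ex, 5)


class TestMembershipOccupancy:
    def test_one_hot_and_hand_count(self, rng):
        segs, _, _ = TestClusterLinearSegments()._planted_segments(rng)
        exset = cluster_linear_segments(segs, K=4, seed=0, n_init=10)
        occ = exemplar_membership_occupancy(exset, "a")
        assert np.isclose(occ.sum(), 1.0, atol=1e-12)
        counts = np.bincount(exset.labels, minlength=4)
        assert np.allclose(occ, counts / counts.sum())

    def test_unknown_subject(self, rng):
        segs, _, _ = TestClusterLinearSegments()._planted_segments(rng)
        exset = cluster_linear_segments(segs, K=4, seed=0, n_init=10)
        with pytest.raises(NotFoundError):
            exemplar_membership_occupancy(exset, "nobody")


def test_segment_counts_and_slope_clipping_on_pipeline(tiny_bundle):
    """Per-subject segment counts are W - tau + 1 and no slope exceeds the bound."""
    import pandas as pd

    meta = tiny_bundle.path / "exemplars" / "meta.json"
    import json

    tau = json.loads(meta.read_text())["tau"]
    bound = json.loads(meta.read_text())["slope_bound"]
    seg = pd.read_csv(tiny_bundle.path / "exemplars" / "segments.csv")
    dfnc_meta = json.loads((tiny_bundle.path / "dfnc" / "meta.json").read_text())
    counts = seg.groupby("subject_id").size()
    for sid, W in dfnc_meta["n_windows"].items():
        assert counts[sid] == W - tau + 1
    assert (seg["slope"].abs() <= bound + 1e-12).all()
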