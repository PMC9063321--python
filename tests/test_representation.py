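"""Tests for RI weights, meta-states and occupancy rates."""

import numpy as np
import pytest

from evodfnc.core_dfnc import DfncSequence
from evodfnc.errors import InvalidInputError, InvalidParameterError, SubjectTooShortError
from evodfnc.lifting import EvoDfnc, EvoDfncSet
from evodfnc.representation import (
    MetaStateSet,
    RiSeries,
    cluster_weight_vectors,
    framewise_correlations,
    induce_meta,
    meta_occupancy,
    ri_series,
    ri_weights,
    stack_ri,
)


def make_motifs(arr):
    arr = np.asarray(arr, dtype=float)
    K, tau, D = arr.shape
    return EvoDfncSet([EvoDfnc(k, arr[k], k) for k in range(K)], tau=tau, n_neighbors=1)


def brute_pearson(a, b):
    return np.corrcoef(a, b)[0, 1]


class TestFramewiseCorrelations:
    def test_identical_window_gives_unit_column(self, rng):
        arr = rng.normal(size=(4, 5, 12))
        motifs = make_motifs(arr)
        corr = framewise_correlations(arr[2], motifs)
        assert np.allclose(corr[:, 2], 1.0)

    def test_negated_frame_gives_minus_one(self, rng):
        base = rng.normal(size=(1, 3, 8))
        motifs = make_motifs(base)
        window = -(base[0] - base[0].mean(axis=1, keepdims=True))
        corr = framewise_correlations(window, motifs)
        assert np.allclose(corr[:, 0], -1.0)

    def test_matches_entrywise_pearson(self, rng):
        motifs = make_motifs(rng.normal(size=(2, 4, 6)))
        window = rng.normal(size=(4, 6))
        corr = framewise_correlations(window, motifs)
        for t in range(4):
            for k in range(2):
                expected = brute_pearson(window[t], motifs.motifs[k].frames[t])
                assert np.isclose(corr[t, k], expected, atol=1e-12)

    def test_zero_variance_frame_scores_zero(self, rng):
        motifs = make_motifs(rng.normal(size=(1, 3, 6)))
        window = rng.normal(size=(3, 6))
        window[1] = 5.0  # flat frame
        corr = framewise_correlations(window, motifs)
        assert corr[1, 0] == 0.0

    def test_wrong_tau_rejected(self, rng):
        motifs = make_motifs(rng.normal(size=(1, 4, 6)))
        with pytest.raises(InvalidInputError):
            framewise_correlations(rng.normal(size=(3, 6)), motifs)


class TestRiWeights:
    def test_single_motif_takes_all_weight(self, rng):
        motifs = make_motifs(rng.normal(size=(1, 4, 6)))
        w = ri_weights(rng.normal(size=(4, 6)), motifs, "argmax")
        assert np.array_equal(w, [1.0])

    def test_hand_counted_proportions(self, rng):
        # construct a window whose frames 0,1,3 match motif 1 and frame 2 motif 0
        base = rng.normal(size=(2, 4, 8))
        motifs = make_motifs(base)
        window = base[1].copy()
        window[2] = base[0, 2]
        w = ri_weights(window, motifs, "argmax")
        assert np.allclose(w, [0.25, 0.75])

    def test_weights_on_simplex_lattice(self, rng):
        motifs = make_motifs(rng.normal(size=(3, 5, 10)))
        w = ri_weights(rng.normal(size=(5, 10)), motifs, "argmax")
        assert np.isclose(w.sum(), 1.0, atol=1e-12)
        assert np.allclose(w * 5, np.round(w * 5), atol=1e-12)

    def test_meancorr_mode_averages_columns(self, rng):
        motifs = make_motifs(rng.normal(size=(2, 4, 6)))
        window = rng.normal(size=(4, 6))
        w = ri_weights(window, motifs, "meancorr")
        corr = framewise_correlations(window, motifs)
        assert np.allclose(w, corr.mean(axis=0), atol=1e-12)
        assert np.all(w >= -1.0) and np.all(w <= 1.0)

    def test_unknown_mode_rejected(self, rng):
        motifs = make_motifs(rng.normal(size=(1, 3, 6)))
        with pytest.raises(InvalidParameterError):
            ri_weights(rng.normal(size=(3, 6)), motifs, "softmax")


class TestRiSeries:
    def test_single_window_when_w_equals_tau(self, rng):
        motifs = make_motifs(rng.normal(size=(2, 6, 8)))
        seq = DfncSequence("s", rng.normal(size=(6, 8)), 22)
        series = ri_series(seq, motifs)
        assert series.weights.shape == (1, 2)

    def test_rows_equal_windowed_ri_weights(self, rng):
        motifs = make_motifs(rng.normal(size=(3, 4, 7)))
        frames = rng.normal(size=(10, 7))
        seq = DfncSequence("s", frames, 22)
        for mode in ("argmax", "meancorr"):
            series = ri_series(seq, motifs, mode)
            assert series.weights.shape == (7, 3)
            for r in range(7):
                expected = ri_weights(frames[r : r + 4], motifs, mode)
                assert np.allclose(series.weights[r], expected, atol=1e-12)

    def test_planted_motif_dominates(self, rng):
        # sequence = motif 1's frames tiled; other motif is independent noise
        motif_frames = rng.normal(size=(2, 5, 30))
        motifs = make_motifs(motif_frames)
        frames = np.tile(motif_frames[1], (4, 1))
        seq = DfncSequence("s", frames, 22)
        series = ri_series(seq, motifs)
        # windows phase-aligned with the tiling reproduce the motif exactly
        aligned = np.arange(0, series.n_windows, 5)
        assert np.allclose(series.weights[aligned, 1], 1.0)
        # and the planted motif dominates on average over all phases
        assert series.weights[:, 1].mean() > series.weights[:, 0].mean()

    def test_too_short_sequence(self, rng):
        motifs = make_motifs(rng.normal(size=(1, 8, 6)))
        seq = DfncSequence("s", rng.normal(size=(5, 6)), 22)
        with pytest.raises(SubjectTooShortError):
            ri_series(seq, motifs)


class TestMetaStates:
    def test_single_cluster_centroid_is_mean(self, rng):
        rows = rng.dirichlet(np.ones(4), size=40)
        ids = np.repeat("a", 40)
        ms = cluster_weight_vectors(rows, ids, M=1, seed=0, n_init=5)
        assert np.allclose(ms.centroids[0], rows.mean(axis=0))

    def test_planted_one_hot_populations(self, rng):
        K = 4
        rows, labels = [], []
        for k in range(K):
            block = np.zeros((30, K))
            block[:, k] = 1.0
            rows.append(block + rng.normal(scale=0.01, size=block.shape))
            labels.extend([k] * 30)
        rows = np.vstack(rows)
        labels = np.array(labels)
        ms = cluster_weight_vectors(rows, np.repeat("a", len(rows)), M=K, seed=0, n_init=10)
        for g in range(K):
            assert len(set(ms.labels[labels == g])) == 1
        # each centroid is close to a one-hot vector
        assert np.allclose(np.sort(ms.centroids.max(axis=1)), 1.0, atol=0.05)

    def test_m_exceeding_rows_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            cluster_weight_vectors(rng.random((3, 2)), np.repeat("a", 3), M=5, seed=0)


class TestInduceMeta:
    def test_one_hot_centroid_reproduces_motif(self, rng):
        motifs = make_motifs(rng.normal(size=(3, 4, 6)))
        meta = induce_meta(motifs, [0.0, 0.0, 1.0])
        assert np.array_equal(meta.frames, motifs.motifs[2].frames)

    def test_uniform_centroid_gives_elementwise_mean(self, rng):
        arr = rng.normal(size=(4, 3, 5))
        motifs = make_motifs(arr)
        meta = induce_meta(motifs, np.full(4, 0.25))
        assert np.allclose(meta.frames, arr.mean(axis=0), atol=1e-12)

    def test_linearity(self, rng):
        motifs = make_motifs(rng.normal(size=(3, 4, 5)))
        c1, c2 = rng.random(3), rng.random(3)
        lhs = induce_meta(motifs, c1 + c2).frames
        rhs = induce_meta(motifs, c1).frames + induce_meta(motifs, c2).frames
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestMetaOccupancy:
    def _metaset(self, centroids):
        centroids = np.asarray(centroids, dtype=float)
        return MetaStateSet(
            centroids=centroids,
            labels=np.zeros(1, dtype=int),
            subject_ids=np.array(["x"], dtype=object),
            M=centroids.shape[0],
        )

    def test_all_rows_in_one_cluster(self):
        ms = self._metaset([[0, 0], [1, 1], [5, 5]])
        series = RiSeries("s", np.tile([1.1, 0.9], (6, 1)))
        assert np.array_equal(meta_occupancy(series, ms), [0, 1, 0])

    def test_hand_counted_fractions(self):
        ms = self._metaset([[0.0], [1.0], [2.0]])
        rows = np.array([[0.1], [0.0], [1.1], [0.9], [2.0], [1.9], [2.1], [1.8]])
        series = RiSeries("s", rows)
        assert np.allclose(meta_occupancy(series, ms), [0.25, 0.25, 0.5])

    def test_empty_series_rejected(self):
        ms = self._metaset([[0.0]])
        with pytest.raises(InvalidInputError):
            meta_occupancy(RiSeries("s", np.empty((0, 1))), ms)


def test_subject_mean_ri_stays_on_simplex(tiny_bundle):
    """Temporal mean of argmax-mode weight rows also sums to one."""
    for series in tiny_bundle.load_ri_series():
        total = series.subject_mean().sum()
        assert np.isclose(total, 1.0, atol=1e-12)
        # each row is a simplex lattice point with denominator tau
        tau = tiny_bundle.load_motifs().tau
        scaled = series.weights * tau
        assert np.allclose(scaled, np.round(scaled), atol=1e-9)


def test_stack_ri_alignment(rng):
    a = RiSeries("a", rng.random((3, 2)))
    b = RiSeries("b", rng.random((5, 2)))
    rows, ids = stack_ri([a, b])
    assert rows.shape == (8, 2)
    assert list(ids) == ["a"] * 3 + ["b"] * 5
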