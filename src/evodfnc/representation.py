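"""Expressing observed dFNC trajectories in the EVOdFNC basis.

Each length-tau window of a subject's observed dFNC sequence is scored
against the K lifted motifs frame-by-frame: frame t of the window is
Pearson-correlated (across the D connectivity features) with frame t of
each motif.  Two weight modes summarize the tau x K correlation matrix into
a K-vector:

* ``argmax`` (representational importance, the default): for each t, find
  the motif whose t-th frame correlates best; the weight on motif k is the
  proportion of the tau frames won by k.  Rows are simplex lattice points
  with denominator tau.
* ``meancorr``: the mean over t of the correlation with motif k (entries in
  [-1, 1], not normalized).

Sliding the window one step at a time yields a K-variate weight time series
per subject.  Stacked weight vectors are clustered into M meta-states;
each centroid induces a meta-EVOdFNC as a centroid-weighted sum of the
basis motifs, and a subject's occupancy rate of a meta-state is the
fraction of their weight vectors in its cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_dfnc import DfncSequence, run_kmeans
from .errors import InvalidInputError, InvalidParameterError, SubjectTooShortError
from .lifting import EvoDfncSet

__all__ = [
    "RiSeries",
    "MetaStateSet",
    "MetaEvoDfnc",
    "framewise_correlations",
    "ri_weights",
    "ri_series",
    "cluster_weight_vectors",
    "induce_meta",
    "meta_occupancy",
]

logger = logging.getLogger(__name__)

MODES = ("argmax", "meancorr")


@dataclass
class RiSeries:
    """One subject's K-variate weight time series over sliding tau-windows."""

    subject_id: str
    weights: np.ndarray  # (W - tau + 1, K)
    mode: str = "argmax"

    @property
    def n_windows(self) -> int:
        return self.weights.shape[0]

    @property
    def K(self) -> int:
        return self.weights.shape[1]

    def subject_mean(self) -> np.ndarray:
        """Temporal mean weight vector — the subject-level RI feature."""
        return self.weights.mean(axis=0)


@dataclass
class MetaStateSet:
    """M weight-vector cluster centroids defining the meta-EVOdFNCs."""

    centroids: np.ndarray  # (M, K)
    labels: np.ndarray     # label per stacked weight vector
    subject_ids: np.ndarray
    M: int
    inertia: float = float("nan")


@dataclass
class MetaEvoDfnc:
    """Centroid-weighted sum of the basis EVOdFNCs."""

    id: int
    frames: np.ndarray  # (tau, D)


def _normalize_rows(X: np.ndarray, what: str) -> np.ndarray:
    """Center rows and scale to unit norm; zero-variance rows -> zero (warn)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    flat = norms[:, 0] == 0
    if flat.any():
        logger.warning(
            "%d zero-variance %s frame(s); their correlations are set to 0",
            int(flat.sum()), what,
        )
        norms[flat] = 1.0
    return Xc / norms


def framewise_correlations(window_frames: np.ndarray, motifs: EvoDfncSet) -> np.ndarray:
    """tau x K matrix: corr of observed frame t with motif k's frame t.

    Correlations are Pearson across the D connectivity features; a
    zero-variance frame (observed or motif) contributes 0.
    """
    window_frames = np.asarray(window_frames, dtype=float)
    tau = motifs.tau
    if window_frames.shape[0] != tau:
        raise InvalidInputError(
            f"window has {window_frames.shape[0]} frames, motifs have tau={tau}"
        )
    if window_frames.shape[1] != motifs.motifs[0].n_features:
        raise InvalidInputError("feature dimension mismatch between window and motifs")
    obs = _normalize_rows(window_frames, "observed")                   # (tau, D)
    mot = motifs.as_array()                                            # (K, tau, D)
    motn = _normalize_rows(mot.reshape(-1, mot.shape[-1]), "motif").reshape(mot.shape)
    # corr[t, k] = obs[t] . motn[k, t]
    return np.einsum("td,ktd->tk", obs, motn)


def ri_weights(window_frames: np.ndarray, motifs: EvoDfncSet, mode: str = "argmax") -> np.ndarray:
    """Collapse a window's tau x K correlation matrix into a K weight vector."""
    if mode not in MODES:
        raise InvalidParameterError(f"mode must be one of {MODES}, got {mode!r}")
    corr = framewise_correlations(window_frames, motifs)
    if mode == "meancorr":
        return corr.mean(axis=0)
    winners = np.argmax(corr, axis=1)  # np.argmax takes the first (smallest k) on ties
    counts = np.bincount(winners, minlength=motifs.K).astype(float)
    return counts / corr.shape[0]


def ri_series(sequence: DfncSequence, motifs: EvoDfncSet, mode: str = "argmax") -> RiSeries:
    """Weight vectors for every sliding tau-window of one subject's sequence.

    A subject with W dFNC frames yields W - tau + 1 weight vectors (step 1).
    Equivalent to calling :func:`ri_weights` on every window slice, but the
    frame-vs-motif-frame correlations are precomputed in one pass.
    """
    if mode not in MODES:
        raise InvalidParameterError(f"mode must be one of {MODES}, got {mode!r}")
    tau, K = motifs.tau, motifs.K
    W = sequence.n_windows
    if W < tau:
        raise SubjectTooShortError(
            f"subject {sequence.subject_id!r} has W={W} frames < tau={tau}"
        )
    obs = _normalize_rows(np.asarray(sequence.frames, dtype=float), "observed")  # (W, D)
    mot = motifs.as_array()                                                      # (K, tau, D)
    motn = _normalize_rows(mot.reshape(-1, mot.shape[-1]), "motif").reshape(mot.shape)
    # all_corr[j, k, t] = corr(observed frame j, motif k frame t); the window
    # starting at r only consumes the diagonal slice t = j - r.
    all_corr = np.einsum("jd,ktd->jkt", obs, motn)
    n_out = W - tau + 1
    weights = np.empty((n_out, K))
    t_idx = np.arange(tau)
    for r in range(n_out):
        corr = all_corr[r + t_idx, :, t_idx]  # (tau, K)
        if mode == "meancorr":
            weights[r] = corr.mean(axis=0)
        else:
            winners = np.argmax(corr, axis=1)
            weights[r] = np.bincount(winners, minlength=K) / tau
    return RiSeries(sequence.subject_id, weights, mode)


def stack_ri(series_list: list[RiSeries]) -> tuple[np.ndarray, np.ndarray]:
    """Stack weight rows over subjects; returns (rows, subject_ids)."""
    rows = np.vstack([s.weights for s in series_list])
    subject_ids = np.concatenate(
        [np.repeat(s.subject_id, s.n_windows) for s in series_list]
    )
    return rows, subject_ids


def cluster_weight_vectors(
    rows: np.ndarray,
    subject_ids: np.ndarray,
    M: int = 10,
    seed: int = 0,
    n_init: int = 500,
    max_iter: int = 2000,
) -> MetaStateSet:
    """k-means on stacked weight vectors (squared Euclidean, best of n_init)."""
    rows = np.asarray(rows, dtype=float)
    if M > rows.shape[0]:
        raise InvalidParameterError(f"M={M} exceeds number of weight vectors {rows.shape[0]}")
    km = run_kmeans(rows, M, seed, n_init, max_iter)
    return MetaStateSet(
        centroids=km.cluster_centers_,
        labels=km.labels_.astype(int),
        subject_ids=np.asarray(subject_ids),
        M=M,
        inertia=float(km.inertia_),
    )


def induce_meta(motifs: EvoDfncSet, centroid: np.ndarray, meta_id: int = 0) -> MetaEvoDfnc:
    """Meta-EVOdFNC: centroid-weighted sum of the basis motifs (no renormalization)."""
    centroid = np.asarray(centroid, dtype=float)
    if centroid.shape != (motifs.K,):
        raise InvalidInputError(f"centroid must have length K={motifs.K}")
    frames = np.tensordot(centroid, motifs.as_array(), axes=(0, 0))
    return MetaEvoDfnc(id=meta_id, frames=frames)


def meta_occupancy(series: RiSeries, metaset: MetaStateSet) -> np.ndarray:
    """Fraction of a subject's weight vectors in each meta-state cluster.

    Rows are assigned to the nearest centroid, which reproduces the stored
    k-means labels for in-sample subjects and projects new subjects onto the
    existing meta-states.  Returns a length-M vector summing to 1.
    """
    if series.n_windows == 0:
        raise InvalidInputError("empty weight series")
    d2 = (
        np.sum(series.weights**2, axis=1, keepdims=True)
        - 2 * series.weights @ metaset.centroids.T
        + np.sum(metaset.centroids**2, axis=1)[None, :]
    )
    labels = np.argmin(d2, axis=1)
    counts = np.bincount(labels, minlength=metaset.M).astype(float)
    return counts / counts.sum()
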