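"""Tapered sliding-window dynamic functional network connectivity (dFNC).

Each subject contributes a matrix of network timecourses (T timepoints by N
networks).  Pairwise Pearson correlations are computed inside a tapered
rectangular window advanced ``step`` TRs at a time, and the upper triangle of
each windowed correlation matrix is vectorized into a D = N(N-1)/2 feature
vector.  The resulting W x D matrix is one subject's dFNC trajectory.

The module also provides the conventional time-blind baseline: k-means
clustering of all windowed connectivity frames into a small number of
"snapshot" states (SNAPdFNC) with per-subject occupancy rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import (
    DegenerateWindowError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "TimecourseMatrix",
    "DfncSequence",
    "SnapStateSet",
    "build_taper",
    "compute_windowed_dfnc",
    "vectorize_upper",
    "devectorize_upper",
    "stack_sequences",
    "cluster_snapshots",
    "snapshot_occupancy",
]


@dataclass
class TimecourseMatrix:
    """One subject's network timecourses: T timepoints by N networks."""

    subject_id: str
    values: np.ndarray
    tr_seconds: float = 2.0
    network_names: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("timecourse matrix must be 2-D (T x N)")
        if self.values.shape[1] < 2:
            raise InvalidInputError("need at least 2 networks")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError(f"non-finite values in timecourses of {self.subject_id!r}")
        if self.tr_seconds <= 0:
            raise InvalidParameterError("tr_seconds must be positive")
        if self.network_names is None:
            self.network_names = [f"net{i + 1}" for i in range(self.values.shape[1])]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_networks(self) -> int:
        return self.values.shape[1]


@dataclass
class DfncSequence:
    """One subject's windowed connectivity trajectory (W windows x D features)."""

    subject_id: str
    frames: np.ndarray
    window_len: int
    step: int = 1

    @property
    def n_windows(self) -> int:
        return self.frames.shape[0]

    @property
    def n_features(self) -> int:
        return self.frames.shape[1]


@dataclass
class SnapStateSet:
    """Time-blind k-means states over all stacked dFNC frames.

    ``labels`` is aligned row-for-row with the stacked frame matrix the
    clustering was fit on; ``subject_ids`` records which subject owns each row.
    Labels are 0-based.
    """

    centroids: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    k: int
    inertia: float = field(default=float("nan"))


def build_taper(window_len: int, sigma: float) -> np.ndarray:
    """Tapered rectangular window: rectangle convolved with a Gaussian.

    A length-``window_len`` rectangle is convolved with a Gaussian kernel of
    standard deviation ``sigma`` (in TRs), truncated back to ``window_len``
    samples centred on the rectangle, and renormalized to sum to one.
    ``sigma = inf`` degenerates to the plain rectangle.

    Parameters
    ----------
    window_len : int
        Window length in TRs, at least 3.
    sigma : float
        Gaussian taper width in TRs; ``np.inf`` for an untapered rectangle.
    """
    if window_len < 3:
        raise InvalidParameterError(f"window_len must be >= 3, got {window_len}")
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    if math.isinf(sigma):
        return np.full(window_len, 1.0 / window_len)
    half = int(np.ceil(4 * sigma))
    t = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    kernel /= kernel.sum()
    full = np.convolve(np.ones(window_len), kernel, mode="full")
    # central window_len samples; the full output has length window_len + 2*half
    w = full[half : half + window_len]
    return w / w.sum()


def vectorize_upper(corr: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Row-major upper-triangle (i < j) vectorization of a symmetric matrix.

    This fixes the feature ordering shared by every downstream module; it is
    the exact inverse of :func:`devectorize_upper`.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise InvalidInputError("expected a square matrix")
    if not np.allclose(corr, corr.T, atol=atol, rtol=0.0):
        raise InvalidInputError("matrix is not symmetric within tolerance")
    iu, ju = np.triu_indices(corr.shape[0], k=1)
    return corr[iu, ju].copy()


def devectorize_upper(vec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; diagonal restored to 1."""
    vec = np.asarray(vec, dtype=float)
    d = vec.shape[0]
    n = int(round((1 + math.sqrt(1 + 8 * d)) / 2))
    if n * (n - 1) // 2 != d:
        raise InvalidInputError(f"vector length {d} is not a triangular number")
    out = np.eye(n)
    iu, ju = np.triu_indices(n, k=1)
    out[iu, ju] = vec
    out[ju, iu] = vec
    return out


def n_pair_features(n_networks: int) -> int:
    """D = N(N-1)/2, the length of a vectorized connectivity frame."""
    return n_networks * (n_networks - 1) // 2


def _weighted_corr(window: np.ndarray, weights: np.ndarray,
                   subject_id: str, window_idx: int,
                   network_names: list[str]) -> np.ndarray:
    mean = weights @ window
    centered = window - mean
    cov = centered.T @ (centered * weights[:, None])
    var = np.diag(cov).copy()
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise DegenerateWindowError(subject_id, window_idx, network_names[bad[0]])
    sd = np.sqrt(var)
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def compute_windowed_dfnc(
    tc: TimecourseMatrix,
    window_len: int = 22,
    sigma: float = 3.0,
    step: int = 1,
    fisher_z: bool = False,
) -> DfncSequence:
    """Compute the tapered sliding-window dFNC sequence for one subject.

    Window w covers TRs ``[w*step, w*step + window_len)`` (0-based); the taper
    weights enter the Pearson correlation as observation weights.  With step 1
    this yields W = T - window_len + 1 frames.

    Parameters
    ----------
    tc : TimecourseMatrix
    window_len : int
        Window length in TRs (default 22 TRs, i.e. 44 s at TR = 2 s).
    sigma : float
        Gaussian taper width in TRs; ``np.inf`` for a pure rectangle.
    step : int
        Advance between successive windows, in TRs.
    fisher_z : bool
        If True, apply the Fisher z-transform arctanh to the correlations
        (off by default).
    """
    if step < 1:
        raise InvalidParameterError(f"step must be >= 1, got {step}")
    T, N = tc.values.shape
    if T < window_len:
        raise InvalidParameterError(
            f"subject {tc.subject_id!r} has T={T} < window_len={window_len}"
        )
    if np.any(np.var(tc.values, axis=0) == 0):
        dead = int(np.flatnonzero(np.var(tc.values, axis=0) == 0)[0])
        raise InvalidInputError(
            f"network {tc.network_names[dead]!r} of subject {tc.subject_id!r} "
            "has zero variance over the scan"
        )
    weights = build_taper(window_len, sigma)
    n_windows = (T - window_len) // step + 1
    D = n_pair_features(N)
    frames = np.empty((n_windows, D))
    for w in range(n_windows):
        start = w * step
        corr = _weighted_corr(
            tc.values[start : start + window_len], weights,
            tc.subject_id, w, tc.network_names,
        )
        frames[w] = vectorize_upper(corr)
    if fisher_z:
        frames = np.arctanh(np.clip(frames, -1 + 1e-15, 1 - 1e-15))
    return DfncSequence(tc.subject_id, frames, window_len, step)


def stack_sequences(sequences: list[DfncSequence]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-subject dFNC frames into one matrix.

    Returns ``(frames, subject_ids, window_idx)`` where the two index arrays
    are aligned row-for-row with ``frames``.
    """
    if not sequences:
        raise InvalidInputError("no sequences to stack")
    dims = {s.n_features for s in sequences}
    if len(dims) != 1:
        raise InvalidInputError(f"inconsistent feature dimensions across subjects: {sorted(dims)}")
    frames = np.vstack([s.frames for s in sequences])
    subject_ids = np.concatenate([np.repeat(s.subject_id, s.n_windows) for s in sequences])
    window_idx = np.concatenate([np.arange(s.n_windows) for s in sequences])
    return frames, subject_ids, window_idx


def run_kmeans(
    X: np.ndarray,
    k: int,
    seed: int,
    n_init: int,
    max_iter: int = 2000,
) -> KMeans:
    """k-means with k-means++ restarts, best inertia kept, deterministic per seed.

    Shared by snapshot-state, exemplar and weight-vector clustering so all
    three stages use the same restart scheme.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if k > X.shape[0]:
        raise InvalidParameterError(f"k={k} exceeds number of samples {X.shape[0]}")
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        max_iter=max_iter,
        random_state=seed,
        algorithm="lloyd",
    )
    km.fit(X)
    return km


def cluster_snapshots(
    frames: np.ndarray,
    subject_ids: np.ndarray,
    k: int = 5,
    seed: int = 0,
    n_init: int = 250,
    max_iter: int = 2000,
) -> SnapStateSet:
    """Cluster all subjects' stacked dFNC frames into k time-blind states.

    Follows the conventional protocol: squared Euclidean k-means, up to
    ``max_iter`` iterations per restart and ``n_init`` restarts, keeping the
    best-inertia solution.  Five states is the customary default.
    """
    frames = np.asarray(frames, dtype=float)
    subject_ids = np.asarray(subject_ids)
    if frames.shape[0] != subject_ids.shape[0]:
        raise InvalidInputError("frames and subject_ids must have equal length")
    km = run_kmeans(frames, k, seed, n_init, max_iter)
    return SnapStateSet(
        centroids=km.cluster_centers_,
        labels=km.labels_.astype(int),
        subject_ids=subject_ids,
        k=k,
        inertia=float(km.inertia_),
    )


def snapshot_occupancy(states: SnapStateSet, subject_id: str) -> np.ndarray:
    """Fraction of a subject's frames assigned to each snapshot state.

    Returns a length-k vector summing to 1.
    """
    from .errors import NotFoundError

    mask = states.subject_ids == subject_id
    if not mask.any():
        raise NotFoundError(f"unknown subject {subject_id!r}")
    counts = np.bincount(states.labels[mask], minlength=states.k).astype(float)
    return counts / counts.sum()
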