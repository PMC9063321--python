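"""Linear trajectory exemplars from the averaged planar embedding.

Each subject's embedded trajectory is cut into every continuous sub-segment
of tau consecutive points (tau defaults to twice the dFNC window length).
Each sub-segment is summarized by a local linearization: its centroid
midpoint, the OLS slope of y on x (clipped to a data-driven bound so
near-vertical slopes cannot dominate), and its length (maximum pairwise
distance among its points).  The (midpoint, slope) triples are clustered
with k-means; each cluster centroid induces a 2D line segment — a *linear
trajectory exemplar* — whose length is the mean member length and whose
temporal orientation is taken from the mean displacement of its members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_dfnc import run_kmeans
from .embed2d import AveragedEmbedding
from .errors import (
    DegenerateExemplarError,
    DegenerateSegmentError,
    InvalidInputError,
    InvalidParameterError,
    SubjectTooShortError,
)

__all__ = [
    "ContinuousSegment",
    "LinearSegment",
    "Exemplar",
    "ExemplarSet",
    "extract_segments",
    "extract_all_segments",
    "linearize_segment",
    "compute_slope_bound",
    "cluster_linear_segments",
    "orient_exemplar",
    "sample_exemplar_points",
    "exemplar_membership_occupancy",
]


@dataclass
class ContinuousSegment:
    """tau temporally consecutive embedded points of one subject."""

    subject_id: str
    start: int
    points: np.ndarray  # (tau, 2)


@dataclass
class LinearSegment:
    """Local linearization of a continuous segment: midpoint, slope, length."""

    midpoint: np.ndarray  # (2,)
    slope: float
    length: float
    source: ContinuousSegment

    @property
    def subject_id(self) -> str:
        return self.source.subject_id

    @property
    def start(self) -> int:
        return self.source.start


@dataclass
class Exemplar:
    """A 2D oriented line segment induced from one k-means centroid."""

    id: int
    midpoint: np.ndarray  # (2,)
    slope: float
    length: float          # mean length of member segments
    direction: int = 1     # +1 / -1: which end is t = 1


@dataclass
class ExemplarSet:
    """The K exemplars plus the membership of every linear segment."""

    exemplars: list[Exemplar]
    slope_bound: float
    labels: np.ndarray                       # cluster label per LinearSegment
    segments: list[LinearSegment] = field(repr=False, default_factory=list)
    inertia: float = float("nan")

    @property
    def K(self) -> int:
        return len(self.exemplars)


def extract_segments(
    embedding: AveragedEmbedding, subject_id: str, tau: int = 44
) -> list[ContinuousSegment]:
    """All continuous sub-segments of tau consecutive embedded points.

    A subject with W embedded frames yields exactly W - tau + 1 segments,
    one per start index.
    """
    if tau < 2:
        raise InvalidParameterError("tau must be >= 2")
    pts = embedding.subject_coords(subject_id)
    W = pts.shape[0]
    if W < tau:
        raise SubjectTooShortError(
            f"subject {subject_id!r} has W={W} embedded frames < tau={tau}"
        )
    return [
        ContinuousSegment(subject_id, j, pts[j : j + tau].copy())
        for j in range(W - tau + 1)
    ]


def extract_all_segments(embedding: AveragedEmbedding, tau: int = 44) -> list[ContinuousSegment]:
    """Concatenate segments over every subject, in subject order."""
    out = []
    for sid in embedding.subjects:
        out.extend(extract_segments(embedding, sid, tau))
    return out


def linearize_segment(segment: ContinuousSegment, slope_bound: float) -> LinearSegment:
    """Summarize a segment by centroid midpoint, clipped OLS slope and length.

    The slope is the ordinary least-squares slope of y on x over the
    segment's points; a vertical segment (zero x-variance) takes the positive
    bound by the clipping convention.  The length is the maximum pairwise
    distance among the points.
    """
    pts = segment.points
    if pts.shape[0] < 2:
        raise DegenerateSegmentError("segment needs at least 2 points")
    diffs = pts[:, None, :] - pts[None, :, :]
    dist = np.linalg.norm(diffs, axis=-1)
    length = float(dist.max())
    if length == 0.0:
        raise DegenerateSegmentError(
            f"all points identical in segment of subject {segment.subject_id!r} "
            f"starting at {segment.start}"
        )
    x, y = pts[:, 0], pts[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        slope = float(slope_bound)
    else:
        slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
        slope = float(np.clip(slope, -slope_bound, slope_bound))
    return LinearSegment(
        midpoint=pts.mean(axis=0),
        slope=slope,
        length=length,
        source=segment,
    )


def compute_slope_bound(embedding: AveragedEmbedding) -> float:
    """Slope clipping bound: max over all embedded coordinates of |x| and |y|."""
    if embedding.coords.size == 0:
        raise InvalidInputError("empty embedding")
    return float(np.abs(embedding.coords).max())


def orient_exemplar(slope: float, members: list[ContinuousSegment]) -> int:
    """Temporal orientation of an exemplar from its members' mean displacement.

    Sign of the dot product between the exemplar's unit direction vector
    (1, m)/||.|| and the mean (last point - first point) displacement of the
    member segments; a zero dot product defaults to +1.
    """
    if not members:
        raise InvalidInputError("need at least one member segment")
    direction = np.array([1.0, slope])
    direction /= np.linalg.norm(direction)
    disp = np.mean([seg.points[-1] - seg.points[0] for seg in members], axis=0)
    dot = float(direction @ disp)
    return -1 if dot < 0 else 1


def cluster_linear_segments(
    segments: list[LinearSegment],
    K: int = 10,
    seed: int = 0,
    n_init: int = 250,
    max_iter: int = 2000,
) -> ExemplarSet:
    """k-means on (x, y, slope) triples; induce one exemplar per centroid.

    Slopes must already be clipped (the bound is part of the clustering
    inputs).  Each exemplar's length is the mean length of its member
    segments and its orientation comes from :func:`orient_exemplar`.
    """
    if K > len(segments):
        raise InvalidParameterError(f"K={K} exceeds number of segments {len(segments)}")
    triples = np.array([[s.midpoint[0], s.midpoint[1], s.slope] for s in segments])
    km = run_kmeans(triples, K, seed, n_init, max_iter)
    labels = km.labels_.astype(int)
    slope_bound = float(np.abs(triples[:, 2]).max())
    exemplars = []
    for k in range(K):
        members = [segments[i] for i in np.flatnonzero(labels == k)]
        cx, cy, cm = km.cluster_centers_[k]
        d_k = float(np.mean([s.length for s in members])) if members else 0.0
        sign = orient_exemplar(cm, [s.source for s in members]) if members else 1
        exemplars.append(Exemplar(k, np.array([cx, cy]), float(cm), d_k, sign))
    return ExemplarSet(
        exemplars=exemplars,
        slope_bound=slope_bound,
        labels=labels,
        segments=list(segments),
        inertia=float(km.inertia_),
    )


def sample_exemplar_points(exemplar: Exemplar, tau: int = 44) -> np.ndarray:
    """tau evenly spaced points along the oriented exemplar segment.

    Point 1 sits at the tail end given by the direction sign; consecutive
    spacing is length/(tau-1); the mean of the points is the midpoint.
    """
    if tau < 2:
        raise InvalidParameterError("tau must be >= 2")
    if exemplar.length <= 0:
        raise DegenerateExemplarError(f"exemplar {exemplar.id} has zero length")
    u = np.array([1.0, exemplar.slope])
    u = exemplar.direction * u / np.linalg.norm(u)
    offsets = np.linspace(-0.5, 0.5, tau) * exemplar.length
    return exemplar.midpoint[None, :] + offsets[:, None] * u[None, :]


def exemplar_membership_occupancy(exemplar_set: ExemplarSet, subject_id: str) -> np.ndarray:
    """Fraction of a subject's linear segments in each exemplar cluster.

    Returns a length-K vector summing to 1.
    """
    from .errors import NotFoundError

    idx = [i for i, s in enumerate(exemplar_set.segments) if s.subject_id == subject_id]
    if not idx:
        raise NotFoundError(f"no linear segments for subject {subject_id!r}")
    counts = np.bincount(exemplar_set.labels[idx], minlength=exemplar_set.K).astype(float)
    return counts / counts.sum()
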