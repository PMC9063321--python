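"""Stabilized planar embedding of stacked dFNC frames.

All subjects' windowed connectivity frames are embedded jointly into the
plane with UMAP, using parameters chosen to preserve within-subject
trajectory continuity (n_neighbors = 25, min_dist = 0.75).  Because any
single stochastic embedding run is somewhat arbitrary, the embedding is
repeated R times with distinct seeds and the R coordinate matrices are
averaged pointwise; averaging stabilizes the final layout while continuity
is preserved under summation.

An optional similarity-Procrustes alignment of runs 2..R onto run 1 before
averaging guards against the rotation/reflection indeterminacy of
independent runs; plain (unaligned) averaging is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, NotFoundError

__all__ = [
    "EmbedConfig",
    "EmbeddingRun",
    "AveragedEmbedding",
    "embed_once",
    "average_runs",
    "embed_frames",
    "continuity_ratio",
]


@dataclass
class EmbedConfig:
    """UMAP and averaging parameters for the planar embedding stage."""

    n_neighbors: int = 25
    min_dist: float = 0.75
    n_runs: int = 25
    base_seed: int = 0
    align_runs: bool = False

    def __post_init__(self):
        if self.n_neighbors < 2:
            raise InvalidParameterError("n_neighbors must be >= 2")
        if not (0 < self.min_dist < 1):
            raise InvalidParameterError("min_dist must lie in (0, 1)")
        if self.n_runs < 1:
            raise InvalidParameterError("n_runs must be >= 1")


@dataclass
class EmbeddingRun:
    """2D coordinates from one embedding run, row-aligned with the input frames."""

    run_index: int
    coords: np.ndarray


@dataclass
class AveragedEmbedding:
    """Pointwise average of R embedding runs.

    ``subject_ids`` and ``window_idx`` index each coordinate row back to the
    stacked frame it embeds, so row i of ``coords`` always refers to stacked
    frame i.
    """

    coords: np.ndarray
    subject_ids: np.ndarray
    window_idx: np.ndarray
    config: EmbedConfig = field(default_factory=EmbedConfig)

    def subject_coords(self, subject_id: str) -> np.ndarray:
        mask = self.subject_ids == subject_id
        if not mask.any():
            raise NotFoundError(f"unknown subject {subject_id!r}")
        order = np.argsort(self.window_idx[mask], kind="stable")
        return self.coords[mask][order]

    @property
    def subjects(self) -> list[str]:
        seen = dict.fromkeys(self.subject_ids.tolist())
        return list(seen)


def embed_once(frames: np.ndarray, config: EmbedConfig, run_index: int = 0) -> EmbeddingRun:
    """One deterministic UMAP run on the stacked frames.

    The run seed is ``base_seed + run_index`` so the R runs are independent
    yet reproducible.  Spectral initialization; row order is preserved.
    """
    import umap

    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < config.n_neighbors + 1:
        raise InvalidParameterError(
            f"need at least n_neighbors+1={config.n_neighbors + 1} frames, got {frames.shape[0]}"
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="n_jobs value.*overridden")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
            init="spectral",
            random_state=config.base_seed + run_index,
        )
        coords = reducer.fit_transform(frames)
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise InvalidInputError("embedding produced non-finite coordinates")
    return EmbeddingRun(run_index, coords)


def _similarity_align(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Best-fit similarity transform (rotation/reflection + scale + translation)
    of ``coords`` onto ``reference`` (full Procrustes)."""
    from scipy.linalg import orthogonal_procrustes

    mu_a, mu_b = coords.mean(axis=0), reference.mean(axis=0)
    A = coords - mu_a
    B = reference - mu_b
    R, _ = orthogonal_procrustes(A, B)
    scale = float(np.sum((A @ R) * B) / np.sum(A * A))
    return (A @ R) * scale + mu_b


def average_runs(runs: list[EmbeddingRun], align_runs: bool = False) -> np.ndarray:
    """Pointwise mean of the run coordinate matrices.

    With ``align_runs`` off this is the literal averaging formula
    coords[i] = (1/R) * sum_r coords_r[i]; with it on, runs 2..R are first
    mapped onto run 1 by the best-fit similarity transform.
    Returns the averaged (total frames x 2) coordinate matrix.
    """
    if not runs:
        raise InvalidInputError("no embedding runs to average")
    shapes = {r.coords.shape for r in runs}
    if len(shapes) != 1:
        raise InvalidInputError(f"mismatched run shapes: {sorted(shapes)}")
    stack = [runs[0].coords]
    for r in runs[1:]:
        stack.append(_similarity_align(r.coords, runs[0].coords) if align_runs else r.coords)
    return np.mean(stack, axis=0)


def embed_frames(
    frames: np.ndarray,
    subject_ids: np.ndarray,
    window_idx: np.ndarray,
    config: EmbedConfig | None = None,
) -> AveragedEmbedding:
    """Run the full embedding stage: R UMAP runs, then pointwise averaging."""
    config = config or EmbedConfig()
    runs = [embed_once(frames, config, r) for r in range(config.n_runs)]
    coords = average_runs(runs, config.align_runs)
    return AveragedEmbedding(
        coords=coords,
        subject_ids=np.asarray(subject_ids),
        window_idx=np.asarray(window_idx),
        config=config,
    )


def continuity_ratio(
    embedding: AveragedEmbedding,
    subject_id: str,
    n_pairs: int = 1000,
    seed: int = 0,
) -> float:
    """Within-subject smoothness of the embedded trajectory.

    Median 2D distance between the subject's temporally consecutive frames,
    divided by the median distance among ``n_pairs`` seeded random frame
    pairs drawn across the whole embedding.  Smaller is smoother; a value
    well below 1 indicates the embedding preserves trajectory continuity.
    """
    pts = embedding.subject_coords(subject_id)
    if pts.shape[0] < 3:
        raise InvalidInputError(f"subject {subject_id!r} has fewer than 3 embedded frames")
    consec = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    rng = np.random.default_rng(seed)
    n = embedding.coords.shape[0]
    i = rng.integers(0, n, n_pairs)
    j = rng.integers(0, n, n_pairs)
    background = np.linalg.norm(embedding.coords[i] - embedding.coords[j], axis=1)
    denom = float(np.median(background))
    if denom == 0.0:
        return 0.0 if float(np.median(consec)) == 0.0 else float("inf")
    return float(np.median(consec)) / denom
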