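"""Data-driven inversion ("lifting") of 2D exemplars into connectivity space.

UMAP has no tractable inverse, so the high-dimensional preimage of a 2D
point is approximated empirically: the unweighted mean of the dFNC frames
whose embedded coordinates are the n spatially nearest neighbors of the
point.  Sampling tau evenly spaced points along an oriented exemplar and
lifting each one produces a tau-frame, D-feature evolving connectivity
motif (EVOdFNC).  Only spatial proximity in the plane is used — the
embedding itself works in spatial terms, so its inverse does too.

Nearest-neighbor search is exact (full distance scan) with ties at the n-th
neighbor broken toward the lower frame index, so results are deterministic
and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embed2d import AveragedEmbedding
from .errors import InvalidInputError, InvalidParameterError
from .exemplars import Exemplar, ExemplarSet, sample_exemplar_points

__all__ = ["EvoDfnc", "EvoDfncSet", "lift_point", "lift_exemplar", "lift_all"]


@dataclass
class EvoDfnc:
    """One lifted motif: tau frames by D connectivity features."""

    id: int
    frames: np.ndarray  # (tau, D)
    exemplar_id: int

    @property
    def tau(self) -> int:
        return self.frames.shape[0]

    @property
    def n_features(self) -> int:
        return self.frames.shape[1]


@dataclass
class EvoDfncSet:
    """The K lifted motifs sharing tau and D."""

    motifs: list[EvoDfnc]
    tau: int
    n_neighbors: int

    @property
    def K(self) -> int:
        return len(self.motifs)

    def as_array(self) -> np.ndarray:
        """(K, tau, D) array of all motif frames."""
        return np.stack([m.frames for m in self.motifs])


def lift_point(
    point: np.ndarray,
    embedding: AveragedEmbedding,
    frames: np.ndarray,
    n: int = 25,
) -> np.ndarray:
    """Lift a single 2D point: mean dFNC frame of its n nearest embedded neighbors."""
    coords = embedding.coords
    if coords.shape[0] == 0:
        raise InvalidInputError("empty embedding")
    if coords.shape[0] != frames.shape[0]:
        raise InvalidInputError("embedding and frame stack are not row-aligned")
    if n < 1 or n > coords.shape[0]:
        raise InvalidParameterError(f"n must be in [1, {coords.shape[0]}], got {n}")
    d = np.linalg.norm(coords - np.asarray(point, dtype=float)[None, :], axis=1)
    order = np.argsort(d, kind="stable")  # stable sort: ties -> lower frame index
    return frames[order[:n]].mean(axis=0)


def lift_exemplar(
    exemplar: Exemplar,
    embedding: AveragedEmbedding,
    frames: np.ndarray,
    tau: int = 44,
    n: int = 25,
) -> EvoDfnc:
    """Lift an exemplar into a tau-frame EVOdFNC.

    Frame i is the lift of the i-th of tau evenly spaced points along the
    oriented exemplar.  The default n = 25 matches the embedding's
    n_neighbors parameter.
    """
    pts = sample_exemplar_points(exemplar, tau)
    lifted = np.array([lift_point(p, embedding, frames, n) for p in pts])
    return EvoDfnc(id=exemplar.id, frames=lifted, exemplar_id=exemplar.id)


def lift_all(
    exemplar_set: ExemplarSet,
    embedding: AveragedEmbedding,
    frames: np.ndarray,
    tau: int = 44,
    n: int = 25,
) -> EvoDfncSet:
    """Lift every exemplar, in id order."""
    motifs = [
        lift_exemplar(ex, embedding, frames, tau, n)
        for ex in sorted(exemplar_set.exemplars, key=lambda e: e.id)
    ]
    return EvoDfncSet(motifs=motifs, tau=tau, n_neighbors=n)
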