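"""Small constructors shared across test modules."""

import numpy as np

from evodfnc.embed2d import AveragedEmbedding


def make_embedding(coords, subject_ids=None) -> AveragedEmbedding:
    """Wrap raw 2D coordinates as an AveragedEmbedding for unit tests."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if subject_ids is None:
        subject_ids = np.repeat("a", n)
    subject_ids = np.asarray(subject_ids, dtype=object)
    window_idx = np.concatenate(
        [np.arange(np.sum(subject_ids == s)) for s in dict.fromkeys(subject_ids)]
    )
    return AveragedEmbedding(coords, subject_ids, window_idx)


def best_motif_match(motif_array: np.ndarray, planted: np.ndarray) -> tuple[int, float]:
    """Best lifted motif for a planted window-resolution sequence.

    Scores mean frame-wise Pearson correlation over both temporal
    orientations (a lifted motif's time direction is conventional) and
    returns (motif index, best mean correlation).
    """
    best, best_k = -2.0, -1
    T = planted.shape[0]
    for k in range(motif_array.shape[0]):
        for arr in (motif_array[k], motif_array[k][::-1]):
            vals = [np.corrcoef(arr[t], planted[t])[0, 1] for t in range(T)]
            m = float(np.mean(vals))
            if m > best:
                best, best_k = m, k
    return best_k, best
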