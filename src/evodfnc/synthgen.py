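"""Synthetic cohorts with planted, smoothly evolving connectivity motifs.

The generator emulates the statistical structure the pipeline is designed to
recover, without any real data:

* a small library of block-modular anchor correlation patterns;
* *evolving motifs*: smooth convex interpolations between two anchors, played
  out over a fixed number of TRs;
* per-subject schedules that tile the scan with motif instances, with the
  probability of drawing the "signal" motif differing between groups by a
  configurable usage ratio;
* Gaussian timecourses sampled TR-by-TR from the scheduled covariance via its
  Cholesky factor, plus white observation noise;
* a cohort manifest with diagnosis, age, gender, mean frame displacement and
  (for patients) six positive-symptom scores.

A ground-truth record stores each subject's schedule and every motif's
correlation sequence at dFNC *window* resolution (the planted TR-level
sequence averaged under the analysis taper), so recovery is compared
like-with-like: windowing is a smoothing the pipeline cannot undo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_dfnc import build_taper, vectorize_upper
from .errors import GenerationError, InvalidParameterError, ValidationError

__all__ = [
    "AnchorPattern",
    "SynthCohortConfig",
    "make_anchor_patterns",
    "make_motif",
    "make_schedule",
    "simulate_subject",
    "simulate_cohort",
    "motif_window_frames",
]

SYMPTOM_COLUMNS = [
    "panss_delusions",
    "panss_grandiosity",
    "panss_hallucinations",
    "panss_suspiciousness",
    "panss_preoccupation",
    "panss_unusual_thought",
]


@dataclass
class AnchorPattern:
    """A block-modular SPD correlation pattern with unit diagonal."""

    id: int
    matrix: np.ndarray
    modules: np.ndarray  # module assignment per network

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        eigmin = float(np.linalg.eigvalsh(self.matrix)[0])
        if eigmin <= 1e-6:
            raise GenerationError(f"anchor {self.id} not positive definite (min eig {eigmin:g})")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise GenerationError(f"anchor {self.id} does not have unit diagonal")


@dataclass
class SynthCohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror a resting-state schizophrenia study design: TR = 2 s,
    158 analyzed volumes, two groups.  ``n_networks`` defaults to 12 (a desk
    scale that keeps the full pipeline fast); 47 reproduces the published
    dimensionality D = 1081.
    """

    n_per_group: tuple[int, int] = (10, 10)
    n_timepoints: int = 158
    n_networks: int = 12
    tr_seconds: float = 2.0
    n_modules: int = 3
    contrast: float = 0.6
    n_motifs: int = 2
    motif_len: int = 65          # TRs per motif instance; 65 = 22 + 44 - 1
    signal_motif: int = 0        # index of the motif whose usage differs by group
    base_usage: float = 1.0 / 3.0  # group-0 probability of drawing the signal motif
    usage_ratio: float = 2.0     # group-1 usage probability = ratio * base_usage
    age_usage_effect: float = 0.0     # shift of usage probability per SD of age
    gender_usage_effect: float = 0.0  # shift of usage probability for gender == 1
    fd_usage_effect: float = 0.0      # shift of usage probability per SD of meanFD
    noise_sd: float = 0.2        # white observation noise on unit-variance signals
    window_len: int = 22         # analysis window used for ground-truth resolution
    taper_sigma: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        violations = []
        if any(n < 1 for n in self.n_per_group):
            violations.append("n_per_group entries must be positive")
        if self.n_timepoints < self.window_len:
            violations.append("n_timepoints must be at least window_len")
        if self.n_networks < 2:
            violations.append("n_networks must be >= 2")
        if not (0 < self.contrast < 1):
            violations.append("contrast must lie in (0, 1)")
        if self.n_modules > self.n_networks:
            violations.append("n_modules cannot exceed n_networks")
        if self.n_motifs < 1:
            violations.append("need at least one motif")
        if not (0 <= self.base_usage <= 1):
            violations.append("base_usage must lie in [0, 1]")
        if self.motif_len < 2:
            violations.append("motif_len must be >= 2")
        if self.noise_sd < 0:
            violations.append("noise_sd must be nonnegative")
        if violations:
            raise ValidationError(violations)


def _ridge_to_spd(C: np.ndarray, min_eig: float = 1e-6, max_ridge: float = 10.0) -> np.ndarray:
    """Shrink toward the identity until positive definite, keeping unit diagonal."""
    ridge = 0.0
    step = 0.05
    while ridge <= max_ridge:
        M = (C + ridge * np.eye(C.shape[0])) / (1.0 + ridge)
        if np.linalg.eigvalsh(M)[0] > min_eig:
            return M
        ridge = step if ridge == 0.0 else ridge * 1.6
    raise GenerationError("could not reach positive definiteness within the ridge budget")


def make_anchor_patterns(
    n_networks: int,
    n_modules: int,
    contrast: float,
    seed: int,
    n_patterns: int = 4,
) -> list[AnchorPattern]:
    """Generate block-structured anchor correlation patterns.

    Each pattern partitions the networks into modules (a rotated assignment
    per pattern so the block structures differ), sets within-module
    correlations to ``+contrast``, one randomly selected between-module block
    to ``-contrast/2``, adds small jitter elsewhere, and shrinks toward the
    identity until positive definite.
    """
    if n_modules > n_networks:
        raise InvalidParameterError("n_modules cannot exceed n_networks")
    if not (0 < contrast < 1):
        raise InvalidParameterError("contrast must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    base_assign = np.arange(n_networks) % n_modules
    patterns = []
    for pid in range(n_patterns):
        modules = base_assign.copy() if pid == 0 else rng.permutation(base_assign)
        C = np.zeros((n_networks, n_networks))
        same = modules[:, None] == modules[None, :]
        C[same] = contrast
        # one anticorrelated between-module pair, distinct per pattern
        pair = (pid % n_modules, (pid + 1) % n_modules)
        if pair[0] != pair[1]:
            anti = (modules[:, None] == pair[0]) & (modules[None, :] == pair[1])
            C[anti | anti.T] = -contrast / 2.0
        jitter = rng.normal(0.0, 0.02, size=C.shape)
        C = C + (jitter + jitter.T) / 2.0
        np.fill_diagonal(C, 1.0)
        patterns.append(AnchorPattern(pid, _ridge_to_spd(C), modules.copy()))
    return patterns


def make_motif(anchor_a: AnchorPattern, anchor_b: AnchorPattern, length: int) -> np.ndarray:
    """Convex interpolation between two anchors at ``length`` evenly spaced steps.

    Returns an array of shape (length, N, N).  Every interpolant is SPD by
    convexity of the SPD cone.
    """
    if length < 2:
        raise InvalidParameterError("motif length must be >= 2")
    u = np.linspace(0.0, 1.0, length)
    return (1 - u)[:, None, None] * anchor_a.matrix[None] + u[:, None, None] * anchor_b.matrix[None]


def motif_window_frames(motif: np.ndarray, window_len: int, taper_sigma: float) -> np.ndarray:
    """Planted motif at dFNC window resolution.

    Averages the TR-level correlation sequence under the analysis taper, one
    frame per window position, and vectorizes the upper triangle.  Shape
    ``(L - window_len + 1, D)``.
    """
    L = motif.shape[0]
    if L < window_len:
        raise InvalidParameterError("motif shorter than the analysis window")
    w = build_taper(window_len, taper_sigma)
    n_frames = L - window_len + 1
    out = []
    for j in range(n_frames):
        avg = np.tensordot(w, motif[j : j + window_len], axes=(0, 0))
        out.append(vectorize_upper(avg))
    return np.asarray(out)


def make_schedule(
    n_timepoints: int,
    motif_len: int,
    n_motifs: int,
    signal_motif: int,
    p_signal: float,
    rng: np.random.Generator,
) -> list[tuple[int, int, int]]:
    """Tile [0, T) with motif instances: list of (motif_id, start, duration).

    The signal motif is drawn with probability ``p_signal``; the remaining
    mass is split evenly over the other motifs.  The final instance is
    truncated at the scan end.
    """
    others = [m for m in range(n_motifs) if m != signal_motif]
    schedule = []
    t = 0
    while t < n_timepoints:
        if n_motifs == 1 or rng.random() < p_signal:
            m = signal_motif
        else:
            m = others[rng.integers(len(others))]
        dur = min(motif_len, n_timepoints - t)
        schedule.append((m, t, dur))
        t += dur
    return schedule


def simulate_subject(
    subject_id: str,
    schedule: list[tuple[int, int, int]],
    motifs: list[np.ndarray],
    noise_sd: float,
    tr_seconds: float,
    seed: int,
):
    """Sample one subject's timecourses from the scheduled covariances.

    At TR t the target correlation C_t is the scheduled motif's interpolant;
    the signal is ``chol(C_t) @ z_t`` with i.i.d. standard-normal z, plus
    white noise of standard deviation ``noise_sd``.
    """
    from .core_dfnc import TimecourseMatrix

    rng = np.random.default_rng(seed)
    T = schedule[-1][1] + schedule[-1][2]
    N = motifs[0].shape[1]
    X = np.empty((T, N))
    for motif_id, start, dur in schedule:
        seq = motifs[motif_id]
        for i in range(dur):
            C = seq[min(i, seq.shape[0] - 1)]
            L = np.linalg.cholesky(C)
            X[start + i] = L @ rng.standard_normal(N)
    X += noise_sd * rng.standard_normal(X.shape)
    return TimecourseMatrix(subject_id, X, tr_seconds)


def _sample_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = rng.normal(38.0, 11.0, n).clip(18, 65)
    gender = rng.integers(0, 2, n)
    mean_fd = rng.lognormal(mean=-1.8, sigma=0.5, size=n)
    return pd.DataFrame({"age": age, "gender": gender, "meanFD": mean_fd})


@dataclass
class GroundTruth:
    """Everything a recovery test needs about a simulated cohort."""

    schedules: dict[str, list[tuple[int, int, int]]]
    motif_frames: list[np.ndarray] = field(repr=False)  # window-resolution, per motif
    signal_motif: int = 0
    usage: pd.DataFrame | None = None  # per-subject signal-motif usage fraction

    def to_jsonable(self) -> dict:
        return {
            "signal_motif": self.signal_motif,
            "schedules": {s: [list(seg) for seg in segs] for s, segs in self.schedules.items()},
            "usage": self.usage.to_dict(orient="list") if self.usage is not None else None,
        }


def simulate_cohort(config: SynthCohortConfig):
    """Generate a full synthetic cohort.

    Returns ``(timecourses, manifest, ground_truth)`` where ``timecourses``
    is a list of :class:`~evodfnc.core_dfnc.TimecourseMatrix`, ``manifest``
    a DataFrame with one row per subject (diagnosis 0 = control, 1 = patient)
    and ``ground_truth`` a :class:`GroundTruth` record.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    anchors = make_anchor_patterns(
        config.n_networks, config.n_modules, config.contrast,
        seed=int(rng.integers(2**31)),
        n_patterns=max(4, 2 * config.n_motifs),
    )
    # motif m interpolates anchor 2m -> anchor 2m+1 so motifs share no anchor
    motifs = [
        make_motif(anchors[2 * m % len(anchors)], anchors[(2 * m + 1) % len(anchors)], config.motif_len)
        for m in range(config.n_motifs)
    ]
    motif_frames = [
        motif_window_frames(m, config.window_len, config.taper_sigma) for m in motifs
    ]

    n0, n1 = config.n_per_group
    n = n0 + n1
    diagnosis = np.array([0] * n0 + [1] * n1)
    cov = _sample_covariates(n, rng)
    z_age = (cov["age"] - cov["age"].mean()) / (cov["age"].std() or 1.0)
    z_fd = (cov["meanFD"] - cov["meanFD"].mean()) / (cov["meanFD"].std() or 1.0)

    timecourses = []
    schedules = {}
    usage_rows = []
    manifest_rows = []
    for i in range(n):
        sid = f"sub{i + 1:03d}"
        p = config.base_usage * (config.usage_ratio if diagnosis[i] == 1 else 1.0)
        p += (
            config.age_usage_effect * z_age.iloc[i]
            + config.gender_usage_effect * cov["gender"].iloc[i]
            + config.fd_usage_effect * z_fd.iloc[i]
        )
        p = float(np.clip(p, 0.02, 0.98))
        schedule = make_schedule(
            config.n_timepoints, config.motif_len, config.n_motifs,
            config.signal_motif, p, rng,
        )
        schedules[sid] = schedule
        tc = simulate_subject(
            sid, schedule, motifs, config.noise_sd, config.tr_seconds,
            seed=int(rng.integers(2**31)),
        )
        timecourses.append(tc)
        total = sum(d for _, _, d in schedule)
        sig = sum(d for m, _, d in schedule if m == config.signal_motif)
        usage_rows.append({"subject_id": sid, "signal_usage": sig / total, "p_signal": p})
        row = {
            "subject_id": sid,
            "diagnosis": int(diagnosis[i]),
            "age": float(cov["age"].iloc[i]),
            "gender": int(cov["gender"].iloc[i]),
            "meanFD": float(cov["meanFD"].iloc[i]),
        }
        if diagnosis[i] == 1:
            for col in SYMPTOM_COLUMNS:
                row[col] = int(rng.integers(1, 8))
        manifest_rows.append(row)

    manifest = pd.DataFrame(manifest_rows)
    for col in SYMPTOM_COLUMNS:
        if col not in manifest.columns:
            manifest[col] = np.nan
    truth = GroundTruth(
        schedules=schedules,
        motif_frames=motif_frames,
        signal_motif=config.signal_motif,
        usage=pd.DataFrame(usage_rows),
    )
    return timecourses, manifest, truth


def write_cohort(timecourses, manifest, out_dir, truth=None) -> str:
    """Write a cohort in the pipeline's on-disk input format.

    One CSV per subject (rows = TRs, columns = networks, header row of
    network names) plus ``manifest.csv`` with a ``file`` column, and
    optionally ``ground_truth.json``.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for tc in timecourses:
        fname = f"{tc.subject_id}_timecourses.csv"
        pd.DataFrame(tc.values, columns=tc.network_names).to_csv(out / fname, index=False)
        files.append(fname)
    man = manifest.copy()
    man.insert(1, "file", files)
    man.to_csv(out / "manifest.csv", index=False)
    if truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(truth.to_jsonable(), indent=1))
    return str(out / "manifest.csv")
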