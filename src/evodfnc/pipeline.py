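"""End-to-end pipeline orchestration over a reproducible run bundle.

A *bundle* is a directory with one subdirectory per stage::

    bundle/
      config.json
      log.txt
      dfnc/       per-subject frame CSVs, snapshot states and occupancy
      embed/      averaged 2D coordinates + frame index
      exemplars/  linear-segment table and exemplar centroids
      lift/       one tau x D CSV per EVOdFNC motif
      represent/  per-subject RI series, meta-state centroids, occupancies
      stats/      covariate-adjusted effect tables

Each stage reads its inputs from the bundle and writes its ``meta.json``
marker last, so a completed stage is skipped on rerun and a deleted stage
output is recomputed without touching upstream results.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_dfnc, embed2d, exemplars as ex_mod, lifting, representation, stats as stats_mod
from .config import PipelineConfig
from .core_dfnc import DfncSequence, SnapStateSet
from .embed2d import AveragedEmbedding, EmbedConfig
from .errors import EvoDfncError, ValidationError
from .exemplars import ContinuousSegment, Exemplar, ExemplarSet, LinearSegment
from .io import (
    load_json,
    load_matrix,
    read_manifest,
    read_timecourses,
    save_json,
    save_matrix,
    validate_manifest,
)
from .lifting import EvoDfnc, EvoDfncSet
from .representation import MetaStateSet, RiSeries
from .synthgen import SYMPTOM_COLUMNS

__all__ = ["RunBundle", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ["dfnc", "embed", "exemplars", "lift", "represent", "stats"]


class RunBundle:
    """Handle to a pipeline run directory; lazily loads stage outputs."""

    def __init__(self, path, config: PipelineConfig | None = None):
        self.path = Path(path)
        self.path.mkdir(parents=True, exist_ok=True)
        cfg_file = self.path / "config.json"
        if config is not None:
            cfg_file.write_text(config.to_json())
            self.config = config
        elif cfg_file.exists():
            self.config = PipelineConfig.from_json(cfg_file.read_text())
        else:
            self.config = PipelineConfig()
            cfg_file.write_text(self.config.to_json())

    # -- stage bookkeeping -------------------------------------------------
    def stage_dir(self, stage: str) -> Path:
        d = self.path / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def stage_done(self, stage: str) -> bool:
        return (self.stage_dir(stage) / "meta.json").exists()

    def _finish(self, stage: str, meta: dict) -> None:
        save_json(self.stage_dir(stage) / "meta.json", meta)

    # -- loaders -----------------------------------------------------------
    def load_sequences(self) -> list[DfncSequence]:
        meta = load_json(self.stage_dir("dfnc") / "meta.json")
        out = []
        for sid in meta["subjects"]:
            frames = load_matrix(self.stage_dir("dfnc") / f"{sid}.csv")
            out.append(DfncSequence(sid, frames, meta["window_len"], meta["step"]))
        return out

    def load_stacked_frames(self):
        return core_dfnc.stack_sequences(self.load_sequences())

    def load_snap_states(self) -> SnapStateSet:
        d = self.stage_dir("dfnc")
        centroids = load_matrix(d / "snap_centroids.csv")
        assign = pd.read_csv(d / "snap_assignments.csv")
        return SnapStateSet(
            centroids=centroids,
            labels=assign["state"].to_numpy(dtype=int),
            subject_ids=assign["subject_id"].to_numpy(dtype=object),
            k=centroids.shape[0],
        )

    def load_embedding(self) -> AveragedEmbedding:
        d = self.stage_dir("embed")
        coords = load_matrix(d / "coords.csv")
        index = pd.read_csv(d / "index.csv")
        meta = load_json(d / "meta.json")
        cfg = EmbedConfig(
            n_neighbors=meta["n_neighbors"],
            min_dist=meta["min_dist"],
            n_runs=meta["n_runs"],
            base_seed=meta["base_seed"],
            align_runs=meta["align_runs"],
        )
        return AveragedEmbedding(
            coords=coords,
            subject_ids=index["subject_id"].to_numpy(dtype=object),
            window_idx=index["window"].to_numpy(dtype=int),
            config=cfg,
        )

    def load_exemplar_set(self) -> ExemplarSet:
        d = self.stage_dir("exemplars")
        seg_table = pd.read_csv(d / "segments.csv")
        ex_table = pd.read_csv(d / "exemplars.csv")
        meta = load_json(d / "meta.json")
        embedding = self.load_embedding()
        tau = meta["tau"]
        segments = []
        for _, row in seg_table.iterrows():
            pts = embedding.subject_coords(row["subject_id"])[
                int(row["start"]) : int(row["start"]) + tau
            ]
            src = ContinuousSegment(row["subject_id"], int(row["start"]), pts)
            segments.append(
                LinearSegment(
                    midpoint=np.array([row["x"], row["y"]]),
                    slope=float(row["slope"]),
                    length=float(row["length"]),
                    source=src,
                )
            )
        exemplar_list = [
            Exemplar(
                int(row["id"]),
                np.array([row["x"], row["y"]]),
                float(row["slope"]),
                float(row["length"]),
                int(row["direction"]),
            )
            for _, row in ex_table.iterrows()
        ]
        return ExemplarSet(
            exemplars=exemplar_list,
            slope_bound=meta["slope_bound"],
            labels=seg_table["cluster"].to_numpy(dtype=int),
            segments=segments,
        )

    def load_motifs(self) -> EvoDfncSet:
        d = self.stage_dir("lift")
        meta = load_json(d / "meta.json")
        motifs = [
            EvoDfnc(k, load_matrix(d / f"evo_{k}.csv"), k) for k in range(meta["K"])
        ]
        return EvoDfncSet(motifs, tau=meta["tau"], n_neighbors=meta["n_neighbors"])

    def load_ri_series(self) -> list[RiSeries]:
        d = self.stage_dir("represent")
        meta = load_json(d / "meta.json")
        return [
            RiSeries(sid, load_matrix(d / f"ri_{sid}.csv"), meta["mode"])
            for sid in meta["subjects"]
        ]

    def load_meta_states(self) -> MetaStateSet:
        d = self.stage_dir("represent")
        centroids = load_matrix(d / "meta_centroids.csv")
        assign = pd.read_csv(d / "meta_assignments.csv")
        return MetaStateSet(
            centroids=centroids,
            labels=assign["cluster"].to_numpy(dtype=int),
            subject_ids=assign["subject_id"].to_numpy(dtype=object),
            M=centroids.shape[0],
        )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_dfnc(bundle: RunBundle, manifest_path) -> None:
    cfg = bundle.config
    manifest = read_manifest(manifest_path)
    timecourses = read_timecourses(manifest, Path(manifest_path).parent)
    d = bundle.stage_dir("dfnc")
    sequences = []
    for tc in timecourses:
        seq = core_dfnc.compute_windowed_dfnc(
            tc, cfg.window_len, cfg.taper_sigma, cfg.step, cfg.fisher_z
        )
        save_matrix(d / f"{seq.subject_id}.csv", seq.frames)
        sequences.append(seq)
    frames, subject_ids, _ = core_dfnc.stack_sequences(sequences)
    states = core_dfnc.cluster_snapshots(
        frames, subject_ids, cfg.k_snap, cfg.seed, cfg.snap_restarts, cfg.kmeans_max_iter
    )
    save_matrix(d / "snap_centroids.csv", states.centroids)
    pd.DataFrame({"subject_id": subject_ids, "state": states.labels}).to_csv(
        d / "snap_assignments.csv", index=False
    )
    occ = pd.DataFrame(
        [core_dfnc.snapshot_occupancy(states, s.subject_id) for s in sequences],
        index=[s.subject_id for s in sequences],
        columns=[f"state{j + 1}" for j in range(states.k)],
    )
    occ.to_csv(d / "snap_occupancy.csv", index_label="subject_id")
    manifest.to_csv(d / "manifest.csv", index=False)
    bundle._finish(
        "dfnc",
        {
            "subjects": [s.subject_id for s in sequences],
            "window_len": cfg.window_len,
            "step": cfg.step,
            "taper_sigma": "inf" if np.isinf(cfg.taper_sigma) else cfg.taper_sigma,
            "n_features": sequences[0].n_features,
            "n_windows": {s.subject_id: s.n_windows for s in sequences},
            "snap_k": cfg.k_snap,
            "snap_inertia": states.inertia,
        },
    )


def _stage_embed(bundle: RunBundle) -> None:
    cfg = bundle.config
    frames, subject_ids, window_idx = bundle.load_stacked_frames()
    econf = EmbedConfig(
        n_neighbors=cfg.n_neighbors,
        min_dist=cfg.min_dist,
        n_runs=cfg.n_runs,
        base_seed=cfg.seed,
        align_runs=cfg.align_runs,
    )
    embedding = embed2d.embed_frames(frames, subject_ids, window_idx, econf)
    d = bundle.stage_dir("embed")
    save_matrix(d / "coords.csv", embedding.coords)
    pd.DataFrame({"subject_id": subject_ids, "window": window_idx}).to_csv(
        d / "index.csv", index=False
    )
    bundle._finish(
        "embed",
        {
            "n_neighbors": econf.n_neighbors,
            "min_dist": econf.min_dist,
            "n_runs": econf.n_runs,
            "base_seed": econf.base_seed,
            "align_runs": econf.align_runs,
            "n_frames": int(frames.shape[0]),
        },
    )


def _stage_exemplars(bundle: RunBundle) -> None:
    cfg = bundle.config
    embedding = bundle.load_embedding()
    bound = ex_mod.compute_slope_bound(embedding)
    continuous = ex_mod.extract_all_segments(embedding, cfg.tau)
    linear = [ex_mod.linearize_segment(s, bound) for s in continuous]
    exset = ex_mod.cluster_linear_segments(
        linear, cfg.K, cfg.seed, cfg.exemplar_restarts, cfg.kmeans_max_iter
    )
    d = bundle.stage_dir("exemplars")
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in linear],
            "start": [s.start for s in linear],
            "x": [s.midpoint[0] for s in linear],
            "y": [s.midpoint[1] for s in linear],
            "slope": [s.slope for s in linear],
            "length": [s.length for s in linear],
            "cluster": exset.labels,
        }
    ).to_csv(d / "segments.csv", index=False)
    pd.DataFrame(
        {
            "id": [e.id for e in exset.exemplars],
            "x": [e.midpoint[0] for e in exset.exemplars],
            "y": [e.midpoint[1] for e in exset.exemplars],
            "slope": [e.slope for e in exset.exemplars],
            "length": [e.length for e in exset.exemplars],
            "direction": [e.direction for e in exset.exemplars],
        }
    ).to_csv(d / "exemplars.csv", index=False)
    occ = pd.DataFrame(
        [
            ex_mod.exemplar_membership_occupancy(exset, sid)
            for sid in embedding.subjects
        ],
        index=embedding.subjects,
        columns=[f"exemplar{k + 1}" for k in range(exset.K)],
    )
    occ.to_csv(d / "membership_occupancy.csv", index_label="subject_id")
    bundle._finish(
        "exemplars",
        {
            "tau": cfg.tau,
            "K": cfg.K,
            "slope_bound": bound,
            "n_segments": len(linear),
            "inertia": exset.inertia,
        },
    )


def _stage_lift(bundle: RunBundle) -> None:
    cfg = bundle.config
    embedding = bundle.load_embedding()
    frames, _, _ = bundle.load_stacked_frames()
    exset = bundle.load_exemplar_set()
    motifs = lifting.lift_all(exset, embedding, frames, cfg.tau, cfg.n_lift)
    d = bundle.stage_dir("lift")
    for m in motifs.motifs:
        save_matrix(d / f"evo_{m.id}.csv", m.frames)
    bundle._finish(
        "lift",
        {
            "K": motifs.K,
            "tau": motifs.tau,
            "n_neighbors": motifs.n_neighbors,
            "n_features": motifs.motifs[0].n_features,
            "window_values": motifs.tau * motifs.motifs[0].n_features,
        },
    )


def _stage_represent(bundle: RunBundle) -> None:
    cfg = bundle.config
    motifs = bundle.load_motifs()
    sequences = bundle.load_sequences()
    d = bundle.stage_dir("represent")
    series = []
    for seq in sequences:
        s = representation.ri_series(seq, motifs, cfg.ri_mode)
        save_matrix(d / f"ri_{s.subject_id}.csv", s.weights)
        series.append(s)
    rows, row_subjects = representation.stack_ri(series)
    metaset = representation.cluster_weight_vectors(
        rows, row_subjects, cfg.M, cfg.seed, cfg.meta_restarts, cfg.kmeans_max_iter
    )
    save_matrix(d / "meta_centroids.csv", metaset.centroids)
    pd.DataFrame({"subject_id": row_subjects, "cluster": metaset.labels}).to_csv(
        d / "meta_assignments.csv", index=False
    )
    occ = pd.DataFrame(
        [representation.meta_occupancy(s, metaset) for s in series],
        index=[s.subject_id for s in series],
        columns=[f"meta{m + 1}" for m in range(metaset.M)],
    )
    occ.to_csv(d / "meta_occupancy.csv", index_label="subject_id")
    ri_mean = pd.DataFrame(
        [s.subject_mean() for s in series],
        index=[s.subject_id for s in series],
        columns=[f"evo{k + 1}" for k in range(motifs.K)],
    )
    ri_mean.to_csv(d / "ri_subject_mean.csv", index_label="subject_id")
    bundle._finish(
        "represent",
        {
            "subjects": [s.subject_id for s in series],
            "mode": cfg.ri_mode,
            "M": cfg.M,
            "K": motifs.K,
            "tau": motifs.tau,
            "window_values": motifs.tau * motifs.motifs[0].n_features,
            "inertia": metaset.inertia,
        },
    )


def _feature_tables(bundle: RunBundle) -> dict[str, pd.DataFrame]:
    """Subject-level feature tables, indexed by subject id."""
    d_rep = bundle.stage_dir("represent")
    tables = {
        "ri": pd.read_csv(d_rep / "ri_subject_mean.csv", index_col="subject_id"),
        "meta_occupancy": pd.read_csv(d_rep / "meta_occupancy.csv", index_col="subject_id"),
        "snap_occupancy": pd.read_csv(
            bundle.stage_dir("dfnc") / "snap_occupancy.csv", index_col="subject_id"
        ),
        "exemplar_occupancy": pd.read_csv(
            bundle.stage_dir("exemplars") / "membership_occupancy.csv",
            index_col="subject_id",
        ),
    }
    return tables


def _stage_stats(bundle: RunBundle) -> None:
    cfg = bundle.config
    manifest = pd.read_csv(bundle.stage_dir("dfnc") / "manifest.csv")
    manifest = manifest.set_index("subject_id", drop=False)
    tables = _feature_tables(bundle)
    d = bundle.stage_dir("stats")
    group_frames = []
    symptom_frames = []
    patients = manifest[manifest["diagnosis"] == 1]
    have_symptoms = all(c in manifest.columns for c in SYMPTOM_COLUMNS) and (
        len(patients) > 0 and not patients[SYMPTOM_COLUMNS].isna().any().any()
    )
    for name, feats in tables.items():
        feats = feats.loc[manifest.index]
        table = stats_mod.fit_group_model(feats, manifest, cfg.correction)
        table.insert(0, "feature_set", name)
        group_frames.append(table)
        min_n = len(SYMPTOM_COLUMNS) + 4 + 1
        if have_symptoms and len(patients) > min_n:
            st = stats_mod.fit_symptom_model(feats, manifest, cfg.correction)
            st.insert(0, "feature_set", name)
            symptom_frames.append(st)
    pd.concat(group_frames, ignore_index=True).to_csv(d / "group_effects.csv", index=False)
    meta = {"correction": cfg.correction, "n_subjects": len(manifest), "models": ["group"]}
    if symptom_frames:
        pd.concat(symptom_frames, ignore_index=True).to_csv(
            d / "symptom_effects.csv", index=False
        )
        meta["models"].append("symptom")
    bundle._finish("stats", meta)


_STAGE_FUNCS = {
    "dfnc": _stage_dfnc,
    "embed": _stage_embed,
    "exemplars": _stage_exemplars,
    "lift": _stage_lift,
    "represent": _stage_represent,
    "stats": _stage_stats,
}


def run_pipeline(
    manifest_path,
    config: PipelineConfig | None = None,
    out_dir="evodfnc_run",
    force: bool = False,
    stop_after: str | None = None,
) -> RunBundle:
    """Run (or resume) the full pipeline on a cohort manifest.

    Stages execute in order dfnc -> embed -> exemplars -> lift -> represent
    -> stats; a stage whose ``meta.json`` marker already exists is skipped
    unless ``force`` is set.  Any stage error aborts with the stage name.
    """
    config = config or PipelineConfig()
    violations = validate_manifest(manifest_path)
    if violations:
        raise ValidationError(violations)
    bundle = RunBundle(out_dir, config)
    log_file = bundle.path / "log.txt"
    handler = logging.FileHandler(log_file)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("evodfnc")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("pipeline start: seed=%d config=%s", config.seed, config.to_dict())
        for stage in STAGES:
            if bundle.stage_done(stage) and not force:
                logger.info("stage %s: cached, skipping", stage)
            else:
                t0 = time.time()
                logger.info("stage %s: running", stage)
                try:
                    if stage == "dfnc":
                        _STAGE_FUNCS[stage](bundle, manifest_path)
                    else:
                        _STAGE_FUNCS[stage](bundle)
                except EvoDfncError as exc:
                    logger.error("stage %s failed: %s", stage, exc)
                    raise EvoDfncError(f"stage {stage!r} failed: {exc}") from exc
                logger.info("stage %s: done in %.1fs", stage, time.time() - t0)
            if stop_after == stage:
                break
    finally:
        root.removeHandler(handler)
        handler.close()
    return bundle
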