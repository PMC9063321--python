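"""Delimited-text + JSON persistence and manifest handling.

Everything the pipeline writes is human-diffable text: matrices as CSV at
17 significant digits (lossless for float64 round trips) and metadata as
JSON.  A *bundle* is a directory with one subdirectory per pipeline stage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_dfnc import TimecourseMatrix
from .errors import InvalidInputError, ValidationError
from .synthgen import SYMPTOM_COLUMNS

__all__ = [
    "save_matrix",
    "load_matrix",
    "save_json",
    "load_json",
    "read_manifest",
    "read_timecourses",
    "validate_manifest",
]

MANIFEST_REQUIRED = ["subject_id", "file", "diagnosis", "age", "gender", "meanFD"]

FLOAT_FMT = "%.17g"


def save_matrix(path, arr: np.ndarray, header: list[str] | None = None) -> None:
    """Write a 1-D or 2-D array as CSV at 17 significant digits."""
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    head = ",".join(header) if header else ""
    np.savetxt(path, arr, fmt=FLOAT_FMT, delimiter=",", header=head, comments="")


def load_matrix(path, has_header: bool = False) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", skiprows=1 if has_header else 0, ndmin=2)


def save_json(path, obj) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def load_json(path):
    return json.loads(Path(path).read_text())


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest CSV; raises if required columns are absent."""
    man = pd.read_csv(path)
    missing = [c for c in MANIFEST_REQUIRED if c not in man.columns]
    if missing:
        raise InvalidInputError(f"manifest missing required columns: {missing}")
    return man


def read_timecourses(manifest: pd.DataFrame, base_dir) -> list[TimecourseMatrix]:
    """Load every subject's timecourse CSV referenced by the manifest.

    Files are resolved relative to ``base_dir`` (normally the manifest's
    directory).  Each CSV has a header row of network names and one row per
    TR.
    """
    base = Path(base_dir)
    out = []
    for _, row in manifest.iterrows():
        df = pd.read_csv(base / row["file"])
        out.append(
            TimecourseMatrix(
                subject_id=str(row["subject_id"]),
                values=df.to_numpy(dtype=float),
                network_names=list(df.columns),
            )
        )
    return out


def validate_manifest(path, check_symptoms: bool = False) -> list[str]:
    """Validate a manifest and its referenced files; returns all violations.

    Checks: required columns, diagnosis/gender coding, file existence,
    consistent network count across subjects, and (optionally) symptom
    completeness for patients.  An empty list means the manifest is valid.
    """
    path = Path(path)
    violations: list[str] = []
    if not path.exists():
        raise OSError(f"manifest not found: {path}")
    try:
        man = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - report parse failures as violations
        return [f"unparseable manifest: {exc}"]
    for col in MANIFEST_REQUIRED:
        if col not in man.columns:
            violations.append(f"missing required column {col!r}")
    if violations:
        return violations
    if man["subject_id"].duplicated().any():
        dups = man.loc[man["subject_id"].duplicated(), "subject_id"].tolist()
        violations.append(f"duplicate subject ids: {dups}")
    bad_dx = man.loc[~man["diagnosis"].isin([0, 1]), "subject_id"].tolist()
    if bad_dx:
        violations.append(f"diagnosis not in {{0,1}} for subjects: {bad_dx}")
    bad_g = man.loc[~man["gender"].isin([0, 1]), "subject_id"].tolist()
    if bad_g:
        violations.append(f"gender not in {{0,1}} for subjects: {bad_g}")
    for col in ["age", "meanFD"]:
        if man[col].isna().any():
            who = man.loc[man[col].isna(), "subject_id"].tolist()
            violations.append(f"missing {col} for subjects: {who}")
    n_by_subject = {}
    for _, row in man.iterrows():
        f = path.parent / row["file"]
        if not f.exists():
            violations.append(f"timecourse file missing for {row['subject_id']}: {row['file']}")
            continue
        with open(f) as fh:
            n_by_subject[row["subject_id"]] = len(fh.readline().rstrip("\n").split(","))
    if len(set(n_by_subject.values())) > 1:
        detail = ", ".join(f"{s}: N={n}" for s, n in sorted(n_by_subject.items(), key=lambda kv: kv[1]))
        violations.append(f"inconsistent network count across subjects ({detail})")
    if check_symptoms:
        patients = man[man["diagnosis"] == 1]
        for col in SYMPTOM_COLUMNS:
            if col not in man.columns:
                violations.append(f"missing symptom column {col!r}")
            elif patients[col].isna().any():
                who = patients.loc[patients[col].isna(), "subject_id"].tolist()
                violations.append(f"missing {col} for patients: {who}")
    return violations
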