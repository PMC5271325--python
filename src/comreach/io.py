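"""Trial-table CSV schema, run configuration, and the MAT-file import adapter.

The canonical interchange format is a UTF-8 CSV with one row per trial and a
fixed column set (:data:`SCHEMA_COLUMNS`).  CSV is used because the data are
small (at most 696 rows per subject) and diffable.  The subject-data MAT
import is isolated behind :func:`import_s1_dataset` so its absence never
blocks the synthetic pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SCHEMA_COLUMNS",
    "TrialTableError",
    "RunConfig",
    "read_trial_table",
    "write_trial_table",
    "validate_trial_table",
    "import_s1_dataset",
    "export_subjects_mat",
    "load_config",
    "save_config",
]

SCHEMA_COLUMNS = [
    "subject_id",
    "phase",
    "block",
    "trial_index",
    "r1_cm",
    "r2_cm",
    "rho",
    "s_true_cm",
    "jitter_cm",
    "perturbation_level",
    "b_cm",
    "uncertainty_class",
    "feedback",
    "r_cm",
    "delta_s_cm",
    "score",
]

_NUMERIC = [
    "block",
    "trial_index",
    "r1_cm",
    "r2_cm",
    "rho",
    "s_true_cm",
    "jitter_cm",
    "perturbation_level",
    "b_cm",
    "r_cm",
    "delta_s_cm",
    "score",
]


class TrialTableError(ValueError):
    """Schema violation in a trial table."""


def write_trial_table(records: pd.DataFrame, path) -> None:
    """Write a trial table in canonical column order (lossless floats)."""
    missing = [c for c in SCHEMA_COLUMNS if c not in records.columns]
    if missing:
        raise TrialTableError(f"missing columns: {missing}")
    records[SCHEMA_COLUMNS].to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV (header-keyed, any column order)."""
    df = pd.read_csv(path)
    missing = sorted(set(SCHEMA_COLUMNS) - set(df.columns))
    extra = sorted(set(df.columns) - set(SCHEMA_COLUMNS))
    if missing or extra:
        raise TrialTableError(
            f"schema mismatch: missing columns {missing}, unexpected columns {extra}"
        )
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise TrialTableError(
                f"non-numeric value in column {col!r} at row {row}: {df[col][row]!r}"
            )
        df[col] = coerced
    if df["feedback"].dtype != bool:
        df["feedback"] = df["feedback"].astype(str).str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        if df["feedback"].isna().any():
            row = int(df["feedback"].isna().idxmax())
            raise TrialTableError(f"non-boolean value in column 'feedback' at row {row}")
        df["feedback"] = df["feedback"].astype(bool)
    df["score"] = df["score"].astype("Int64")
    df["block"] = df["block"].astype(int)
    df["trial_index"] = df["trial_index"].astype(int)
    return df[SCHEMA_COLUMNS]


def validate_trial_table(df: pd.DataFrame) -> None:
    """Check row-level invariants beyond the column schema."""
    resp = df["r_cm"].notna() & df["delta_s_cm"].notna()
    err = (df.loc[resp, "r_cm"] - df.loc[resp, "s_true_cm"] - df.loc[resp, "delta_s_cm"]).abs()
    if (err > 1e-9).any():
        raise TrialTableError("delta_s_cm inconsistent with r_cm - s_true_cm")
    has_score = df["score"].notna()
    if (has_score & ~df["feedback"]).any():
        raise TrialTableError("score present on a no-feedback trial")
    if (resp & df["feedback"] & ~has_score).any():
        raise TrialTableError("score missing on a responded feedback trial")


# ---------------------------------------------------------------------------
# MAT-file adapter

_MAT_FIELDS = [c for c in SCHEMA_COLUMNS if c != "subject_id"]


def export_subjects_mat(records: pd.DataFrame, path) -> None:
    """Write a cohort to a MAT-file (v5) container, one struct per subject.

    This is the synthetic stand-in layout used for round-trip testing of the
    import adapter: a struct array ``subjects`` whose entries carry an ``id``
    plus one array per trial-table column.
    """
    from scipy.io import savemat

    subjects = []
    for sid, df in records.groupby("subject_id", sort=True):
        entry = {"id": sid}
        for col in _MAT_FIELDS:
            if col in ("phase", "uncertainty_class"):
                entry[col] = np.array(df[col].astype(str))
            elif col == "feedback":
                entry[col] = df[col].to_numpy(bool).astype(float)
            elif col == "score":
                entry[col] = df[col].astype(float).to_numpy()  # NaN = no feedback
            else:
                entry[col] = df[col].to_numpy(float)
        subjects.append(entry)
    savemat(path, {"subjects": subjects}, oned_as="column")


def import_s1_dataset(path) -> pd.DataFrame:
    """Import a per-subject MAT-file container onto the trial-table schema.

    The adapter discovers the container's layout rather than assuming it: it
    looks for a struct array whose entries expose per-trial arrays named
    after the schema columns.  Unrecognized layouts raise an error listing
    the variable names found, and unmapped per-subject fields are dropped.
    """
    from scipy.io import loadmat

    raw = loadmat(path, simplify_cells=True)
    names = [k for k in raw if not k.startswith("__")]
    subjects = None
    for k in names:
        v = raw[k]
        if isinstance(v, dict):
            v = [v]
        if (
            isinstance(v, (list, np.ndarray))
            and len(v) > 0
            and all(isinstance(e, dict) for e in v)
        ):
            subjects = v
            break
    if subjects is None:
        raise TrialTableError(
            "unrecognized MAT layout: no per-subject struct array found; "
            f"variables present: {names}"
        )
    frames = []
    for i, entry in enumerate(subjects):
        cols = {}
        for col in _MAT_FIELDS:
            if col not in entry:
                raise TrialTableError(
                    f"subject entry {i} lacks field {col!r}; fields present: "
                    f"{sorted(entry)}"
                )
            arr = np.atleast_1d(np.asarray(entry[col])).ravel()
            cols[col] = arr
        n = len(cols["rho"])
        sid = str(entry.get("id", f"S{i + 1:02d}"))
        df = pd.DataFrame({c: cols[c] for c in _MAT_FIELDS})
        df.insert(0, "subject_id", sid)
        df["phase"] = df["phase"].astype(str)
        df["uncertainty_class"] = df["uncertainty_class"].astype(str)
        df["feedback"] = df["feedback"].astype(float) > 0.5
        df["score"] = pd.array(
            [pd.NA if not np.isfinite(s) else int(round(s)) for s in df["score"]],
            dtype="Int64",
        )
        df["block"] = df["block"].astype(int)
        df["trial_index"] = df["trial_index"].astype(int)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)[SCHEMA_COLUMNS]


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """Serializable description of a pipeline run."""

    seed: int = 1
    n_subjects: int = 16
    observer: dict = field(
        default_factory=lambda: dict(
            sigma_rho=0.063, dim_d=1.94, alpha=3.1, sigma_adj=2.8, sigma_motor=0.76
        )
    )
    session: dict = field(default_factory=dict)
    grid_step_cm: float = 0.01
    n_quad: int = 61
    outdir: str = "results"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)
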