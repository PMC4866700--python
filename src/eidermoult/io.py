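"""CSV schemas, validation, and serialization for the pipeline tables.

Four long-format tables travel between stages:

* ``birds.csv``     -- bird_id, year, sex, cohort_year, treatment
* ``feathers.csv``  -- bird_id, year, feather, t, replicate, length
* ``masses.csv``    -- bird_id, year, t, mass
* ``scans.csv``     -- session_id, treatment, scan_idx, n_in, n_out

Time columns are fractional days on the run's continuous axis.  Every
file written by the pipeline carries a ``# seed=... config_sha=...``
comment header so outputs are traceable to their generating run.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import pandas as pd

__all__ = ["SCHEMAS", "read_table", "write_table", "read_tables",
           "write_tables", "ValidationError"]


class ValidationError(ValueError):
    """A table failed schema validation; the message lists offenders."""


SCHEMAS: dict[str, dict] = {
    "birds": {
        "columns": ["bird_id", "year", "sex", "cohort_year", "treatment"],
        "key": ["bird_id", "year"],
    },
    "feathers": {
        "columns": ["bird_id", "year", "feather", "t", "replicate", "length"],
        "key": ["bird_id", "year", "feather", "t", "replicate"],
        "nonneg": ["length"],
    },
    "masses": {
        "columns": ["bird_id", "year", "t", "mass"],
        "key": ["bird_id", "year", "t"],
        "positive": ["mass"],
    },
    "scans": {
        "columns": ["session_id", "treatment", "scan_idx", "n_in", "n_out"],
        "key": ["session_id", "scan_idx"],
        "nonneg": ["n_in", "n_out"],
    },
}


def _validate(df: pd.DataFrame, name: str) -> pd.DataFrame:
    schema = SCHEMAS[name]
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing column(s) {missing}")
    dup = df.duplicated(subset=schema["key"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:10]  # 1-based + header line
        raise ValidationError(
            f"{name}: duplicate {tuple(schema['key'])} key at file line(s) {rows}")
    for col in schema.get("nonneg", []):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValidationError(
                f"{name}: negative {col} at file line(s) {(bad + 2).tolist()[:10]}")
    for col in schema.get("positive", []):
        bad = df.index[df[col] <= 0]
        if len(bad):
            raise ValidationError(
                f"{name}: non-positive {col} at file line(s) {(bad + 2).tolist()[:10]}")
    return df[schema["columns"]]


def read_table(path: str | Path, name: str) -> pd.DataFrame:
    """Read and schema-validate one pipeline CSV (comment lines allowed)."""
    df = pd.read_csv(path, comment="#")
    return _validate(df, name)


def write_table(df: pd.DataFrame, path: str | Path, name: str,
                *, seed: int | None = None,
                config_sha: str | None = None) -> None:
    """Write one pipeline CSV with a provenance comment header."""
    _validate(df, name) if name in SCHEMAS else None
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    meta = []
    if seed is not None:
        meta.append(f"seed={seed}")
    if config_sha is not None:
        meta.append(f"config_sha={config_sha}")
    if meta:
        buf.write(f"# {' '.join(meta)}\n")
    df.to_csv(buf, index=False, lineterminator="\n")
    path.write_text(buf.getvalue())


_TABLE_FILES = {"birds": "birds.csv", "feathers": "feathers.csv",
                "masses": "masses.csv", "scans": "scans.csv"}

_SIM_KEYS = {"birds": "birds", "feathers": "feather_measurements",
             "masses": "mass_series", "scans": "scan_sessions"}


def read_tables(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read whichever of the four pipeline tables exist in ``directory``.

    ``birds`` and ``feathers`` are required; ``masses`` and ``scans`` are
    optional stages.
    """
    directory = Path(directory)
    out: dict[str, pd.DataFrame] = {}
    for name, fname in _TABLE_FILES.items():
        p = directory / fname
        if p.exists():
            out[name] = read_table(p, name)
        elif name in ("birds", "feathers"):
            raise FileNotFoundError(f"required table missing: {p}")
    return out


def config_hash(config) -> str:
    """Short stable hash of a configuration object for provenance."""
    try:
        payload = json.dumps(config, default=str, sort_keys=True)
    except TypeError:
        payload = repr(config)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_tables(cohort: dict[str, pd.DataFrame], directory: str | Path,
                 *, seed: int | None = None,
                 config_sha: str | None = None) -> None:
    """Write a simulated cohort's four tables (plus true_params) to CSV."""
    directory = Path(directory)
    for name, fname in _TABLE_FILES.items():
        write_table(cohort[_SIM_KEYS[name]], directory / fname, name,
                    seed=seed, config_sha=config_sha)
    if "true_params" in cohort:
        write_table(cohort["true_params"], directory / "true_params.csv",
                    "true_params", seed=seed, config_sha=config_sha)
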