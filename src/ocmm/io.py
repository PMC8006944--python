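"""Subject-record container and on-disk formats.

A subject record is one oral test (OGTT or MMTT): demographics plus the
sampled glucose and C-peptide time courses.  The CSV dialect embeds the
metadata as leading ``# key: value`` comment lines so a record is a
single self-describing file; units are part of the column names to make
unit drift loud.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

from .van_cauter import Demographics

__all__ = ["SubjectRecord", "read_subject", "write_subject", "config_hash"]

_COLUMNS = ["time_min", "glucose_mmol_L", "cpeptide_pmol_L"]
_TEST_TYPES = ("OGTT", "MMTT")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's oral-test data: demographics and sampled time series."""

    subject_id: str
    demographics: Demographics
    test_type: str
    times: np.ndarray = field(repr=False)
    glucose: np.ndarray = field(repr=False)
    cpeptide: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        glucose = np.asarray(self.glucose, dtype=float)
        cpeptide = np.asarray(self.cpeptide, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "glucose", glucose)
        object.__setattr__(self, "cpeptide", cpeptide)
        if self.test_type not in _TEST_TYPES:
            raise ValueError(f"test_type must be one of {_TEST_TYPES}, got {self.test_type!r}")
        if not (times.shape == glucose.shape == cpeptide.shape) or times.ndim != 1:
            raise ValueError("times, glucose and cpeptide must be 1-d arrays of equal length")
        if not np.all(np.diff(times) > 0):
            raise ValueError("sample times must be strictly increasing")
        if times.size == 0 or times[0] != 0:
            raise ValueError("record must contain a t=0 (basal) sample")
        for name, arr in (("glucose", glucose), ("cpeptide", cpeptide)):
            bad = np.flatnonzero(~(np.isfinite(arr) & (arr > 0)))
            if bad.size:
                raise ValueError(
                    f"{name} must be positive and finite; offending rows: {bad.tolist()}"
                )

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    @property
    def glucose_basal(self) -> float:
        """Pre-test basal glucose G_b, mmol/L (first sample)."""
        return float(self.glucose[0])

    @property
    def cp_basal(self) -> float:
        """Basal plasma C-peptide CP1b, pmol/L (first sample)."""
        return float(self.cpeptide[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "glucose_mmol_L": self.glucose,
                "cpeptide_pmol_L": self.cpeptide,
            }
        )


def read_subject(path: str | Path) -> SubjectRecord:
    """Read a subject-record CSV (metadata in leading ``#`` comment lines)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    for line in lines:
        if not line.startswith("#"):
            break
        if ":" in line:
            key, _, value = line.lstrip("#").partition(":")
            meta[key.strip()] = value.strip()
    required_meta = ("id", "age_years", "bmi_kg_m2", "test_type")
    missing = [k for k in required_meta if k not in meta]
    if missing:
        raise ValueError(f"{path}: missing metadata keys {missing}")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    try:
        return SubjectRecord(
            subject_id=meta["id"],
            demographics=Demographics(
                age=float(meta["age_years"]),
                bmi=float(meta["bmi_kg_m2"]),
                subject_class=meta.get("subject_class") or None,
            ),
            test_type=meta["test_type"],
            times=df["time_min"].to_numpy(dtype=float),
            glucose=df["glucose_mmol_L"].to_numpy(dtype=float),
            cpeptide=df["cpeptide_pmol_L"].to_numpy(dtype=float),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_subject(record: SubjectRecord, path: str | Path) -> Path:
    """Write a subject record to the CSV dialect read by :func:`read_subject`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    demo = record.demographics
    header = (
        f"# id: {record.subject_id}\n"
        f"# age_years: {demo.age}\n"
        f"# bmi_kg_m2: {demo.bmi}\n"
        f"# subject_class: {demo.subject_class}\n"
        f"# test_type: {record.test_type}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        record.to_frame().to_csv(fh, index=False)
    return path


def config_hash(config: object) -> str:
    """Short deterministic hash of a configuration for output provenance."""
    try:
        payload = json.dumps(config, sort_keys=True, default=lambda o: vars(o))
    except TypeError:
        payload = repr(config)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
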