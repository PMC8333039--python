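"""Core data types and cohort I/O.

A cohort of eye-tracking recordings is stored as one CSV per subject
(columns ``t, lx, ly, rx, ry``; the y columns are optional) plus a
cohort-level manifest CSV (``subject_id, label, path, reading_end_index,
sample_rate_hz``).  Coordinates are unitless screen positions; samples are
0-based and ``reading_end_index`` is exclusive (the active reading part is
the half-open slice ``[0, reading_end_index)``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Binary risk labels: high risk / low risk of dyslexia.
LABELS = ("HR", "LR")


def _as_float_array(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be a 1-D sequence, got shape {arr.shape}")
    return arr


@dataclass
class Recording:
    """One subject's raw eye-tracking record during a text reading test.

    ``lx``/``rx`` (and optionally ``ly``/``ry``) are the left/right-eye
    screen coordinates sampled uniformly at ``sample_rate_hz`` (nominally
    100 Hz).  ``reading_end_index`` marks the end of active reading; any
    samples past it (gaze wandering after the last line) are ignored by
    the preprocessing chain.
    """

    subject_id: str
    label: str
    lx: np.ndarray
    rx: np.ndarray
    ly: np.ndarray | None = None
    ry: np.ndarray | None = None
    reading_end_index: int = 0
    sample_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {self.label!r}")
        self.lx = _as_float_array("lx", self.lx)
        self.rx = _as_float_array("rx", self.rx)
        if len(self.lx) != len(self.rx):
            raise FormatError(
                f"ragged eye traces: len(lx)={len(self.lx)} != len(rx)={len(self.rx)}"
            )
        if (self.ly is None) != (self.ry is None):
            raise FormatError("ly and ry must be given together")
        if self.ly is not None:
            self.ly = _as_float_array("ly", self.ly)
            self.ry = _as_float_array("ry", self.ry)
            if not (len(self.ly) == len(self.ry) == len(self.lx)):
                raise FormatError("y traces must match x traces in length")
        if not 0 < self.reading_end_index <= len(self.lx):
            raise ValidationError(
                f"reading_end_index={self.reading_end_index} out of range "
                f"(0, {len(self.lx)}]"
            )
        if not self.sample_rate_hz > 0:
            raise ValidationError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.lx)

    @property
    def reading_time_s(self) -> float:
        """Active reading duration in seconds."""
        return self.reading_end_index / self.sample_rate_hz

    @property
    def has_y(self) -> bool:
        return self.ly is not None


@dataclass
class PreparedSignal:
    """A single x-trace after eye averaging and trimming to active reading."""

    subject_id: str
    label: str
    x: np.ndarray
    original_length: int
    sample_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.x = _as_float_array("x", self.x)
        if len(self.x) != self.original_length:
            raise ValidationError("len(x) must equal original_length at creation")
        if self.original_length < 2:
            raise ValidationError("original_length must be >= 2")

    @property
    def reading_time_s(self) -> float:
        return self.original_length / self.sample_rate_hz


@dataclass
class ManifestEntry:
    subject_id: str
    label: str
    path: str
    reading_end_index: int
    sample_rate_hz: float = 100.0


@dataclass
class CohortManifest:
    """Index of a cohort: one entry per subject plus per-class counts."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.subject_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject_ids in a manifest must be unique")

    @property
    def n_hr(self) -> int:
        return sum(1 for e in self.entries if e.label == "HR")

    @property
    def n_lr(self) -> int:
        return sum(1 for e in self.entries if e.label == "LR")

    def __len__(self) -> int:
        return len(self.entries)

    def ids_by_label(self, label: str) -> list[str]:
        return [e.subject_id for e in self.entries if e.label == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": e.subject_id,
                    "label": e.label,
                    "path": e.path,
                    "reading_end_index": e.reading_end_index,
                    "sample_rate_hz": e.sample_rate_hz,
                }
                for e in self.entries
            ]
        )


_REQUIRED_COLS = ("t", "lx", "rx")


def read_recording(path: str, meta: ManifestEntry) -> Recording:
    """Read one per-subject CSV and return a validated :class:`Recording`."""
    if not os.path.exists(path):
        raise FormatError(f"recording file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df[["lx", "rx"]].isna().any().any():
        raise FormatError(f"{path}: ragged or missing x-trace values")
    has_y = "ly" in df.columns and "ry" in df.columns
    if has_y and df[["ly", "ry"]].isna().any().any():
        raise FormatError(f"{path}: ragged or missing y-trace values")
    return Recording(
        subject_id=meta.subject_id,
        label=meta.label,
        lx=df["lx"].to_numpy(),
        rx=df["rx"].to_numpy(),
        ly=df["ly"].to_numpy() if has_y else None,
        ry=df["ry"].to_numpy() if has_y else None,
        reading_end_index=meta.reading_end_index,
        sample_rate_hz=meta.sample_rate_hz,
    )


def write_cohort(cohort: list[Recording], directory: str) -> CohortManifest:
    """Write per-subject CSVs plus ``manifest.csv``; returns the manifest.

    Round-trips bit-for-bit for integer fields and within 1e-12 for floats
    (values are serialised with 17 significant digits).
    """
    if not cohort:
        raise ValidationError("cohort must be non-empty")
    ids = [r.subject_id for r in cohort]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate subject_id in cohort")
    os.makedirs(directory, exist_ok=True)
    entries = []
    for rec in cohort:
        fname = f"{rec.subject_id}.csv"
        t = np.arange(rec.n_samples) / rec.sample_rate_hz
        cols = {"t": t, "lx": rec.lx}
        if rec.has_y:
            cols["ly"] = rec.ly
        cols["rx"] = rec.rx
        if rec.has_y:
            cols["ry"] = rec.ry
        pd.DataFrame(cols).to_csv(
            os.path.join(directory, fname), index=False, float_format="%.17g"
        )
        entries.append(
            ManifestEntry(
                subject_id=rec.subject_id,
                label=rec.label,
                path=fname,
                reading_end_index=rec.reading_end_index,
                sample_rate_hz=rec.sample_rate_hz,
            )
        )
    manifest = CohortManifest(entries)
    manifest.to_frame().to_csv(os.path.join(directory, "manifest.csv"), index=False)
    return manifest


def read_manifest(path: str) -> CohortManifest:
    df = pd.read_csv(path)
    required = {"subject_id", "label", "path", "reading_end_index"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {sorted(missing)}")
    entries = [
        ManifestEntry(
            subject_id=str(row.subject_id),
            label=str(row.label),
            path=str(row.path),
            reading_end_index=int(row.reading_end_index),
            sample_rate_hz=float(getattr(row, "sample_rate_hz", 100.0)),
        )
        for row in df.itertuples(index=False)
    ]
    return CohortManifest(entries)


def read_cohort(directory: str) -> tuple[list[Recording], CohortManifest]:
    """Read ``manifest.csv`` in *directory* and every recording it lists."""
    manifest = read_manifest(os.path.join(directory, "manifest.csv"))
    cohort = [
        read_recording(os.path.join(directory, e.path), e) for e in manifest.entries
    ]
    return cohort, manifest


def manifest_from_cohort(cohort: list[Recording]) -> CohortManifest:
    """Build an in-memory manifest (empty paths) for an unwritten cohort."""
    return CohortManifest(
        [
            ManifestEntry(r.subject_id, r.label, "", r.reading_end_index, r.sample_rate_hz)
            for r in cohort
        ]
    )
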