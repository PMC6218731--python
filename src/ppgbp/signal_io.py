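"""Plain-text I/O for PPG segments, manifests and feature tables.

Waveforms are stored one sample per line; a CSV manifest pairs each waveform
file with its case identity, sampling rate and reference blood pressures.
Feature tables are CSV with one row per segment.  All formats are UTF-8 with
dot decimal separators, independent of locale.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Seconds per accepted segment.
SEGMENT_SECONDS = 5.0
#: Default sampling rate in Hz.
DEFAULT_RATE = 100.0

MANIFEST_COLUMNS = [
    "case_id",
    "segment_id",
    "waveform_path",
    "rate_hz",
    "ref_sbp_mmHg",
    "ref_dbp_mmHg",
]

FEATURE_COLUMNS = [
    "case_id",
    "segment_id",
    "area",
    "rising_time",
    "width_25",
    "width_50",
    "width_75",
    "ref_sbp",
    "ref_dbp",
]


class ManifestError(ValueError):
    """Malformed manifest or waveform file."""


class SegmentValidationError(ValueError):
    """Segment violates a structural invariant (e.g. wrong sample count)."""


@dataclass
class PPGSegment:
    """One 5 s PPG waveform with identity and reference blood pressures.

    Parameters
    ----------
    case_id, segment_id : str
        Recording/session identifiers; ``segment_id`` is unique per dataset.
    samples : ndarray
        Raw photodetector values (arbitrary units), finite.
    rate : float
        Sampling rate in Hz (default 100).
    ref_sbp, ref_dbp : float or None
        Reference systolic/diastolic pressure in mmHg; ``None`` when the
        monitor produced no reading for the segment.
    """

    case_id: str
    segment_id: str
    samples: np.ndarray
    rate: float = DEFAULT_RATE
    ref_sbp: float | None = None
    ref_dbp: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise SegmentValidationError(
                f"segment {self.segment_id!r}: rate must be positive, got {self.rate}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise SegmentValidationError(
                f"segment {self.segment_id!r}: samples contain non-finite values"
            )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @property
    def has_reference(self) -> bool:
        return self.ref_sbp is not None and self.ref_dbp is not None

    def validate_length(self) -> None:
        """Raise unless the segment holds exactly 5 s of samples."""
        expected = int(round(self.rate * SEGMENT_SECONDS))
        if len(self.samples) != expected:
            raise SegmentValidationError(
                f"segment {self.segment_id!r}: expected {expected} samples "
                f"({SEGMENT_SECONDS:g} s at {self.rate:g} Hz), got {len(self.samples)}"
            )


def _parse_optional_float(cell: str, *, line_no: int, path: os.PathLike) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        value = float(cell)
    except ValueError as exc:
        raise ManifestError(f"{path}, line {line_no}: cannot parse {cell!r} as a number") from exc
    if not math.isfinite(value):
        raise ManifestError(f"{path}, line {line_no}: non-finite value {cell!r}")
    return value


def read_waveform(path: str | os.PathLike) -> np.ndarray:
    """Read a one-sample-per-line waveform file."""
    values = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ManifestError(f"{path}, line {line_no}: bad sample {line!r}") from exc
    return np.asarray(values, dtype=float)


def write_waveform(samples: Sequence[float], path: str | os.PathLike) -> None:
    samples = np.asarray(samples, dtype=float)
    with open(path, "w", encoding="utf-8") as fh:
        for v in samples:
            fh.write(f"{v:.9g}\n")


def read_manifest(path: str | os.PathLike, *, validate_length: bool = True) -> list[PPGSegment]:
    """Read a CSV manifest and its referenced waveform files.

    Row order is preserved.  Empty reference-BP cells become ``None`` (missing,
    never zero).  A waveform whose sample count disagrees with 5 s at the
    declared rate raises :class:`SegmentValidationError` naming the segment.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    base = path.parent
    segments: list[PPGSegment] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = [c.strip() for c in header.split(",")]
        if cols != MANIFEST_COLUMNS:
            raise ManifestError(
                f"{path}, line 1: expected header {','.join(MANIFEST_COLUMNS)!r}, got {header!r}"
            )
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split(",")
            if len(cells) != len(MANIFEST_COLUMNS):
                raise ManifestError(
                    f"{path}, line {line_no}: expected {len(MANIFEST_COLUMNS)} fields, "
                    f"got {len(cells)}"
                )
            case_id, segment_id, wf_path, rate_cell, sbp_cell, dbp_cell = cells
            rate = _parse_optional_float(rate_cell, line_no=line_no, path=path)
            if rate is None:
                raise ManifestError(f"{path}, line {line_no}: rate_hz cell is empty")
            wf_file = base / wf_path.strip()
            if not wf_file.exists():
                raise ManifestError(f"{path}, line {line_no}: waveform file not found: {wf_file}")
            segment = PPGSegment(
                case_id=case_id.strip(),
                segment_id=segment_id.strip(),
                samples=read_waveform(wf_file),
                rate=rate,
                ref_sbp=_parse_optional_float(sbp_cell, line_no=line_no, path=path),
                ref_dbp=_parse_optional_float(dbp_cell, line_no=line_no, path=path),
            )
            if validate_length:
                segment.validate_length()
            segments.append(segment)
    return segments


def write_manifest(
    segments: Sequence[PPGSegment],
    manifest_path: str | os.PathLike,
    waveform_dir: str | os.PathLike | None = None,
) -> None:
    """Write segments as waveform files plus a CSV manifest.

    Waveform files land next to the manifest (or under ``waveform_dir``),
    named ``<segment_id>.txt``; manifest paths are stored relative to the
    manifest so the pair is relocatable.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    wf_dir = Path(waveform_dir) if waveform_dir is not None else base / "waveforms"
    wf_dir.mkdir(parents=True, exist_ok=True)
    with open(manifest_path, "w", encoding="utf-8") as fh:
        fh.write(",".join(MANIFEST_COLUMNS) + "\n")
        for seg in segments:
            wf_file = wf_dir / f"{seg.segment_id}.txt"
            write_waveform(seg.samples, wf_file)
            rel = os.path.relpath(wf_file, base)
            sbp = "" if seg.ref_sbp is None else f"{seg.ref_sbp:.9g}"
            dbp = "" if seg.ref_dbp is None else f"{seg.ref_dbp:.9g}"
            fh.write(f"{seg.case_id},{seg.segment_id},{rel},{seg.rate:.9g},{sbp},{dbp}\n")


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check feature-table invariants; return the table for chaining.

    Every morphology feature must lie in [0, 1] and widths must be ordered
    ``width_25 >= width_50 >= width_75`` row-wise.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise SegmentValidationError(f"feature table missing columns: {missing}")
    if len(table) == 0:
        return table
    feats = table[["area", "rising_time", "width_25", "width_50", "width_75"]].to_numpy(float)
    if not np.all(np.isfinite(feats)):
        raise SegmentValidationError("feature table contains non-finite feature values")
    if feats.min() < 0.0 or feats.max() > 1.0:
        raise SegmentValidationError("feature values outside [0, 1]")
    w = table[["width_25", "width_50", "width_75"]].to_numpy(float)
    bad = ~((w[:, 0] >= w[:, 1] - 1e-12) & (w[:, 1] >= w[:, 2] - 1e-12))
    if bad.any():
        ids = table.loc[bad, "segment_id"].tolist()[:5]
        raise SegmentValidationError(f"width ordering violated for segments {ids}")
    return table


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_feature_table(table)
    table = table[FEATURE_COLUMNS]
    table.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"case_id": str, "segment_id": str})
    return validate_feature_table(table)
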