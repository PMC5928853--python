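"""Reading and writing PPG record datasets.

On-disk layout: one plain-text sample file per record (ASCII numeric tokens
separated by any whitespace) plus a UTF-8 manifest CSV with the exact header

    subject_id,segment_id,file,fs,label

``file`` is relative to the data directory; ``label`` may be empty for
unlabeled records.  The round trip ``read_records(write_records(R))`` is
lossless for samples (text floats with 17 significant digits), sampling
rates, identities, and labels, and preserves manifest row order.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

from .records import PPGRecord, QUALITY_LABELS, UNLABELED

__all__ = ["MANIFEST_COLUMNS", "read_records", "write_records"]

MANIFEST_COLUMNS = ("subject_id", "segment_id", "file", "fs", "label")

PathLike = Union[str, Path]


class ManifestError(ValueError):
    """Raised when the manifest CSV is malformed."""


class SampleFileError(ValueError):
    """Raised when a sample file contains a non-numeric token."""


def _read_sample_file(path: Path) -> np.ndarray:
    """Parse a whitespace-separated numeric text file into a float vector.

    Reports the 1-based position of the first unparseable token so that a
    corrupted file can be located by hand.
    """
    text = path.read_text()
    tokens = text.split()
    values = np.empty(len(tokens), dtype=float)
    for i, tok in enumerate(tokens):
        try:
            values[i] = float(tok)
        except ValueError:
            raise SampleFileError(
                f"non-numeric token {tok!r} at position {i + 1} in {path}"
            ) from None
    return values


def read_records(manifest_path: PathLike, data_dir: PathLike | None = None) -> List[PPGRecord]:
    """Load every record listed in a manifest CSV, in row order.

    Parameters
    ----------
    manifest_path : path
        CSV with header exactly ``subject_id,segment_id,file,fs,label``.
    data_dir : path, optional
        Directory sample-file paths are relative to; defaults to the
        manifest's own directory.

    Returns
    -------
    list of PPGRecord
        One record per manifest row.  An empty ``label`` cell maps to
        ``"unlabeled"``.

    Raises
    ------
    ManifestError
        Malformed header, non-positive ``fs``, or unknown label.
    FileNotFoundError
        A referenced sample file is missing (the message names the row).
    SampleFileError
        A sample file contains a non-numeric token.
    """
    manifest_path = Path(manifest_path)
    base = Path(data_dir) if data_dir is not None else manifest_path.parent

    df = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    if tuple(df.columns) != MANIFEST_COLUMNS:
        raise ManifestError(
            f"manifest header must be {','.join(MANIFEST_COLUMNS)!r}, "
            f"got {','.join(df.columns)!r} in {manifest_path}"
        )

    records: List[PPGRecord] = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        try:
            fs = float(row.fs)
        except ValueError:
            raise ManifestError(
                f"row {row_num} of {manifest_path}: fs {row.fs!r} is not numeric"
            ) from None
        if fs <= 0:
            raise ManifestError(f"row {row_num} of {manifest_path}: fs must be > 0, got {fs}")
        label = row.label.strip() or UNLABELED
        if label not in QUALITY_LABELS and label != UNLABELED:
            raise ManifestError(
                f"row {row_num} of {manifest_path}: unknown label {row.label!r}"
            )
        sample_path = base / row.file
        if not sample_path.is_file():
            raise FileNotFoundError(
                f"row {row_num} of {manifest_path}: sample file {sample_path} not found"
            )
        samples = _read_sample_file(sample_path)
        records.append(
            PPGRecord(
                samples=samples,
                fs=fs,
                subject_id=row.subject_id,
                segment_id=row.segment_id,
                label=label,
            )
        )
    return records


def write_records(
    records: Sequence[PPGRecord],
    out_dir: PathLike,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write records as per-record text files plus a manifest CSV.

    Sample values are written one per line with 17 significant digits, which
    round-trips IEEE doubles exactly.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / manifest_name

    used_names: set = set()
    rows = []
    for i, rec in enumerate(records):
        stem = f"{rec.subject_id}_{rec.segment_id}".strip("_") or f"record{i:04d}"
        name = f"{stem}.txt"
        if name in used_names:  # ids are not required to be unique
            name = f"{stem}_{i:04d}.txt"
        used_names.add(name)
        np.savetxt(out_dir / name, rec.samples, fmt="%.17g")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "segment_id": rec.segment_id,
                "file": name,
                "fs": repr(rec.fs) if rec.fs != int(rec.fs) else str(int(rec.fs)),
                "label": "" if rec.label == UNLABELED else rec.label,
            }
        )

    with manifest_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(MANIFEST_COLUMNS))
        writer.writeheader()
        writer.writerows(rows)
    return manifest_path
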