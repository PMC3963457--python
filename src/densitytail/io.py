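"""File I/O and run manifests.

Pinned CSV dialect: comma separator, "." decimal, UTF-8, header row
required, no index column.  All floating-point output round-trips through
the readers at full double precision (pandas writes with repr-level
precision via float_format=None and reads with the default C parser).
"""

from __future__ import annotations

import csv
import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputFormatError
from .image import EmpiricalImageDF, ImageSample

__all__ = [
    "read_observations",
    "write_observations",
    "read_image_sample",
    "write_image_sample",
    "write_empirical_df",
    "write_manifest",
    "file_sha256",
]


def read_observations(path) -> pd.DataFrame:
    """Observation matrix CSV with a header row; every row checked for raggedness."""
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"input file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise InputFormatError(f"{path}: empty file") from None
        width = len(header)
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width:
                raise InputFormatError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} fields, header has {width})"
                )
            rows.append(row)
    frame = pd.DataFrame(rows, columns=[h.strip() for h in header])
    for col in frame.columns:
        if col == "label":
            continue
        try:
            frame[col] = frame[col].astype(float)
        except ValueError as exc:
            raise InputFormatError(f"{path}: non-numeric value in column {col!r}: {exc}") from exc
    return frame


def write_observations(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def write_image_sample(sample: ImageSample, path) -> None:
    """Single-column CSV with header 'density', plus a JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"density": sample.values}).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(
            {"y_max": sample.y_max, "n": len(sample), "fingerprint": sample.fingerprint},
            fh,
            indent=1,
        )


def read_image_sample(path) -> ImageSample:
    path = Path(path)
    frame = read_observations(path)
    if list(frame.columns) != ["density"]:
        raise InputFormatError(f"{path}: expected a single 'density' column")
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            meta = json.load(fh)
        y_max = float(meta["y_max"])
        fingerprint = meta.get("fingerprint")
    else:
        y_max = float(frame["density"].max())
        fingerprint = None
    return ImageSample(frame["density"].to_numpy(), y_max, fingerprint=fingerprint)


def write_empirical_df(df: EmpiricalImageDF, path) -> None:
    path = Path(path)
    pd.DataFrame({"sorted_value": df.sorted_values}).to_csv(path, index=False)
    with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
        json.dump({"n": df.n}, fh)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, inputs: dict, config: dict) -> Path:
    """Record the resolved run configuration and input hashes for reproducibility."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "inputs": {name: file_sha256(p) for name, p in inputs.items() if Path(p).exists()},
        "config": config,
        "versions": {
            "densitytail": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path
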