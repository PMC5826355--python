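"""File formats: NIfTI volumes, TCK tractograms, TSV tables, JSON.

The TCK reader/writer implements the minimal core of the MRtrix track
format (Float32LE triplets, NaN-separated streamlines, Inf terminator)
sufficient for round-tripping the toy bundles; coordinates are stored
as-is (this package keeps streamlines in voxel space, 0-based,
corner-origin, and documents that convention in the header).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "save_volume",
    "load_volume",
    "write_tck",
    "read_tck",
    "write_table",
    "read_table",
    "write_json",
]


def save_volume(data: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    """Write a float32 NIfTI with the given (default identity) affine."""
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float32), img.affine


def write_tck(streamlines: list[np.ndarray], path: str | Path) -> None:
    """Minimal MRtrix .tck writer (Float32LE)."""
    header_lines = [
        "mrtrix tracks",
        "datatype: Float32LE",
        f"count: {len(streamlines)}",
        "coordinate_space: voxel (0-based, corner origin)",
    ]
    # the offset field's own digits contribute to the header length
    base = "\n".join(header_lines) + "\nfile: . "
    tail = "\nEND\n"
    for digits in range(1, 9):
        offset = len(base) + digits + len(tail)
        if len(str(offset)) == digits:
            break
    else:
        raise RuntimeError("could not settle tck header offset")
    text = base + str(offset) + tail
    with open(path, "wb") as fh:
        fh.write(text.encode("ascii"))
        for line in streamlines:
            arr = np.asarray(line, dtype="<f4")
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError("streamlines must be (n, 3) arrays")
            fh.write(arr.tobytes())
            fh.write(np.full((1, 3), np.nan, dtype="<f4").tobytes())
        fh.write(np.full((1, 3), np.inf, dtype="<f4").tobytes())


def read_tck(path: str | Path) -> list[np.ndarray]:
    raw = Path(path).read_bytes()
    end = raw.find(b"END\n")
    if not raw.startswith(b"mrtrix tracks") or end < 0:
        raise ValueError(f"{path} is not a tck file")
    header = raw[:end].decode("ascii")
    fields = dict(
        line.split(": ", 1) for line in header.splitlines() if ": " in line
    )
    if fields.get("datatype") != "Float32LE":
        raise ValueError("only Float32LE tck supported")
    offset = int(fields["file"].split()[-1])
    data = np.frombuffer(raw[offset:], dtype="<f4").reshape(-1, 3)
    streamlines: list[np.ndarray] = []
    current: list[np.ndarray] = []
    for row in data:
        if np.isinf(row).all():
            break
        if np.isnan(row).any():
            if current:
                streamlines.append(np.array(current))
                current = []
        else:
            current.append(row.astype(float))
    if current:
        streamlines.append(np.array(current))
    return streamlines


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """UTF-8 TSV, header row, '.' decimal separator."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
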