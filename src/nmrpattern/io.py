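"""Readers and writers for the package's plain-text formats.

Spectra travel as two-column CSV (``ppm,intensity``) or a minimal JCAMP-DX
subset (``##XUNITS=PPM``, ``##XYDATA=(X++(Y..Y))`` with AFFN numbers only).
Bucket tables are CSV with a JSON sidecar holding the bin edges; partitions
and model summaries are JSON.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .synthetic import Spectrum

if TYPE_CHECKING:  # pragma: no cover
    from .preprocess import BucketTable, Partition

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_jcamp",
    "read_labels_csv",
    "write_bucket_table",
    "read_bucket_table",
    "write_partition",
    "read_partition",
]


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """Two-column CSV with a header line; 6 significant digits."""
    with open(path, "w") as fh:
        fh.write("ppm,intensity\n")
        for x, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{x:.6g},{y:.6g}\n")


def read_spectrum_csv(path: str | Path, sample_id: str | None = None, label: str = "") -> Spectrum:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    sid = sample_id if sample_id is not None else Path(path).stem
    return Spectrum(
        ppm=df.iloc[:, 0].to_numpy(dtype=float),
        intensity=df.iloc[:, 1].to_numpy(dtype=float),
        sample_id=sid,
        label=label,
    )


_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def read_jcamp(path: str | Path, sample_id: str | None = None, label: str = "") -> Spectrum:
    """Minimal JCAMP-DX reader.

    Supports only the dialect this package writes and tests: single block,
    ``##XUNITS=PPM``, AFFN-encoded ``##XYDATA=(X++(Y..Y))`` where each data
    line starts with an X value followed by evenly spaced Y values.  XFACTOR
    and YFACTOR default to 1.
    """
    header: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "XYDATA":
                if "(X++(Y..Y))" not in val.replace(" ", ""):
                    raise ValueError(f"{path}: unsupported XYDATA form {val!r}")
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            header[key] = val
        elif in_data:
            data_lines.append(line)
    if header.get("XUNITS", "").upper() != "PPM":
        raise ValueError(f"{path}: ##XUNITS must be PPM")
    if not data_lines:
        raise ValueError(f"{path}: no XYDATA block found")
    xfactor = float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))

    # Each line: X Y1 Y2 ... — Y values sit on an even grid starting at X.
    starts: list[float] = []
    ys: list[list[float]] = []
    for line in data_lines:
        nums = [float(m) for m in _NUM.findall(line)]
        if len(nums) < 2:
            raise ValueError(f"{path}: malformed XYDATA line {line!r}")
        starts.append(nums[0] * xfactor)
        ys.append([v * yfactor for v in nums[1:]])
    n_total = sum(len(v) for v in ys)
    if "FIRSTX" in header and "LASTX" in header:
        firstx = float(header["FIRSTX"]) * xfactor
        lastx = float(header["LASTX"]) * xfactor
    else:
        firstx = starts[0]
        if len(starts) < 2:
            raise ValueError(f"{path}: cannot infer grid spacing from a single line without FIRSTX/LASTX")
        step = (starts[1] - starts[0]) / len(ys[0])
        lastx = firstx + step * (n_total - 1)
    ppm = np.linspace(firstx, lastx, n_total)
    intensity = np.concatenate([np.asarray(v) for v in ys])
    sid = sample_id if sample_id is not None else Path(path).stem
    return Spectrum(ppm=ppm, intensity=intensity, sample_id=sid, label=label)


def read_labels_csv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["sample_id"].astype(str), df["label"].astype(str)))


def write_bucket_table(table: "BucketTable", path: str | Path) -> None:
    """CSV (sample_id, label, V1..Vn) plus an ``.edges.json`` sidecar."""
    path = Path(path)
    df = table.to_dataframe()
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".edges.json")
    with open(sidecar, "w") as fh:
        json.dump(
            {"variable_names": list(table.variable_names),
             "bucket_edges": [[lo, hi] for lo, hi in table.bucket_edges]},
            fh,
        )


def read_bucket_table(path: str | Path) -> "BucketTable":
    from .preprocess import BucketTable

    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".edges.json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    names = list(meta["variable_names"])
    values = df[names].to_numpy(dtype=float)
    return BucketTable(
        values=values,
        bucket_edges=[(float(lo), float(hi)) for lo, hi in meta["bucket_edges"]],
        variable_names=names,
        sample_ids=list(df["sample_id"].astype(str)),
        labels=list(df["label"].astype(str)),
    )


def write_partition(partition: "Partition", path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "train_indices": [int(i) for i in partition.train_indices],
                "test_indices": [int(i) for i in partition.test_indices],
                "stratum_counts": {k: [int(a), int(b)] for k, (a, b) in partition.stratum_counts.items()},
                "seed": int(partition.seed),
            },
            fh,
        )


def read_partition(path: str | Path) -> "Partition":
    from .preprocess import Partition

    with open(path) as fh:
        d = json.load(fh)
    return Partition(
        train_indices=np.asarray(d["train_indices"], dtype=int),
        test_indices=np.asarray(d["test_indices"], dtype=int),
        stratum_counts={k: (int(a), int(b)) for k, (a, b) in d["stratum_counts"].items()},
        seed=int(d["seed"]),
    )
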