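"""Readers and writers for the pipeline's text artifacts.

Tables are RFC-4180 CSV with a header row; matrices are tab-separated text
with a parcel-id header line (floats printed at 17 significant digits, so a
write/read round trip is exact); the parcellation map is 3-column TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_FLOAT_FMT = "%.17g"


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("cohort table must contain a 'subject_id' column")
    return df


def write_matrix(matrix: np.ndarray, path, parcel_ids=None) -> None:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D")
    ids = (
        list(parcel_ids)
        if parcel_ids is not None
        else [f"p{i:04d}" for i in range(m.shape[0])]
    )
    if len(ids) != m.shape[0]:
        raise ValueError("parcel_ids length must match matrix rows")
    with open(path, "w") as fh:
        fh.write("\t".join(ids) + "\n")
        for row in m:
            fh.write("\t".join(_FLOAT_FMT % v for v in row) + "\n")


def read_matrix(path, symmetric: bool = False):
    """Returns (parcel_ids, matrix); optionally enforces symmetry."""
    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    m = np.array([[float(v) for v in row] for row in rows])
    if m.shape[0] != len(ids):
        raise ValueError(
            f"matrix file {path}: {len(ids)} header ids but {m.shape[0]} rows"
        )
    if symmetric:
        if m.shape[0] != m.shape[1] or not np.array_equal(m, m.T):
            raise ValueError(f"matrix file {path} is not symmetric")
    return ids, m


def write_map(pmap: pd.DataFrame, path) -> None:
    pmap[["parcel_id", "network", "hemisphere"]].to_csv(path, sep="\t", index=False)


def read_map(path) -> pd.DataFrame:
    pmap = pd.read_csv(path, sep="\t")
    required = {"parcel_id", "network", "hemisphere"}
    missing = required - set(pmap.columns)
    if missing:
        raise ValueError(f"parcellation map missing columns: {sorted(missing)}")
    return pmap


def check_map_covers(parcel_ids, pmap: pd.DataFrame) -> None:
    known = set(pmap["parcel_id"].astype(str))
    for p in parcel_ids:
        if str(p) not in known:
            raise KeyError(f"parcel {p!r} missing from parcellation map")


def timeseries_path(outdir, subject_id: str, run: int) -> Path:
    return Path(outdir) / f"{subject_id}_run-{run}.tsv"
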