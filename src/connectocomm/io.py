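"""Delimited-text I/O for matrices, coordinates and phenotype tables."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _sniff_delim(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def load_matrix(path) -> np.ndarray:
    """Dense square numeric matrix from a comma- or tab-delimited file with
    an optional single header row of region labels.  NaN entries are
    rejected."""
    delim = _sniff_delim(path)
    df = pd.read_csv(path, sep=delim, header=None)
    # header row: first row non-numeric
    if df.iloc[0].apply(lambda v: isinstance(v, str)
                        and not _is_number(v)).any():
        df = df.iloc[1:].reset_index(drop=True)
    arr = df.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{path}: matrix is not square {arr.shape}")
    if np.isnan(arr).any():
        raise ValueError(f"{path}: NaN entries forbidden")
    return arr


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def save_matrix(path, M: np.ndarray, delim: str = "\t") -> None:
    np.savetxt(path, np.asarray(M, dtype=float), delimiter=delim, fmt="%.10g")


def load_coords(path) -> pd.DataFrame:
    """Coordinate table with columns region_id, x, y, z, hemisphere."""
    df = pd.read_csv(path, sep=_sniff_delim(path))
    required = {"region_id", "x", "y", "z", "hemisphere"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return df


def save_coords(path, coords: pd.DataFrame) -> None:
    coords.to_csv(path, sep="\t", index=False)


def load_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sniff_delim(path))


def save_phenotypes(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
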