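"""File I/O: multi-page TIFF stacks, label masks and CSV tables.

TIFF handling goes through tifffile; only 8/16-bit unsigned stacks are
accepted (the camera model is integer counts). CSV is the single tabular
interchange format; round trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["read_stack", "write_stack", "read_table", "write_table"]

_ALLOWED = (np.uint8, np.uint16)


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF as a (frames, rows, cols) array."""
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # corrupt/truncated file: surface the page info
        raise IOError(f"failed to parse TIFF {path}: {exc}") from exc
    if arr.dtype not in [np.dtype(t) for t in _ALLOWED]:
        raise ValueError(f"{path}: unsupported bit depth {arr.dtype}; expected uint8/uint16")
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack(array: np.ndarray, path) -> None:
    array = np.asarray(array)
    if array.dtype not in [np.dtype(t) for t in _ALLOWED]:
        raise ValueError(f"refusing to write {array.dtype}; convert to uint8/uint16 first")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, array, photometric="minisblack")


def write_table(records, path) -> None:
    """Write records (DataFrame or list of dicts) as UTF-8 CSV with header."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
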