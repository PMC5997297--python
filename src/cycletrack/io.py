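"""File I/O: multi-page TIFF stacks, CSV tables, run manifests.

All tables are comma-separated UTF-8 with a header row and '.' decimals;
label masks are written as 16-bit multi-page TIFFs (one page per frame).
Floats round-trip at full precision (written via repr).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (T, H, W) stack as a multi-page TIFF."""
    tifffile.imwrite(Path(path), np.asarray(stack))


def read_stack(path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_labels(path, labels: np.ndarray) -> None:
    """Write integer label masks as 16-bit TIFF (error above 65535 labels)."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise InputError("more than 65535 labels cannot round-trip in uint16")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_labels(path) -> np.ndarray:
    return read_stack(path).astype(np.int32)


def write_table(path, df: pd.DataFrame) -> None:
    """CSV with full-precision floats (repr round-trip)."""
    df.to_csv(Path(path), index=False, float_format=None)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_manifest(path, entries: dict) -> None:
    """Flat key=value manifest (sorted keys) for reproducibility records."""
    lines = [f"{k}={v}" for k, v in sorted(entries.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_manifest(path) -> dict:
    out = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            k, _, v = line.partition("=")
            out[k] = v
    return out
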