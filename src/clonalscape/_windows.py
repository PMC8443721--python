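"""Shared non-overlapping genomic window tiling (1-based, inclusive)."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def tile_windows(chrom_lengths: Sequence[tuple[str, int]], span: int) -> pd.DataFrame:
    """Tile each chromosome from position 1 with non-overlapping windows.

    The trailing window keeps its true (possibly shorter) span. Returns a
    frame with columns chrom, start, end, span (end inclusive, 1-based).
    """
    if span <= 0:
        raise ValueError("span must be positive")
    rows = []
    for chrom, length in chrom_lengths:
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        starts = np.arange(1, length + 1, span, dtype=np.int64)
        ends = np.minimum(starts + span - 1, length)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e), int(e - s + 1)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "span"])


def assign_windows(windows: pd.DataFrame, chrom: np.ndarray,
                   pos: np.ndarray) -> np.ndarray:
    """Window row index for each site (-1 if the site falls outside tiling)."""
    out = np.full(len(pos), -1, dtype=np.int64)
    for c, grp in windows.groupby("chrom", sort=False):
        mask = chrom == c
        if not mask.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = np.searchsorted(starts, pos[mask], side="right") - 1
        ok = (idx >= 0) & (pos[mask] <= ends[np.clip(idx, 0, len(ends) - 1)])
        rows = grp.index.to_numpy()[np.clip(idx, 0, len(ends) - 1)]
        out[np.where(mask)[0][ok]] = rows[ok]
    return out


def infer_chrom_lengths(chrom: np.ndarray, pos: np.ndarray) -> list[tuple[str, int]]:
    """Chromosome lengths inferred as the last observed position."""
    lengths = []
    for c in pd.unique(np.asarray(chrom, dtype=object)):
        lengths.append((c, int(pos[chrom == c].max())))
    return lengths
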