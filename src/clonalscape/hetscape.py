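"""Heterozygosity landscape: site/window het-genotype frequency and LCHRs.

A clonal population accumulates somatic mutations that are carried as
heterozygous genotypes by a minority of ramets (low-frequency class, het
carrier frequency <= 0.10), while founder heterozygosity is clonally fixed
and carried by nearly all individuals (high-frequency class, >= 0.90). The
window-level track (200-kb tiles) defines long continuous heterozygous
regions (LCHRs): maximal runs of windows whose mean site-level frequency
stays above mean+SD (high) or below mean-SD (low) for more than 5 Mb.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._windows import assign_windows, infer_chrom_lengths, tile_windows
from .genotype_io import GenotypeMatrix

__all__ = [
    "site_het_frequency",
    "classify_het_class",
    "window_het_frequency",
    "het_thresholds",
    "detect_lchr",
    "individual_het_stats",
    "HetThresholds",
]

DEFAULT_WINDOW_SPAN = 200_000
DEFAULT_MIN_RUN_BP = 5_000_000
LOW_MAX = 0.10
HIGH_MIN = 0.90


def site_het_frequency(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-site heterozygous-genotype carrier frequency.

    ``h = n_het / n_called``; sites with no called genotype get ``h = NaN``.
    """
    n_het = (g.calls == 1).sum(axis=1)
    n_called = (g.calls >= 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    return pd.DataFrame({"chrom": g.chrom, "pos": g.pos,
                         "n_het": n_het, "n_called": n_called, "h": h})


def classify_het_class(h: np.ndarray | float, low_max: float = LOW_MAX,
                       high_min: float = HIGH_MIN) -> np.ndarray:
    """Label sites low / high / intermediate by het carrier frequency.

    Boundaries are inclusive: "no more than 10%" -> low at h == 0.10, "no
    less than 90%" -> high at h == 0.90. Undefined h labels as "undefined".
    """
    h = np.atleast_1d(np.asarray(h, dtype=float))
    out = np.full(h.shape, "intermediate", dtype=object)
    out[h <= low_max] = "low"
    out[h >= high_min] = "high"
    out[np.isnan(h)] = "undefined"
    return out


def window_het_frequency(site_stats: pd.DataFrame,
                         span: int = DEFAULT_WINDOW_SPAN,
                         chrom_lengths: Sequence[tuple[str, int]] | None = None,
                         ) -> pd.DataFrame:
    """Mean site-level het frequency in non-overlapping windows.

    The window value is the unweighted mean of per-site ``h`` over SNP sites
    in the window; windows without sites carry ``NaN`` and are excluded from
    downstream mean/SD and break LCHR runs.
    """
    chrom = site_stats["chrom"].to_numpy(dtype=object)
    pos = site_stats["pos"].to_numpy()
    if chrom_lengths is None:
        chrom_lengths = infer_chrom_lengths(chrom, pos)
    windows = tile_windows(chrom_lengths, span)
    widx = assign_windows(windows, chrom, pos)
    h = site_stats["h"].to_numpy(dtype=float)
    ok = (widx >= 0) & ~np.isnan(h)
    sums = np.bincount(widx[ok], weights=h[ok], minlength=len(windows))
    counts = np.bincount(widx[ok], minlength=len(windows))
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    track = windows.copy()
    track["value"] = value
    track["n_sites"] = counts
    return track


class HetThresholds(NamedTuple):
    t_high: float
    t_low: float
    mean: float
    sd: float


def het_thresholds(track: pd.DataFrame) -> HetThresholds:
    """mean +/- one SD of the defined window values (sample SD, ddof=1)."""
    vals = track["value"].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise ValueError("need at least 2 defined windows for thresholds")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return HetThresholds(mean + sd, mean - sd, mean, sd)


def detect_lchr(track: pd.DataFrame, t_high: float, t_low: float,
                min_run_bp: int = DEFAULT_MIN_RUN_BP) -> pd.DataFrame:
    """Call long continuous high/low heterozygosity regions.

    Maximal runs of consecutive defined windows with value > ``t_high``
    (class "high") or value < ``t_low`` (class "low"); an undefined window
    breaks a run. A run qualifies when its summed span is strictly greater
    than ``min_run_bp``. Returns chrom, start, end, cls, length, n_windows.
    """
    out = []
    for _, grp in track.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        vals = grp["value"].to_numpy(dtype=float)
        state = np.full(len(vals), "none", dtype=object)
        state[vals > t_high] = "high"
        state[vals < t_low] = "low"
        state[np.isnan(vals)] = "none"
        i = 0
        while i < len(vals):
            if state[i] == "none":
                i += 1
                continue
            j = i
            while j + 1 < len(vals) and state[j + 1] == state[i]:
                j += 1
            start = int(grp["start"].iloc[i])
            end = int(grp["end"].iloc[j])
            length = int(grp["span"].iloc[i:j + 1].sum())
            if length > min_run_bp:
                out.append((grp["chrom"].iloc[i], start, end, state[i],
                            length, j - i + 1))
            i = j + 1
    df = pd.DataFrame(out, columns=["chrom", "start", "end", "cls",
                                    "length", "n_windows"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def individual_het_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample heterozygosity among that sample's own variant loci.

    ``het_fraction = n_het / (n_het + n_hom_alt)`` and
    ``het_hom_ratio = n_het / n_hom_alt`` (inf when a sample has no hom-alt
    call; both NaN when a sample has no variant locus at all).
    """
    n_het = (g.calls == 1).sum(axis=0).astype(float)
    n_hom_alt = (g.calls == 2).sum(axis=0).astype(float)
    denom = n_het + n_hom_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, n_het / np.maximum(denom, 1), np.nan)
        ratio = np.where(n_hom_alt > 0, n_het / np.maximum(n_hom_alt, 1),
                         np.where(n_het > 0, np.inf, np.nan))
    return pd.DataFrame({"sample_id": g.sample_ids,
                         "n_het": n_het.astype(int),
                         "n_hom_alt": n_hom_alt.astype(int),
                         "het_fraction": frac,
                         "het_hom_ratio": ratio})
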