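"""Windowed diversity and differentiation statistics, DAF, and region calls.

Statistics follow the usual windowed conventions: per-bp theta_pi and
Watterson's theta_w use the fixed window span as denominator (not the number
of callable bases), Tajima's D uses the 1989 constants with the window's
modal called-allele count, and F_ST is the Weir & Cockerham (1984) estimator
combined across sites in a window as a ratio of sums (sum a / sum(a+b+c)).
Derived allele frequencies are polarized by a single outgroup sample whose
homozygous genotypes define the ancestral allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._windows import assign_windows, infer_chrom_lengths, tile_windows
from .genotype_io import GenotypeMatrix

__all__ = [
    "window_theta_pi",
    "window_theta_w",
    "window_tajimas_d",
    "window_fst",
    "site_fst_components",
    "polarize_and_daf",
    "top_quantile_regions",
    "genes_overlapping_regions",
    "tajimas_d_from_counts",
    "ScoreRegions",
]

DEFAULT_SPAN = 100_000


# ---------------------------------------------------------------------------
# per-site building blocks

def _site_pi(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site heterozygosity contribution and called allele count k.

    pi_site = c_ref * c_alt / C(k, 2): the probability that two alleles
    drawn without replacement differ. Sites with k < 2 return pi = 0, k as
    observed.
    """
    called = calls >= 0
    k = 2 * called.sum(axis=1)
    alt = np.where(called, calls, 0).sum(axis=1)
    ref = k - alt
    pairs = k * (k - 1) / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(pairs > 0, ref * alt / np.maximum(pairs, 1), 0.0)
    return pi, k


def _harmonic(n: np.ndarray | int) -> np.ndarray:
    """a_n = sum_{i=1}^{n} 1/i, elementwise, a_0 = 0."""
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    top = int(n.max(initial=0))
    cum = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, top + 1))]) \
        if top > 0 else np.array([0.0])
    return cum[np.clip(n, 0, top)]


def _window_frame(g: GenotypeMatrix, span: int,
                  chrom_lengths: Sequence[tuple[str, int]] | None
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    if chrom_lengths is None:
        chrom_lengths = infer_chrom_lengths(g.chrom, g.pos)
    windows = tile_windows(chrom_lengths, span)
    widx = assign_windows(windows, g.chrom, g.pos)
    return windows, widx


def window_theta_pi(g: GenotypeMatrix, span: int = DEFAULT_SPAN,
                    chrom_lengths: Sequence[tuple[str, int]] | None = None
                    ) -> pd.DataFrame:
    """Pairwise nucleotide diversity per bp in non-overlapping windows."""
    windows, widx = _window_frame(g, span, chrom_lengths)
    pi, k = _site_pi(g.calls)
    ok = (widx >= 0) & (k >= 2)
    seg = pi > 0
    track = windows.copy()
    track["theta_pi"] = np.bincount(widx[ok], weights=pi[ok],
                                    minlength=len(windows)) / track["span"]
    track["n_snps"] = np.bincount(widx[ok & seg], minlength=len(windows))
    return track


def window_theta_w(g: GenotypeMatrix, span: int = DEFAULT_SPAN,
                   chrom_lengths: Sequence[tuple[str, int]] | None = None
                   ) -> pd.DataFrame:
    """Watterson's theta per bp: sum over segregating sites of 1/a_(k-1)."""
    windows, widx = _window_frame(g, span, chrom_lengths)
    pi, k = _site_pi(g.calls)
    seg = (pi > 0) & (k >= 2)
    a = _harmonic(np.maximum(k - 1, 0))
    contrib = np.zeros(g.n_sites)
    contrib[seg] = 1.0 / a[seg]
    ok = (widx >= 0) & seg
    track = windows.copy()
    track["theta_w"] = np.bincount(widx[ok], weights=contrib[ok],
                                   minlength=len(windows)) / track["span"]
    track["n_snps"] = np.bincount(widx[ok], minlength=len(windows))
    return track


def tajimas_d_from_counts(S: int, pi_sum: float, k: int) -> float:
    """Tajima's (1989) D from segregating sites, summed pi and allele count."""
    if S < 1 or k < 4:
        return float("nan")
    n = k
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((pi_sum - S / a1) / np.sqrt(var))


def window_tajimas_d(g: GenotypeMatrix, span: int = DEFAULT_SPAN,
                     chrom_lengths: Sequence[tuple[str, int]] | None = None
                     ) -> pd.DataFrame:
    """Tajima's D per window (NaN when S = 0 or fewer than 4 called alleles).

    The window uses its modal per-site called-allele count for the constants.
    """
    windows, widx = _window_frame(g, span, chrom_lengths)
    pi, k = _site_pi(g.calls)
    seg = (pi > 0) & (k >= 2)
    d_vals = np.full(len(windows), np.nan)
    s_counts = np.zeros(len(windows), dtype=int)
    for w in range(len(windows)):
        sel = (widx == w) & seg
        S = int(sel.sum())
        s_counts[w] = S
        if S == 0:
            continue
        kk = k[sel]
        modal_k = int(pd.Series(kk).mode().iloc[0])
        d_vals[w] = tajimas_d_from_counts(S, float(pi[sel].sum()), modal_k)
    track = windows.copy()
    track["tajima_d"] = d_vals
    track["n_snps"] = s_counts
    return track


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST

def site_fst_components(g: GenotypeMatrix, pop_labels: Sequence[str]
                        ) -> pd.DataFrame:
    """Per-site Weir & Cockerham (1984) variance components a, b, c.

    Components follow the r-population genotype formulation with the
    observed heterozygote correction; per-site F_ST is a/(a+b+c) and a
    multi-site estimate should use ratio-of-sums.
    """
    pops = np.asarray(pop_labels)
    if len(pops) != g.n_samples:
        raise ValueError("pop_labels must have one label per sample")
    labels = pd.unique(pops)
    r = len(labels)
    if r < 2:
        raise ValueError("need >= 2 populations")

    called = g.calls >= 0
    n_i = np.stack([called[:, pops == l].sum(axis=1) for l in labels], axis=1).astype(float)
    alt_i = np.stack([np.where(called, g.calls, 0)[:, pops == l].sum(axis=1)
                      for l in labels], axis=1).astype(float)
    het_i = np.stack([(g.calls[:, pops == l] == 1).sum(axis=1)
                      for l in labels], axis=1).astype(float)

    valid = (n_i >= 1).all(axis=1) & (n_i.sum(axis=1) > r)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = alt_i / (2 * np.maximum(n_i, 1))
        h_i = het_i / np.maximum(n_i, 1)
        n_sum = n_i.sum(axis=1)
        nbar = n_sum / r
        nc = (n_sum - (n_i ** 2).sum(axis=1) / n_sum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=1) / n_sum
        s2 = (n_i * (p_i - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=1) / n_sum

        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    for arr in (a, b, c):
        arr[~valid] = np.nan
    return pd.DataFrame({"chrom": g.chrom, "pos": g.pos,
                         "a": a, "b": b, "c": c})


def window_fst(g: GenotypeMatrix, pop_labels: Sequence[str],
               span: int = DEFAULT_SPAN,
               chrom_lengths: Sequence[tuple[str, int]] | None = None
               ) -> pd.DataFrame:
    """Weighted (ratio-of-sums) Weir-Cockerham F_ST per window.

    Windows with no polymorphic testable site are NaN.
    """
    windows, widx = _window_frame(g, span, chrom_lengths)
    comp = site_fst_components(g, pop_labels)
    a = comp["a"].to_numpy()
    b = comp["b"].to_numpy()
    c = comp["c"].to_numpy()
    denom_site = a + b + c
    ok = (widx >= 0) & ~np.isnan(denom_site) & (denom_site != 0)
    num = np.bincount(widx[ok], weights=a[ok], minlength=len(windows))
    den = np.bincount(widx[ok], weights=denom_site[ok], minlength=len(windows))
    n = np.bincount(widx[ok], minlength=len(windows))
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den != 0, num / np.where(den == 0, 1, den), np.nan)
    fst[n == 0] = np.nan
    track = windows.copy()
    track["fst"] = fst
    track["n_snps"] = n
    return track


# ---------------------------------------------------------------------------
# outgroup polarization

def polarize_and_daf(g: GenotypeMatrix, outgroup_sample: str,
                     span: int = DEFAULT_SPAN,
                     chrom_lengths: Sequence[tuple[str, int]] | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outgroup-polarized derived allele frequencies, per site and window.

    A site is polarizable iff the outgroup genotype is called and homozygous;
    the outgroup's allele is ancestral and the derived frequency is that of
    the other allele among the ingroup's called alleles. Returns
    ``(window_track, per_site_frame)``.
    """
    if outgroup_sample not in g.sample_ids:
        raise ValueError(f"outgroup sample {outgroup_sample!r} not in matrix")
    og_col = g.sample_ids.index(outgroup_sample)
    og = g.calls[:, og_col]
    ingroup = np.ones(g.n_samples, dtype=bool)
    ingroup[og_col] = False
    calls = g.calls[:, ingroup]

    called = calls >= 0
    k = 2 * called.sum(axis=1)
    alt = np.where(called, calls, 0).sum(axis=1)
    polarizable = ((og == 0) | (og == 2)) & (k > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(k > 0, alt / np.maximum(k, 1), np.nan)
    daf = np.where(og == 0, p_alt, 1.0 - p_alt)
    daf[~polarizable] = np.nan

    per_site = pd.DataFrame({"chrom": g.chrom, "pos": g.pos,
                             "polarizable": polarizable, "daf": daf})
    windows, widx = _window_frame(g, span, chrom_lengths)
    ok = (widx >= 0) & polarizable
    sums = np.bincount(widx[ok], weights=daf[ok], minlength=len(windows))
    n = np.bincount(widx[ok], minlength=len(windows))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_daf = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    track = windows.copy()
    track["daf"] = mean_daf
    track["n_polarizable"] = n
    return track, per_site


# ---------------------------------------------------------------------------
# generic peak calling and gene overlap

@dataclass
class ScoreRegions:
    """Intervals exceeding an upper-quantile cutoff on a window track."""

    intervals: pd.DataFrame  # chrom, start, end, n_windows, max_value
    cutoff: float
    upper_fraction: float


def top_quantile_regions(track: pd.DataFrame, upper_fraction: float,
                         value_col: str | None = None) -> ScoreRegions:
    """Call regions in the top ``upper_fraction`` of a per-window score.

    The cutoff is the empirical (1 - upper_fraction) order statistic of the
    defined window values (no interpolation); windows with value >= cutoff
    (ties qualify) are merged when adjacent on a chromosome.
    """
    if not 0 < upper_fraction < 1:
        raise ValueError("upper_fraction must be in (0, 1)")
    if value_col is None:
        candidates = [c for c in track.columns
                      if c not in ("chrom", "start", "end", "span")
                      and not c.startswith("n_")]
        value_col = candidates[0]
    vals = track[value_col].to_numpy(dtype=float)
    defined = ~np.isnan(vals)
    if not defined.any():
        raise ValueError("no defined windows in track")
    cutoff = float(np.quantile(vals[defined], 1 - upper_fraction,
                               method="higher"))
    qualify = defined & (vals >= cutoff)

    rows = []
    for _, grp in track.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        q = qualify[grp.index.to_numpy()]
        i = 0
        while i < len(grp):
            if not q[i]:
                i += 1
                continue
            j = i
            while (j + 1 < len(grp) and q[j + 1]
                   and grp["start"].iloc[j + 1] == grp["end"].iloc[j] + 1):
                j += 1
            rows.append((grp["chrom"].iloc[i], int(grp["start"].iloc[i]),
                         int(grp["end"].iloc[j]), j - i + 1,
                         float(np.nanmax(vals[grp.index.to_numpy()[i:j + 1]]))))
            i = j + 1
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                            "n_windows", "max_value"])
    return ScoreRegions(intervals, cutoff, upper_fraction)


def genes_overlapping_regions(regions: pd.DataFrame, genes: pd.DataFrame,
                              flank: int = 0) -> list[list[str]]:
    """Gene ids whose (flank-extended) interval intersects each region.

    Both inputs are 1-based closed intervals with columns chrom, start, end;
    ``genes`` additionally carries ``gene_id``. Intervals sharing a single bp
    overlap.
    """
    out: list[list[str]] = []
    gby = {c: grp for c, grp in genes.groupby("chrom", sort=False)}
    for _, reg in regions.iterrows():
        grp = gby.get(reg["chrom"])
        if grp is None:
            out.append([])
            continue
        gs = grp["start"].to_numpy() - flank
        ge = grp["end"].to_numpy() + flank
        hit = (gs <= reg["end"]) & (ge >= reg["start"])
        out.append(list(grp["gene_id"].to_numpy()[hit]))
    return out
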