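"""Genotype containers, VCF I/O and the site/sample QC filters.

The central container is :class:`GenotypeMatrix`: biallelic SNP calls coded
0 (hom-ref), 1 (het), 2 (hom-alt), -1 (missing) in a sites x samples int8
array, with 1-based positions strictly increasing within each chromosome.
Genotypes are treated as unphased throughout; linkage pruning therefore uses
genotype-dosage (composite) r^2 rather than haplotypic r^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "filter_sites",
    "batch_effect_filter",
    "ld_prune",
    "prune_related_samples",
]

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1
_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotype calls for sites x samples.

    Parameters
    ----------
    chrom, pos, ref, alt
        Per-site arrays; ``pos`` is 1-based and strictly increasing within
        each chromosome.
    calls
        ``(n_sites, n_samples)`` int8 array with codes 0/1/2/-1.
    sample_ids
        Unique sample identifiers, one per column of ``calls``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D sites x samples array")
        n_sites, n_samples = self.calls.shape
        for name, arr in (("chrom", self.chrom), ("pos", self.pos),
                          ("ref", self.ref), ("alt", self.alt)):
            if len(arr) != n_sites:
                raise ValueError(f"{name} length {len(arr)} != n_sites {n_sites}")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match calls")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("sample_ids must be unique")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    def site_ids(self) -> np.ndarray:
        """``chrom:pos`` identifier per site."""
        return np.array([f"{c}:{p}" for c, p in zip(self.chrom, self.pos)],
                        dtype=object)

    def dosage(self, impute_mean: bool = False) -> np.ndarray:
        """Alt-allele dosage as float; missing is NaN or the site mean."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        if impute_mean:
            mu = np.nanmean(d, axis=1)
            mu = np.where(np.isnan(mu), 0.0, mu)
            idx = np.where(np.isnan(d))
            d[idx] = mu[idx[0]]
        return d

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.chrom[index], self.pos[index],
                              self.ref[index], self.alt[index],
                              self.calls[index], self.sample_ids)

    def take_samples(self, samples: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        """Subset (and reorder) columns by sample id."""
        order = [self.sample_ids.index(s) for s in samples]
        return GenotypeMatrix(self.chrom, self.pos, self.ref, self.alt,
                              self.calls[:, order], [self.sample_ids[i] for i in order])

    def drop_samples(self, samples: Iterable[str]) -> "GenotypeMatrix":
        drop = set(samples)
        keep = [s for s in self.sample_ids if s not in drop]
        return self.take_samples(keep)


@dataclass
class FilterReport:
    """Bookkeeping for a filtering step.

    Invariant: ``sites_in == sites_out + sum(sites_removed_by_rule.values())``.
    """

    sites_in: int
    sites_out: int
    sites_removed_by_rule: dict[str, int] = field(default_factory=dict)
    samples_in: int = 0
    samples_out: int = 0

    def __post_init__(self) -> None:
        removed = sum(self.sites_removed_by_rule.values())
        if self.sites_in != self.sites_out + removed:
            raise ValueError(
                f"site accounting broken: {self.sites_in} != "
                f"{self.sites_out} + {removed}")


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path: str) -> tuple[GenotypeMatrix, FilterReport]:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped and counted in the report.
    Half-calls and unknown genotypes map to missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has zero samples")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    dropped_multi = 0
    dropped_nonsnp = 0
    for var in vcf:
        if len(var.ALT) != 1:
            dropped_multi += 1
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1 or var.ALT[0] not in "ACGT":
            dropped_nonsnp += 1
            continue
        alleles = np.asarray([g[:2] for g in var.genotypes], dtype=np.int16)
        gt = alleles.sum(axis=1).astype(np.int8)
        gt[(alleles < 0).any(axis=1)] = MISSING  # ./., half-calls
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(gt)
    vcf.close()

    calls = (np.vstack(rows) if rows
             else np.zeros((0, len(samples)), dtype=np.int8))
    g = GenotypeMatrix(np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
                       np.array(refs, dtype=object), np.array(alts, dtype=object),
                       calls, samples)
    n_in = g.n_sites + dropped_multi + dropped_nonsnp
    report = FilterReport(
        sites_in=n_in, sites_out=g.n_sites,
        sites_removed_by_rule={"multiallelic": dropped_multi,
                               "non_snp": dropped_nonsnp},
        samples_in=len(samples), samples_out=len(samples))
    return g, report


def write_vcf(g: GenotypeMatrix, path: str,
              chrom_lengths: Sequence[tuple[str, int]] | None = None) -> None:
    """Write a minimal VCF v4.2 with unphased GT calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clonalscape\n")
        if chrom_lengths:
            for name, length in chrom_lengths:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for i in range(g.n_sites):
            gts = "\t".join(_GT_STRINGS[int(c)] for c in g.calls[i])
            fh.write(f"{g.chrom[i]}\t{g.pos[i]}\t.\t{g.ref[i]}\t{g.alt[i]}\t"
                     f".\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Site / sample filters


def _allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt allele count, called allele count)."""
    called = calls >= 0
    alt = np.where(called, calls, 0).sum(axis=1)
    return alt.astype(np.int64), 2 * called.sum(axis=1).astype(np.int64)


def filter_sites(g: GenotypeMatrix, maf_min: float = 0.05,
                 missing_max: float = 0.2) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep sites with MAF > ``maf_min`` and missing fraction < ``missing_max``.

    Both inequalities are strict, matching the conventional "MAF > 0.05,
    missing rate < 0.2" phrasing. A site failing both rules is attributed to
    the MAF rule in the report.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    if not 0 <= missing_max <= 1:
        raise ValueError("missing_max must be in [0, 1]")
    alt, called = _allele_counts(g.calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / np.maximum(called, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    miss = (g.calls == MISSING).mean(axis=1)
    pass_maf = maf > maf_min
    pass_miss = miss < missing_max
    keep = pass_maf & pass_miss
    if not keep.any():
        warnings.warn("all sites removed by filter_sites", stacklevel=2)
    removed_maf = int((~pass_maf).sum())
    removed_miss = int((pass_maf & ~pass_miss).sum())
    out = g.take_sites(np.where(keep)[0])
    report = FilterReport(g.n_sites, out.n_sites,
                          {"maf": removed_maf, "missing": removed_miss},
                          g.n_samples, g.n_samples)
    return out, report


def batch_effect_filter(g: GenotypeMatrix, batches: Sequence[str],
                        alpha: float = 0.01) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove sites whose allele counts differ between sequencing batches.

    Per site, a batches x {ref, alt} allele-count table is tested with a
    Pearson chi-square (no continuity correction, (r-1) df for r batches);
    sites with p < ``alpha`` are removed. Sites where any batch has zero
    called alleles, or where one allele is absent overall, are not testable
    and are kept.
    """
    batches = np.asarray(batches)
    if len(batches) != g.n_samples:
        raise ValueError("batches must have one label per sample")
    labels = pd.unique(batches)
    r = len(labels)
    if r < 2:
        raise ValueError("need at least 2 batch labels")

    called = g.calls >= 0
    altmat = np.where(called, g.calls, 0)
    # per-site allele counts by batch: shape (n_sites, r, 2)
    alt_b = np.stack([altmat[:, batches == b].sum(axis=1) for b in labels], axis=1)
    tot_b = np.stack([2 * called[:, batches == b].sum(axis=1) for b in labels], axis=1)
    ref_b = tot_b - alt_b

    row_tot = tot_b.astype(float)
    n_tot = row_tot.sum(axis=1)
    alt_tot = alt_b.sum(axis=1).astype(float)
    ref_tot = ref_b.sum(axis=1).astype(float)
    testable = (row_tot > 0).all(axis=1) & (alt_tot > 0) & (ref_tot > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        e_alt = row_tot * (alt_tot / n_tot)[:, None]
        e_ref = row_tot * (ref_tot / n_tot)[:, None]
        chi2 = (np.where(e_alt > 0, (alt_b - e_alt) ** 2 / e_alt, 0.0).sum(axis=1)
                + np.where(e_ref > 0, (ref_b - e_ref) ** 2 / e_ref, 0.0).sum(axis=1))
    pvals = stats.chi2.sf(chi2, df=r - 1)
    remove = testable & (pvals < alpha)
    out = g.take_sites(np.where(~remove)[0])
    report = FilterReport(g.n_sites, out.n_sites,
                          {"batch_effect": int(remove.sum())},
                          g.n_samples, g.n_samples)
    return out, report


def batch_chi2_pvalues(g: GenotypeMatrix, batches: Sequence[str]) -> np.ndarray:
    """Per-site batch-effect chi-square p-values (NaN where untestable)."""
    batches = np.asarray(batches)
    labels = pd.unique(batches)
    called = g.calls >= 0
    altmat = np.where(called, g.calls, 0)
    alt_b = np.stack([altmat[:, batches == b].sum(axis=1) for b in labels], axis=1)
    tot_b = np.stack([2 * called[:, batches == b].sum(axis=1) for b in labels], axis=1)
    ref_b = tot_b - alt_b
    row_tot = tot_b.astype(float)
    n_tot = row_tot.sum(axis=1)
    alt_tot = alt_b.sum(axis=1).astype(float)
    ref_tot = ref_b.sum(axis=1).astype(float)
    testable = (row_tot > 0).all(axis=1) & (alt_tot > 0) & (ref_tot > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_alt = row_tot * (alt_tot / n_tot)[:, None]
        e_ref = row_tot * (ref_tot / n_tot)[:, None]
        chi2 = (np.where(e_alt > 0, (alt_b - e_alt) ** 2 / e_alt, 0.0).sum(axis=1)
                + np.where(e_ref > 0, (ref_b - e_ref) ** 2 / e_ref, 0.0).sum(axis=1))
    p = stats.chi2.sf(chi2, df=len(labels) - 1)
    p[~testable] = np.nan
    return p


def _dosage_r2(dose: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation between dosage columns."""
    z = dose - dose.mean(axis=0)
    sd = z.std(axis=0)
    sd[sd == 0] = np.nan
    z = z / sd
    r = (z.T @ z) / z.shape[0]
    r2 = r ** 2
    np.fill_diagonal(r2, 0.0)
    return np.nan_to_num(r2, nan=0.0)


def ld_prune(g: GenotypeMatrix, window_snps: int = 100, step: int = 10,
             r2_max: float = 0.2) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning on genotype-dosage r^2.

    Within each window of ``window_snps`` retained SNPs (advanced by ``step``)
    the SNP with the highest mean r^2 to the window is removed from the worst
    offending pair until no pair exceeds ``r2_max``; passes repeat until the
    retained set is stable. Missing dosages are mean-imputed per site for the
    correlation only.
    """
    if not window_snps >= step >= 1:
        raise ValueError("require window_snps >= step >= 1")
    dose = g.dosage(impute_mean=True).T  # samples x sites
    keep = np.ones(g.n_sites, dtype=bool)
    for c in pd.unique(g.chrom):
        chrom_idx = np.where(g.chrom == c)[0]
        changed = True
        while changed:
            changed = False
            retained = chrom_idx[keep[chrom_idx]]
            if len(retained) < 2:
                break
            for start in range(0, len(retained), step):
                win = retained[start:start + window_snps]
                win = win[keep[win]]
                if len(win) < 2:
                    continue
                r2 = _dosage_r2(dose[:, win])
                while True:
                    i, j = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[i, j] <= r2_max:
                        break
                    # drop the member more correlated with the rest of the window
                    victim = i if r2[i].mean() >= r2[j].mean() else j
                    keep[win[victim]] = False
                    r2[victim, :] = 0.0
                    r2[:, victim] = 0.0
                    changed = True
                if start + window_snps >= len(retained):
                    break
    return g.take_sites(np.where(keep)[0])


def prune_related_samples(d: "DistanceMatrix | np.ndarray", cutoff: float,
                          sample_ids: Sequence[str] | None = None) -> list[str]:
    """Greedily drop samples until all pairwise distances are >= ``cutoff``.

    While any retained pair is closer than ``cutoff``, the closest pair is
    examined and the member with more sub-cutoff neighbours is dropped (ties
    broken by dropping the lexicographically larger id).
    """
    if hasattr(d, "values") and hasattr(d, "sample_ids"):
        mat = np.asarray(d.values, dtype=float)
        ids = list(d.sample_ids)
    else:
        mat = np.asarray(d, dtype=float)
        ids = list(sample_ids) if sample_ids is not None else [
            f"S{i}" for i in range(mat.shape[0])]
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    n = mat.shape[0]
    retained = list(range(n))
    while True:
        sub = mat[np.ix_(retained, retained)]
        tri = np.triu(np.ones_like(sub, dtype=bool), k=1)
        close = tri & (sub < cutoff)
        if not close.any():
            break
        vals = np.where(close, sub, np.inf)
        a, b = np.unravel_index(np.argmin(vals), vals.shape)
        ia, ib = retained[a], retained[b]
        below = (sub < cutoff) & ~np.eye(len(retained), dtype=bool)
        deg_a, deg_b = int(below[a].sum()), int(below[b].sum())
        if deg_a > deg_b:
            drop = ia
        elif deg_b > deg_a:
            drop = ib
        else:
            drop = ia if ids[ia] > ids[ib] else ib
        retained.remove(drop)
    return [ids[i] for i in retained]
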