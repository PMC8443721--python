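"""GWAS covariates, stand-in association, and the multi-method consensus.

The consensus procedure mirrors common practice for low-power association
panels: per-method significance thresholds (Bonferroni on the effective SNP
number for p-value methods, LOD > 3 for the multi-locus method), a rescue
rule admitting SNPs in the top 500 of at least two methods, single-linkage
merging of candidate SNPs within 10 kb into marker-trait associations
(MTAs), gene assignment within a 5-kb flank, and hypergeometric term
enrichment with Benjamini-Hochberg control.

The covariate-adjusted OLS scan here is a stand-in generator of association
tables for exercising the consensus logic; mixed-model or multi-locus
methods are consumed as externally produced tables with the same columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotype_io import GenotypeMatrix

__all__ = [
    "env_covariates",
    "associate_linear",
    "bonferroni_threshold",
    "Thresholds",
    "candidate_snps",
    "merge_mtas",
    "assign_genes",
    "enrichment",
]

MIN_P = 5e-324  # smallest positive subnormal double; p stays in (0, 1]


# ---------------------------------------------------------------------------
# covariates

def env_covariates(meta: pd.DataFrame, n_pcs: int = 3,
                   factors: Sequence[str] | None = None
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the environmental factors.

    Factors are standardized (mean 0, SD 1); PCs come from the
    eigen-decomposition of their correlation matrix. Constant factors are
    dropped with a warning, missing values are mean-imputed. Returns the
    sample scores (columns ``PC1..PCk``) and variance-explained fractions.
    Component signs are fixed so each PC's largest-magnitude loading is
    positive.
    """
    if factors is None:
        from .synthdata import ENV_FACTORS
        factors = [f for f in ENV_FACTORS if f in meta.columns]
    X = meta[list(factors)].astype(float).to_numpy().copy()
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    if len(nan_idx[0]):
        warnings.warn("missing environmental values mean-imputed", stacklevel=2)
        X[nan_idx] = col_mean[nan_idx[1]]
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(factors, keep) if not k]
        warnings.warn(f"constant factors dropped: {dropped}", stacklevel=2)
        X = X[:, keep]
        sd = sd[keep]
    if X.shape[1] < n_pcs:
        raise ValueError("fewer usable factors than requested components")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Z @ evecs[:, :n_pcs]
    var_frac = np.clip(evals, 0, None) / np.clip(evals, 0, None).sum()
    cols = [f"PC{i + 1}" for i in range(n_pcs)]
    return (pd.DataFrame(scores, index=meta.index, columns=cols),
            var_frac[:n_pcs])


# ---------------------------------------------------------------------------
# stand-in single-variant association

def associate_linear(g: GenotypeMatrix, phenotype: Sequence[float],
                     covariates: pd.DataFrame | np.ndarray | None = None,
                     method: str = "ols") -> pd.DataFrame:
    """Per-SNP OLS of phenotype on alt dosage plus covariates.

    Two-sided t-test on the dosage coefficient; missing dosages are
    mean-imputed per site. Returns an association table with columns
    method, chrom, pos, snp_id, stat, p_or_lod, stat_type and rank
    (significance rank, ties broken by chrom/pos).
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != g.n_samples:
        raise ValueError("phenotype length must match sample count")
    n = len(y)
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    # project out covariates once
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    D = g.dosage(impute_mean=True).T  # samples x sites
    D_r = D - Q @ (Q.T @ D)

    xx = (D_r ** 2).sum(axis=0)
    xy = D_r.T @ y_r
    df = n - C.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough samples for the model")
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(xx > 0, xy / np.where(xx == 0, 1, xx), 0.0)
        rss = (y_r ** 2).sum() - beta * xy
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(np.where(xx > 0, sigma2 / np.where(xx == 0, 1, xx), np.inf))
        t = np.where(se > 0, beta / np.where(se == 0, 1, se),
                     np.sign(beta) * np.inf)
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, MIN_P, 1.0)
    p[xx == 0] = 1.0  # monomorphic after projection: uninformative

    tab = pd.DataFrame({"method": method, "chrom": g.chrom, "pos": g.pos,
                        "snp_id": g.site_ids(), "stat": t,
                        "p_or_lod": p, "stat_type": "p"})
    return rank_table(tab)


def rank_table(table: pd.DataFrame) -> pd.DataFrame:
    """Assign unique significance ranks (1 = most significant).

    p-value tables rank ascending, LOD tables descending; ties are broken by
    (chrom, pos).
    """
    stat_type = table["stat_type"].iloc[0]
    ascending = stat_type == "p"
    order = table.sort_values(["p_or_lod", "chrom", "pos"],
                              ascending=[ascending, True, True]).index
    ranks = pd.Series(np.arange(1, len(table) + 1), index=order)
    out = table.copy()
    out["rank"] = ranks
    return out


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-corrected per-test threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class Thresholds:
    """Per-method significance thresholds for the consensus step."""

    alpha_snp: float = 0.05
    alpha_gene: float = 0.05
    lod_min: float = 3.0
    per_method: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, effective_snps: int, n_genes: int | None = None,
                    alpha: float = 0.05, lod_min: float = 3.0) -> "Thresholds":
        return cls(alpha_snp=bonferroni_threshold(alpha, effective_snps),
                   alpha_gene=(bonferroni_threshold(alpha, n_genes)
                               if n_genes else alpha),
                   lod_min=lod_min)

    def for_table(self, table: pd.DataFrame) -> float:
        method = table["method"].iloc[0]
        if method in self.per_method:
            return self.per_method[method]
        return self.lod_min if table["stat_type"].iloc[0] == "lod" else self.alpha_snp


# ---------------------------------------------------------------------------
# consensus

def candidate_snps(tables: Sequence[pd.DataFrame], thresholds: Thresholds,
                   top_n: int = 500, min_methods: int = 2) -> pd.DataFrame:
    """Candidate SNPs by significance or by multi-method top-``top_n`` rank.

    A SNP is a candidate iff (a) it passes its method's threshold (p strictly
    below alpha, or LOD strictly above lod_min) in any table, or (b) it sits
    within the ``top_n`` most significant entries (ties at the boundary
    included) in at least ``min_methods`` tables. The output records which
    rule and which methods fired per SNP.
    """
    if not tables:
        raise ValueError("need at least one association table")
    sig_methods: dict[tuple, set] = {}
    top_methods: dict[tuple, set] = {}
    for tab in tables:
        method = tab["method"].iloc[0]
        if tab.duplicated(["chrom", "pos"]).any():
            raise ValueError(f"duplicated (chrom, pos) in table {method!r}")
        cut = thresholds.for_table(tab)
        if tab["stat_type"].iloc[0] == "lod":
            sig = tab["p_or_lod"] > cut
            comp_rank = tab["p_or_lod"].rank(method="min", ascending=False)
        else:
            sig = tab["p_or_lod"] < cut
            comp_rank = tab["p_or_lod"].rank(method="min", ascending=True)
        top = comp_rank <= top_n
        for key in zip(tab.loc[sig, "chrom"], tab.loc[sig, "pos"]):
            sig_methods.setdefault(key, set()).add(method)
        for key in zip(tab.loc[top, "chrom"], tab.loc[top, "pos"]):
            top_methods.setdefault(key, set()).add(method)

    rows = []
    for key in sorted(set(sig_methods) | set(top_methods)):
        by_sig = sorted(sig_methods.get(key, ()))
        by_top = sorted(top_methods.get(key, ()))
        is_cand = bool(by_sig) or len(by_top) >= min_methods
        if is_cand:
            rows.append((key[0], key[1], bool(by_sig),
                         len(by_top) >= min_methods,
                         ",".join(by_sig), ",".join(by_top)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "by_threshold",
                                       "by_top_n", "sig_methods",
                                       "top_methods"])


def merge_mtas(candidates: pd.DataFrame, merge_gap: int = 10_000) -> pd.DataFrame:
    """Merge candidate SNPs within ``merge_gap`` bp into MTAs.

    Single-linkage chaining along each chromosome; the MTA interval spans
    the member SNPs (a lone SNP gives a zero-length interval).
    """
    cols = ["mta_id", "chrom", "start", "end", "n_snps", "members", "methods"]
    if candidates.empty:
        return pd.DataFrame(columns=cols)
    cand = candidates.sort_values(["chrom", "pos"]).reset_index(drop=True)
    rows = []
    mta_idx = 0
    for chrom, grp in cand.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > merge_gap)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            sub = grp.iloc[a:b]
            methods = set()
            for col in ("sig_methods", "top_methods"):
                if col in sub:
                    for s in sub[col]:
                        methods.update(m for m in str(s).split(",") if m)
            rows.append((f"MTA{mta_idx:04d}", chrom, int(pos[a]),
                         int(pos[b - 1]), b - a,
                         ",".join(f"{chrom}:{p}" for p in pos[a:b]),
                         ",".join(sorted(methods))))
            mta_idx += 1
    return pd.DataFrame(rows, columns=cols)


def assign_genes(mtas: pd.DataFrame, genes: pd.DataFrame,
                 flank: int = 5_000) -> pd.DataFrame:
    """Genes within an MTA or its ``flank`` bp up/downstream.

    Closed-interval intersection of the gene with [start - flank,
    end + flank] on 1-based coordinates. Returns one row per (MTA, gene).
    """
    rows = []
    gby = {c: grp for c, grp in genes.groupby("chrom", sort=False)}
    for _, mta in mtas.iterrows():
        grp = gby.get(mta["chrom"])
        if grp is None:
            continue
        lo, hi = mta["start"] - flank, mta["end"] + flank
        hit = (grp["start"].to_numpy() <= hi) & (grp["end"].to_numpy() >= lo)
        for gid in grp["gene_id"].to_numpy()[hit]:
            rows.append((mta["mta_id"], gid))
    return pd.DataFrame(rows, columns=["mta_id", "gene_id"])


# ---------------------------------------------------------------------------
# enrichment

def enrichment(selected_genes: Sequence[str], background_genes: Sequence[str],
               term_map: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric term over-representation with BH correction.

    For each term with K >= 1 background members, the upper-tail
    P(X >= k) of drawing k selected members in n draws from a population of
    N genes with K successes; Benjamini-Hochberg adjustment across all
    tested terms, significance at ``p_adj < alpha``.
    """
    bg = pd.unique(pd.Series(list(background_genes)))
    sel = pd.unique(pd.Series(list(selected_genes)))
    if not set(sel) <= set(bg):
        raise ValueError("selected genes must be a subset of the background")
    N, n = len(bg), len(sel)
    tm = term_map[term_map["gene_id"].isin(bg)]
    sel_set = set(sel)
    rows = []
    for term, grp in tm.groupby("term_id", sort=True):
        members = set(grp["gene_id"])
        K = len(members)
        k = len(members & sel_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    if len(out):
        _, p_adj, _, _ = multipletests(out["p"], method="fdr_bh")
        out["p_adj"] = p_adj
        out["significant"] = out["p_adj"] < alpha
    else:
        out["p_adj"] = []
        out["significant"] = []
    return out
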