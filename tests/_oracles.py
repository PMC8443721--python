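"""Independent brute-force oracles used to cross-check the implementations.

Everything here is written from first principles (explicit loops,
enumeration, union-find) and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pairwise_pi_sum(calls_window: np.ndarray) -> float:
    """Sum over sites of the fraction of differing allele pairs.

    Explicitly enumerates every unordered pair of called alleles per site.
    """
    total = 0.0
    for site in calls_window:
        alleles = []
        for c in site:
            if c == 0:
                alleles += [0, 0]
            elif c == 1:
                alleles += [0, 1]
            elif c == 2:
                alleles += [1, 1]
        if len(alleles) < 2:
            continue
        diff = 0
        pairs = 0
        for a, b in itertools.combinations(alleles, 2):
            pairs += 1
            diff += a != b
        total += diff / pairs
    return total


def watterson_sum(calls_window: np.ndarray) -> float:
    """Sum over segregating sites of 1 / a_(k-1), a_m = sum 1/i."""
    total = 0.0
    for site in calls_window:
        alleles = []
        for c in site:
            if c >= 0:
                alleles += [1 if c == 2 else 0, 1 if c >= 1 else 0]
        if len(alleles) < 2 or len(set(alleles)) < 2:
            continue
        a = sum(1.0 / i for i in range(1, len(alleles)))
        total += 1.0 / a
    return total


def tajimas_d(S: int, pi_sum: float, n: int) -> float:
    """Tajima (1989) D evaluated directly from the published constants."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi_sum - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def wc_fst_components(site_calls: np.ndarray, labels: list) -> tuple:
    """Weir & Cockerham (1984) a, b, c for one site, plain-Python loops."""
    pops = sorted(set(labels))
    r = len(pops)
    n_i, p_i, h_i = [], [], []
    for pop in pops:
        idx = [j for j, l in enumerate(labels) if l == pop]
        called = [site_calls[j] for j in idx if site_calls[j] >= 0]
        if not called:
            return (float("nan"),) * 3
        n_i.append(len(called))
        p_i.append(sum(1 if c == 2 else (0.5 if c == 1 else 0)
                       for c in called) / len(called))
        h_i.append(sum(1 for c in called if c == 1) / len(called))
    n_sum = sum(n_i)
    if n_sum <= r:
        return (float("nan"),) * 3
    nbar = n_sum / r
    nc = (n_sum - sum(x * x for x in n_i) / n_sum) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / n_sum
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / n_sum
    a = (nbar / nc) * (s2 - 1.0 / (nbar - 1)
                       * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def ibs_matrix(calls: np.ndarray, normalized: bool = True) -> np.ndarray:
    """Per-pair per-site shared-allele tally under the flat-missing rule."""
    n_sites, n_samples = calls.shape
    out = np.zeros((n_samples, n_samples))
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            total = 0.0
            for s in range(n_sites):
                a, b = calls[s, i], calls[s, j]
                if a < 0 or b < 0:
                    continue  # flat-missing: contributes 0, denominator fixed
                shared = 2 - abs(int(a) - int(b))
                total += 2 - shared
            if normalized:
                total /= 2.0 * n_sites
            out[i, j] = out[j, i] = total
    return out


def merge_within_gap(positions: list[int], gap: int) -> list[tuple[int, int]]:
    """Transitive closure of the <= gap relation via union-find."""
    parent = list(range(len(positions)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if abs(positions[i] - positions[j]) <= gap:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i, p in enumerate(positions):
        groups.setdefault(find(i), []).append(p)
    return sorted((min(g), max(g)) for g in groups.values())


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exact enumeration of the hypergeometric pmf."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up with monotonicity enforcement."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def site_het_tally(calls: np.ndarray) -> list[float]:
    """Direct per-site het carrier frequency tally."""
    out = []
    for site in calls:
        het = sum(1 for c in site if c == 1)
        called = sum(1 for c in site if c >= 0)
        out.append(het / called if called else float("nan"))
    return out
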