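"""Pairwise genetic distances, relatedness networks and isolation by distance.

IBS distance follows the "1-ibs flat-missing" convention: at each site a
pair shares s in {0, 1, 2} alleles identical-by-state; the distance is
sum(2 - s) over sites divided by twice the total site count, with sites
where either call is missing contributing zero to the numerator while the
denominator stays fixed. The Hamming distance is the same tally left
unnormalized. Isolation by distance is tested with a Mantel permutation
test on F_ST/(1 - F_ST) against great-circle distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "ibs_distance",
    "hamming_distance",
    "lowest_quantile_edges",
    "EdgeSet",
    "mantel_ibd",
    "great_circle",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray
    kind: str = "ibs"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.values[iu]


def _pairwise_mismatch(g: GenotypeMatrix) -> np.ndarray:
    """Sum over sites of |g_i - g_j| with missing pairs contributing 0."""
    calls = g.calls.astype(np.int16)
    called = calls >= 0
    vals = np.where(called, calls, 0)
    n = g.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        both = called[:, i][:, None] & called[:, i + 1:]
        diff = np.abs(vals[:, i][:, None] - vals[:, i + 1:])
        s = (diff * both).sum(axis=0)
        out[i, i + 1:] = s
        out[i + 1:, i] = s
    return out


def ibs_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Normalized identity-by-state distance, "flat-missing" denominator."""
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    mis = _pairwise_mismatch(g) / (2.0 * g.n_sites)
    return DistanceMatrix(list(g.sample_ids), mis, kind="ibs")


def hamming_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Unnormalized genetic Hamming distance under the same convention."""
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    return DistanceMatrix(list(g.sample_ids), _pairwise_mismatch(g),
                          kind="hamming")


@dataclass
class EdgeSet:
    """Sample pairs in the lowest distance quantile, with node degrees."""

    edges: pd.DataFrame  # columns: sample_i, sample_j, distance (i < j)
    cutoff: float
    fraction: float
    degrees: pd.Series


def lowest_quantile_edges(d: DistanceMatrix, fraction: float) -> EdgeSet:
    """Edges at or below the empirical ``fraction`` quantile of distances.

    The cutoff is the order statistic without interpolation; ties at the
    cutoff are included, so a uniquely closest pair at a small fraction
    yields exactly that edge.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    ids = d.sample_ids
    iu = np.triu_indices(len(ids), k=1)
    vals = d.values[iu]
    cutoff = float(np.quantile(vals, fraction, method="lower"))
    sel = vals <= cutoff
    edges = pd.DataFrame({
        "sample_i": [ids[a] for a in iu[0][sel]],
        "sample_j": [ids[b] for b in iu[1][sel]],
        "distance": vals[sel],
    })
    deg = pd.concat([edges["sample_i"], edges["sample_j"]]).value_counts()
    degrees = deg.reindex(ids, fill_value=0).astype(int)
    return EdgeSet(edges, cutoff, fraction, degrees)


def _offdiag_r(x: np.ndarray, y: np.ndarray, iu: tuple) -> float:
    a, b = x[iu], y[iu]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("constant matrix: Mantel r undefined")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def mantel_ibd(fst_matrix: np.ndarray, geo: np.ndarray, n_perm: int = 9999,
               seed: int | None = None, transform_fst: bool = True,
               exact: bool = False) -> tuple[float, float]:
    """Mantel test of isolation by distance.

    Correlates off-diagonal F_ST/(1 - F_ST) (the linearized differentiation,
    unless ``transform_fst`` is False) with geographic distance; the null is
    generated by jointly permuting rows and columns of the genetic matrix.
    One-sided p with the add-one rule: ``(1 + #{r_perm >= r_obs}) /
    (1 + n_perm)``. With ``exact=True`` all n! relabelings are enumerated
    instead and p is the exact enumeration fraction.
    """
    x = np.asarray(fst_matrix, dtype=float)
    y = np.asarray(geo, dtype=float)
    if x.shape != y.shape or x.shape[0] != x.shape[1]:
        raise ValueError("matrices must be square and conformable")
    if transform_fst:
        if np.any(x >= 1):
            raise ValueError("F_ST must be < 1 for the linearizing transform")
        x = x / (1.0 - x)
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    r_obs = _offdiag_r(x, y, iu)

    if exact:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            r_p = _offdiag_r(x[np.ix_(p, p)], y, iu)
            count += r_p >= r_obs - 1e-12
            total += 1
        return r_obs, count / total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_p = _offdiag_r(x[np.ix_(p, p)], y, iu)
        hits += r_p >= r_obs
    return r_obs, (1 + hits) / (1 + n_perm)


def great_circle(lat: Sequence[float], lon: Sequence[float]) -> np.ndarray:
    """Haversine great-circle distance matrix in km (R = 6371.0088 km)."""
    la = np.radians(np.asarray(lat, dtype=float))
    lo = np.radians(np.asarray(lon, dtype=float))
    dla = la[:, None] - la[None, :]
    dlo = lo[:, None] - lo[None, :]
    h = (np.sin(dla / 2) ** 2
         + np.cos(la)[:, None] * np.cos(la)[None, :] * np.sin(dlo / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
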