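"""Divergence-based mutation-rate estimation and coalescent output scaling.

The per-generation nucleotide mutation rate is estimated from interspecific
divergence as mu = D * g / (2 * T), where D is the observed frequency of
pairwise differences between the focal species and a comparison species,
g the generation time in years and T the divergence time in years (each
lineage accumulates mutations for T / g generations, and the two lineages
are independent, hence the factor 2). Sequential-coalescent (PSMC-style)
trajectories produced in scaled units are converted to years and
individuals with the standard 2N0 scaling, N0 = theta / (4 * mu * s) for
bin size s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DivergenceInputs",
    "mutation_rate",
    "mutation_rate_from_windows",
    "scale_coalescent_output",
    "unscale_coalescent_output",
]


@dataclass(frozen=True)
class DivergenceInputs:
    """Interspecific divergence D, generation time g (yr), split time T (yr)."""

    divergence_D: float
    generation_time_g: float
    divergence_time_T: float

    def __post_init__(self) -> None:
        if not 0 <= self.divergence_D < 1:
            raise ValueError("divergence D must be in [0, 1)")
        if self.generation_time_g <= 0:
            raise ValueError("generation time must be positive")
        if self.divergence_time_T <= 0:
            raise ValueError("divergence time must be positive")


def mutation_rate(inputs: DivergenceInputs | None = None, *,
                  D: float | None = None, g: float | None = None,
                  T: float | None = None) -> float:
    """Per-site per-generation mutation rate mu = D * g / (2 * T)."""
    if inputs is None:
        inputs = DivergenceInputs(D, g, T)
    return (inputs.divergence_D * inputs.generation_time_g
            / (2.0 * inputs.divergence_time_T))


def mutation_rate_from_windows(divergence_per_window: Sequence[float],
                               g: float, T: float) -> float:
    """Mutation rate from the median of a per-window divergence table."""
    d = np.asarray(divergence_per_window, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) == 0:
        raise ValueError("no defined divergence windows")
    return mutation_rate(D=float(np.median(d)), g=g, T=T)


def scale_coalescent_output(trajectory: pd.DataFrame, mu: float, g: float,
                            theta: float, bin_size: int = 100) -> pd.DataFrame:
    """Convert a scaled coalescent trajectory to years and individuals.

    ``trajectory`` holds ``t`` (time in units of 2*N0 generations) and
    ``lambda`` (size in units of N0). With N0 = theta / (4 * mu * bin_size),
    time in years is 2 * N0 * g * t and effective size is N0 * lambda.
    """
    if mu <= 0 or g <= 0:
        raise ValueError("mu and g must be positive")
    t = np.asarray(trajectory["t"], dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("times must be non-negative and monotone")
    n0 = theta / (4.0 * mu * bin_size)
    return pd.DataFrame({
        "years": 2.0 * n0 * g * t,
        "ne": n0 * np.asarray(trajectory["lambda"], dtype=float),
    })


def unscale_coalescent_output(scaled: pd.DataFrame, mu: float, g: float,
                              theta: float, bin_size: int = 100) -> pd.DataFrame:
    """Inverse of :func:`scale_coalescent_output` (exact algebraic inverse)."""
    n0 = theta / (4.0 * mu * bin_size)
    return pd.DataFrame({
        "t": np.asarray(scaled["years"], dtype=float) / (2.0 * n0 * g),
        "lambda": np.asarray(scaled["ne"], dtype=float) / n0,
    })
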