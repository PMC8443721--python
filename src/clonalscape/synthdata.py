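"""Synthetic clonal-population generator with known ground truth.

Emulates the data regime of a long-lived clonal plant population surveyed
by whole-genome resequencing: very low nucleotide diversity, pervasive
heterozygosity split into a low-frequency class (recent somatic mutations
carried by a small clade of ramets) and a high-frequency class (founder
heterozygosity clonally fixed in nearly all individuals), planted
high/low-heterozygosity megabase segments, weak group structure with
geographic distance decay, one nearly fully homozygous outgroup sample for
allele polarization, causal SNPs behind quantitative traits, and 12
correlated environmental factors.

Three site classes are emitted:

* founder sites - heterozygous in ~98% of samples; dense inside planted
  high-LCHR segments, sparse in the background, absent from low segments;
* somatic sites - each mutation placed on one edge of a random bifurcating
  clonal genealogy and inherited by that clade (constrained to clades of at
  most 10% of samples, the low-frequency class);
* background sites - ordinary Hardy-Weinberg polymorphisms whose group
  allele frequencies follow a Balding-Nichols draw calibrated so the
  expected Weir-Cockerham F_ST matches ``group_fst_target``.

Everything is deterministic under a fixed ``SimConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_population",
    "simulate_phenotypes",
    "simulate_annotation",
    "ENV_FACTORS",
    "TRAITS",
    "write_sample_table",
    "write_phenotypes",
    "write_genes_bed",
    "write_genes_gff3",
    "write_term_map",
    "write_truth_json",
]

ENV_FACTORS = ["latitude", "longitude", "altitude", "soil_type",
               "precipitation", "temperature", "n", "p", "k", "mg", "b", "zn"]

TRAITS = ["culm_height", "node_number", "ground_diameter", "density",
          "compressive_strength", "bending_strength", "elastic_modulus",
          "maximum_load", "tensile_modulus"]

FOUNDER_HET_PROB = 0.98       # per-sample het carrier probability, founder sites
SOMATIC_MAX_CLADE_FRAC = 0.10  # somatic mutations live on small clades
OUTGROUP_HET_PROB = 0.005      # outgroup is homozygous at >= 99% of sites
LOW_REGION_BG_FACTOR = 0.3     # purged regions are depleted of polymorphism


@dataclass
class SimConfig:
    """Study conditions for the synthetic clonal population."""

    n_samples: int = 190
    n_groups: int = 5
    chrom_lengths: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 20_000_000), ("chr2", 16_000_000)])
    founder_het_density: float = 8e-4       # sites/bp inside high-LCHRs
    founder_background_density: float = 1e-4
    somatic_mut_rate: float = 1e-6          # new het mutations /lineage /bp
    background_snp_density: float = 1e-4    # HWE group-structured sites /bp
    planted_high_lchr: dict[str, list[tuple[int, int]]] = field(
        default_factory=lambda: {"chr1": [(2_000_001, 9_800_000)]})
    planted_low_lchr: dict[str, list[tuple[int, int]]] = field(
        default_factory=lambda: {"chr2": [(3_000_001, 10_000_000)]})
    group_fst_target: float = 1e-3
    outgroup: bool = True
    outgroup_id: str = "OG1"
    n_causal: int = 3
    effect_size: float = 0.8                # per-allele shift, trait SD units
    env_latent_dim: int = 3
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_groups < 1:
            raise ValueError("need >= 2 samples and >= 1 group")
        for name, length in self.chrom_lengths:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        lengths = dict(self.chrom_lengths)
        for planted in (self.planted_high_lchr, self.planted_low_lchr):
            for chrom, ivals in planted.items():
                if chrom not in lengths:
                    raise ValueError(f"planted interval on unknown chrom {chrom}")
                last_end = 0
                for start, end in sorted(ivals):
                    if start < 1 or end > lengths[chrom] or start > end:
                        raise ValueError(
                            f"planted interval {chrom}:{start}-{end} out of bounds")
                    if start <= last_end:
                        raise ValueError(
                            f"planted intervals overlap on {chrom}")
                    last_end = end
        if not 0 <= self.group_fst_target < 1:
            raise ValueError("group_fst_target must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.effect_size or self.n_causal < 0:
            raise ValueError("effect_size and n_causal must be non-negative")


@dataclass
class SimTruth:
    """Ground truth emitted next to the genotype matrix."""

    planted_high: dict[str, list[tuple[int, int]]]
    planted_low: dict[str, list[tuple[int, int]]]
    causal: pd.DataFrame          # snp_id, chrom, pos, effect, trait
    groups: pd.Series             # sample_id -> group label
    lineage_depth: pd.Series      # sample_id -> edges to genealogy root
    site_class: np.ndarray        # per retained site: founder/somatic/background
    env_latent: pd.DataFrame      # sample x latent factors


# ---------------------------------------------------------------------------
# clonal genealogy


def _random_genealogy(n: int, rng: np.random.Generator
                      ) -> tuple[list[np.ndarray], np.ndarray]:
    """Random bifurcating tree over ``n`` leaves.

    Returns the clade (descendant-leaf index set) of every non-root edge and
    the per-leaf depth (edge count to the root).
    """
    active: list[list[int]] = [[i] for i in range(n)]
    depth = np.zeros(n, dtype=int)
    clades: list[np.ndarray] = [np.array(c) for c in active]
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[min(i, j)], active[max(i, j)]
        merged = a + b
        for leaf in merged:
            depth[leaf] += 1
        active = [c for k, c in enumerate(active) if k not in (i, j)]
        active.append(merged)
        if len(active) > 1:  # the root itself carries no edge
            clades.append(np.array(merged))
    return clades, depth


# ---------------------------------------------------------------------------
# site placement


def _segment_positions(length: int, density: float, rng: np.random.Generator,
                       offset: int = 0) -> np.ndarray:
    n = rng.poisson(density * length)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    pos = rng.integers(1, length + 1, size=n) + offset
    return np.unique(pos)


def _region_complement(length: int, intervals: Sequence[tuple[int, int]]
                       ) -> list[tuple[int, int]]:
    out = []
    cursor = 1
    for start, end in sorted(intervals):
        if start > cursor:
            out.append((cursor, start - 1))
        cursor = end + 1
    if cursor <= length:
        out.append((cursor, length))
    return out


def simulate_population(config: SimConfig
                        ) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Generate genotypes, sample metadata and ground truth.

    Returns ``(GenotypeMatrix, SampleTable, SimTruth)``; the matrix carries
    the outgroup as its last sample when ``config.outgroup`` is set.
    Monomorphic hom-ref sites (no alternate allele in any sample) are not
    retained.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    lengths = dict(config.chrom_lengths)

    clades, depth = _random_genealogy(n, rng)
    max_clade = max(1, int(np.floor(SOMATIC_MAX_CLADE_FRAC * n)))
    small_edges = [c for c in clades if len(c) <= max_clade]

    # group assignment: contiguous near-equal blocks
    group_sizes = np.full(config.n_groups, n // config.n_groups)
    group_sizes[: n % config.n_groups] += 1
    group_of = np.repeat(np.arange(config.n_groups), group_sizes)

    chroms: list[str] = []
    positions: list[int] = []
    classes: list[str] = []
    rows: list[np.ndarray] = []

    F = config.group_fst_target

    for chrom, length in config.chrom_lengths:
        high = config.planted_high_lchr.get(chrom, [])
        low = config.planted_low_lchr.get(chrom, [])
        site_plan: list[tuple[int, str]] = []

        # founder sites: dense in high segments, absent in low segments
        for start, end in high:
            for p in _segment_positions(end - start + 1,
                                        config.founder_het_density, rng,
                                        offset=start - 1):
                site_plan.append((int(p), "founder"))
        for start, end in _region_complement(length, list(high) + list(low)):
            for p in _segment_positions(end - start + 1,
                                        config.founder_background_density, rng,
                                        offset=start - 1):
                site_plan.append((int(p), "founder"))

        # somatic sites: uniform over the chromosome; background HWE sites:
        # uniform except depleted inside planted low segments (purged regions
        # lose intermediate-frequency polymorphism as well)
        for p in _segment_positions(length, config.somatic_mut_rate * n, rng):
            site_plan.append((int(p), "somatic"))
        for start, end in low:
            for p in _segment_positions(
                    end - start + 1,
                    config.background_snp_density * LOW_REGION_BG_FACTOR,
                    rng, offset=start - 1):
                site_plan.append((int(p), "background"))
        for start, end in _region_complement(length, list(low)):
            for p in _segment_positions(end - start + 1,
                                        config.background_snp_density, rng,
                                        offset=start - 1):
                site_plan.append((int(p), "background"))

        site_plan.sort()
        seen: set[int] = set()
        for pos, cls in site_plan:
            if pos in seen:
                continue
            seen.add(pos)
            if cls == "founder":
                het = rng.random(n) < FOUNDER_HET_PROB
                hom = np.where(rng.random(n) < 0.5, 0, 2)
                calls = np.where(het, 1, hom).astype(np.int8)
            elif cls == "somatic":
                calls = np.zeros(n, dtype=np.int8)
                clade = small_edges[rng.integers(len(small_edges))]
                calls[clade] = 1
            else:  # background, Balding-Nichols group frequencies
                pbar = rng.uniform(0.05, 0.95)
                if F > 0:
                    p_g = rng.beta(pbar * (1 - F) / F,
                                   (1 - pbar) * (1 - F) / F,
                                   size=config.n_groups)
                else:
                    p_g = np.full(config.n_groups, pbar)
                calls = rng.binomial(2, p_g[group_of]).astype(np.int8)
            chroms.append(chrom)
            positions.append(pos)
            classes.append(cls)
            rows.append(calls)

    calls = (np.vstack(rows) if rows
             else np.zeros((0, n), dtype=np.int8))
    site_class = np.array(classes, dtype=object)

    # outgroup: homozygous at >= 99% of sites; ancestral allele at
    # background sites is either allele with equal probability
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    if config.outgroup:
        og = np.zeros(calls.shape[0], dtype=np.int8)
        bg_mask = site_class == "background"
        og[bg_mask] = np.where(rng.random(bg_mask.sum()) < 0.5, 0, 2)
        og[rng.random(calls.shape[0]) < OUTGROUP_HET_PROB] = 1
        calls = np.column_stack([calls, og])
        sample_ids = sample_ids + [config.outgroup_id]

    # retain sites that actually carry the alternate allele
    keep = (calls > 0).any(axis=1)
    calls = calls[keep]
    site_class = site_class[keep]
    chrom_arr = np.array(chroms, dtype=object)[keep]
    pos_arr = np.array(positions, dtype=np.int64)[keep]

    # uniform random missingness, independent of genotype
    if config.missing_rate > 0 and calls.size:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = np.where(mask, np.int8(-1), calls)
        # a site must keep at least one called genotype
        dead = (calls < 0).all(axis=1)
        if dead.any():
            calls[dead, 0] = 0

    ref = np.array(["A"] * len(pos_arr), dtype=object)
    alt = np.array(["G"] * len(pos_arr), dtype=object)
    g = GenotypeMatrix(chrom_arr, pos_arr, ref, alt, calls, sample_ids)

    meta, env_latent = _sample_table(config, group_of, rng)
    truth = _build_truth(config, g, site_class, group_of, depth, env_latent, rng)
    return g, meta, truth


def _sample_table(config: SimConfig, group_of: np.ndarray,
                  rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    group_labels = np.array([f"G{i + 1}" for i in group_of], dtype=object)

    # groups sit on a southwest-northeast gradient with local jitter
    lat = 24.0 + 1.6 * group_of + rng.normal(0, 0.4, n)
    lon = 104.0 + 3.0 * group_of + rng.normal(0, 0.5, n)

    L = config.env_latent_dim
    latent = rng.normal(0, 1, size=(n, L))
    lat_std = (lat - lat.mean()) / lat.std()
    latent[:, 0] = 0.8 * lat_std + 0.6 * latent[:, 0]  # climate tracks latitude
    loadings = rng.normal(0, 1, size=(L, 10))
    env10 = latent @ loadings + 0.15 * rng.normal(0, 1, size=(n, 10))

    meta = pd.DataFrame({"sample_id": sample_ids, "group": group_labels,
                         "batch": np.where(np.arange(n) % 2 == 0, "b1", "b2"),
                         "latitude": lat, "longitude": lon})
    for j, name in enumerate(ENV_FACTORS[2:]):
        meta[name] = env10[:, j]
    if config.outgroup:
        og_row = {"sample_id": config.outgroup_id, "group": "OUTGROUP",
                  "batch": "b1", "latitude": float(lat.mean()),
                  "longitude": float(lon.mean())}
        for name in ENV_FACTORS[2:]:
            og_row[name] = 0.0
        meta = pd.concat([meta, pd.DataFrame([og_row])], ignore_index=True)
    latent_df = pd.DataFrame(latent, index=sample_ids,
                             columns=[f"L{j + 1}" for j in range(L)])
    return meta, latent_df


def _build_truth(config: SimConfig, g: GenotypeMatrix, site_class: np.ndarray,
                 group_of: np.ndarray, depth: np.ndarray,
                 env_latent: pd.DataFrame, rng: np.random.Generator) -> SimTruth:
    n = config.n_samples
    ingroup = slice(0, n)
    causal_rows = []
    if config.n_causal > 0 and g.n_sites > 0:
        calls_in = g.calls[:, ingroup]
        called = calls_in >= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (np.where(called, calls_in, 0).sum(axis=1)
                 / np.maximum(2 * called.sum(axis=1), 1))
        maf = np.minimum(p, 1 - p)
        common = np.where((site_class == "background") & (maf >= 0.15))[0]
        if len(common) == 0:
            common = np.where(maf >= 0.05)[0]
        if len(common) > 0:
            chosen = rng.choice(common, size=min(config.n_causal, len(common)),
                                replace=False)
            ids = g.site_ids()
            for i, row in enumerate(np.sort(chosen)):
                causal_rows.append({"snp_id": ids[row], "chrom": g.chrom[row],
                                    "pos": int(g.pos[row]),
                                    "effect": config.effect_size,
                                    "trait": TRAITS[i % len(TRAITS)]})
    causal = pd.DataFrame(causal_rows,
                          columns=["snp_id", "chrom", "pos", "effect", "trait"])
    sample_ids = g.sample_ids[:n]
    groups = pd.Series([f"G{i + 1}" for i in group_of], index=sample_ids,
                       name="group")
    lineage = pd.Series(depth, index=sample_ids, name="lineage_depth")
    return SimTruth(planted_high={k: list(v) for k, v in
                                  config.planted_high_lchr.items()},
                    planted_low={k: list(v) for k, v in
                                 config.planted_low_lchr.items()},
                    causal=causal, groups=groups, lineage_depth=lineage,
                    site_class=site_class, env_latent=env_latent)


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(truth: SimTruth, genotypes: GenotypeMatrix,
                        config: SimConfig, env_weight: float = 0.3,
                        noise_sd: float = 1.0) -> pd.DataFrame:
    """Nine quantitative traits with additive causal effects.

    ``trait = sum(effect * dosage) + env_weight * latent + noise`` with the
    latent environmental factor cycling over the configured latent
    dimensions per trait. Only ingroup samples receive phenotypes.
    """
    rng = np.random.default_rng(config.seed + 1)
    samples = list(truth.groups.index)
    cols = [genotypes.sample_ids.index(s) for s in samples]
    ids = genotypes.site_ids()
    row_of = {sid: i for i, sid in enumerate(ids)}

    L = truth.env_latent.shape[1]
    latent = truth.env_latent.loc[samples].to_numpy()
    out = {}
    for t_idx, trait in enumerate(TRAITS):
        y = np.zeros(len(samples))
        for _, row in truth.causal[truth.causal["trait"] == trait].iterrows():
            if row["snp_id"] not in row_of:
                raise ValueError(f"causal SNP {row['snp_id']} not in matrix")
            d = genotypes.calls[row_of[row["snp_id"]], cols].astype(float)
            miss = d < 0
            if miss.any():
                fill = d[~miss].mean() if (~miss).any() else 0.0
                d[miss] = fill
            y += row["effect"] * d
        y += env_weight * latent[:, t_idx % L]
        y += noise_sd * rng.normal(0, 1, len(samples))
        out[trait] = y
    return pd.DataFrame(out, index=pd.Index(samples, name="sample_id"))


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimConfig, n_genes: int = 500,
                        n_terms: int = 50, gene_length: int = 3_000,
                        pitch: int | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-overlapping gene intervals plus a heavy-tailed gene-to-term map.

    With ``pitch`` set, genes tile deterministically at that spacing
    (``floor(length / pitch)`` genes per chromosome); otherwise ``n_genes``
    are placed with random gaps, allocated to chromosomes by length. Each
    gene maps to 1-5 terms drawn with Zipf-like term weights.
    """
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    if pitch is not None:
        for chrom, length in config.chrom_lengths:
            for k in range(length // pitch):
                start = k * pitch + 1
                rows.append((chrom, start,
                             min(start + gene_length - 1, length)))
    elif n_genes > 0:
        total = sum(l for _, l in config.chrom_lengths)
        for chrom, length in config.chrom_lengths:
            n_c = int(round(n_genes * length / total))
            if n_c == 0:
                continue
            # random non-overlapping placement via sorted gap draws
            free = length - n_c * gene_length
            if free < 0:
                raise ValueError("too many genes for chromosome length")
            gaps = np.sort(rng.integers(0, free + 1, size=n_c))
            starts = gaps + gene_length * np.arange(n_c) + 1
            for s in starts:
                rows.append((chrom, int(s), int(s + gene_length - 1)))
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    genes["gene_id"] = [f"gene{i + 1:05d}" for i in range(len(genes))]

    term_rows = []
    if len(genes) and n_terms > 0:
        weights = 1.0 / np.arange(1, n_terms + 1)
        weights /= weights.sum()
        for gid in genes["gene_id"]:
            k = rng.integers(1, 6)
            terms = rng.choice(n_terms, size=min(k, n_terms), replace=False,
                               p=weights)
            for t in np.sort(terms):
                term_rows.append((gid, f"term{t + 1:03d}"))
    term_map = pd.DataFrame(term_rows, columns=["gene_id", "term_id"])
    return genes, term_map


# ---------------------------------------------------------------------------
# writers (all plain text)


def write_sample_table(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_phenotypes(phen: pd.DataFrame, path: str) -> None:
    phen.to_csv(path, sep="\t", float_format="%.6g")


def write_genes_bed(genes: pd.DataFrame, path: str) -> None:
    """BED is 0-based half-open: start-1, end."""
    with open(path, "w") as fh:
        for _, r in genes.iterrows():
            fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t"
                     f"{r['gene_id']}\n")


def write_genes_gff3(genes: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in genes.iterrows():
            fh.write(f"{r['chrom']}\tclonalscape\tgene\t{r['start']}\t"
                     f"{r['end']}\t.\t+\t.\tID={r['gene_id']}\n")


def write_term_map(term_map: pd.DataFrame, path: str) -> None:
    term_map.to_csv(path, sep="\t", index=False)


def write_truth_json(truth: SimTruth, path: str) -> None:
    payload = {
        "planted_high": truth.planted_high,
        "planted_low": truth.planted_low,
        "causal": truth.causal.to_dict(orient="records"),
        "groups": truth.groups.to_dict(),
        "lineage_depth": {k: int(v) for k, v in
                          truth.lineage_depth.items()},
        "site_class_counts": pd.Series(truth.site_class)
                               .value_counts().to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
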