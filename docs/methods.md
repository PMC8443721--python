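# Methods

## The model

`clonalscape` analyses a diploid population that reproduces mostly or
entirely asexually. Under clonal propagation, a heterozygous genotype is
transmitted intact: there is no segregation to break it up and no
recombination to shuffle it. Two predictions follow. First, somatic
mutations — which necessarily arise in the heterozygous state — accumulate
as **low-frequency heterozygous genotypes**, each carried by exactly the
clonal clade descending from the mutated ramet. Second, heterozygosity
present in the founding genet becomes **clonally fixed**: nearly every
sampled individual is heterozygous at those sites. The pipeline quantifies
this landscape at three scales: per site (het carrier frequency
*h* = n_het / n_called), per 200-kb window (mean of *h* over the window's
SNPs), and per region (LCHRs: runs of windows whose value stays above
mean + SD or below mean − SD of the genome-wide track for more than 5 Mb).

Class boundaries are read inclusively: *h* ≤ 0.10 is low-frequency and
*h* ≥ 0.90 is high-frequency. The LCHR length rule is strict
(run length > 5,000,000 bp, length summed over member-window spans).

## Synthetic data: what it emulates

The generator (`synthdata`) is a first-class model of the clonal regime,
not a fixture. Its components:

* **Clonal genealogy.** A random bifurcating tree over the samples. Each
  somatic mutation is assigned to one edge and inherited by every
  descendant leaf, so carrier sets of somatic sites are nested or disjoint
  — the defining signature of mutation without recombination. Edges are
  restricted to clades of at most 10 % of samples, placing somatic sites
  in the low-frequency class by construction. The somatic rate default
  (1e-6 new het mutations per lineage per bp) yields a somatic site
  density comparable to the founder/background densities, reproducing a
  regime in which roughly a third to a half of SNP sites are
  low-frequency heterozygotes.
* **Founder heterozygosity.** Sites heterozygous in each sample
  independently with probability 0.98 (occasional reversion to a
  homozygote emulates gene conversion / somatic loss). Density 8e-4 /bp
  inside planted high-LCHR segments and 1e-4 /bp in the background; zero
  inside planted low segments. The 8:1 contrast keeps the three window
  strata (high ≈ 0.75, background ≈ 0.36, low ≈ 0.1) separated by several
  window-level standard deviations, so planted segments are recoverable
  under the default mean ± SD thresholds rather than balancing on them.
* **Background polymorphism.** Ordinary Hardy–Weinberg sites whose group
  allele frequencies are Balding–Nichols draws,
  p_g ~ Beta(p̄(1−F)/F, (1−p̄)(1−F)/F) with F = `group_fst_target`,
  giving an expected Weir–Cockerham F_ST of ≈ F. The default target
  (1e-3) matches the near-panmictic differentiation typical of a clonal
  species; the generator also reaches moderate targets (0.05) for
  estimator-recovery checks. Background density is reduced to 0.3× inside
  planted low segments: a region purged of heterozygosity is modelled as
  depleted of intermediate-frequency polymorphism as well.
* **Outgroup.** One appended sample homozygous at ≥ 99 % of sites
  (0.5 % residual heterozygosity), homozygous-ref at founder/somatic
  sites and homozygous for either allele at background sites, so DAF
  polarization has both orientations to resolve.
* **Phenotypes.** Nine traits; each is Σ(effect × dosage) over its causal
  SNPs plus `env_weight` × a latent environmental factor plus Gaussian
  noise (SD 1 by default, so effects are in trait-SD units). Causal SNPs
  are drawn from background sites with MAF ≥ 0.15 so a dosage contrast
  exists at GWAS sample sizes.
* **Environment and geography.** Groups sit on a SW–NE gradient
  (~1.6° latitude per group) with local jitter; 12 environmental factors
  are linear mixtures of `env_latent_dim` latent factors, the first of
  which tracks latitude — giving the correlated factor structure that
  makes environmental PCs meaningful covariates.
* **Missingness** is uniform and genotype-independent — the simplest null
  for filter testing.

What it does **not** emulate: sequencing error and genotype-likelihood
uncertainty, linkage disequilibrium within the background class (sites are
independent given the genealogy), SV/CNV variation, selection, and any
spatially continuous population structure beyond the group gradient.
Passing tests therefore demonstrate correctness of the statistics and the
detection/consensus logic under the clonal model, not robustness to
caller artefacts or to LD-induced dependence.

## Numerical and convention choices

* **Windows** tile from position 1 per chromosome; the trailing partial
  window keeps its true span (both for its mean and for run-length
  accounting). Empty windows are flagged undefined, excluded from
  mean/SD, and break LCHR runs — "continuous" is read as contiguity of
  qualifying windows, so SNP deserts cannot bridge two regions.
* **Track moments** use the sample (n−1) standard deviation; at hundreds
  of windows the difference from the population form is immaterial.
* **θ_π and θ_w** divide by the fixed window span, not by callable sites,
  matching the windowed-diversity convention of the standard VCF tools.
  Per-site allele counts use called genotypes only; Watterson's
  correction uses each site's own called-allele count (sum of 1/a_{k−1}).
* **Tajima's D** uses the window's modal called-allele count for the 1989
  constants; windows with S = 0 or fewer than 4 called alleles are
  undefined (never reported as 0).
* **F_ST** is Weir & Cockerham (1984) with the observed-heterozygote
  correction; multi-site values are ratios of sums (Σa / Σ(a+b+c)).
  Per-site ratios are also exposed because the mean-of-ratios is the
  quantity recovered in the Balding–Nichols calibration.
* **LD pruning** approximates the phased-pairwise convention with
  genotype-dosage (composite) r², since true phase is unavailable for
  unphased calls — a documented deviation. Greedy within-window removal
  repeats until stable; missing dosages are mean-imputed for the
  correlation only.
* **IBS "flat-missing"**: a site with a missing call in either member of
  a pair contributes 0 to the mismatch numerator while the denominator
  stays 2 × total sites; Hamming is the same tally unnormalized.
* **Quantiles** (top-score regions, lowest-distance edges) use empirical
  order statistics without interpolation; ties at the cutoff qualify.
* **Mantel p-values** use the add-one rule, (1 + hits)/(1 + n_perm), so
  p is never 0; an exact enumeration mode covers small matrices.
* **Filters**: MAF strictly >, missingness strictly <, matching the
  conventional printed inequalities; the batch χ² test is Pearson without
  continuity correction on batch × allele counts; untestable sites (a
  batch with no called alleles, or a monomorphic site) are kept.
* **p-values** from the association scan are clamped to the smallest
  positive double so they stay in (0, 1] even when the t statistic
  overflows.

## Open design decisions

* The consensus rescue rule ("top 500 in each method and identified by
  more than two methods") is implemented with `min_methods=2` — the
  phrasing is read as "two or more", and the literal ≥ 3 reading is one
  argument away.
* The effective SNP number for the Bonferroni threshold is an input;
  when absent, the raw SNP count is used (conservative).
* The relatedness-network fraction is a parameter with presets 0.005 and
  0.01; both conventions appear in practice and neither is asserted as
  canonical.
* The association scan is a deliberately plain covariate-adjusted OLS: it
  is the table *generator* for exercising the consensus machinery, not a
  replacement for mixed-model or multi-locus methods, whose tables are
  consumed as TSV inputs with the same schema.
* `het_thresholds` is deliberately decoupled from detection so that
  externally reported track moments can be replayed through the same code
  path.

## Problem sizes

Default study conditions are chosen for a desk-scale analysis: 190
samples (+1 outgroup), two chromosomes totalling 36 Mb, ≈ 15–20 k SNPs,
planted 7.8-Mb high and 7.0-Mb low segments; GWAS panels of 190 samples ×
≈ 5,000 common SNPs with one causal variant at 0.8 SD, repeated over 20
seeds; calibrations use 20,000 null sites (batch χ²) and 400 null runs of
99 permutations (Mantel). These sizes make every invariant testable in
seconds to a couple of minutes on one core.

## Known limitations

* LCHR length accounting sums window spans; a run's reported interval is
  the union of its windows, so boundaries are quantized to the window
  size (200 kb by default).
* The per-window modal-k convention for Tajima's D is an approximation
  when missingness varies strongly within a window.
* `ld_prune` guarantees the r² bound only for pairs that co-occur in some
  scan window (as the windowed convention intends); genome-distant pairs
  are never compared.
* The Mantel permutation null assumes exchangeable locations; spatially
  autocorrelated noise (not simulated) would inflate its size, as it does
  for every Mantel-type test.
* `associate_linear` does not model kinship; on clonal panels the
  IBS-based sample pruning (`prune_related_samples`, cutoff 0.06) is the
  intended guard against duplicated genets.
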