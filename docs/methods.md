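# Methods

## The VMR caller

The unit of analysis is the per-probe sample standard deviation of beta
values (n−1 denominator) computed within a stratum (cell type × sex).
Probes with fewer than `min_samples_per_probe` (default 10) non-missing
values are excluded from threshold computation and can never count as
variable.

Windows are probe-anchored and half-open: for a probe at 1-based position
p, the window is [p, p + 1000). A window qualifies when (a) at least
`min_variable_probes` (3) of its member probes have SD at or above the
variability threshold and (b) those variable probes are at least
`min_variable_fraction` (50%) of *all* probes in the window. Overlapping
qualifying windows on a chromosome are merged; the merged VMR spans the
minimum to maximum position of its variable probes (not the window
edges), which is why mean VMR size comes out well under 1 kb. The
representative probe is the variable member with the highest SD, ties
broken by lowest genomic position.

The variability threshold is the 95th percentile (linear interpolation
between order statistics; ties at the threshold are included) of the SDs
of the **background probe set**: the union of probes in windows holding
≥ 3 probes. The same background set is the universe for every enrichment
statistic.

Calling runs separately per sex with per-sex thresholds, because a mean
methylation offset between the sexes inflates pooled SD at loci that are
not variable within either sex; the per-sex VMR sets are unioned, merging
overlapping intervals and pooling member probes. With fewer than two
samples of either sex the caller falls back to a single pooled run and
logs it.

Replication between two VMR sets uses a minimum 1 bp interval overlap.
The accompanying enrichment-over-chance is computed at the probe level:
with N background probes, n query-VMR probes and K reference-VMR probes,
expected sharing is nK/N, fold is observed/expected, and the p-value the
hypergeometric upper tail. This treats probes as exchangeable units; the
test suite checks it against a cluster-label permutation oracle in the
regime (one representative probe per cluster) where the two agree.

## Co-methylation networks

Inputs are the representative-probe betas, one column per VMR. The
correlation matrix is Pearson on beta values, pairwise-complete with a
minimum of 10 overlapping samples per pair (under-observed pairs get
r = 0 and a log flag). The network is unsigned: adjacency |r|^6. Soft
power 6 is the default; `scale_free_fit` reports, per candidate power,
the squared Pearson correlation between log₁₀(mean connectivity per bin)
and log₁₀(bin frequency) over 10 equal-width connectivity bins, choosing
the smallest power whose index reaches 0.8 and falling back to 6
otherwise. Note that a network made of a few equal-size tight modules has
a bimodal connectivity distribution and legitimately never fits a
scale-free line well; the fit index is informative only when
connectivity is heterogeneous, so the fallback path is the common one on
small planted simulations.

The TOM is the unsigned topological overlap,
TOM_ij = (Σ_{u≠i,j} A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 − A_ij) with
k_i = Σ_{u≠i} A_iu and unit diagonal; it is verified against a
triple-loop oracle at 1e−12 relative tolerance.

Module detection is a dynamic branch decomposition of the average-linkage
dendrogram of 1 − TOM: branches are visited recursively; a branch is
accepted as a module when it has ≥ `min_module_size` (10) leaves, none of
its sub-branches was itself accepted, and its mean internal dissimilarity
is below `branch_gap` (0.95) times the height at which it merges with its
sibling. The gap factor is what keeps loose, noise-level branches (whose
internal dissimilarity is essentially their merge height) unassigned;
without it any sufficiently large branch would qualify. This is a
deliberate re-implementation of the *idea* of hybrid dynamic tree cutting,
not a port of any particular codebase; its acceptance test is recovery of
planted modules, not label parity with other software.

Module refinement: the module eigengene is the first principal component
of the z-scored member columns, sign-oriented to correlate positively
with the mean member profile; kME(v, m) is the Pearson correlation of
column v with eigengene m. Members with |kME| < 0.7 are dropped;
unassigned VMRs whose best |kME| reaches 0.7 are rescued into that module
(this mirrors common practice and repairs near-boundary dendrogram splits,
e.g. a 12-leaf module splitting 10+2 where the 2-leaf remnant would
otherwise be orphaned); modules falling below the minimum size are
dissolved. kME uses the absolute value because the even soft power makes
the network sign-blind.

## Enrichment statistics

All probe-level enrichments use the fold formula
(k/n)/(K/N) — VMR-probe hit rate over background hit rate — with exact
hypergeometric tails (upper for enrichment, lower for depletion, both
always reported with a direction column). TFBS enrichment is at the VMR
level: each factor's sites are extended ±500 bp, a VMR overlaps at ≥ 1 bp,
and the 2×2 table (in-module vs not) × (overlap vs not) over all VMRs is
tested one-sided by Fisher's exact test with Bonferroni across factors.
GO enrichment runs over unique linked genes (a gene linked by several
VMRs counts once) against the background-gene universe, hypergeometric
with Benjamini–Hochberg FDR; terms annotating fewer than 3 universe genes
are skipped. Genes are linked to a VMR when the VMR intersects the closed
window TSS ± 2000 bp; auxiliary link tables (DHS-expression links, eQTMs)
are merged with their provenance recorded.

## Environmental statistics

Twin discordance is the per-probe mean of |β_twin1 − β_twin2| over pairs
with both values present. Under the generator's model the difference at
an environmentally responsive probe is Normal with variance
2(env_sd² + noise_sd²), so the expected mean absolute discordance has the
folded-normal closed form 2·s/√π, s² = env_sd² + noise_sd²; the
acceptance test requires agreement within 10% at 100 pairs.

The exposure test is a per-probe two-sample Student's t (pooled variance,
Welch behind a flag), with −log₁₀ p contrasted between VMR and background
probes by a Wilcoxon rank-sum test. The time-course caller is the
population caller run unstratified on the series (minimum-sample rule
relaxed to the series length, no quantile normalization at n = 9), with a
per-VMR Spearman trend against the time index.

Heritability is consumed as a user-supplied per-probe table and only
compared between probe sets; no variance-component estimation is done.

## The synthetic-data generator

The generator's defaults define the study conditions: 5 chromosomes ×
4,000 probes in clusters of Poisson(4)+1 probes spaced ~150 bp and
separated by > 12 kb gaps; per-probe baselines from a bimodal mixture
(45% near β = 0.1, 45% near 0.9, 10% intermediate, clipped to
[0.05, 0.95]); iid Gaussian measurement noise (SD 0.02) clamped to
[0.001, 0.999]; 100 samples; 50 planted VMR clusters whose probes share a
per-sample latent shift z_v ~ N(0, 0.15), of which 36 load on three trans
module factors (z_v = 0.15·(0.9·f_m + √(1−0.81)·ε_v), module members
spread round-robin across chromosomes so every module is trans); a 0.10
mean offset between the sexes at 20 non-VMR clusters; 40% of planted VMRs
flagged environmentally responsive. The effect-to-noise ratio (7.5×)
reflects the visibly bimodal per-individual spread real VMRs show; it is
configurable. Planted clusters are re-centred to intermediate baselines
(uniform 0.3–0.7) so latent shifts are not crushed by boundary clamping.

The planted layout is drawn from a seed stream derived only from the
config, so the population, twin, exposure and time-course designs built
from one config plant the same loci — cross-design overlap analyses then
have a real shared signal to measure.

Deliberate simplifications: beta values are clamped Gaussians, not Beta
variates (the caller's statistic is the SD, not distributional shape);
no probe-type chemistry, batch effects, or cell-composition mixtures; the
exposure design carries no per-sample latent variation, so its per-probe
SD equals the noise SD and the group test's effect size is exactly
delta/noise. Consequently, passing tests demonstrate that the algorithms
recover the structure they target under their stated assumptions — not
that real arrays are free of the technical structure the generator omits.

## Numerical and design choices

* Coordinates: probes and internal intervals are 1-based (closed);
  BED files are 0-based half-open, converted only at the I/O boundary.
* Quantile normalization replaces each sample's values by the mean of
  per-sample order statistics (ties receive the average of the tied
  reference entries; samples with missing values are mapped by rank
  interpolation against the same reference). With complete data the
  sorted per-sample vectors are exactly equal afterwards. In the
  synthetic pipeline it is **off by default**: it exists to remove
  between-array distribution shifts, which the generator does not
  emulate; on already-commensurable data it only propagates rank noise at
  distribution edges (measured: false-discovery proportion 0.19 with it,
  0.10 without, at unchanged sensitivity). It remains available as a
  config toggle and via `vmrscan preprocess`.
* Probe filters run in a fixed order (detection-p masking →
  sex-chromosome → SNP → CNV → sample-fail drop) and the report counts
  removals per step, so the counts are interpretable. The SNP window is
  the closed interval [pos − 5, pos + 1], covering the CpG dinucleotide
  and 5 bp upstream.
* The filter interpreting "failed in too many samples" uses the fraction
  of samples in which a probe's detection p exceeds the threshold
  (default 5%), exposed as a parameter.
* All randomness flows through integer seeds recorded in provenance
  blocks; the pipeline is single-process and rerunning a config with the
  same seed is byte-identical.
* Problem sizes in the test suite (e.g. 3 × 800-probe chromosomes for
  unit tests, 20,000 probes × 10 seeds for the recovery sweep, 20 seeds
  for module recovery) were chosen as the smallest sizes at which the
  statistical assertions are stable.

## Known limitations

* The branch decomposition can oversplit a very large homogeneous module
  into two accepted sub-branches; the kME rescue reassigns members but
  the partition may differ from coarser cutters. At the planted module
  sizes tested (12 VMRs) this does not occur.
* The probe-level replication enrichment assumes exchangeable probes;
  with strongly varying cluster sizes it is only an approximation to the
  cluster-permutation null.
* The false-discovery proportion of the caller at the default conditions
  is dominated by chance co-exceedance of the 95th-percentile threshold
  by 3-probe clusters (~5 calls per 20,000 probes per sex-stratified
  run); it sits near 0.10 of calls and scales with the percentile rule
  itself, not with any implementation choice.
* Heritability, DHS and eQTM inputs are taken as given; no attempt is
  made to estimate them.
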