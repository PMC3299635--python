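# Methods

This note documents the models, conventions and design choices behind
`rohmap`, in the spirit of the methods documentation of packages such as
msprime or statsmodels: what is computed, under which assumptions, and what
the synthetic benchmarks do and do not demonstrate.

## ROH detection

A 50-SNP window is *homozygous* when it contains at most 1 heterozygous and
at most 1 missing genotype. A SNP is ROH material when the fraction of
windows spanning it that are homozygous strictly exceeds 0.05. Windows never
cross chromosome ends; near an edge the spanning-window count (the
denominator) shrinks. A chromosome shorter than one window supports no
windows, and no calls. Maximal runs of flagged SNPs are split where adjacent
SNPs are more than 1 Mb apart (`max_gap_kb`), and kept when they contain at
least 50 SNPs, span at least 1 Mb, and average at least 1 SNP per 50 kb.

Conventions worth stating:

* Coordinates are 1-based inclusive; `length_kb = (end − start + 1)/1000`.
* `min_snps` defaults to 50 (not PLINK's 100): segments of exactly 50 SNPs
  are legitimate calls under a 50-SNP window rule.
* There is no cap on heterozygotes inside a final segment beyond what the
  window rule admits; per-segment het/missing counts are reported so users
  can post-filter.
* Segment boundaries are exactly the flagged-SNP runs; no edge trimming.

**Window smearing and truncation.** For a noise-free homozygous run, called
boundaries can exceed the true edges by at most `window_snps − 1` SNPs per
side (windows reaching into the run can pass). Under missingness, the
1-missing-per-window cap is strict: two nearby missing calls inside a true
run can un-flag a handful of SNPs, splitting the call, and a resulting
fragment below the 1 Mb floor is discarded, truncating the recovered
boundary by up to a few hundred SNPs. At 1% missingness this affects roughly
one run in six. With the more tolerant cap of 5 missing per window (the
PLINK default) the one-window boundary bound holds essentially always; the
strict cap is retained as the default here because it is the documented
analysis rule, and the test suite reports the truncation behaviour rather
than hiding it.

The brute-force oracle (`brute_force_roh`) re-implements the identical
contract by enumerating every window and every candidate run in plain
Python; the fast caller must match it segment for segment.

## Common/rare classification

For each minimum-length stratum t ∈ {2, 3, 4, 5} Mb: a per-SNP track counts
distinct individuals with a qualifying ROH covering the SNP; maximal runs of
SNPs at carrier frequency ≥1% become hotspot regions. A qualifying ROH that
overlaps a region by ≥1 bp is marked common unless its length strictly
exceeds the region's retention cutoff, mean + 3×SD of the lengths of all
qualifying ROHs overlapping that region (population SD, n denominator, for
determinism; immaterial at realistic carrier counts). A ROH is rare iff no
stratum marks it common; removals accumulate across strata. ROHs under 2 Mb
are outside the split (downstream analyses use ≥2 Mb). A region overlapped
by fewer than two ROHs has undefined SD; SD is set to 0 so the cutoff
collapses to the region mean (this cannot occur at a 1% threshold on
realistic sample sizes). Any-overlap membership is the default; a
full-containment mode is available (`containment=True`).

## Burden statistics

Proportion (fraction of group members with ≥1 qualifying ROH) and rate
(mean qualifying-ROH count per member) per threshold; case/control ratios;
one-tailed equal-variance t-tests (cases > controls; Welch by flag); and
empirical p-values from case/control label permutation with the add-one
estimator p = (1 + r)/(1 + B), which is never zero and is valid
(super-uniform) under the null. The permutation statistic is the difference
in group means — of the carrier indicator for proportion, of the count for
rate; group sizes are preserved by permuting labels. The default B is
10,000, configurable; the original analysis scale of 10⁸ permutations is a
cluster-scale setting, not a library default.

## Covariates and models

* **LD pruning:** greedy windowed pruning (window 50, step 5, r² ≤ 0.2,
  PLINK folk-standard; all configurable). Within a window, while any pair of
  retained SNPs exceeds the r² cap, the lower-MAF member is dropped (ties:
  later position). Correlations are computed on mean-imputed centred
  dosages.
* **Inbreeding coefficient:** method of moments,
  f = (O − E)/(N − E), with E the sum over the sample's non-missing pruned
  SNPs of 1 − 2p q T/(T−1), T the non-missing allele count at the SNP. The
  T/(T−1) factor makes the 2pq term unbiased for the panel; a naive
  uncorrected variant is available by flag. f is computed on the pruned
  subset so local haplotype structure does not masquerade as autozygosity.
* **MDS:** classical metric scaling of D = 1 − IBS-similarity
  (IBS-similarity = mean shared alleles / 2 over SNPs called in both
  samples). Coordinates are eigenvectors scaled by √eigenvalue, ordered by
  decreasing eigenvalue, sign fixed by making each axis's
  largest-magnitude loading positive. A sample pair sharing no called SNP
  is an error (filter missingness first).
* **Logistic series:** Models 1–4 add covariates cumulatively
  (— / f / f, age / f, age, C1, C2) for two predictors per threshold: the
  binary indicator of ≥1 rare ROH (proportion) and the rare-ROH count
  (rate). Fits are maximum likelihood via statsmodels (Newton, tol 1e-8,
  100 iterations); complete cases only, dropped counts reported in
  `n_used`. Perfect separation or non-convergence is flagged on the result,
  never silently reported. 95% CI = exp(β ± 1.96 SE).

## Homozygosity mapping

Pools are connected components of the per-chromosome interval-overlap graph
with ≥2 members (allelic matching is deliberately not required). Because
overlap is not transitive, a pool's global intersection can be empty; the
pool then splits into its maximal mutually-overlapping sub-groups (the
maximal cliques of an interval graph, found at interval right endpoints),
each yielding its own consensus interval. A consensus region must span at
least 2 consecutive map SNPs; identical intervals across pools are emitted
once.

Carrier counting is by complete overlap: an individual carries a region iff
one of their ROHs contains the whole region, counted once per individual.
The permutation statistic is the case-carrier count (group sizes are fixed
under permutation, so this is equivalent to case excess). Family-wise
correction is max-T: each region's permutation distribution is standardised
by its own mean/SD, and the corrected p of a region is the fraction of
permutations in which *any* region's standardised statistic reaches the
region's observed standardised value (add-one estimator; a region with a
degenerate permutation distribution standardises to 0). Bonferroni is also
reported. Max-T was chosen over Bonferroni because carrier statistics across
regions are strongly dependent (one long ROH spans many regions), making
Bonferroni sharply conservative.

**Calibration and discreteness.** Carrier counts are small integers, so the
permutation p-value is discrete and, with the add-one estimator,
super-uniform (conservative) under the null — a valid p-value. Its empirical
distribution over null replicates therefore cannot pass a two-sided test of
exact uniformity; the meaningful calibration property, which the test suite
asserts, is the absence of anti-conservatism (one-sided KS against the
empirical CDF exceeding the uniform).

Gene-based mapping applies the same machinery to a caller-supplied gene
interval list (containment counting by default, any-overlap by flag) and
merges genes with identical carrier sets into groups, since such genes are
statistically a single test.

## Synthetic data generator

The generator emulates a post-QC case-control SNP panel:

* SNP positions: cumulative sums of exponential gaps, mean 6,500 bp
  (≈1 SNP per 6.5 kb, matching a ~400k-SNP genome-wide panel), so any ≥2 Mb
  run is detectable by construction at the 1-per-50 kb density floor.
* MAFs uniform on (0.05, 0.5), matching post-QC GWAS panels.
* Background genotypes per SNP from HWE inflated by per-sample F:
  (p² + pqF, 2pq(1−F), q² + pqF). Genotypes are independent across SNPs —
  no background LD — because ROH calling responds to homozygosity runs, not
  haplotypes. An optional block-LD mode (latent block haplotypes copied
  with error, giving within-block r² ≈ a target) exists to exercise the
  pruner.
* Planted autozygous runs overwrite genotypes with homozygous calls whose
  allele is drawn by population frequency; heterozygote miscalls (planted
  runs only) and global missingness are applied afterwards. IBS hotspot
  clusters plant independent runs with Normal lengths truncated at 2 Mb,
  centred in a configured region.
* Phenotypes: fixed group sizes, or drawn from
  logit P(case) = intercept + β × planted-run count.

What passing tests on this generator do **not** show: behaviour under real
LD structure (hotspot boundaries in real data are haplotype-shaped),
genotyping batch effects, related individuals, or population admixture
beyond the two-subpopulation MDS check. The generator's F acts on single
SNPs; real autozygosity is segmental, which is why the subgroup analyses
("carriers of long runs also carry more short runs") are exercised by
planting per-individual segment budgets rather than by the F parameter.

## Benchmark problem sizes

The statistical benchmarks use desk-scale panels chosen to keep the full
suite a few minutes on one CPU while leaving each check well-powered:
type-I calibration uses 500 replicates of 1,000 samples × 2,000 SNPs with
B = 1,000 permutations; power and locus-mapping checks use 500/500 samples;
f recovery uses 20,000 independent SNPs and 50 samples per consanguinity
level; odds-ratio recovery uses n = 4,000. The mapping benchmark's
background rare-ROH density (1% carriers of a 2–2.8 Mb run on a ~26 Mb
two-chromosome panel) is scaled from a genome-wide rare-ROH rate of ≈0.9
runs per person over ≈3,000 Mb.

## Known limitations

* No genetic-map (cM) lengths; physical distance only.
* No likelihood/HMM autozygosity caller; the window rule is the contract.
* The exact multiple-testing scheme of legacy analyses of this design is
  not reverse-engineerable; max-T is this package's documented choice.
* Binary PLINK (BED/BIM/FAM) is not parsed; text PED/MAP is the interface.
* The logistic models assume independent samples (no kinship adjustment).
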