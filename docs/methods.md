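# Methods

## Problem setting

Genomic breeding values (GEBVs) are dosage-weighted sums of per-marker
effects: with an $n \times m$ matrix of alternate-allele dosages and an
effect vector $\hat g$ per trait, the prediction is $\hat b = M\hat g$ for
SNP-array genotypes and $\hat a = N\hat g$ for sequence-derived genotypes.
Low-coverage sequencing (0.5–6x) makes $N$ noisy in two distinct ways: a
depth-dependent chance of calling a heterozygote homozygous, and outright
missing loci (no overlapping read). The package implements the complete
chain from per-locus read counts through genotype calling, three
missing-genotype strategies, prediction and evaluation, plus a synthetic
generator so every stage is testable at desk scale.

## Genotype calling: the depth-adaptive minimum allele count

For a true heterozygote sequenced to depth $d$, the alternate-read count is
$X \sim \mathrm{Bin}(d, 1/2)$. The genotyper derives, per exact integer
depth, the largest threshold $t(d) \ge 1$ such that

$$P(t \le X \le d - t) \ge 0.95,$$

falling back to $t = 1$ where no threshold reaches the target
($d \le 5$ at the default). A cell is called heterozygous when both allele
counts reach $t(d)$, homozygous for the majority allele otherwise; a single
read calls a homozygote for the observed allele; zero depth is missing.
Reads matching neither target allele are recorded but excluded from depth
and from the call, so third-base sequencing errors cannot shift thresholds.

Two consequences are worth stating explicitly because they bound what any
downstream result can show. First, choosing the **largest** qualifying
$t$ maximises protection against error reads faking an allele, but pins
heterozygote sensitivity to the smallest achievable value at or above 95%
at *every* depth — roughly 3–5% of true heterozygotes are called
homozygous even from error-free reads. Exact recovery therefore saturates
near 98–99% overall (and above 99.5% on homozygous loci) no matter how
deep or clean the data; the tests assert exactly those saturation limits.
Second, because the rule depends only on the two counts, calls are
invariant to read order and the whole matrix is callable by a vectorised
depth-indexed table lookup.

## Missing-genotype strategies

* **non-imputed** (`fill_homref`): missing cells become dosage 0. An
  individual's prediction loses every term at its missing loci, so
  predictions shrink with missingness.
* **imputed-AF** (`fill_af`): missing cells get the Hardy–Weinberg
  expected dosage $0(1-p)^2 + 1 \cdot 2p(1-p) + 2p^2 = 2p$ for population
  alternate-allele frequency $p$ — a continuous dosage. An individual
  missing everywhere receives exactly the population-mean prediction
  $\sum_i 2 p_i \hat g_i$; partial missingness regresses predictions
  toward that mean.
* **imputed-LD** (`impute_ld`): a deterministic windowed haplotype-pair
  matcher against a phased reference panel. For each missing cell, every
  unordered panel haplotype pair is scored by how many of the up-to-$K$
  called loci on each side (default $K = 10$) match the pair's dosage;
  the best pair(s) supply the missing dosage, ties averaged. Scores and
  dosages are symmetric in the pair, so unordered pairs give the same
  tie-average as ordered ones at half the cost; missing cells between
  the same two called loci share a window and are imputed together.
  Cells with no called locus in the window fall back to the
  Hardy–Weinberg dosage and are labelled as such.
* **Beagle adapter** (`beagle_adapter`): optional bridge to external
  Beagle 5.1 (VCF out, `ne=100000`, `window=100`, read imputed GT back;
  raise the window toward ~158 cM for very sparse 0.5x inputs so called
  markers still overlap the panel in every chromosome window). The
  adapter is never required: when the executable is absent it raises a
  documented error pointing at `impute_ld`, and with nothing missing it
  returns its input without invoking the program.

No strategy ever alters a called cell; all outputs stay in $[0, 2]$.

## Evaluation

* **Concordance** scores each cell by correctly called alleles,
  $2 - |g_{\mathrm{seq}} - g_{\mathrm{array}}|$, giving both-correct /
  one-wrong / both-wrong proportions over hard-called, non-missing cells
  (missing counted separately; continuous dosages are excluded rather
  than rounded).
* **Correlation** is the Pearson correlation of $\hat a$ with $\hat b$.
* **Prediction bias** is the OLS slope of $\hat b$ on $\hat a$, fitted
  with an intercept so scale bias is not conflated with location shifts
  (raw 0–2 dosages are not centered, so constant offsets are real).
  Slope 1 means the sequence predictions are correctly dispersed;
  slope > 1 means they are shrunk toward the mean, under-predicting
  high-merit individuals.
* **Covariate screening** uses a two-stage regression: residuals of
  $\hat b \sim \hat a$ regressed on a per-sample covariate (read length,
  base quality, ...), reporting the slope and two-sided t-test p-value
  with a 0.01 significance convention and no multiplicity correction.

`run_experiment` sweeps coverages × fill methods × traits on one
simulated cohort: lower coverages are produced by binomial thinning of
the full-coverage counts (each read kept with probability
`target/full`), mirroring a subsampled sequencing run, not a fresh one.

## The synthetic generator

The generator emulates the statistical structure the analysis needs,
not sequence-level detail.

* **Panel**: founder haplotypes are marker-wise Bernoulli($p_i$) with
  $p_i \sim U(0.05, 0.95)$; panel haplotypes copy a founder and switch
  template between adjacent markers with probability `switch_rate`
  (default 0.005, i.e. haplotype blocks of ~200 markers — at typical
  array density of one SNP per ~4 kb this is the long-range linkage
  disequilibrium of a closed cattle population with strong recent
  relatedness). Marker order is the only positional structure; genetic
  map distances are not modelled.
* **Individuals**: two haplotypes each, drawn from the panel by the same
  mosaic process; dosage is their sum. The locus list records the panel
  empirical alternate-allele frequency, which is what the AF fill
  consumes (the frequency "calculated from array data" of a real
  pipeline).
* **Marker effects**: the default emulates how SNP-BLUP effect tables
  are produced in practice. True effects $\gamma$ are i.i.d.
  Normal(0, `effect_sd`²); a reference cohort (default 400 individuals)
  is drawn from the panel; and the returned effects are the ridge
  back-solve $\hat g = Z_c'(Z_cZ_c' + \lambda I)^{-1} Z_c\gamma$ with
  $\lambda$ = `ridge` × mean diagonal of $Z_cZ_c'$, rescaled to
  per-marker SD `effect_sd`. The back-solve matters scientifically:
  back-solved effects lie in the row space of the reference genotype
  matrix, so between-individual GEBV variance is large relative to
  per-locus sampling noise. That is the regime in which mean-imputation
  visibly shrinks prediction variance (bias slope > 1 at low coverage);
  with effects drawn independently of the genotype structure
  (`method="iid"`, also available) the independent-noise terms dominate
  and the slope cannot exceed 1 in expectation — the qualitative bias
  pattern is then unobservable at any sample size. Both methods produce
  a highly polygenic architecture (largest single-marker share of the
  summed magnitude of order $1/m$).
* **Pileups**: depth per individual × locus is Poisson(`coverage`);
  each read reports the wrong allele with probability $10^{-Q/10}$
  (symmetric ref↔alt flip; an `other_rate` switch reroutes a fraction of
  error reads to a third base to exercise the genotyper's other-allele
  handling). Reads are collapsed to counts: no read lengths, mapping or
  FASTQ; run-level covariates (read length, yield, mapping quality) are
  summary statistics supplied as numbers, as in the run-summary table.
* **Seeding**: one master seed; every operation draws from a named,
  documented substream, so regenerating one artifact never perturbs
  another, and identical configurations are bit-identical.

What passing tests on this generator do **not** show about real data:
no genetic map, no variable marker spacing, no mapping or alignment
artifacts, no coverage heterogeneity along the genome or between
samples, no multi-allelic sites or indels, and a panel whose haplotype
diversity (8 founders, 40 haplotypes) is far below a real 1,200-animal
panel. Absolute correlations and biases from the sweep are therefore
properties of these study conditions, not forecasts for any particular
real cohort; the direction and ordering of effects (correlation falling
with coverage, homref/AF over-shrinkage, LD imputation restoring the
scale) are the transferable content.

## Numerical and design choices

* Depth for genotyping is `ref + alt`; other-allele reads never enter
  depth or calls.
* Thinning operates on counts (binomial per read), distributionally
  equivalent to subsampling reads under uniform coverage.
* Coordinates are 1-based; ref/alt are single forward-strand bases; a
  locus list is keyed by (chrom, pos) and loci are matched to effect
  tables by (chrom, pos, ref, alt), with allele-swapped records sign-
  flipped rather than dropped, and mismatches reported, never silently
  reordered.
* Ties in the LD imputer are averaged (deterministic), not sampled;
  averaged dosages may be continuous, consistent with the dosage-matrix
  contract.
* Degenerate inputs raise typed errors (zero depth everywhere, zero
  variance in a regression, empty panel) rather than returning NaN.
* The default sweep (5 replicate cohorts of 200 individuals × 2000
  markers, coverages 4/2/1/0.5x at Q 20.54 thinned from 6.3x) was
  chosen as the smallest design in which the seed-averaged bias and
  correlation orderings are stable; it runs in about a minute on one
  core.

## Known limitations

* The built-in LD imputer is a windowed matcher, not a phasing HMM: it
  degrades when the cohort's haplotypes are poorly represented in the
  panel, and its window is marker-count-based, not genetic-distance-
  based.
* Marker effects are exchangeable across loci; no major genes, no
  frequency-dependent effect sizes.
* The genotyper's 95% rule caps heterozygote sensitivity by design (see
  above); pipelines needing near-perfect deep-coverage calls should
  lower the target or use genotype likelihoods, which are out of scope
  here.
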