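# Methods

## The model

Each growth trait y (n fish) is decomposed as

    y = X b + S c + Z g + W q + e

- **b** — fixed effects: population mean and a selection-line contrast.
  Keeping the line contrast in X throughout the scan prevents
  line-stratified markers from masquerading as QTL.
- **c ~ N(0, I σc²)** — random cage effect. Each full-sib family occupies
  one cage, so cage and family environment are confounded by design; the
  cage term absorbs both.
- **g ~ N(0, K σg²)** — polygenic effect, with K the realized genomic
  relationship matrix (VanRaden's first method): K = WW′ / (2 Σ pⱼ(1−pⱼ)),
  dosages column-centered by 2pⱼ, allele frequencies pooled over both
  lines (one K enters one model), missing dosages mean-imputed per marker,
  monomorphic markers excluded. Eigenvalues below −1e−8 are an error;
  smaller negatives are numerical noise. A ridge δ on K's diagonal is
  available where K⁻¹ is required.
- **q** — allele-substitution effects of currently selected major QTL,
  fitted as fixed regressions on dosage columns.
- **e ~ N(0, I σe²)** — residual.

The phenotypic covariance is V = σc² SS′ + σg² ZKZ′ + σe² I. Effects solve
Henderson's mixed model equations with blocks ordered (b, q, c, g); the
cage block carries S′S + λ₁I and the polygenic block Z′Z + λ₂K⁻¹ with
λ₁ = σe²/σc², λ₂ = σe²/σg². A random term whose variance estimate is zero
is dropped (the infinite-λ limit). Breeding values are GEBV = Zĝ + Wq̂
(an exact identity of the returned fit), and

    h² = (σq² + σg²) / (σq² + σg² + σc² + σe²),

where σq² is defined as the sample variance of the fitted fixed-QTL term
Wq̂ — the decomposition table gives this quantity a name but no formula,
so the realized-variance definition is adopted; per-QTL contribution is
Cp = Var(wⱼq̂ⱼ)/V̂p with V̂p = σq² + σg² + σc² + σe².

## Variance-component estimation

REML over (σc², σg², σe²), with the QTL columns treated as fixed
covariates. σe² is profiled out and the restricted log-likelihood is
maximized over the log variance ratios (γc, γg) = (σc², σg²)/σe² by
Nelder–Mead from several starting points spanning interior and
near-boundary regimes (boundary solutions are genuinely common: several
traits in this class of data put σg² or σc² at zero). Ratios below 1e−8
are reported as exactly zero. Convergence tolerance is 1e−6 on the
restricted log-likelihood; failure to produce a finite optimum raises an
error carrying the likelihood trace. Each evaluation is one Cholesky
factorization of an n×n matrix (n ≈ 250), so a full fit takes well under
a second.

Identifiability caveat: with K = I the polygenic and residual structures
coincide and only σg² + σe² is identified; the test suite checks the
identified sum in that configuration.

## Genome scan and stepwise selection

During the per-marker scan the variance components are held fixed at
their current REML estimates (the standard approximation for
mixed-model association at this scale). The data are whitened by the
Cholesky factor of V, after which each candidate marker is an OLS
regression; the Wald test is a t-test with n − p − 1 degrees of freedom,
which calibrates better at n = 250 than the asymptotic chi-square (the
acceptance suite verifies a pooled null rejection rate of 0.05 ± 0.02).
Monomorphic and collinear candidates (whitened residual norm below 1e−10
of their total norm) are skipped.

Stepwise selection: forward-add the most significant marker while its
p-value clears the Bonferroni threshold α / (markers tested this round);
re-estimate variance components after each inclusion; backward-remove any
included marker whose conditional p-value (given the others) rises above
the threshold; exclude markers within 1 Mb (configurable) of an accepted
QTL from later rounds; stop when no candidate qualifies or at max_qtl.

## Population-genetic scan

Per-site Fst uses the Weir & Cockerham (1984) estimator with the
individual-level components a (among populations), b (among individuals
within populations) and c (within individuals; observed heterozygosity),
Fst = a/(a+b+c) — matching the per-site output of the standard VCF
toolchain. Undefined sites (zero denominator) are NaN, distinct from 0;
negative estimates are retained for window means and ranking.

Nucleotide diversity per site is π = 2·nA·na/(n(n−1)) over observed
alleles (the exact mean pairwise difference). Windows are non-overlapping,
tiled from position 1, half-open [start, start+size); window π is the sum
of per-site π divided by the window span in bp (the natural scale for
sparse marker panels — note its magnitude depends directly on marker
density). Window Fst is reported unweighted (mean of per-SNP values),
weighted (Σa/Σ(a+b+c)) and as the 95% quantile with linear interpolation
between order statistics, so quantile flags are exactly reproducible.
Defaults follow the study conventions: 1 Mb windows for signature calling
(flags: mean > 0.05, q95 > 0.25), 2 Mb for diversity reporting, 100 kb
for the Manhattan export, and top-1% outlier SNPs (threshold = 99%
quantile of defined per-SNP Fst, ties included).

The overlap stage emits a hit when a QTL position falls inside a flagged
window (default criterion: the q95 flag; the mean flag and
"window contains a top-quantile SNP" are selectable, since published
practice varies between them), and reports per-line allele frequencies
for all SNPs within ±5 kb of a candidate, flagging loci fixed in one
line.

## The synthetic cohort generator

The generator emulates the study design the analysis assumes: 25 full-sib
families (19 selection, 6 control), 2 parents + 8 offspring each, one
cage per family. Defaults are desk-scale — 5,000 SNPs on 10 chromosomes
of 2 Mb — chosen so a full simulate-to-overlap run takes seconds while
preserving every structural feature (family blocks, two lines, cage
confounding, genome-wide marker map).

- **Founder frequencies**: ancestral p ~ U[0.05, 0.95]; a configurable
  fraction of markers is line-divergent, with each line's frequency drawn
  independently from the Balding–Nichols distribution
  Beta(p(1−F)/F, (1−p)(1−F)/F) at differentiation parameter F. This is
  the standard single-parameter divergence model and matches the Fst
  estimand; note that independent draws put substantial probability on
  near-equal realized frequencies, so individual "divergent" markers vary
  widely in realized differentiation even though the multi-locus
  (ratio-of-sums) Fst matches F to within sampling error.
- **Clustered divergence** (`divergent_centers`): markers segregate
  independently — no recombination map or multi-generation selection is
  simulated — so the local hitchhiking footprint that surrounds a truly
  selected site cannot emerge from the dynamics. When a scenario needs
  that topology (a swept region around a trait locus), the divergent
  block is planted directly around the chosen marker, clipped to its
  chromosome. Scattered divergence remains the default.
- **Genotypes**: parents Binomial(2, p_line); offspring receive one
  allele per parent per marker (exact Mendelian transmission). Optional
  uniform missingness.
- **Phenotypes**: generated from the fitted model itself — fixed line
  effect (default 1.0), cage effects N(0, σc²), polygenic vector drawn
  N(0, K σg²) with K computed from the simulated genotypes (so simulation
  truth and fitted model coincide exactly), planted QTL effects applied
  to centered dosages (planting a QTL does not move the trait mean), and
  i.i.d. residuals. Default variance components σc² = 0.1, σg² = 1.0,
  σe² = 0.9 give h² = 0.5 with a realistically small cage component.
- Parents receive phenotypes too, so either parent-inclusive or
  offspring-only analyses can be exercised; the analysis default includes
  them.

What passing tests on this generator do **not** show about real data:
there is no linkage disequilibrium beyond family structure, no
genotyping-error model, no multi-generation selection dynamics, and
marker density (1 per 4 kb) is far above reduced-representation panels
(≈1 per 30 kb), which scales per-bp window π upward correspondingly.

## Numerical and design notes

- Dosage containers use NaN for missing; MAF and call-rate QC act on
  observed alleles only; QC is idempotent.
- VCF coordinates are 1-based inclusive; all window logic converts to
  half-open intervals; a position exactly at a window end belongs to the
  next window.
- Sampling-theory caveat: the Weir–Cockerham estimator corrects for
  sampling of independent individuals, but full-sib cohorts have far
  fewer founder chromosomes than fish (here ~76 vs 24 per line), so
  background per-site Fst between lines is inflated relative to an
  unrelated-sample design. This is a property of the study design itself
  and affects any analysis of such cohorts; the top-quantile threshold is
  a rank rule and remains well-defined.
- Stepwise detection power for a QTL at Cp ≈ 0.2 under a 5,000-marker
  Bonferroni threshold is moderate (the strongest marker usually
  localizes the locus, but its p-value does not always clear α/m);
  localization, not guaranteed inclusion, is the tested guarantee at that
  effect size.
- Determinism: every stochastic step draws from
  `numpy.random.default_rng` seeded from the cohort/run seed (salted per
  stage), so identical config + seed reproduce outputs byte-for-byte;
  the pipeline manifest records SHA-256 checksums to verify this.
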