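# Methods

## Model and procedure

The pipeline aggregates per-SNP case-control association p-values to the
gene level, reconciles two gene statistics by meta-combination, and tests
the selected genes for pathway over-representation.

### SNP-to-gene assignment

A SNP is assigned to a gene iff it lies on the same chromosome within
`[start − flank, end + flank]`, both boundaries **inclusive**, with
`flank = 50 kb` by default. The inclusive reading of the ±50 kb window is a
deliberate maximal-inclusion choice and is pinned by boundary tests (a SNP
exactly 50,000 bp upstream is in; 50,001 bp is out). A SNP inside several
extended intervals is assigned to all of them; there is no nearest-gene
tie-breaking, so neighbouring genes legitimately share signal. Gene
boundaries (not transcript-aware UTR coordinates) anchor the flank.
Coordinates are 1-based inclusive throughout, and chromosome labels are
compared after stripping a leading `chr`.

### Gene statistics and the MVN null

Method A inverts each SNP p-value to a 1-df chi-squared value and sums
them; method B takes the minimum SNP p-value. Method B is the package's
fully specified stand-in for generic set-based gene screening: it preserves
the two-method architecture with an independent, reproducible statistic.

Under the null, the vector of SNP z-scores in a gene is modelled as
MVN(0, R) where R is the LD correlation matrix. R is either supplied
directly (synthetic studies, where the generating AR(1) matrix is known) or
estimated as the Pearson correlation of reference-panel dosage columns.
Either way R is regularized by eigenvalue flooring (clip at ε = 1e-8,
reconstruct, renormalize the diagonal to 1) so that a Cholesky factor
always exists — perfect LD (duplicated markers) occurs in real and
synthetic panels alike. Null replicates are `z = L u` with `L L' = R` and
`u` standard normal; the sum replicate is `Σ z_i²` and the min-p replicate
is the 1-df upper tail at `max z_i²` (equal to the minimum across SNPs of
the per-SNP tail, computed without forming all k tails).

**Empirical p-values** are `r/N` with ties counted as exceedances (the
conservative direction). `r/N` rather than `(r+1)/(N+1)` is used so that a
zero-exceedance outcome is representable; it is then reported as the upper
bound `1/N` with `is_upper_bound = True`, matching the convention that an
empirical zero from 10⁶ simulations means p < 10⁻⁶. Downstream, bounded
p-values are combined at their bound value and the combined result inherits
the bound flag.

**Adaptive staging**: 10³ replicates first; escalate to 10⁴ when the
current empirical p < 0.1; escalate to 10⁶ when the 10⁴-replicate p
< 0.001; at the final stage a zero-exceedance result becomes the bound, not
more simulation. The thresholds are applied to the stage's own (bound-
corrected) estimate, so a stage-1 zero (bound 10⁻³ < 0.1) escalates as it
should. The reported `n_sims_used` is the last stage executed.

Per-gene randomness is split from a single seed via
`numpy.random.SeedSequence.spawn` in tested-gene order; rows are therefore
independent across genes and byte-reproducible across runs.

### Meta-combination and selection

Fisher's statistic `x² = −2 Σ ln p_i` with `2k` degrees of freedom combines
the k = 2 method p-values; for k = 1 the combination is the exact identity,
which the tests exploit as a closed-form anchor. Selection uses strict
inequalities everywhere. The meta-Bonferroni divisor is always the runtime
intersection size (never a hard-coded historical count); the stringent
divisor defaults to the tested-gene count of method B but is an explicit
parameter so either method's count can be used.

### Over-representation

`p = P(X ≥ J)` for `X ~ Hypergeom(N, S, m)` is the default tail — the
standard over-representation convention — with the strictly-greater variant
`P(X > J)` switchable for compatibility with tools that define the tail
that way. Pathway sizes are measured **after** intersecting membership with
the reference universe (the statistic is only coherent on genes that could
have been selected), and the 20–300 size filter applies to that in-universe
size. The universe defaults to the genes actually tested (those with ≥ 1
assigned SNP), an explicit assumption since enrichment tools differ here;
it is configurable. Pathway p-values are not multiplicity-corrected — the
risk subset is the raw p < 0.05 set.

## Synthetic data: what it emulates, what it does not

The generator produces gene regions laid out non-overlapping on a synthetic
chromosome with inter-gene gaps of 120 kb (> 2 × the 50 kb flank, so
flanked intervals never overlap between genes), SNPs at 500 bp spacing
inside gene bodies, AR(1) within-gene LD, and association p-values from the
exact MVN law the gene tests assume. Causal genes receive a mean shift
(non-centrality) on the z-score of one designated SNP (the middle one);
one causal SNP per causal gene keeps power attribution unambiguous.
Defaults: 50 genes × 20 SNPs, ρ = 0.5, 5 causal genes at non-centrality 6,
and a case/control scale of 215/1244 mirroring the NMOSD case study; the
genotype reference panel holds 400 individuals, enough that panel LD
estimation error is small relative to ρ = 0.5. The GMT file contains one
pathway concentrating the causal genes (padded with null genes to the
minimum filter size of 20) and size-filter edge-case decoys with 19, 20,
300 and 301 members; the over-size decoys contain the entire universe, so
after intersection they are the universe itself and have enrichment p = 1
by construction.

What the generator does **not** emulate: realistic human LD maps (AR(1) is
a surrogate), allele-frequency-dependent power, population stratification,
imputation uncertainty, sex chromosomes, or overlapping genes. Passing
calibration and recovery tests therefore demonstrates correctness of the
statistical machinery under its stated model, not performance on real GWAS
data with model misspecification.

Genotype simulation uses latent-Gaussian thresholding (two haplotype draws
per individual; a haplotype carries the allele iff its latent normal
exceeds the upper-MAF quantile). The resulting dosage correlation is an
attenuated version of the latent ρ (tetrachoric attenuation); this is
intentional — the genotype path validates the LD-estimation plumbing, while
calibration claims rest on the summary-level path where the null model is
exact.

## Numerical choices

* `p → χ²₁` inversion clamps inputs below 1e-300 (quantile range);
  generated p-values are likewise floored at 1e-300 so they stay in (0, 1].
* Eigen-floor ε = 1e-8: large enough to make Cholesky robust in double
  precision, small enough to leave well-conditioned matrices untouched.
* Null simulation is chunked at 2×10⁵ replicates per batch to bound memory
  at ~tens of MB for genes with hundreds of SNPs.
* Monomorphic panel columns are an error naming the SNP (their correlation
  is undefined); monomorphic SNPs in the allelic test return p = 1 with a
  flag instead, since that is a data condition, not a user error.
* Result-table p-values are written at 3 significant digits (scientific
  notation), the precision of the published tables they mirror.

## Problem sizes in the test suite

The suite's heavier checks are sized for reliability per unit time:
simulation-null accuracy uses 10⁵ replicates per (k, quantile) point with a
3-standard-error acceptance band; calibration uses 500-gene null studies
(binomial 3-SE band ≈ ±0.029 around 0.05); the exhaustive hypergeometric
oracle sweeps every parameter combination up to N = 60 against exact
integer enumeration; recovery runs the full pipeline on the default
50-gene study. These sizes give stable verdicts at seeds fixed in advance.

## Known limitations

* Method B is a designed substitute for set-based screening tools whose
  internals are not publicly specified; its results are not comparable
  tool-for-tool, only architecture-for-architecture.
* With small simulation counts the empirical p-value grid (multiples of
  1/N) makes threshold rules slightly conservative near the cutoff.
* The stringent rule in small synthetic studies (n_tested ≈ 50) is a much
  weaker filter than in genome-wide use (n_tested ≈ 16,000), so synthetic
  stringent sets can contain moderately significant nulls.
* Fisher's method assumes the two combined p-values are independent; the
  two methods here are computed from the same data, so combined p-values on
  real intersections are anti-conservative to an unquantified degree. The
  calibration test constructs independence explicitly (methods on disjoint
  null halves); the pipeline reproduces the published procedure as is.
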