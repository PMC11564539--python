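# Methods

## Model

Counts of filtered reads in disjoint, equal-width (100 bp) genomic bins
are modelled as independent Poisson variables.  For a bin `B` in GC
stratum `i`:

- autosomal: `A(B) ~ Poisson(2 · Np · β_i)` — the factor 2 is the diploid
  autosomal copy number;
- target compartment (mtDNA, chrX, chrY): `M(B) ~ Poisson(μ · Np · β_i)`,
  with `μ` the copies per diploid cell.

`Np` is the average per-bin, per-haploid-copy read intensity; `β_i` is a
multiplicative GC bias shared by all bins of stratum `i`.  Independence
across bins is what motivates counting each read exactly once, in the bin
containing its leftmost aligned position: any spanning-read rule that
credits two bins would correlate neighbours.

Estimation is two-stage.  Autosomal bins (≈10⁵ per genome at 100 bp after
filtering, versus ~160 mtDNA bins) determine the nuisance parameters by
per-stratum Poisson MLE:

```
Np    = (Σ_i S_i / Σ_i n_i) / 2
β̂_i   = (S_i / n_i) / (2 · Np)
```

with `n_i` bins and `S_i` summed counts in stratum `i`.  The target copy
number is then the pooled MLE with the nuisances plugged in:

```
μ̂ = Σ_i S_{c,i} / (Np · Σ_i n_{c,i} · β̂_i)
```

summed over strata that actually contain target bins.  A joint MLE over
(μ, Np, β) is numerically indistinguishable at this bin-count imbalance;
the small-instance likelihood-oracle test quantifies the agreement
(relative error < 10⁻⁶ even on ≤ 50-bin instances, where the imbalance
argument is weakest).

Two algebraic properties anchor the design and are asserted to machine
precision in tests:

- **Scale invariance.**  μ̂ depends on counts only through ratios, so
  multiplying every count by a constant leaves it unchanged.  This is what
  licenses mean-depth tables (mosdepth-style) as a drop-in surrogate for
  read counts at constant read length; mixing the two sources in one
  sample is rejected.
- **Reduction to the coverage ratio.**  When the fitted β̂ are flat, μ̂
  equals `2 × (target mean) / (autosomal mean)` exactly — the classical
  estimator is the uniform-coverage special case.  Conversely, when target
  bins concentrate in strata with β > 1, the ratio inflates by the factor
  `Σ n_{c,i} β_i / Σ n_{c,i}` while μ̂ does not; both directions are
  exercised by simulation.

### Normalisation convention

`Np` could equally be defined as the mean autosomal bin count ("total
reads / total bins") with β̂ absorbing a factor ½; only the product
`Np · β_i` is identified.  This package fixes the split by requiring the
count-weighted mean of β̂ over autosomal bins to be exactly 1, so β_i
reads directly as relative bias.  μ̂ is provably invariant to the split; a
test fits both conventions and checks identity.

### Uncertainty

The reported SE and 95% CI are conditional on (Np, β̂): given the
denominator, `Σ S_{c,i}` is Poisson, so `se = μ̂ / √ΣS` and the CI is the
exact chi-square (Garwood) interval for a Poisson total, scaled by the
denominator.  Ignoring nuisance uncertainty makes the interval slightly
anticonservative — empirical coverage in the recovery simulations runs
≈ 94% rather than 95% — which is acceptable for QC use and is measured,
not assumed, by the acceptance script.  A zero target total yields μ̂ = 0
with a one-sided interval.

Per-stratum diagnostics report observed versus expected autosomal means
and the bin-level Pearson dispersion (mean squared Pearson residual),
which is ≈ 1 under the Poisson assumption; real data with overdispersion
will show values above 1.  Overdispersion is deliberately not modelled —
the estimator stays a method-of-moments-like ratio that is consistent
under it, but the CI narrows.

## Bin construction

- Contigs are tiled from position 0 into 100-bp bins; a trailing partial
  bin is dropped (equal Poisson exposure per bin).  Non-default widths are
  supported but untested against real mappability tracks.
- GC fraction is `(G+C)/(A+C+G+T)` over the bin; bins containing any
  non-ACGT base are excluded outright (their GC is ill-defined for
  stratification).
- GC strata: six 5%-wide intervals covering [30%, 60%], half-open
  `[lo, lo+5%)` with the top edge 60% closed — the one convention that
  tiles the range with no gap or overlap.  The assignment is verified
  exhaustively over all 101 achievable GC counts of a 100-bp bin.  A 1e-6
  tolerance on the boundaries absorbs float error; achievable fractions
  are spaced 0.01 apart so no two strata can merge.
- Mappability: a bin is kept only if **fully** covered by the merged
  uniquely-mappable regions; partial overlap would need fractional
  exposure the model does not have.  Track provenance (k-mer length used
  to compute mappability) is the caller's responsibility.  Pseudoautosomal
  regions should be excluded via this track if chrX/chrY ploidy is of
  interest.
- Coordinates are 0-based half-open (BED) everywhere, in memory and on
  disk.

## Read filtering and counting

Records are rejected if MAPQ < 30 or if any bit of the SAM flag mask 3844
is set (unmapped, secondary, QC-fail, duplicate, supplementary).  The mask
test is verified against an oracle that enumerates the five conditions
separately, over all 4096 flags × four MAPQ values.  No fragment-level
deduplication is applied beyond the duplicate flag.  Each passing read
increments exactly one bin (leftmost position rule); reads starting in
excluded bins are discarded.

## Synthetic data

The generator draws per-bin counts from the model itself, at a default
scale emulating a 30× genome in miniature: Np = 15, μ_mt = 150, μ_X = 2,
μ_Y = 0, 10⁵ autosomal bins skewed toward mid-GC, 160 mtDNA bins centred
on mtDNA's ~44% GC, 300 chrX and 60 chrY bins.  `true_beta` is
renormalised to autosomal-weighted mean 1 on construction.  A
`noise=False` mode emits exact expected values for algebraic-identity
tests.  Separate generators produce (a) tiny FASTA/BED pairs whose
per-bin GC is exact by construction, with expected annotations computed
by independent string counting (an oracle for the preparation code), and
(b) minimal sorted BAMs containing intended clean reads plus contaminants
for every filter condition (an oracle for the counting code).

The simulations do **not** emulate overdispersion, within-stratum GC
gradients, mappability error, NUMT cross-mapping or paired-end structure;
green tests validate the estimator's mathematics and plumbing, not
robustness to those artifacts.

## Cohort tools

Clustering is a two-component univariate Gaussian mixture on log μ̂
(copy number is right-skewed and multiplicative; the paper-scale
regressions in this field model log copy number).  EM is run from a
quantile-based initialisation plus seeded random perturbations (default
10 starts, tol 1e-8 on the log-likelihood, ≤ 500 iterations); the best
final log-likelihood wins, component 1 is always the lower-mean
component, and hard assignments are argmax posteriors with ties to
component 1.  Variances are unconstrained (no equal-variance tie); a
start whose variance falls below 1e-12 × data variance (with an absolute
floor at float-rounding scale, so exactly-constant input registers) is
discarded, and if every start is discarded the fit is returned flagged
`converged = False` rather than raising.  The log-likelihood trajectory
is retained and its monotonicity asserted in tests; the fit is also
cross-checked against an independent mixture implementation.  Samples
with posterior near 0.5 are not excluded — assignment quality is the
caller's call.

Estimator comparison reports per-sample relative change
`(other − reference)/reference` (serialised ×100 as percent) and
concordance as squared Pearson correlation; degenerate inputs (zero
variance, non-positive reference) yield flagged NaNs rather than errors.

## Problem sizes

The test suite and acceptance script run the recovery study at 200
replicates of the default miniature genome, the likelihood oracle at 100
random ≤ 50-bin instances, clustering at 2 × 500 samples, and the null
concordance at n = 1000 — sizes chosen so the full suite completes in
well under a minute while keeping Monte-Carlo error far below every
asserted tolerance.

## Known limitations

- Poisson (not negative binomial): real WGS depth is overdispersed; CIs
  are anticonservative there, and the dispersion diagnostic is the guard.
- One global β per GC stratum: no per-sample spline, no fragment-length
  GC model.
- No NUMT-specific masking beyond the mappability track.
- CRAM requires the caller to supply the same reference used for
  alignment.
- The mixture tool fits exactly two components; cohorts with one DNA
  source show near-equal means (a documented diagnostic, not an error).
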