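# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `funprs`, stage by stage in pipeline order.

## Data model and conventions

All genomic coordinates are 1-based inclusive internally; the BED reader
converts from 0-based half-open on ingest, so a BED interval [s, e) and the
GFF3 interval [s+1, e] yield identical annotations. Genotypes are hard-call
additive dosages in {0, 1, 2} of a recorded counted allele (PLINK .bim A1,
VCF ALT), missing as NaN; only biallelic variants are supported, since the
additive coding is defined for two alleles. Duplicate summary-statistic ids
keep the smallest p-value — deterministic and conservative for threshold
selection. A summary-statistic file without an effect direction is readable,
but scoring will refuse any selected SNP lacking a direction rather than
guess an orientation. Tabular outputs are TSV written at %.17g so re-reading
reproduces reals bit-exactly; every CLI stage writes a JSON sidecar with the
package version, seed and parameters, recording input provenance (the gene
annotation source and genome build are the user's input and are not
interpreted).

## Genotype QC

**Hardy–Weinberg exact test.** The conditional test: given the observed
allele counts, the probability of each compatible heterozygote count is
accumulated with a log-space closed form, and the p-value sums the
probabilities of configurations no more probable than the observed one
(relative tie tolerance 1e-12). Monomorphic variants return 1.0. The test is
computed on all samples, unstratified — a limitation when strong population
structure is present (stratified QC would need ancestry labels the pipeline
does not assume).

**Filters.** Fixed order so removal reason codes are unambiguous: variant
missingness ≥ 5%, then sample missingness ≥ 5% (boundaries inclusive), then
MAF < 1% and HWE p < 1e-6 recomputed on the surviving samples. All
thresholds are configurable.

**LD pruning.** r² is the squared Pearson correlation of dosages over
pairwise-complete samples. Windows are physical (default 50 kb) anchored
every `step_snps` variants; within a window, while any kept pair exceeds
r²_max the variant with the lowest MAF among those in violating pairs is
removed (ties broken by later position). A final per-chromosome pass applies
the same rule to any residual pair, so the retained set provably satisfies:
no kept pair within the window exceeds r²_max. Defaults (50 kb / step 5 /
r² 0.5) are the classic PLINK-style choice. An exclusion BED for known
long-range-LD regions can be supplied by the user; none ships with the
package.

## Enrichment engine

**Gene statistic.** s_g = max over mapped SNPs of −log10 p — the
best-SNP-per-gene convention; the number of SNPs in a gene influences the
statistic only through the maximum being taken over more draws. Alternative
combinations (e.g. Fisher) are out of scope. Ranking ties are broken by
lexicographic gene id, which together with stable sorting makes every run
bit-reproducible.

**ES and SPES.** The weighted KS running sum uses hit increments
proportional to gene score (normalized by the set's score sum) and uniform
miss decrements; the ES is the extremum of largest magnitude, clamped to
[−1, 1] against float round-off. If every member of a set scores exactly 0
the hit weights degenerate to uniform 1/|S|. A "significant" gene for the
competitive correction is one whose best SNP lies in the top 5% of all SNP
p-values (the fraction is configurable); SPES = ES·k/K is 0 with a warning
when the universe has no significant gene. SPES is not bounded by 1: k/K can
exceed 1 for concentrated sets.

**Permutation null and FDR.** The permutation unit is the SNP label: the
p-value vector is shuffled across SNP ids, preserving the SNP→gene topology
and requiring no genotypes. The p-value pool is unchanged by shuffling, so
the significance threshold for k/K is permutation-invariant. Per set,
p_perm = (1 + #{perm SPES ≥ observed}) / (1 + B). Because SPES has a point
mass at 0 (sets with k = 0), p_perm is conservative there rather than
exactly grid-uniform; the test suite asserts validity (never
anti-conservative) plus non-degeneracy. The q-value at threshold t is the
mean permuted count of sets with SPES ≥ t over the observed count, capped at
1 and monotonized (q(t) = min over thresholds t′ ≤ t), the standard
tail-ratio estimator. Defaults: B = 1000 (floor 100), set size restricted to
10–200 genes *within the universe*, selection at q < 0.05 strictly.

**Tiers.** Mapped = every SNP mapping (±20 kb) to a gene of a retained set;
functional = the mapped subset passing the annotation index (direct coding /
regulatory / eQTL class, or an LD proxy with r² ≥ 0.8 to an annotated SNP).
Nesting functional ⊆ mapped ⊆ all is asserted end-to-end.

## PRS construction

Unit weights; risk allele = effect allele when the direction is positive,
the other allele otherwise — counting risk alleles is what makes the sum a
*risk* score and matches PLINK's scoring semantics. Dosages are flipped
(2 − d) when the risk allele is the file's non-counted allele; alleles are
matched literally, and a palindromic SNP whose alleles cannot be reconciled
is an error, never a silent strand flip. Missing calls contribute twice the
sample-set risk-allele frequency (mean imputation, PLINK's default; an
omit policy is selectable). Thresholds are strict (p < 0.05 default, p < 0.01
for the sensitivity variant). Scores are Z-standardized with the n−1
denominator; zero variance is an error, not silent zeros.

## Ancestry PCA

Per-variant standardization (d − 2p̂)/√(2p̂(1−p̂)) with missing → 0 after
centering; monomorphic variants are dropped with a report. The decomposition
is an SVD of the standardized matrix; eigenvalues are reported as s²/m —
the samples×samples covariance convention of population-genetics PCA — and
scores are U·S, mean-zero by construction because variants are centered.
Eigenvector signs are fixed (largest-magnitude loading positive) so runs are
comparable. A shifted square-root utility is provided for skewed covariates
(the shift is returned for recording); applying it is the caller's choice.
The pruned variant set is the recommended PCA input.

## Time-varying effect model

y_it = Σ_v β_v(t)·x_v,it + γ'z_i + ε_it with each β_v(t) a cubic B-spline
with 10 interior knots. Knots are equidistant over the observed age range
and *extended* beyond each boundary at the same spacing (the Eilers–Marx
P-spline convention) rather than clamped: with extended knots the nullspace
of the order-2 difference penalty is exactly the linear-in-age functions, so
λ → ∞ shrinks each coefficient function to its best linear fit and constants
are reproduced exactly at every λ. The basis keeps the partition of unity on
the whole observed range.

Estimation is penalized least squares with one λ shared across coefficient
functions, selected by AIC (n·log(RSS/n) + 2·edf, edf = trace of the
smoother matrix) over a log-spaced grid 1e-4…1e6 (25 points). Identically
zero design columns are pivoted out (their coefficients are 0 and the rest
of the fit is unchanged); genuine rank deficiency at the largest penalty is
an error.

**Uncertainty.** Within-subject correlation is handled by working
independence plus a cluster-robust (by subject) sandwich with the CR1
G/(G−1) factor. The pure sandwich ignores the penalty's shrinkage bias and
measurably under-covers (≈87% at nominal 95% in the sine-truth simulation),
so the covariance is augmented with the smoothing-bias term
λ·σ̂²·A⁻¹PA⁻¹ (σ̂² = RSS/(n−edf)), the Wahba–Silverman "Bayesian" interval
adapted to a clustered meat — the same construction mgcv uses for smooth
terms. Measured interior coverage under the sine design is ≈92%, with the
zero-effect pointwise flag rate ≈6% at the 5% nominal level. Bands are
pointwise, not simultaneous.

Significant intervals are maximal runs of the 101-point reporting grid where
the band excludes zero, reported at grid resolution; positive and negative
runs are listed separately. Subgroup fits are fully independent per level
(no cross-model test is offered); levels with fewer than 2 subjects are
skipped with a warning. Ages are years as reals; month-coded inputs should
be converted on ingest. Collinearity among nested-tier scores is real — the
fit reports the design condition number but leaves the modeling decision to
the user. Random-effect TVEM variants are out of scope.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
biological realism: genes on 2 chromosomes with spacing > gene + 2·flank by
default (so the SNP→gene map is single-valued; an overlapping mode halves
the spacing), one guaranteed SNP per gene body plus uniform extras; gene
sets sampled without replacement with the first few planted. Null p-values
are Uniform(0,1); SNPs in planted genes draw p = 10^(−e) with
e = planted_effect + Exp(scale 1/ln 10), so effect 0 reduces exactly to the
uniform null and the mean −log10 p uplift equals `planted_effect` (default
3, the regime where planted sets are reliably separable). Genotypes are
Hardy–Weinberg draws at frequencies in (0.05, 0.5), optionally split into
populations with symmetric frequency offsets spanning `freq_divergence`.
Phenotypes follow y = β₀ + β(t)·PRS + γ'z + b_i + ε with a subject random
intercept (SD 0.5) included deliberately so the cluster-robust TVEM
uncertainty is exercised against real within-subject correlation, noise SD
1, 4–8 observations per subject over ages 2–5 by default; β(t) profiles:
constant, linear, sine, Gaussian bump, zero. `simulate_all` drives the
phenotype with the *truth-defined* functional-tier PRS (SNPs in planted
genes, functional, p < 0.05) so end-to-end recovery is testable, and writes
a `truth.json` sidecar sufficient to recompute every recovery metric. One
master seed fixes every output byte.

What passing tests on these data do **not** show: behavior under realistic
LD (genotypes are independent across variants apart from planted structure;
the LD-prune tests build correlation explicitly), under confounded ancestry
(population structure is orthogonal to the planted signal), or under
measurement models of real instruments. Study-scale defaults
(20,000 SNPs, 1,000 genes, 100 sets / 5 planted, 500 samples) keep the full
suite at a few minutes; simulation-heavy checks use those sizes or modest
reductions stated in the tests.

## Numerical notes

- HWE probabilities accumulate in log space and normalize before summing;
  the tie comparison uses a 1e-12 relative tolerance.
- The enrichment engine is fully vectorized over sets (membership matrix ×
  ranked cumulative sums); an independent scalar replay oracle checks the
  whole engine — gene scores, ES, SPES, p_perm, q — on small instances.
- B-spline bases are evaluated by `scipy.interpolate.BSpline.design_matrix`
  with the base-interval endpoints pinned exactly; a de Boor recursion
  oracle checks values.
- PCA truncates at numerical rank (singular values > 1e-12 of the largest)
  and warns when that is below the requested component count.
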