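# Methods

`driftscan` implements the statistical chain commonly used to ask whether a
SNP's frequency distribution across populations was shaped by selection or
by drift alone: descriptive genotype/allele frequencies with exact
Hardy–Weinberg tests, between-population structure (Reynolds distances and
classical MDS), a three-population PBS selection scan, and windowed
Tajima's D. This note records the models, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Genotype substrate

All statistics operate on a samples × variants matrix of alternate-allele
dosages (0/1/2, or missing) read from biallelic SNP records of a VCF.
Phased and unphased genotypes are treated identically; half-calls (`./1`)
are treated as fully missing, conservatively. Allele frequencies always use
the per-site non-missing allele count as denominator; nothing is imputed.
Positions are 1-based throughout (VCF convention).

The MAF filter removes variants whose minor-allele frequency is **less
than or equal to** the threshold (default 0.05) — the boundary value is
eliminated — computed on the matrix the filter receives, so filtering a
population subset is intentionally not the same operation as filtering the
full cohort.

## Exact Hardy–Weinberg test

Conditional on the observed allele counts, the heterozygote count h at a
biallelic site follows the Levene distribution
P(h) ∝ n! / (n_rr! h! n_aa!) · 2^h over all h with the parity of the
minor-allele count. Because the support has at most n+1 states the
distribution is enumerated in full — no Monte Carlo chain is needed —
with log-space factorials so cohort-scale samples (2n ≈ 5000) do not
overflow. Three p-values are reported: `probability` (sum over outcomes no
more probable than the observed one), `deficit` (P(h ≤ obs)) and `excess`
(P(h ≥ obs)). Monomorphic samples return 1.0 by convention. Note the exact
test is discrete and conservative: its null p-value distribution has an
atom at 1 and is stochastically larger than uniform; the test suite
therefore checks calibration through the randomized-p construction rather
than naive uniformity.

## Reynolds distance and classical MDS

Between-population distance is the frequency-based Reynolds–Weir–Cockerham
coancestry measure, for biallelic loci
D = Σ_l (p1−p2)² / Σ_l (1 − p1·p2 − q1·q2), with no small-sample
correction. It is computed from population allele frequencies only, so
groups known solely through published frequency tables can be placed in
the same matrix as genotype-derived groups. A degenerate pair fixed for
the same allele at every locus gets distance 0 with a warning (keeping the
matrix usable downstream) rather than NaN. Matrices can be exported in the
square Phylip format (10-character name fields; longer labels error unless
`relaxed=True` truncates them).

Ordination is classical (Torgerson) metric MDS: double-center the squared
distances, eigendecompose, scale eigenvectors by the square roots of the
positive eigenvalues. The method is deterministic and recovers any
Euclidean-realizable configuration exactly; coancestry matrices need not
be Euclidean, in which case negative-eigenvalue axes are zeroed with a
logged warning. Axis signs follow a fixed convention — the
largest-magnitude loading on each axis is made positive, magnitude ties
(to 1e−8 relative precision) resolved toward the highest population
index — so repeated runs are bit-identical. No nonmetric/stress-based
refinement is attempted: for cluster-topology questions the closed-form
solution is sufficient and exactly testable.

## PBS selection scan

For each variant and population pair, differentiation is the Hudson
estimator in the Bhatia et al. ratio form,

    N = (p̂1 − p̂2)² − p̂1(1−p̂1)/(n1−1) − p̂2(1−p̂2)/(n2−1),
    D = p̂1(1−p̂2) + p̂2(1−p̂1),    FST = N/D,

with n_i the allele counts. Per-locus values may be slightly negative for
undifferentiated pairs; when combining loci into a single figure the
package uses the ratio of averages (ΣN / ΣD), since the per-locus mean of
ratios is biased downward. Pairwise FST becomes a branch length
T = −ln(1 − FST) after clamping FST to [0, 1−1e−9] (negative estimates
contribute zero branch length; the cap keeps T finite at fixed
differences), and the focal population's branch statistic is
PBS = (T_AB + T_AC − T_BC)/2. The focal population is configurable; the
sum identity PBS_A + PBS_B + PBS_C = (T_AB + T_AC + T_BC)/2 holds per
variant and is enforced in tests.

Outlier calling is empirical: after MAF-filtering the pooled
three-population matrix, the threshold is the configured percentile
(default 99.9) of the scan's own PBS values, using the
linear-interpolation ("type 7") percentile definition so the threshold is
reproducible across implementations. Variants where a pairwise FST is
undefined (both populations identically fixed) stay in the output with NaN
PBS but are excluded from the percentile. The empirical distribution is
the analyzed region's variants — gene/region-scale scans, not genome-wide
null calibration, which is out of scope.

## Tajima's D

Nucleotide diversity is computed exactly from per-site allele counts:
a site with n_A reference and n_B alternate alleles among n chromosomes
contributes n_A·n_B / C(n,2), identical to the all-haplotype-pairs count,
so phasing is never required. Watterson's estimator is S/a1 and D follows
the standard normalization D = (π − S/a1) / sqrt(e1·S + e2·S(S−1)).
Windows default to 10 kb non-overlapping tiles; each window's constants
use the modal non-missing allele count over its sites (exact with complete
data), and a `strict` mode drops sites with any missingness instead.
Windows with S = 0 report D as undefined (None/NaN), never 0, so invariant
windows cannot read as neutrality. A per-rsID mode reports the containing
window's D for named variants.

## Synthetic-data generator

Two study shapes are generated, both reproducible from a single seed.

**Fixed-count sample.** A deterministic single-variant cohort with exactly
prescribed genotype counts; the packaged `sardinia` preset encodes the
worked example of 94 individuals (13 reference homozygotes, 54
heterozygotes, 27 alternate homozygotes at a chr20 5′-UTR SNP).

**Balding–Nichols divergence.** K populations drift independently from a
common ancestor: per locus p_anc ~ Uniform(0.05, 0.95); each population
draws p_i ~ Beta(p_anc(1−F_i)/F_i, (1−p_anc)(1−F_i)/F_i); genotypes are
Binomial(2, p_i) (HWE within populations). Expected pairwise FST ≈ F gives
the generator an analytic contract that the scan must recover
(ratio-of-averages FST over 5000 loci reproduces F = 0.10 within ±0.01).
The default trio uses 99/103/105 diploid samples — the sizes of the
European/East-Asian/African reference trio the scan design mirrors. The
`sweep_trio` preset (per-branch F = 0.05, 1000 loci) plants a positive
control by redrawing the first population's genotypes at one locus at ALT
frequency 0.95; the locus is chosen deterministically as the one whose
pooled outgroup frequency is nearest 0.3, so the planted frequency jump —
and hence the expected PBS — is controlled rather than left to a lucky
draw. The `two_cluster_world` preset nests the model hierarchically
(27 populations in two clusters, between-cluster F = 0.20, within 0.02)
to reproduce the continental-cluster topology that MDS must separate.

The divergence model has no linkage disequilibrium, no recombination map,
and no explicit demography; its site-frequency spectrum is flat (p_anc is
uniform), which is fine for frequency-differentiation statistics but *not*
for Tajima's D: a flat spectrum over-represents common variants and pushes
D strongly positive regardless of selection. Null checks of D therefore
use `simulate_neutral_sites`, which draws segregating sites from the
standard neutral spectrum (alternate-allele count i among 2n chromosomes
with P(i) ∝ 1/i, carriers a uniform subset). Under that spectrum
E[π_site] = 1/a1, so π and S/a1 estimate the same quantity and windowed D
is centred near zero (loose band −0.6 to 0.3 in the tests). Passing tests
consequently demonstrate correctness of the statistics under their own
model assumptions — frequency divergence, HWE sampling, neutral SFS — not
robustness to LD, demography, or genotyping error present in real cohorts.

## Problem sizes

Default test-scale conditions: 5000 loci × 307 samples for the neutral
trio (FST recovery and null calibration), 1000 loci for each of the 100
sweep-power replicates, 200 loci × 540 samples for the 27-population
world, and 40 000 neutral-spectrum sites (~200 windows of 10 kb) for the
Tajima band. Each is a few seconds of vectorized NumPy on one core; the
whole suite runs in well under a minute.

## Known limitations

- Biallelic SNPs only; indels, multiallelic records and genotype
  likelihoods are rejected or skipped at input.
- No haplotype statistics (XP-EHH, iHS), no sliding-window PBS, no
  genome-wide null for either scan.
- The empirical-percentile rule flags ~0.1% of variants by construction
  even under pure drift; it ranks, it does not test.
- Printed per-SNP Tajima's D values from cohort-scale reference data
  depend on window size and sample-subset choices that published analyses
  often leave unstated; such values are treated as qualitative context,
  not numeric targets.
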