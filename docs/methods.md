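# Methods

Statistical model, numerical choices, and limitations of each component.
Coordinates are 0-based half-open internally; PED/MAP positions are 1-based at
the file boundary.

## Cohort simulator (`simulate`)

Genotypes are organized in independent LD blocks. Each block has a founder
pool of haplotypes (allele-letter strings over its markers) with specified or
Dirichlet(1)-drawn frequencies; individuals draw two independent founder
haplotypes per block (Hardy–Weinberg within block, linkage equilibrium across
blocks). Disease status follows a logistic model on the number of copies of
one designated risk haplotype and a sex indicator:

    logit P(affected) = b0 + log(OR_risk)·copies + log(OR_sex)·male

The intercept `b0` is calibrated by Brent root-finding so the exact
HWE-by-sex expectation of the penetrance equals the target prevalence.
Cases are obtained by rejection sampling (draw risk-block diplotype and sex,
draw disease status, keep affected); controls are by default *population*
controls (no screening), with a `screened_controls` flag for
confirmed-unaffected controls. Because the non-risk blocks are independent of
status under the model, they are drawn only for accepted individuals, keeping
large null panels cheap; this is statistically identical to drawing them in
the rejection stream. A hard cap on total rejection draws turns pathological
prevalence/sample-size combinations into an error rather than a hang.

Dosage is coded as the count of the *observed sample* minor allele (ties
broken lexicographically), applied after missingness injection, so a
write→read PED round trip reproduces the matrix exactly. Marker ids are
`b{block:03d}m{site:02d}`; positions place blocks 100 kb apart, markers 1 kb
apart.

Limitations: no recombination within blocks, no LD between blocks, exactly
two alleles per site, a single risk haplotype with multiplicative per-copy
effect, sex independent of genotype.

## Genotype I/O and QC (`genio`)

PED/MAP is whitespace-delimited; sex 1/2/0 → male/female/unknown, status
2/1/0 → case/control/missing, `0` alleles → missing. The QC cascade applies,
in order: heterozygous-haploid calls on haploid chromosomes set to missing;
individuals with call rate below `mind` removed; markers with missingness
above `geno` removed; markers with MAF at or below `maf` removed (defaults
keep everything except entirely missing markers). A report records per-step
removals and the final genotyping rate.

## Prioritizer (`prioritize`)

*Rank product*: for K case-by-control sample pairings, genes are ranked per
pairing by log fold change; the rank product is the geometric mean of a
gene's K ranks, computed for both directions. The permutation null draws K
iid uniform ranks per replicate; `p_perm = (1 + #{null ≤ obs}) / (n_perm + 1)`
and the proportion of false positives is `p_perm · n_genes / rank`. The
default pairing scheme is K = min(n_cases, n_controls) *disjoint* random
pairs: with disjoint pairs the K comparisons are mutually independent under
the null, which is exactly the condition the iid-rank null requires — with
all-pairings comparisons the shared samples correlate the ranks and the
permutation p-values become anticonservative (observed ~18% of null genes
below 0.05). `pairing="all"` is available but documented as miscalibrated.

*Intervals*: gene regions are flanked by a buffer (default 5 kb), clipped at
zero, and merged (book-ended intervals merge); markers map into a set when
their 0-based position lies in a half-open interval. Set overlaps are plain
intersection counts.

## Random forest (`forest`)

scikit-learn `RandomForestClassifier` on median-imputed dosages; importance
is the *unnormalized* mean decrease in Gini impurity, averaged over trees via
`tree_.compute_feature_importances(normalize=False)`, so values are
comparable across runs with different feature counts. A variance filter
removes monomorphic markers first. Selection rules: top-K, top fraction, or
importance threshold; ties break by marker id.

## Association engine (`assoc`)

Each marker is fit by maximum-likelihood logistic regression (statsmodels) of
status on additive dosage plus covariates (sex indicator by default;
constant covariate columns are dropped as they are absorbed by the
intercept). If the fit fails to converge or shows separation symptoms
(|beta| ≥ 15 or SE ≥ 50), the marker is refit with a hand-written Firth
penalized-likelihood Newton solver (Jeffreys penalty, hat-diagonal score
correction, step-halving), which always yields finite estimates. P-values
are two-sided Wald. Monomorphic, all-missing, or single-class markers return
a degenerate result (p = 1) rather than an error.

Multiple testing: Bonferroni uses an explicit denominator `m` — the size of
the *submitted prioritized set* — so restricting the panel genuinely reduces
the penalty; Holm and Benjamini–Hochberg come from statsmodels. Genomic
control is the median 1-df chi-square over 0.4549. Convergence analysis
intersects per-strategy top-k lists at the locus level.

## Haplotype engine (`haplotype`)

EM treats the ordered haplotype pair as the latent variable. Individuals
missing more than half the window are excluded; the rest are grouped into
unique dosage patterns, and all compatible ordered pairs are enumerated per
pattern (heterozygous site → 2 ordered options, missing site → 4). The
E-step weights pairs by f_h·f_k; the M-step sets frequencies to expected
counts over 2n. The observed-data log-likelihood is asserted non-decreasing
each iteration. Two starts are run — product of marginal allele frequencies
and uniform over the compatible universe — and the better final likelihood
wins. Window width is capped at 12 markers (pair enumeration is exponential
in heterozygous/missing sites).

Association splits posterior expected haplotype counts by case/control into a
fractional 2×2 (this haplotype vs all others) tested by 1-df Pearson
chi-square; the odds ratio uses a Haldane–Anscombe 0.5 correction when any
cell is below 0.5. Haplotypes under 1% pooled frequency merge into one
pooled class. The window scan runs EM + association over every contiguous
window (widths in a requested range) intersecting an anchor region and
reports the window minimizing the best haplotype p-value. For a single
marker with complete data the EM posterior is exact and the haplotype
chi-square equals the allelic 2×2 chi-square identically.

The tests validate EM against an independent dense grid-search oracle: a
multi-resolution simplex lattice (coarse lattice, shrink-and-zoom rounds down
to ~1e-5 per-coordinate resolution) maximizing the same observed-data
likelihood with independently written enumeration code; on ≤3-marker,
≤60-individual instances EM matches within total-variation 1e-3. A
single-pass dense lattice at fine resolution over a 7-simplex is
computationally infeasible; the refinement keeps the search EM-independent
while reaching the needed resolution.

## Power calculator (`power`)

Discrete-trait, allelic (2N-allele) 1-df test under a multiplicative
per-allele odds model. Baseline odds are solved (Brent) so the HWE-weighted
penetrance equals the prevalence; case and control allele frequencies follow
by Bayes inversion (controls are population controls). With `p1, p2` the
case/control risk-allele frequencies and `n1 = 2·cases`, `n2 = 2·controls`:

    var_null = p̄(1−p̄)(1/n1 + 1/n2)      (pooled, defines the test threshold)
    var_alt  = p1(1−p1)/n1 + p2(1−p2)/n2  (alternative-hypothesis variance)
    power    = P[ χ²₁(ncp = (p1−p2)²/var_alt) > χ²₁,₁₋α · var_null/var_alt ]

Scaling the critical value by `var_null/var_alt` accounts for the test
statistic being studentized with the pooled variance while the sampling
variance under the alternative differs; a 20,000-replicate Monte-Carlo
simulator of binomial allele counts agrees with the analytic value within
binomial error. `min_cases_for_power` brackets by doubling and bisects
(power is monotone in case count) and is test-verified against exhaustive
scans. The allelic test assumes HWE and independence of the 2N alleles; at
the study's unbalanced design its chi-square differs from the logistic score
(trend) statistic by a few percent, which is expected, not a defect.

## Problem sizes and runtime

Chosen so the full test suite runs on one CPU in well under the time
budget: null-calibration checks use 10,000 independent single-marker blocks
(KS uniformity, genomic control) and 200 replicate 20-marker cohorts
(family-wise error); planted-haplotype recovery uses 30 seeded 68/830
cohorts with a 2–4-marker window scan. The family-wise error check asserts
at the one-sided 99% binomial envelope of the nominal 0.05 level, so a
correctly calibrated implementation fails with probability below 1%.
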