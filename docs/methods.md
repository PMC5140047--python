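# Methods

## Scope and data model

The package operates downstream of variant calling and array segmentation:
its inputs are somatic point-mutation tables with tumor read counts, CNA
segment tables with a copy state per interval, heterozygous SNP-probe BAF
tables, and a probes × samples methylation beta matrix. Segmentation,
alignment, and raw-intensity normalization are upstream and out of scope.
Internally all coordinates are 0-based half-open; every reader/writer
converts to 1-based inclusive in files and says so in the file header.

## Purity and CNA cell fractions

A specimen is modeled as a two-population mixture: a fraction α of cells are
tumor, and a fraction β of tumor cells carry a given CNA, so the fraction of
*all* cells carrying it is c = αβ. For heterozygous probes the BAF bands
implied by allele counting are (1−c)/(2−c) and 1/(2−c) for hemizygous
deletion and (1−c)/2 and (1+c)/2 for copy-neutral LOH; both are symmetric
about ½ with separation increasing in c, and both inversions (c = 2d/(1+d)
and c = d, d = μ₂−μ₁) are exact, which the tests verify as a round trip to
1e-9 on a grid of c.

**EM fit.** The mixture fitted per segment is deliberately constrained:
two Gaussians with mirrored means (μ, 1−μ) and shared variance. The
constraint is what makes the fit identifiable on het-probe BAFs — the A/B
labeling of alleles is arbitrary, so an unconstrained mixture could trade
mean differences against weights. The M-step has a closed form under the
constraint (reflect component-2 points through ½ and average). The lower
mean is initialized at the 10th percentile of the folded BAFs, the scale at
half the folded 10–90 percentile range. Iteration stops when the
log-likelihood change falls below 1e-8 or the parameter change below 1e-7,
capped at 1000 iterations; the log-likelihood is non-decreasing by
construction and asserted per iteration in tests. Segments with fewer than
50 probes are left unassigned rather than fitted. A fitted separation below
0.02 sets a degenerate flag (no resolvable allelic imbalance): this happens
legitimately when a CNA is carried by fewer than ~10% of cells at BAF noise
0.03, and such segments may also hit the iteration cap — the fit returned
is then best-so-far with a warning, and its c ≈ 0 simply contributes to the
lowest clone peak. The standard-deviation floor is 1e-4 so that noise-free
input cannot collapse the likelihood.

**Purity.** The per-CNA fractions π = c are pooled per sample and smoothed
with a Gaussian KDE (Silverman's rule). Each local maximum of the density is
a candidate clone; a peak must hold at least 5% of the total density mass
(watershed basins at the minima between peaks) to count, which keeps noise
wiggles from inflating purity. Purity α is the rightmost surviving peak —
the primary clone. π is a fraction of all cells, so purity needs no further
rescaling. CN0 segments contribute nothing (no heterozygous tumor signal);
amplifications are excluded because their band positions depend on the
unknown allele-specific copy number. If all π values coincide the KDE is
skipped and α is that value. A CNA is called clonal iff c ≥ (1−rel_tol)·α.
The default rel_tol = 0.2 is a documented package choice: with per-segment c
estimates accurate to a few percent, a 20% relative band cleanly separates
clonal events from subclones at β ≤ 0.6 while absorbing estimation noise;
the CNA-label recovery test holds at ≥90% accuracy under exactly those
conditions.

**Copy state from read ratio.** When states must be derived rather than
given, the tumor/normal read-depth ratio is thresholded: below 0.3 → CN0,
0.3–0.9 → CN1 if the BAF bands are split (separation ≥ 0.1) else CN2,
0.9–1.1 → LOH if split else CN2, above 1.1 → AMP. The 0.9 boundary comes
from the clonal hemizygous-deletion expectation (2−c)/2 evaluated at
c ≈ 0.2, the smallest deletion the BAF criterion can also see. These
thresholds are coarse by nature; the pipeline trusts an input state column
when present.

## SNV clonality

Under the clonal null the mutation predates any overlapping deletion/LOH,
so allele counting over the four cell classes (normal; tumor without CNA;
tumor with CNA, mutant on the retained/duplicated or on the lost/replaced
allele) gives the closed-form expected MAFs tabulated in the README. All
five forms are verified against an exact rational cell-enumeration oracle
to 1e-9 on a 20×20 (α, β) grid. The test is the one-sided binomial lower
tail P(X ≤ alt | depth, MAF): subclonality can only depress the mutant
allele fraction, so only the lower tail is evidence. The test is
conservative under the null because of binomial discreteness — empirical
type-I error at nominal 0.05 sits near 0.035–0.04 at depth 100, inside the
[0.02, 0.06] band asserted in the acceptance suite. Plain binomial is used
rather than beta-binomial, matching the stated read-sampling model.

Decisions per mutation: AMP and CN0 regions are excluded (no clonal-null
MAF exists); an unknown allele configuration in a CN1/LOH segment is
resolved conservatively by testing both configurations and keeping the
larger p; configurations whose null MAF is degenerate (0 or 1, e.g. the
mutant on the lost allele of a fully clonal deletion) are skipped since
such a mutation could not have been observed. β is inherited from the
overlapping segment as c/α̂ clipped to [0,1]; mutations in segments with no
usable c are tested at β = 0 (diploid null). The subclonality cutoff
p < 0.05 is a package default; per-SNV calls carry no multiple-testing
correction because the downstream use is descriptive aggregation, not
per-site discovery. FSM (subclonal / classified) is computed per sample,
per gene, and pooled; gene-level departures from the cohort background use
the two-sided Fisher exact test, which the tests check against exhaustive
hypergeometric tail enumeration over all 2×2 tables with margins ≤ 30
(via symmetry-orbit representatives, with orbit invariance spot-checked).

## Mutation signatures

Substitutions are collapsed to the pyrimidine strand; C→X types are split
by whether the reference C is followed by G after collapse (dinucleotide
CpG, not island membership), yielding the nine types; T→X types are not
split. APOBEC-mediated means C→T or C→G in TCA/TCT after collapse.
Transversions are {C→A, C→G, T→A, T→G}. All 192 (ref, alt, context)
combinations are checked against a reverse-complement enumeration oracle.
Rank-sum association uses scipy's Mann-Whitney implementation, exact for
small untied samples and normal-approximated otherwise. The
clinical-outcome association plan is represented as the full grid of five
clinical traits × fourteen genomic features (TNSM, FT, the nine type
fractions, CNA genome fraction, TP53 and KRAS status) = 70 hypotheses,
with FDR control applied by the caller via the Benjamini-Hochberg step-up
helper; the regressions themselves are out of scope.

## Methylation association

The mutation trait is regressed on each probe's methylation plus covariates
(trait as response; the effect sign therefore reads "methylation up, trait
up" when positive). The genome-wide scan residualizes the trait and all
probes on the covariates once (Frisch–Waugh–Lovell) and computes per-probe
slopes and t-tests vectorized; the tests verify exact agreement with
per-probe multiple regression (statsmodels as oracle). Covariate encoding:
categorical variables are expanded to indicator columns, age kept
continuous. Collinear designs raise and the probe is skipped with a logged
reason. Significance uses alpha/n_probes with n_probes taken from the input
(never hard-coded). Category enrichment is the ratio of significant-probe
proportions (category vs overall), reported at full precision with a
one-decimal display rounding; the fraction-of-positive-associations summary
is the share of significant probes in a category with positive effect.

## Synthetic-data generator

The generator emulates exactly the structure the analyses invert, so every
stage has ground truth. Defaults, chosen once as the study conditions the
package targets: 50 samples; purity uniform on [0.2, 0.9]; 60 segments per
sample with state weights CN2 0.30 / CN1 0.30 / LOH 0.25 / AMP 0.10 /
CN0 0.05 (deletions and LOH dominate the informative events); a CNA is
subclonal with probability 0.35, its β uniform on [0.2, 0.9]; 200 probes
per segment with truncated-to-[0,1] Gaussian BAF noise, sd 0.03 (a typical
Infinium het-probe spread; configurable); 200 SNVs per sample at Poisson
depth with mean 100 (whole-exome scale), subclonal with probability 0.55,
subclonal cancer-cell fraction uniform on [0.1, 0.8]; allele
configurations uniform over the valid options per state. A subclonal
mutation's expected MAF is modeled as CCF × the clonal-null MAF (the
mutant lineage nested within the CNA-bearing clone); only the clonal null
is ever tested, so this choice affects power experiments, not calibration.
Mutations whose null MAF would be zero (mutant on the lost allele of a
fully clonal deletion) are reassigned to the retained allele, since such
mutations are unobservable in reads. Trinucleotide contexts are uniform
over contexts matching the reference base — signature classification needs
only the context string, not a realistic genome composition.

The methylation generator plants associations as methylation responding to
the trait: planted probes shift by effect_size (default 0.05 beta units per
trait SD, against probe noise sd 0.05) on top of small random covariate
loadings; the trait itself depends on smoking, age and stage. Planting in
this direction keeps each planted probe's marginal association independent
and of controlled strength — the reverse direction (trait as a sum of many
probe effects) caps every marginal correlation at 1/√n_assoc and makes the
stated Bonferroni-power experiment unattainable at any effect size.
Annotations are drawn at Infinium-450K-like category proportions.

What the generator does **not** emulate: probe-specific noise
heteroskedasticity, genomic waves in BAF/LRR, mutation hotspots and
context-dependent mutation rates, whole-genome doubling, beta-value
compression at the extremes, or correlated methylation blocks. Passing
parameter-recovery tests therefore demonstrates correctness of the
inversion logic under the stated model, not robustness to every artifact of
real arrays.

## Problem sizes in tests

The bundled experiments use 50-sample cohorts (purity recovery), 10,000
SNVs (test calibration), 5,000 probes × 500 samples (methylation scan), and
exhaustive enumeration up to margin 30 (Fisher agreement) — sizes at which
all Monte-Carlo margins in the assertions are comfortable while the whole
suite stays fast.

## Known limitations

Single-sample design: no multi-region phylogenies or subclone clustering.
Amplification clonality is not estimated. The purity density can merge
clones closer than the KDE bandwidth; very low-purity samples (α < 0.15)
leave deletion bands inside the noise floor and are reported with degenerate
fits rather than guessed. The binomial clonality test has low power for
subclones at cancer-cell fraction near 1, so cohort FSM underestimates the
true subclonal fraction at moderate depth; this conservatism is inherent to
the test, not a calibration error.
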