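# Methods

This note documents the statistical models, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and the
known limitations.  Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is imported from outside
measurements.

## Study design and contrasts

The design is a WT/HOMO genotype by 6-/12-somite stage factorial with a
maternal-mutant arm at the 6-somite stage (groups WT6, HOMO6, WT12, HOMO12,
MATWT6, MATMUT6; four replicate embryos per group by default).  All
inference is organized around named two-group contrasts, each written
`A vs B` with positive log2 fold change meaning *higher in A*:

| name   | contrast          | reading of an `up` call                       |
|--------|-------------------|-----------------------------------------------|
| N6     | WT6 vs HOMO6      | needed high to *be normal* at 6 somites        |
| N12    | WT12 vs HOMO12    | same at 12 somites                             |
| D_WT   | WT12 vs WT6       | rises while *developing* from 6 to 12 somites  |
| D_HOMO | HOMO12 vs HOMO6   | same within the mutant                         |
| CONV   | WT12 vs HOMO6     | the confounded uterus-mate comparison          |
| MAT    | MATMUT6 vs MATWT6 | responds to loss of the maternal factor        |

In this direction space, "down in N6/N12" means *suppressed by the factor in
the wild type* (derepressed in the mutant).  The four-way classification
intersects the calls of N6/N12/D_WT/D_HOMO per direction; a feature hit in
both a "normal" and a "develop" contrast, or with opposite directions in two
contrasts, is labelled `mixed` rather than forced into a Venn cell.  All
contrasts are computed on one shared filtered feature universe so the Venn
arithmetic is well defined (the alternative — per-comparison filtering —
would make compartment counts depend on which contrast dropped a feature).

## Differential expression

Counts are filtered (CPM > 1 in at least 2 samples, on raw library sizes),
normalized by trimmed mean of M-values (reference column = upper quartile
closest to the mean upper quartile; 30%/5% double trimming with inverse
asymptotic-variance weights; factors rescaled to geometric mean 1; verified
against an independent brute-force implementation to 1e-8 and against the
Bioconductor implementation to 1e-10), and modelled as negative binomial
with `var = mu + phi mu^2` — the same parameterization everywhere in the
package, including the simulator.

Per-feature dispersion is estimated in three layers: a pooled within-group
moment estimate (raw), a mean–dispersion trend, and a trend-shrunken value
with weight `n_trend / (n_trend + residual df)`, `n_trend = 10`.  The trend
is *not* a smooth of the raw moments: at four replicates the moment
estimator is biased low by the mean–variance correlation of count data
(measured ~30% at these settings), so the trend instead maximizes the
Cox–Reid adjusted profile likelihood for a common dispersion within each
abundance bin and interpolates.

The two-group test fits the one-way NB GLM with log effective-library
offsets at the trended dispersion (group abundances solved by a safeguarded
Newton iteration on the strictly monotone score; the root is unique).  The
deviance difference against the pooled model is then moderated
quasi-likelihood style: each gene's residual deviance over its effective
residual df (groups fitted at exactly zero contribute no df) yields a
quasi-dispersion, which is squeezed toward an abundance-dependent prior
scale by empirical Bayes with prior df fitted per abundance bin from the
spread of log quasi-dispersions in excess of sampling variation; the
moderated statistic is referred to F(1, d0 + df).  A plain chi-square(1) LRT
is available as `method="lrt"`, but it is anti-conservative in the far tail
whenever true dispersions scatter around the trend — on 5,000-gene
global-null studies it produces several BH discoveries per run (the
Bioconductor chi-square LRT behaves identically on the same matrices),
whereas the moderated test's far tail is mildly conservative
(P(p < 1e-4)/1e-4 ~ 0.55 over 200k null p-values) and yields a mean
realized false-discovery proportion of ~0.05–0.10.  Abundance-binned prior
df matter because dispersion heterogeneity is fully visible only at high
abundance; a single global prior df is too light-tailed exactly where the
heterogeneity is largest.

DEG calls require BH q < 0.05 *and* |log2FC| > 1.2 (read as log2; a ~2.3-fold
change).  Features that are all-zero carry NA p-values and are excluded from
the BH denominator.

## Differential variability

The double NB GLM puts the group indicator in both the mean and the
dispersion (`log mu = b0 + b1 x`, `log phi = g0 + g1 x`).  Because both
parameter sets separate by group, the full model reduces to independent
per-group (abundance, dispersion) fits and the null to a common-dispersion
fit; each is a one-dimensional search over log phi (vectorized golden
section on [1e-6, 50], 35 iterations, inner Newton for the profiled
abundance) — exact for this separable model, so no derivative-based
optimizer or fallback is needed.  The likelihood is Cox–Reid adjusted for
the profiled means; without the adjustment the n=4 null type-I error is
0.109, with it 0.070 (band: 0.02–0.08).  Calls require dispersion FDR < 0.05
and |dispersion log2FC| > 1.5, applied to the dispersion coefficient, not
the mean.

A hard limitation worth stating plainly: at the default scale
(mu = 100, four replicates per group) a fourfold dispersion difference is
close to undetectable by *any* valid test.  The measured null spread of the
dispersion log2FC estimate is ~1.6 at n=8, making gamma1 = ln 4 a z ~ 1.3
effect; measured power at q < 0.05 is 0.00 at n=4 and n=8 (median p among
truly inflated genes ~0.09).  Reaching 80% power would need on the order of
70 replicates per group.  The test is still useful as a *ranking* device —
truly inflated genes are strongly enriched among the top LRT statistics
(hypergeometric p < 0.01 in the suite) — which is how the top-k dispersed
heatmap view uses it.

Group-wise CVs are computed on variance-stabilized values
`y = log2(x/s + 1/(2 alpha))` with a single trended alpha (median of the
trend).  Values are shifted positive by the minimum of the full matrix plus
1% of its range — computed *before* any feature subsetting, so every
compartment shares one scale and the CV is exactly invariant to rescaling.
A subset-local shift was rejected after it made the lowest-expressed group
in a compartment look spuriously noisy.  PCA scatter is the mean pairwise
distance of a group's samples in PC1/PC2 of the centered (not unit-scaled,
matching common defaults; a `scale` flag exists) feature submatrix; sample
clustering is average-linkage on Euclidean distances with samples pre-sorted
by id for deterministic ties.

## Allele classification

Maternal/paternal CPMs use the total-library effective sizes.  Ratios are
reported only where at least 10 allele-assigned reads support them.  Classes
are thresholded per-allele fold changes mutant/control (prior 0.5 CPM):
"up" at fold >= 2, a bias at a fold-ratio >= 2 — the source analysis states
no thresholds, so these are declared defaults exposed as flags.  The rule
set is exactly mirror-symmetric under swapping the parental labels.
Classification is information-limited at low expression (an imprinted
allele at 2% of a 30-CPM gene leaves < 1 assigned read per sample);
accuracy >= 0.9 holds in the informative regime (base expression >= 100 CPM,
eightfold derepression), which is the regime the classifier is intended
for.

## DMR calling

Per-CpG differences (group-mean A minus B, missing calls excluded per CpG)
are segmented into candidate regions: runs split at > 300 bp gaps, then at
sign changes of a centered 5-CpG running mean.  Only candidates with >= 12
CpGs are tested — the CpG floor is structural, so no reported DMR can ever
fall below it.  Each candidate is tested by a Wilcoxon signed-rank test on
the raw per-CpG differences: with single-library bisulfite designs (the
intended n = 1 vs 1) the differences across CpGs within the region play the
role of pairs, and independent equiprobable signs per CpG are the declared
working null.  The null distribution is computed exactly by dynamic
programming over twice-the-ranks (integers even under tie-averaged ranks)
up to 200 CpGs — a uniform 12-CpG shift gives exactly p = 2 * (1/2)^12 —
and by the tie-corrected normal approximation above that.  Candidates are
BH-corrected jointly; reported DMRs additionally need q < 0.05 and
|mean delta| >= 0.2 (chosen for single-replicate robustness; exposed).

Promoters are TSS +/- 1000 bp (TSS = start on +, end-1 on −); element
priority is promoter > exon > intron > intergenic, with repeat overlap
recorded independently.  Promoter DMRs of DE genes are cross-classified
with the gene's compartment direction: hypermethylated-in-WT with
lower-in-WT expression reads "methylates-and-silences";
hypomethylated-in-WT with higher-in-WT expression reads
"keeps-hypomethylated-and-expressed"; other combinations are discordant.

## Repeat drivers and passengers

Locus-level DE repeats are merged into clusters by a single linear scan:
consecutive same-direction loci on one chromosome with inter-locus gaps
<= 50 kb, keeping clusters of >= 3 members (both operationalize the
qualitative notion of a "large cluster" and are exposed as flags; an O(n^2)
run-enumeration oracle confirms the scan exactly).  For each cluster the
transcript strand is the majority strand of stranded coverage from the
misexpressing groups (HOMO6 and HOMO12 combined); the cluster is reported
only when the strand-consistency score S = max(cov+, cov-)/(cov+ + cov-)
reaches 0.9 and a member overlaps a DMR.  The driver is the DMR-overlapping
member nearest the transcript's 5' end (leftmost boundary on +, rightmost
on −; ties broken by larger |delta-beta|), matching the observation that
read-through transcription initiates at the hypomethylated element and runs
unidirectionally across the passengers.  Flanking expression averages
log2(CPM-scaled coverage + 1) over 10-kb windows on both sides of each
driver, clipped at chromosome bounds.

## The synthetic-data generator

The generator is the package's study-condition definition, not a test
fixture.  Defaults: 5,000 genes, four replicates per group, log-normal
library sizes (median 1e6, sd 0.15 on the log scale), planted log2 effect
2.0, HOMO6 dispersion inflation 4.0, 2% of genes per planted class
(genotype-effect up/down, stage-switch up/down, noisy-switch up/down,
variance-inflated-only), allele classes on 6% of genes, 8 driver clusters
of 6 passengers each, 12 promoter DMRs and one DMR per driver with 15 CpGs
and delta-beta 0.4.  Dispersions are Gamma(shape 2, rate 40), i.e. mean
phi 0.05 (biological CV ~0.22) — the conventional magnitude for inbred-mouse
biological replicates, and the value at which the planted classes form an
adequate-power regime at four replicates (with mean phi 0.1 about 15% of
planted genes are undetectable at these thresholds, which would cap
compartment recovery near 80% for reasons unrelated to the classifier).
Planted-effect genes draw baselines from a high-expression prior floored at
100 CPM for the same reason.  Dispersion inflation is restricted to the
noisy-switch and variance-only classes by default (`inflated_classes`);
setting `inflated_classes="all"` reproduces the observation that the
6-somite mutants are globally the most variable group, which is the
configuration the variability acceptance check uses.

Maternal-arm allele structure: imprinted genes keep a 2% maternal fraction
(not 0, to avoid degenerate ratios); derepression is a per-embryo Bernoulli
event (probability 0.8) multiplying the maternal component by 8 (and, for
the both-allele class, the paternal by 3) — this per-embryo randomness is
what makes maternal-mutant derepression *variable* rather than uniform,
mirroring the biology and driving the maternal-arm variability analyses.
Allele-assigned reads are a Binomial(total, 0.7) subset split
Binomial(assigned, maternal fraction), so maternal + paternal never exceeds
the total.

The toy genome places genes on one chromosome (2 exons each, alternating
strands) and repeats on another: driver clusters (an RLTR17/ERVK driver and
passengers from several LINE/SINE/LTR subfamilies, 5-kb spacing), isolated
direction-alternating independent DE loci, and null loci.  Read-through
coverage is planted on exactly one strand per cluster in the mutant samples,
extending 8 kb beyond the last repeat; background noise coverage sits away
from clusters.  Methylomes cover every promoter (200-bp CpG spacing, beta
~0.75, noise sd 0.04) with planted DMR windows at 60-bp spacing.

What the generator does **not** emulate: read-level artifacts (GC bias,
mappability, duplicates), batch effects, correlated genes or co-regulated
modules, sex effects (sex is recorded but has no planted effect, as the
study design balances it), splicing, partial methylation haplotypes, and
multi-mapping ambiguity of repeat reads.  Passing recovery tests therefore
demonstrates the *statistical* machinery under the declared generative
model, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

Dispersions are floored at 1e-8; abundances at exactly zero are handled in
closed form (a group fitted at zero contributes no residual df and no
likelihood curvature); golden-section searches use fixed iteration counts so
results are bit-reproducible; BH propagates NA without affecting the
denominator; empty compartments, empty annotation files and empty coverage
tracks round-trip and classify without error.  All randomness flows through
one seeded generator per simulation; rerunning the pipeline on the same
study writes byte-identical outputs.

## Known limitations

* The develop-WT-only enrichment of noisy-switch genes is weak at a
  fourfold dispersion inflation: the mutant stage contrast's log2FC variance
  grows at most by a factor ~(1 + 4 phi mu)/(1 + phi mu) relative to an
  uninflated gene, so with a planted log2FC of 2 the mutant contrast still
  detects most switch genes, and only ~10–15% land in develop-WT-only.
  Reproducing a dominant masking effect requires either inflating the
  biological CV (not phi) fourfold — i.e. phi x16, which pushes the
  fraction to ~0.8 — or a mixture-type noise model (some embryos switched,
  some not), both stronger assumptions than the declared generator makes.
* Differential-dispersion testing at n <= 8 is information-limited (see
  above); its q-threshold calls should not be expected to have power at
  moderate inflation, and the maternal-arm pipeline therefore selects
  features by DE in addition to dispersion calls.
* The DMR caller's signed-rank working model treats CpGs as independent;
  smoothing-induced correlation makes candidate *segmentation* slightly
  optimistic, which the delta-beta floor compensates for in practice.
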