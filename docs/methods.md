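# Methods

`rrqtl` implements the statistical machinery for mapping quantitative trait
loci (QTL) in a panel of haploid yeast crosses arranged in a round-robin
design, decomposing trait variance with kinship-based mixed models, and
fine-mapping QTL to genes.  This note describes the models, their
assumptions, the synthetic-data generator used to exercise them, and the
numerical and design choices a maintainer should know about.

## The experimental design being modeled

Sixteen (in general, *k*) parent strains are crossed in a ring: each parent
mates with exactly two others, giving *k* crosses.  Each cross yields
hundreds to a thousand haploid recombinant segregants, phenotyped in
replicate.  Biallelic markers are recoded against a single reference parent
(−1 = carries the reference parent's allele, +1 = the other allele); a
marker whose two parents carry the same allele does not segregate in that
cross and is set to missing for all of its segregants — such variants are
completely confounded with the cross and their effects belong to a per-cross
fixed effect, not to genetic covariance.

## Within-cross QTL mapping

Linkage at a marker is measured by r², the squared Pearson correlation of
genotype with phenotype.  Genome-wide significance uses the empirical null
of the maximum statistic over B permutations of the phenotype-to-strain
assignment; the empirical p-value is the fraction of null maxima at or above
the observed maximum, floored at 1/B (with the study-faithful B = 10,000
this floor is 1e−4; desk-scale runs use B = 200–1,000 and the floor
generalizes accordingly).

Forward stepwise selection adds the genome-wide best marker, conditions the
next scan on the selected set (the phenotype is replaced by its residual on
the selected markers, and the permutations shuffle those residuals —
a Freedman–Lane scheme), and stops the first time the ForwardStop statistic

    FS(k) = −(1/k) · Σ_{i≤k} log(1 − p_i)

exceeds the target FDR level α (default 0.05).  The exceeding step's marker
is not retained.  p = 1 is treated as an infinite ForwardStop term, i.e. a
certain stop.  Ties at the maximum statistic break to the lowest
(chromosome, position), making selection deterministic.

Selected peaks are re-localized one at a time: holding the other peaks as
covariates, every marker on the peak's chromosome is tried in the multiple
regression and the likelihood-maximizing marker kept; since the incumbent is
among the candidates the likelihood never decreases.  Confidence intervals
are LOD-drop intervals with LOD = −(n/2)·log10(1−r²) computed conditional on
the other peaks; the interval is the contiguous run of markers within `drop`
(default 1.5) of the peak LOD.  Variance explained by the selected model is
estimated honestly by 10-fold cross-validation (detection and effect
estimation in the training folds, R² in the held-out fold).

## Kinship matrices and variance components

Markers are standardized to mean 0 / variance 1 over the segregants for
which they are informative — within one cross for within-cross models, or
across all segregants of crosses in which the marker segregates for joint
models — and set to 0 outside that scope, which excludes non-segregating
entries from genetic covariance exactly.  From the standardized matrix **M**
(n segregants × m markers):

- per-marker normalization: **A** = **MM′**/m, average diagonal ≈ 1;
- Gower centering: **A** = **MM′**·n/tr(**MM′**), average diagonal exactly 1,
  which puts variance components on the phenotypic scale.

Pairwise epistasis kernels are Hadamard (element-wise) products of additive
kernels, re-Gower-centered; by the Schur product theorem they remain PSD.
A PSD check clips eigenvalues below −1e−8 with a warning.

REML estimation uses Newton–Raphson with the expected (Fisher) information
and step-halving, so the restricted likelihood increases monotonically.
Components are constrained non-negative by an active-set scheme: a component
stepping below zero is clamped, and released if its score turns positive.
Initialization splits the phenotypic variance equally across components
(scale-free and reproducible).  Convergence requires the free-component
score norm below tolerance or a relative likelihood change below 1e−10; a
non-convergent fit is returned flagged, with a warning.  Standard errors are
square roots of the diagonal of the inverse Fisher information at
convergence; derived shares (e.g. the rare-variant fraction of genetic
variance, or the non-additive/additive ratio) carry delta-method standard
errors from the same matrix.  The restricted log-likelihood uses the
Harville convention (includes log|X′X|/2), so it equals the density of any
orthonormal basis of error contrasts — handy because a dense
contrast-space evaluation then serves as an exact independent oracle in the
tests.

Model builders cover: the two-component additive model y = a + e (with
heritability σ²_A/(σ²_A+σ²_E)); the seven-component replicated model with
detected-QTL kinship, genome kinship, the three epistasis kernels
AQTL∘AQTL, AQTL∘A, A∘A, segregant repeatability, and observation-level
residual (a reduced variant omits the QTL-involving epistasis kernels); and
the joint allele-frequency-partitioned model y = Xβ + Σ_b u_b + e with one
fixed effect per cross and one Gower kinship per MAF bin (rare/common at
panel MAF 0.01 — the boundary value 0.01 goes to the common bin — or seven
equal-count bins).  The observation-level residual is always on the L
observations (L = n × replicates).

## Joint mapping across crosses

Assuming a variant has a consistent additive effect wherever it segregates,
evidence is pooled: per chromosome, each cross's phenotype is residualized
for off-chromosome detected QTL (fixed effects) and the polygenic background
of the other chromosomes (REML BLUP with a leave-one-chromosome-out
kinship), and the residuals are re-standardized per cross so cross-scale
differences cannot dominate the pooled correlation.  For each marker, the
pooled statistic over its informative segregants (those from crosses where
it segregates, n varying per marker) is t = r·√(n−2)/√(1−r²) with
−log10 p from the t distribution on n−2 degrees of freedom, which puts
private and shared variants on a common p scale.  Permutations shuffle
phenotypes within cross only (never between crosses), and selection uses the
same ForwardStop rule; the default joint B is 1,000 with floor 1e−3.

With a single cross and the polygenic term disabled, this pipeline reduces
*exactly* to the within-cross pipeline (same selections and p-values given
the same seed) — the permutation streams and tie-breaks are deliberately
shared, and the reduction is asserted in the tests.

Effects are estimated per cross by multiple regression of the per-cross
standardized phenotype on the segregating peak markers under −1/+1 coding,
so β² is the variance explained in a balanced cross; 2β, the difference
between the two allele means, is also emitted.  The average of β over
segregating crosses is the headline effect.  Winner's-curse-free estimates
come from a 9/10–1/10 split: detection in the nine-tenths training set,
effect estimation at the detected peaks in the held-out tenth, with the
held-out estimate oriented by the training sign (taking absolute values in
the held-out data would re-introduce a folding bias).

## Fine-mapping (PICS) and gene-level FDR

For a QTL whose effect exceeds the gate √0.02 ≈ 0.1414 SD (2% of
phenotypic variance), every variant in the closed 50 kb window centered on
the peak is evaluated by forward simulation: the observed effect is planted
on the candidate's standardized genotype over permuted within-cross model
residuals (n_sims = 500 by default), the window is re-scanned, and the
candidate's weight is the fraction of simulations in which the observed peak
re-emerges as the lead variant.  One permuted-residual background per
simulation is shared across candidates, which makes the posterior exactly
symmetric for variants in perfect LD (a simulation counts as a hit whenever
the observed peak attains the maximal statistic, ties included).  Weights
are normalized to sum to 1 (equal priors); zero-hit variants keep
probability 0 (no pseudocount).  Re-scanning covers the window only, not
the genome — the simulated signal lives in the window, and this keeps
500 × |window| scans desk-scale.  With zero residual variance the window is
degenerate and mass is spread over variants in perfect LD with the peak,
flagged as such.

QTL from two crosses that share a parent, with overlapping 1.5-LOD-drop
intervals (closed-interval overlap, so touching intervals count) and
consistent effect signs (comparable because all genotypes are recoded
against one reference parent), are combined by multiplying per-variant
probabilities over the shared segregating variants and renormalizing.
Variant probabilities are summed over gene territories — the open reading
frame plus half of each flanking intergenic span, a variant exactly at a
midpoint going to the left gene, terminal genes taking the full span to the
chromosome end.  Genes are ranked by summed probability and the FDR at rank
k is the cumulative mean of the posterior error probabilities 1 − p over the
top k, which is non-decreasing down the ranked list.  QTL replicated in
three crosses are handled as pairs only.

## Population-frequency annotation

Markers are rare below panel MAF 0.01, common otherwise.  Where an outgroup
allele is known, the non-outgroup allele is the derived (recent) allele and
its panel frequency the unfolded frequency; a variant whose minor allele
matches the outgroup is ancient, whose major allele matches is recent, and
anything else is unknown (in the emulated panel the determinable fraction is
configurable, defaulting to 80–100%).  Summaries include mean |effect| with
s.e.m. in consecutive equal-count frequency bins (≈100 QTL per bin at full
scale; |effect| because the sign depends on arbitrary allele orientation),
2×2 enrichment tests reporting the sample odds ratio with a two-sided Fisher
exact p (Haldane-corrected OR alongside when a cell is zero), and counts of
trait-decreasing vs -increasing derived alleles by age class, with effects
signed on the derived allele.

## The synthetic-data generator

The generator emulates the statistical structure of the study, not its
molecular detail:

- **Panel.** Marker minor-allele frequencies follow a truncated power-law
  density ∝ maf^(−shape) on (lo, 0.5] (shape 1 by default, the neutral 1/x
  spectrum), with the lower truncation solved in closed form so the expected
  rare fraction (MAF < 0.01) hits a target, 27.8% by default.  Minor-allele
  carriers are placed by count, clipped to keep every marker biallelic in
  the panel.  The ancestral allele is the major allele for 80% of markers by
  default (the rest are ancient minor alleles), with a configurable unknown
  fraction.
- **Map.** Uniform cM/bp per chromosome; defaults of 150 cM over 500 kb per
  chromosome give yeast-like linkage decay.  Mapping methods only consume
  marker order and genetic distance, so nothing finer is modeled.
- **Meiosis.** Haploid progeny are parental mosaics with Poisson crossover
  counts (mean = map length in Morgans), uniform crossover positions and no
  interference.
- **Architecture.** Causal effects have magnitude ∝ [2·maf(1−maf)]^τ ×
  |N(0,1)|; τ < 0 concentrates large effects on rare variants
  (negative-selection-like).  With probability `sign_bias_recent` the
  derived allele's effect is trait-decreasing.  Causal markers can be
  restricted to those segregating in a cross design so every planted QTL is
  mappable.
- **Phenotypes.** Replicate value = additive value (+ optional pairwise
  epistasis) + a segregant-level permanent deviate + replicate noise.  When
  a target additive fraction is set, the additive part is rescaled so the
  realized fraction matches it, and the rescaled effects are recorded back
  into the returned truth; the permanent deviate tops the
  segregant-consistent variance up to the repeatability target and replicate
  noise supplies the rest.  A budget where the genetic fraction exceeds the
  repeatability is rejected.

What the generator does **not** emulate: sequencing error, genotyping
uncertainty, structural variation, diploidy/dominance, crossover
interference, population structure within a cross, and environment × genotype
effects.  Passing tests therefore demonstrate correctness of the estimators
under a clean additive(+epistatic) haploid model, not robustness to the
artifacts of real data.

## Operating-characteristic studies and the sizes used

`rrqtl.studies` packages the simulation studies run by the test suite and
the reproduction script.  Problem sizes are chosen to make each study
complete in seconds to a couple of minutes while leaving clear margins on
the properties being demonstrated: null FDR over 200 traits on one 400 × 500
cross with B = 200; power over 60 traits per effect size at n = 800 and 150
split-sample replicates; REML recovery over 20 replicates at n = 600;
rare/common partition recovery on 4 crosses × 400 segregants with 6,000
panel markers (~28% rare) and 40 causal markers per bin; 30 pooling-power
replicates; 50 PICS windows of 20 variants at n = 800 with 300 simulations
each.  The PICS study places its 20 window variants on a genetic map loose
enough that neighbouring variants are only partially correlated (r² ≈ 0.8);
with near-perfect LD no method can separate neighbours and the posterior
correctly spreads over the LD block instead.

Two behaviours observed in these studies are worth knowing: (i) the
rare-share estimate from the two-kinship partition runs a few points above
the planted value when the causal fraction of the rare bin is much larger
than that of the common bin — a standard GREML misspecification effect, not
a bug; (ii) Fisher standard errors for single-kernel REML run up to ~1.4×
the empirical SD at these sizes, i.e. mildly conservative.

## Known limitations

- The seven-component epistatic model at large n is the slowest fit
  (several dense n³ operations per Newton iteration).
- `unbiased_effects` and the cross-validated R² re-run the full stepwise
  machinery per fold/replicate; at the study-faithful B = 10,000 they are
  expensive and should be run with reduced B for exploration.
- Gene territories assume non-overlapping, strand-less ORFs per chromosome;
  overlapping genes would need a richer assignment rule.
- The joint pipeline assumes phenotypes are exchangeable within a cross
  after per-cross standardization; strong within-cross substructure would
  invalidate the permutation null.
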