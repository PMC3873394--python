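# Methods

`daughterqtl` implements the statistical machinery of a candidate-gene
association study in a half-sib daughter design: genotyped daughters of a
small set of progeny-tested sires, phenotyped by estimated breeding values
(EBVs) from a national genetic evaluation, with a dense SNP panel inside a
single candidate gene. This note documents the models, the numerical
choices, and what the synthetic data generator does and does not emulate.

## Phenotypes and the residual model

EBVs are treated as phenotypic observations. An EBV is a shrunken
prediction whose sampling error shrinks as its reliability REL (squared
accuracy) grows, so the residual variance of individual *i*'s EBV is
modelled as σ²e/RELᵢ. Equivalently, the residual covariance is
**e** ~ N(0, **W**σ²e) with the diagonal weight matrix Wᵢᵢ = 1/RELᵢ. This
weight enters both association models identically.

Using EBVs double-counts family information relative to de-regressed
proofs or yield deviations; the package follows the EBV convention because
the design it targets does, and because the weighting above absorbs the
heterogeneous accuracy. Variance components (σ²a, σ²e, and the phenotypic
variance σ²P used for variance-explained scaling) are external inputs per
trait — in practice they come from the evaluation that produced the EBVs —
and are never estimated internally on the acceptance path. For synthetic
or exploratory data an optional REML estimator is provided
(`estimate_variance_components`); it maximises the restricted likelihood
by explicit construction of **V**, which is exact but only practical at
moderate n, and in a shallow half-sib pedigree σ²a carries a large
sampling error — another reason production components should come from
the full evaluation.

## Single-locus mixed model

For each SNP,

  **y** = 1μ + **x**b + **a** + **e**,  **a** ~ N(0, **A**σ²a),  **e** ~ N(0, **W**σ²e),

where **x** counts copies of the *minor* allele (0/1/2) and **A** is the
pedigree additive relationship matrix over every pedigree member (sires
included, whether or not phenotyped). Solutions come from Henderson's
mixed model equations with residual precision R⁻¹ = diag(REL)/σ²e and
penalty **A**⁻¹/σ²a; the sampling covariance of the fixed effects is the
fixed block of the inverse coefficient matrix. The SNP test is a Wald
chi-square b̂²/V̂ar(b̂) on 1 df. With 0/1/2 coding, b̂ is the average
allele-substitution effect α, so the variance explained by the SNP is
reported as 2p(1−p)α̂²/σ²P with p the sample minor-allele frequency of the
analysed individuals.

The MME path is verified, instance by instance, against an independent
generalized-least-squares reference that inverts
**V** = **A**σ²a + diag(1/REL)σ²e explicitly; the two agree to ~1e−14 on
random pedigrees (the acceptance suite requires 1e−8 over 200 instances).

Genotype-class least-squares means use the same mixed model with a
cell-means class design (no intercept); pairwise Wald z-tests feed a
greedy compact-letter display at the 0.05 (lowercase) and 0.01 (uppercase)
levels. Classes with fewer than two individuals keep their estimate but
are excluded from letters.

## Haplotype trend regression

Per detected block, **y** = 1μ + **X**h + **a** + **e**, where **X** holds
each individual's *expected* dosage of each retained haplotype (posterior
haplotype counts from the EM phasing; exactly 0/1/2 when phase is
certain). Rows of **X** sum to 2, so all k columns plus the intercept are
collinear; the most frequent haplotype's column is dropped as the
reference and the joint Wald statistic ĥ′[V̂ar(ĥ)]⁻¹ĥ is tested on k−1 df.
The statistic is invariant (to ~1e−6) to which haplotype serves as
reference. Haplotypes below 5% frequency are pooled into one
pseudo-haplotype before the design is built; the pooled class is treated
as an ordinary column.

The k−1 df convention follows Zaykin-style trend regression with an
intercept: one degree of freedom of the haplotype space is absorbed by the
row-sum constraint. With k = 2 the block test reduces algebraically to the
single-SNP dosage test, which the suite asserts to 1e−9.

## Pedigree relationship matrices

**A** is built by the tabular method (Aᵢᵢ = 1 + ½A_sd, Aᵢⱼ = ½(A_js +
A_jd)); **A**⁻¹ is assembled directly by the Henderson rules with the
Quaas inbreeding adjustment (Mendelian-sampling variance dᵢ = ½ −
¼(F_s + F_d), ¾ − ¼F_p, or 1 as parents are known). Individuals appearing
only as parents are inserted as founders, which is what a daughter design
needs for its sires. Both constructions are cross-checked against a
separately coded recursive-kinship (coancestry) oracle on an exhaustive
sweep of small pedigrees and against numerical inversion up to n = 200.
Matrices are stored dense; the target scale is ≲10⁴ individuals, and
sparse assembly of **A**⁻¹ is the documented scaling path beyond that.

## Haplotype frequencies, LD, and blocks

Phasing is an exhaustive-diplotype EM: every individual's genotype vector
is expanded into all compatible haplotype pairs (missing genotypes
marginalised over both alleles), the E-step weights pairs by current
frequencies, and the M-step re-estimates frequencies from expected counts.
This is exact maximum likelihood for the window sizes the package targets
and is capped at 12 SNPs (the enumeration grows as 2^het·4^missing).
Frequencies start uniform; 5 restarts with seeded Dirichlet jitter guard
against the saddle points that arise with symmetric data (e.g. panels of
double heterozygotes); convergence is declared at 1e−8 on the
log-likelihood, whose monotone increase is asserted on every run. Ties
between restarts break toward lexicographically ordered frequencies.
Haplotypes driven below 1e−10 frequency are pruned and the dosage rows
renormalised to sum to 2.

Pairwise D′ and r² come from two-locus EM haplotype frequencies on
complete-case individuals, with D′ = |D|/D_max under the standard
normalisation. The D′ confidence interval is a likelihood profile: the
two-locus multinomial likelihood is evaluated on a |D′| grid (step 0.001)
with allele frequencies held at their sample values and the sign of D at
its MLE; equal-tail bounds at the configured coverage (default 95%) come
from the normalised cumulative likelihood. The interval is widened, if
needed, to contain the EM point estimate, so point-in-interval holds by
construction (the profile and joint MLEs can differ at the grid
resolution).

Block detection follows the Gabriel confidence-interval rules with the
Haploview-default thresholds: a pair is strong LD when its CI is
[≥0.70, ≥0.98], strong recombination when the upper bound is <0.90; a
contiguous candidate is a block when ≥95% of its informative pairs are
strong LD *and* its outermost pair is itself strong LD (the edge condition
prevents gluing two unrelated tight clusters across an intervening
free-recombining SNP); candidates are accepted greedily from longest to
shortest without overlap. Block membership is always data-driven — the
package never hard-codes a block layout.

## Expression analysis

Relative quantification uses the Livak 2^−ΔΔCt method: technical
replicates are averaged on the Ct scale, ΔCt = Ct_target − Ct_reference,
and the calibrator constant is chosen so the calibrator group's arithmetic
mean relative quantity is exactly 1 (the usual "calibrator defined as 1"
presentation; centring on the mean ΔCt would pin the geometric mean
instead). Group comparisons report the ratio of mean relative quantities
as the fold change and a two-sided two-sample t-test on the RQ values —
Welch by default, pooled-variance by flag. No amplification-efficiency
correction is applied. Note that RQ values are a log-scale transform of
Ct noise, so with normal Ct errors the t-test operates on skewed data;
at qPCR-typical noise levels the null rejection rate stays near nominal,
which the suite checks empirically.

## Synthetic data generator

The generator emulates the study conditions end to end: 14 sires and 638
daughters by default (half-sib families; dams unknown and unrelated, which
keeps **A** sparse and matches how daughter designs are recorded), and a
13-SNP candidate-gene panel containing a 5-SNP block (four haplotypes at
0.34/0.33/0.26/0.07) and a 2-SNP block (three haplotypes at
0.44/0.388/0.172) among independent SNPs with minor-allele frequencies
between 0.05 and 0.45 — frequency shapes typical of a genotyped
candidate-gene panel. Block haplotypes are gene-dropped without
within-block recombination (every carried haplotype is a pool member);
blocks segregate independently.

Phenotypes follow the analysis model exactly: y = μ + xα + a + e with the
polygenic value gene-dropped (founders N(0, σ²a); offspring receive half
of each known parent's value plus Mendelian sampling of variance
σ²a(1 − ¼·n_known_parents), ignoring parental inbreeding — founders are
non-inbred by construction, while the analysis-side **A**⁻¹ handles
inbreeding generally), and e ~ N(0, σ²e/RELᵢ) with RELᵢ uniform on
(0.5, 0.95) — a realistic reliability band for progeny-tested daughters;
the real distribution of reliabilities is not published, so a uniform band
is an explicit modelling choice. Defaults are σ²a = σ²e = 1 (standardised
trait units, heritability 0.5 of the EBV-scale variance), σ²P = σ²a + σ²e,
and a causal-SNP substitution effect of 0.5 within the 5-SNP block. The
five milk traits are simulated independently; real milk traits are
genetically correlated, so multi-trait behaviour is outside what passing
tests demonstrate. Likewise absent: genotyping error, within-block
recombination, selection, and non-uniform family sizes beyond the
46/45-daughter split.

A single seed drives everything through spawned per-stage substreams;
identical (config, seed) reproduces datasets bit for bit.

## Problem sizes used in the checks

The statistical acceptance checks run at the study scale (652 pedigree
members): test calibration over 1000 null replicates with phenotypes
re-simulated on one fixed genotype panel and refitted through the full
scan each time; effect recovery over 200 replicates with fresh genotypes
and phenotypes; block-structure recovery over 50 replicates; the
MME-vs-GLS oracle over 200 random instances of up to 50 individuals. The
exhaustive pedigree sweep covers all 617 ordered-parent structures on up
to four individuals plus seeded random pedigrees to eight.

## Known limitations

- Variance components must be supplied; misspecified λ = σ²e/σ²a biases
  the shrinkage, though Wald calibration is fairly robust to moderate
  misspecification.
- The EM phasing window is capped at 12 SNPs; genome-scale phasing is out
  of scope by design.
- The D′ CI treats allele frequencies as known at their sample values
  (profile, not joint, likelihood), the standard Gabriel/Haploview
  approximation.
- Expression comparisons test RQ means on the linear scale, mirroring
  common qPCR practice; log-scale (ΔΔCt-scale) testing would be more
  nearly normal but is not what the presentation convention reports.
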