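# Methods

`kindyad` implements a pipeline for studying nepotism among dispersing male
primates when pedigrees are only partially known: estimate pairwise genetic
relatedness from microsatellites, classify dyads as related/unrelated at the
half-sibling level, and test whether co-resident kin extend a male's
residence in a group and his tenure at high dominance rank. Because the
motivating field study's genotypes and demographic records are not public,
the package includes a first-class synthetic-data module that generates all
inputs under known truth; every statistical guarantee quoted below is a
property of that generative model.

## Dyad likelihood and the ML relatedness estimator

A non-inbred dyad's genetic relationship at a locus is summarized by the IBD
coefficients k = (k0, k1, k2): the probabilities of sharing 0, 1 or 2 alleles
identical by descent. The canonical categories are unrelated
UR = (1,0,0), half-siblings HS = (1/2,1/2,0), full siblings
FS = (1/4,1/2,1/4) and parent-offspring PO = (0,1,0); relatedness is
r = k1/2 + k2.

Given locus allele frequencies p, the probability of an unordered genotype
pair is

    Pr(g1, g2 | k) = k0·P0 + k1·P1 + k2·P2,

with P0 the product of Hardy-Weinberg genotype probabilities, P2 the
probability of the shared genotype drawn once (0 if g1 ≠ g2), and
P1 = Σ_x p_x · p_{other(g1,x)} · p_{other(g2,x)}, the sum running over
alleles x present in both genotypes. These are exactly the enumeration of
the simulator's generative model (state k2: both genotypes are the pair
{x,y}; k1: {x,y} and {x,z}; k0: four independent genes), and the test suite
verifies term-by-term agreement and that the pair probabilities sum to 1.

Genotyping error is a whole-genotype miscall: with probability e per locus
per individual the observed genotype is replaced by a fresh Hardy-Weinberg
draw. Because the marginal distribution of each genotype is Hardy-Weinberg
under every k, the error-folded likelihood collapses to

    Pr_e = (1-e)²·Pr(g1,g2|k) + (2e - e²)·P0.

The ML estimate maximises the product of per-locus terms over the
k-simplex. Each term is *linear* in k, so the log-likelihood is concave and
the maximiser is found by an EM fixed point (mixture-weight updates,
tolerance 1e-12 on the log-likelihood, at most 5000 iterations) started at
the simplex centre — guaranteed to reach the global optimum, which a dense
0.01-step simplex grid search confirms in the tests. The non-inbred
feasibility constraint k1² ≥ 4·k0·k2 is **not** enforced by default; with
`enforce_noninbred=True` the optimum is re-sought on the boundary curve
k = ((1-m)², 2m(1-m), m²). Loci missing in either genotype are skipped and
estimates with fewer than 8 usable loci (configurable) are refused.
Allele frequencies are always supplied externally (from the full genotyped
sample), never re-estimated from the dyad.

A symmetrized Queller-Goodnight moment estimator (numerators and
denominators pooled over loci and both reference directions) is provided
for comparison; `benchmark_estimators` reproduces the simulation study that
ranks estimators by per-category mean, variance, MSE and pooled correlation
with the expected r. On the default panels the ML estimator attains the
higher pooled correlation (~0.93) and is the one used downstream; its
truncation at r = 0 gives a small upward bias for unrelated dyads
(mean r̂ ≈ 0.04) and a mean of ≈ 0.26 for half-siblings.

## Power of relationship inference (PW_R)

`pw_r` measures how well a panel discriminates a primary relationship from
a null: simulate n dyads under each, score each dyad by the fixed-hypothesis
log-likelihood ratio log L(primary) − log L(null), set the threshold at the
(1−α) empirical quantile of the null scores, and report the fraction of
primary dyads strictly above it (ties are non-rejections; α ≥ 1 degenerates
to power 1). This fixed-k LLR construction is this package's
operationalization of the power index — the published tool the field uses
does not document its internal definition — and it is calibrated: applying
the threshold to a fresh null sample rejects ≈ α. On 18 equifrequent
8-allele loci, PO vs UR power saturates at 1.00 (a single locus without a
shared allele has zero likelihood under PO, so 18 loci essentially always
separate); HS vs UR is ≈ 0.85.

## Classification cutoffs (A1 and A2)

* **A1** retains the top `retain_fraction` (default 0.85) of the empirical
  r distribution of *known* half-sib dyads: the threshold is its 15th
  percentile, boundary inclusive, and every dyad is labelled related or
  unrelated.
* **A2** builds two thresholds from simulated distributions: the lower 5%
  quantile of half-sib r̂ (related cutoff) and the upper 5% quantile of
  unrelated r̂ (unrelated cutoff), boundaries exclusive, with the band
  between them unassigned.

Quantiles use linear interpolation between order statistics everywhere;
cutoffs are sensitive to the convention, so it is fixed and documented.
A design subtlety: a dyad is labelled related only if its r clears *both*
thresholds (and unrelated only if it falls below both). With a normal,
non-inverted rule this is exactly "above the related cutoff" / "below the
unrelated cutoff". On highly informative panels, however, the half-sib
lower tail can fall *below* the unrelated upper tail (the exclusion zone
inverts — `a2_cutoffs` warns); the both-thresholds rule then leaves the
ambiguous band unassigned, preserving the guarantee that at most ~5% of
truly unrelated dyads are labelled related. On the default equifrequent
panel the zone is inverted; with frequency profiles giving tighter half-sib
distributions it is not.

Validation reports counts and percentage rates with half-up rounding to two
decimals (e.g. 60/1/18 of 79 → 75.95% / 1.27% / 22.78%). Maternal
relationships can be screened by `mendelian_check`: a locus mismatches when
the offspring shares no allele with the mother, and one mismatch is
tolerated by default to absorb a genotyping error or null allele.

## Synthetic data

* **Marker panels** — per-locus frequencies from a symmetric Dirichlet;
  defaults 18 loci × 8 alleles, concentration 2.0 (moderate microsatellite
  diversity); `concentration=inf` gives the equifrequent reference panel
  used in the quantitative tests.
* **Dyads** — drawn directly from the IBD-state model above, or by
  gene-dropping through a pedigree built with paternity skew (default 0.8:
  that fraction of each cohort's offspring share the top male, mirroring
  observed skews of 60-100%); the two routes agree in the tests to within
  0.02 in mean r̂. Mothers are drawn without replacement within cohorts, so
  the pedigree is dominated by paternal half-sibships. Founders are
  unrelated and non-inbred; there is no mutation and no linkage.
* **Demography** — one spell per male; residence duration is exponential
  with hazard `baseline_hazard · kin_hazard_ratio^kin`, right-censored at
  the observation horizon. Defaults encode the study conditions: kin
  log-hazard −2.36 (hazard ratio ≈ 0.094), baseline 0.0145/month (median
  residence ≈ 48 months without kin), horizon 146 months; high-rank tenure
  (for the ~50% of males reaching rank 1-3) is Gaussian with mean
  14.2 + 12.7·kin months, SD 8, truncated at 1 month.

What the generator deliberately omits — multiple spells per male,
overlapping generations, time-varying kin presence, between-group dispersal
structure, locus-specific error rates — bounds what passing tests show:
they demonstrate that the estimators and models recover known effects under
these idealized conditions, not that they would do so under every pattern
of real field data.

## Survival and tenure models

The Cox proportional-hazards fit is an own implementation of the partial
likelihood (Breslow ties by default, Efron optional; monthly resolution
keeps tie groups small), maximised by Newton-Raphson with step-halving to a
gradient norm below 1e-8. Likelihood-ratio statistics are drop-one
comparisons per term. Monotone likelihoods (separation) are flagged
(`converged=False`) rather than raised, detected by runaway coefficients or
exploded standard errors. The Kaplan-Meier estimator is likewise authored
here; both are cross-checked against an independent survival library in the
test suite. The one-year-stay analysis is a logistic LR test of
(duration ≥ 12 months) on a kin flag, excluding records censored before
month 12 (count reported); under perfect separation the LR statistic is
recovered from the saturated two-binomial likelihood and the infinite
coefficient is flagged. High-rank tenure is OLS on the kin flag after the
eligibility filter (rank ≤ 3, or ≤ 2 in groups with fewer than five
non-natal males), with a Gaussian LR statistic n·log(RSS0/RSS1).

Individual-level random effects (males contributing several spells, nested
in population) are approximated by fixed-effects fits plus a cluster
bootstrap over males (percentile CIs, default 500 resamples): with at most
a couple of spells per male the random-effect variance would be weakly
identified, and the bootstrap propagates within-male dependence into the
intervals without a mixed-model likelihood.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale simulation sizes chosen
to keep Monte-Carlo error well inside the asserted tolerances: 1000 dyads
per category for estimator recovery (±0.03 around 0.25), 10,000 per
hypothesis for power (the power target rounds to two decimals), 100
replicates at n = 300 for Cox recovery within 2 SE, 1000 replicates for the
5% ± 2% type-I check of the one-year-stay test. Full-scale analyses (e.g.
10⁶ simulated dyads) use the same code paths with larger `n` arguments. All
randomness flows through explicitly seeded NumPy generators; Hardy-Weinberg
Monte-Carlo p-values use the add-one convention (1+extreme)/(1+n_perm) and
the Guo-Thompson conditional-array-probability statistic by default (a
two-sided heterozygote-count statistic is available). Zero-probability
genotype configurations return −inf log-likelihood rather than raising, so
impossible hypotheses are excluded smoothly during maximisation.

## Known limitations

Inbreeding (Jacquard 9-state likelihoods) is out of scope; the estimator's
k-simplex assumes non-inbred dyads. The error model is a single
whole-genotype miscall rate shared across loci, not an allelic
dropout/false-allele decomposition. Linkage-disequilibrium testing and
null-allele estimation are not implemented (marker QC covers missingness,
Hardy-Weinberg and Bonferroni correction only). The Cox model has no
time-varying covariates, so kin presence is a time-fixed indicator per
spell with the co-residence fraction reported alongside.
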