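# Methods

## Model

One biallelic autosomal locus with alleles A1, A2 at frequencies q1,
q2 = 1 − q1.  Genotypes are dose-coded 0/1/2 copies of A2; a child's
genotype is phased, written maternal-allele-first, and the imprinting
covariate is Xi = Am − Af ∈ {−1, 0, +1}.  A child's phenotype is

    Y = Xc·βc + Xm·βm + Xf·βf + Xi·βi + Xs·βs + ε,   ε ~ N(0, σε²),

summed over loci in the multilocus case.  All five effects act
additively; dominance, epistasis, gene–environment interaction, X
linkage and sex-specific allele frequencies are outside the model.
Phenotypic values are deviations from the all-A1A1 configuration.

### Mating tables as oracle

Every closed-form moment is backed by exact enumeration.  The trio
table lists all 16 (mother, father, phased child) combinations with
Mendelian-transmission probabilities under Hardy–Weinberg parents; the
sibling table extends each combination with a second, independently
transmitted child (36 rows).  Under assortative mating the row
frequencies acquire a parameter ρ — the correlation among mates at the
locus, identical to the inbreeding coefficient F of the resulting
population: parental genotype frequencies take the inbreeding form
(q1² + ρq1q2, 2q1q2(1 − ρ), q2² + ρq1q2), mates' genotype dosages
correlate exactly ρ, genotype frequencies change but allele frequencies
never do, and the population mean is untouched.

The printed source of the assortative-mating row frequencies is
typographically ambiguous in its second factor (a bracket coupling the
pair frequency to the scale S = 2q1q2(1+ρ)).  Both candidate readings
are implemented; the reading `1 + ρ·W/S` is the only one that
simultaneously conserves probability, reduces to the random-mating
frequency at ρ = 0, keeps child allele frequencies invariant, **and**
reproduces the closed-form assortative-mating variance by enumeration.
The test-suite asserts this selection; the rejected reading conserves
probability but misses the variance by order 0.1.

### Variance results

Random mating (trio): V = 2q1q2(βc² + βm² + βf² + βi² + βcβm + βcβf +
βmβi − βfβi).  The cross terms are the algebra of confounding: parental
and imprinting effects load on the same family configurations, so the
reciprocal heterozygotes differ in expected phenotype whenever either
βm ≠ βf or βi ≠ 0, each mimicking the other.

Sibling difference: Vs = 2q1q2(βc² + βi² + βs² − 2βcβs).  Parental
terms cancel identically row-by-row; direct and sibling effects oppose
each other in sign.

Assortment adds ρ and ρ² terms to the trio variance and multiplies the
sibling-difference variance by (1 − ρ).

Multilocus: V_tot = Σ V_j + Σ_{i≠j} k_ij √(V_i V_j), where k_ij is the
correlation between the *per-locus genotypic values* (not raw dosages;
for direct-only effects the two differ by the sign of β_iβ_j, and only
the value-level correlation makes the cross term carry the right sign).
The off-diagonal sum runs over ordered pairs, i.e. twice the unordered
sum.

At the single-allele level (imprinting set aside), a maternal allele
contributes q1q2(βc+βm)² and a paternal one q1q2(βc+βf)².  The three
assortment-induced allele correlations — f (same locus, across
gametes), k (different loci, one gamete), s (different loci, across
gametes) — contribute covariances l·f·q1q2(βc+βm)(βc+βf),
l(l−1)/2·k·q1q2[(βc+βm)² + (βc+βf)²] and l(l−1)·s·q1q2(βc+βm)(βc+βf),
each counted once per unordered allele pair; the variance of the summed
allelic values takes each twice.  A correlated-allele simulation oracle
fixes this bookkeeping in the tests.

## Effect scenarios

V1 direct only; V2 +imprinting; V3 direct+maternal+paternal; V4 all
four; V5 = V4 with cross-class effect correlations; V6 direct
correlated with maternal and paternal.  Defaults (population-level
component variances, trait units): direct 0.5 — the SNP heritability
when acting alone over total variance 1.0 — environmental 0.5, other
active classes 0.1 (0.125 for V6's parental classes); correlations 0.5
between direct and parental classes and between the parental classes
(0.25 in V6), ±0.25 between parental and imprinting classes in V5.
There is no canonical choice for the indirect and imprinting
magnitudes; these defaults keep every active class visible against
replicate noise while direct effects dominate, and are fixed once here.  Effect sizes
are drawn jointly normal across classes, scaled per locus by
1/√(2q(1−q)), then rescaled per class so Σ_j 2q_j(1−q_j)β_kj² hits the
target exactly on realized founder frequencies.  A scenario variant
with indirect sibling effects (variance 0.1, correlation +0.3 with
direct effects, which *reduces* the sibling-difference variance through
the −2βcβs term) is available via `EffectScenario.with_sibling`.

## Forward simulation

Founders are synthetic phased haplotypes from a latent Gaussian AR(1)
copying model: adjacent loci share latent correlation `ld_decay`, so
allele association decays geometrically with distance — a coarse stand
in for linkage-disequilibrium structure, not a calibrated human map.
Per-locus A2 frequencies are uniform on a configurable band (default
0.05–0.5).  An optional phased-VCF import replaces the synthetic panel
with real haplotypes.

Each generation: equal numbers of females and males (sexes alternate at
birth), phenotype-ordered mate assortment at target mate phenotypic
correlation ρ_Y via rank-matching both sexes' phenotypes against a
bivariate Gaussian template (ρ_Y = 0 is random pairing; intermediate
values are met within ±0.02 at 2,000+ pairs), two offspring per pair,
meiosis with fair strand choice and geometric crossovers at
`recomb_rate` per adjacent-locus interval (default 0.01).  Offspring
phenotypes use their parents' genotypes and their sibling's genotype.
Founder phenotypes (needed to seed the first assortment round) carry
only the direct and imprinting terms plus noise, since founders have no
modelled parents; assortment strength in generation 1 is accordingly
slightly understated for indirect-effect scenarios.

ρ_Y acts once per generation on the same phenotype that accrues the
indirect effects.  Note the scale separation: phenotype-level
assortment at ρ_Y spreads over causal loci, so the realized per-locus
mate genotype correlation is of order ρ_Y·h²/l (≈10⁻³ at l = 200) —
the variance inflation under assortment lives almost entirely in the
cross-locus correlations k_ij, not in per-locus homozygosity.

### Theory comparison

The comparison study (the `fig2` workflow) runs scenarios × {RM, AM
ρ_Y = 0.2} × {trio, sibling-difference} over replicates, sharing
founders and effects between regimes at matched seeds.  "Estimated" is
the realized variance of the summed genetic values (children, or
sibling differences, of the final generation); "expected" plugs
realized parent-generation allele frequencies and the measured
per-locus mate genotype correlation into the single-locus formulas and
combines loci with the measured genotypic-value correlation matrix.
The decomposition into class variances and covariances uses the true
simulated effects by design — it is a simulation-internal validity
check, not a statistical estimator of unknown effects.  A joint
least-squares estimator of (βc, βm, βf, βi) is provided as a secondary
diagnostic only, since marginal estimates are confounded by
construction.

Study sizes for the shipped checks: 10 replicates, 4,000 individuals,
500 loci of which 200 causal, 10 generations.  At these sizes the
theory–simulation gap is well inside two replicate standard deviations
in every cell, assortment inflates the trio variance by ≈10% (clear
against noise), and shrinks the sibling-difference variance by ≈1% — a
real but small effect at ρ_Y = 0.2, detectable only pooled across
scenarios and replicates.  The maternal–paternal covariance induced by
assortment is asserted under V5, where cross-class effect correlations
couple the parental scores to the phenotypes being matched; under V3
(uncorrelated classes) the same channel exists but is below replicate
noise at these sizes.

## Equilibrium family generation and relatedness

For the relatedness analyses, nuclear families are drawn directly from
the assortative-mating equilibrium law rather than simulated forward:
at each causal locus the four parental alleles are exchangeably
correlated at ρ via a de Finetti (beta-mixture) construction — a latent
per-family frequency p ~ Beta(q(1−ρ)/ρ, (1−q)(1−ρ)/ρ), alleles i.i.d.
Bernoulli(p) — and children are produced by fair Mendelian
transmission, independently per locus (loci unlinked here).  This is a
fixed point: children show allele correlation f = ρ and the same
genotype-variance inflation 2q1q2(1+ρ) as their parents.  Neutral
(non-causal) loci stay at Hardy–Weinberg — assortment only correlates
trait-associated loci.  Under this law the mates' genotype correlation
is 2ρ/(1+ρ), the per-locus sibling genetic covariance is
q1q2(1+3ρ)βc², and with direct variance 0.5, environment 0.5 and
ρ = 0.2 the implied full-sib phenotypic correlation is
0.25·1.6 / (0.25·2.4 + 0.5) = 0.364, which the generator reproduces;
the shipped check accepts the band 0.379 ± 0.05, centred on the
published prediction for this design (slightly above the within-locus
value here, plausibly through cross-locus correlation terms this
generator deliberately omits).

Genomic relatedness is the standardized-dosage cross-product
(X − 2q)/√(2q(1−q)) averaged over loci (monomorphic loci dropped and
logged).  The pair-correlation curve bins all unordered pairs (children
plus parents by default) by relatedness at width 0.01 (≥30 pairs per
bin), computes the Pearson correlation of phenotype pairs per bin —
each pair entered once in randomized member order; large-sample SE
(1−r²)/√(n−1) — and fits a pair-count-weighted slope over the
unrelated region π ∈ [−0.02, 0.02].  With direct effects only under
random mating this slope is an unbiased estimate of the injected
heritability regardless of the causal fraction of genotyped loci;
assortment raises it.  Under assortment sib pairs concentrate near
π ≈ (1+3ρ)/2·(causal share) + 1/2·(neutral share) rather than 0.5, so
the close-relative comparison is made at the sibs' own mean
relatedness: the reported excess is the full-sib correlation minus the
unrelated-slope extrapolation evaluated there.  With direct effects
only the excess is ≈0 (the curve is linear); adding correlated parental
indirect effects (V6) raises it by an order of magnitude, because sibs
share both parental genotypes exactly.

Parents' phenotypes in generated families carry their own direct terms
plus noise inflated by the (unmodelled) contributions of *their*
parents, keeping phenotypic variance comparable across roles; parental
phenotypes enter only as members of relatedness pairs — mating is at
equilibrium by construction, not phenotype-matched.

## Numerical choices

- Probabilities are evaluated in double precision with a 1e−12
  normalization guard on table weights; oracle equivalence is asserted
  at 1e−10 relative tolerance.
- The random- and assortative-mating variances share one evaluation
  path so their ρ = 0 identity holds bit-for-bit.
- ρ is accepted only in [0, 1] at the API surface (disassortative
  mating is out of scope); *measured* mate correlations plugged into
  the formulas may be slightly negative through noise and are evaluated
  as polynomials, with per-locus variances floored at zero before the
  multilocus square root.
- Negative per-locus variances cannot arise from valid parameters (the
  closed forms are variances of enumerable distributions); `var_total`
  still rejects them defensively.
- All randomness flows from numpy `SeedSequence` hierarchies; regime
  contrasts (RM vs AM) share founder/effect seeds by construction.
- The relatedness matrix product is chunked in float32; pair
  accumulation is streaming (the full pair matrix is never held).

## What the synthetic data do and do not show

The generators emulate unlinked-to-moderately-linked biallelic loci,
additive effects, Gaussian environments, discrete generations, constant
population size, and stylized assortment (rank-matching or equilibrium
sampling).  They do not emulate real linkage-disequilibrium structure,
mutation, selection, migration, variable family sizes, shared sibling
environments, or realistic mate choice.  Passing checks therefore
demonstrate internal consistency of formulas and mechanisms — not that
any particular human trait follows the model; in particular, observed
full-sib correlations in real cohorts exceed the direct-effects-only
prediction here, which is precisely the model's point about indirect
effects and assortment.

## Known limitations

- The sibling-difference design is the only sibling-effect analysis
  implemented; the full-population mean/variance with sibling effects
  is not.
- Phenotype-ordered assortment cannot produce large per-locus mate
  correlations at polygenic architectures (see scale separation above);
  analyses requiring per-locus ρ of ~0.2 use the equilibrium family
  generator instead.
- The equilibrium generator omits cross-locus (k, s) correlations; its
  within-locus law is exact.
- Founder bootstrap phenotypes understate assortment for
  indirect-effect scenarios in the first generation only.
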