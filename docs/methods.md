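# Methods

`domrev` packages three things: a biophysically explicit model of how a
cis-regulatory "dominance modifier" can evolve and reverse the dominance
of a sexually antagonistic polymorphism; the deterministic single-locus
theory of when such a reversal protects the polymorphism; and two data
analyses that detect dominance reversal in real designs (diallel crosses
and allele-specific expression).  This note records the models, the
parameter choices and their rationale, the numerical conventions, and
what the synthetic data do and do not emulate.

## The regulatory network (`domrev.regnet`)

A three-gene linear network: a sex-limited regulatory stimulus `D` binds
the cis-regulatory site `alpha_i` of transcription-factor gene `A`, and
the A protein variants compete for the cis-regulatory site `beta_i` of
downstream gene `B`.  Gene A carries a sexually antagonistic coding
polymorphism: `A1` (male-benefit) lowers the expression of B, `A2`
(female-benefit) raises it.  Only the binding sites `alpha` and `beta`
mutate; coding alleles and stimulus sequences are fixed.  `alpha_i`/`A_i`
and `beta_i`/`B_i` are fully linked cis units; the three genes assort
independently.

**Occupancy.**  The allele-specific concentration of an A product is

    [A_i] = A_max * ([D] / k^m) / (1 + 2 [D] / k^m),

where `m = m(sex, alpha_i)` is the proportion of mismatched nucleotides
between the stimulus recognition sequence of the individual's sex and
the haplotype's alpha site, and `k > 1` is the dissociation-constant
base.  The factor 2 reflects the two diploid copies of the regulated
gene competing for stimulus and caps the occupancy at 1/2.  `k` is
parameterized *stepwise*: the simulator takes `k_step` per mismatched
nucleotide (default 2) and uses `k = k_step**L_site` in the
proportion-unit formula, so one extra mismatched nucleotide always
weakens binding by the factor `k_step`.  With `L_site = 8` the affinity
range across a site spans 2^8 = 256; a per-proportion base of 2 would
span only a factor of 2, which makes single-nucleotide effects nearly
neutral in a population of a few hundred and lets mutation pressure
destroy the sites.

**Expression of B.**  Each of the two B gene copies has one beta site
for which the two A products compete:

    occ_i = (c_i / k^{m_i}) / (1 + sum_j c_j / k^{m_j}),

with `m_i` the mismatch of product i's recognition sequence to the beta
site.  A copy produces `effect_on_B(A_i)` when bound by allele i and the
basal activity `basal_B` when unbound:

    [B] = sum over copies of ( sum_i occ_i * e_i + (1 - sum_i occ_i) * basal_B ).

With the defaults `e(A1) = 0`, `e(A2) = 1`, `basal_B = 0.5`, A2 is an
activator and A1 a repressor of constitutive expression.  The basal term
is essential to the model's logic: it is what makes A1's *occupancy*
consequential, so that a haplotype raising [A1] in males actively lowers
[B] rather than merely diluting A2.  It also makes the fully resolved
state balanced -- an A2A2 male whose A2 copies are silenced sits at the
basal level and still pays `s * 0.5`, exactly as an A1A1 female with
silenced A1 does; `basal_B = 0.5` is the symmetric choice.

**Standardized trait.**  `phi = min(1, [B] / B_max)` with `B_max` the
analytic network maximum ([B] of an A2A2 genotype with zero mismatches
everywhere), so the scaling is deterministic and run-independent.

**Default sequences** (length 8 over ACGT): the two sex-specific
stimulus recognition sequences are fully divergent, so every alpha
position trades affinity in one sex against the other; the initial
alpha site matches each at exactly 4/8 (equidistant -- neither coding
allele starts with a cis advantage).  The initial beta site equals A2's
recognition sequence while A1 mismatches it at 2/8 positions, giving A2
its intrinsic dominance at the beta site.  With partially shared
stimulus sequences the shared positions form a pure degradation target
for mutation and the modifier dynamics stall; full divergence channels
mutation pressure into the sex-specific trade-off.

**Concentration scale.**  `A_max = 30` in the simulator (the generic
`RegNetParams` default stays 1.0): a fully matched activator then
occupies its site >90% of the time and the homozygote `phi` range spans
roughly 0.15-0.98.  At `A_max = 1` occupancies stay below ~0.2, the
genotypic `phi` differences shrink to ~0.2, and selection on the focal
polymorphism is too weak to be visible against drift at N = 500.

## Forward simulation (`domrev.simulator`)

Discrete non-overlapping generations; soft viability selection within
each sex (N/2 mothers and N/2 fathers sampled with replacement,
probability proportional to fitness); one random haplotype per gene per
parent; sexes assigned to keep N/2 each; then mutation.  For this scheme
the effective size is N for equal sex numbers, and the neutral
calibration checks the heterozygosity decay against `1 - 1/(2N)`
(the fitted rate sits ~8% above the idealized value, inside the 15%
acceptance band).

Fitness is linear in `phi` by default: `w_male = 1 - s_m * phi`,
`w_female = 1 - s_f * (1 - phi)`; a Gaussian scheme with sex-specific
optima is available.

Default run conditions: `N = 500`, 5000 generations, `mu = 1e-3` per
nucleotide per generation at the alpha sites, `[D] = 1`, `k_step = 2`,
`s_f = s_m = 0.2`, initial A2 frequency 0.5, 50 replicates per arm in
the replicate experiment.  Beta sites are held fixed by default
(`mu_site_beta = 0`) and can be mutated via the config: before a
reversal matures, beta match to A2 raises `phi` in *both* sexes, so net
selection on beta nearly cancels while mutation erodes it; the erosion
collapses all occupancies toward the basal level and removes the
antagonism itself.  The modifier under study is the alpha site
(`modifier_enabled` freezes alpha mutation for the control arm), so the
main experiments keep beta fixed.

Populations are stored as packed numpy arrays (sexes in fixed blocks)
for single-CPU throughput; a converter to per-individual genotype
objects exists, and the test suite holds the two evaluation paths to
agreement.

Per-replicate summaries report: retention time of the A polymorphism
(right-censored at the horizon); the allele-specific expression (ASE)
ratio `[A1]/([A1]+[A2])` among heterozygotes per sex at the last
generation where both sexes had measurable heterozygotes; the
time-averaged between-sex ASE difference; and the heterozygote `phi`
displacement from the homozygote midpoint per sex, averaged over the
last 100 recorded generations.  Arms sharing seeds are compared with a
paired sign test (ties dropped); the equalized-stimulus contrast uses a
Mann-Whitney rank test on the time-averaged ASE difference.

## Deterministic theory (`domrev.theory`)

Standard two-sex viability model: one autosomal locus, alleles F
(female-benefit) and M (male-benefit); female fitnesses (FF, FM, MM) =
(1, 1 - h_f s_f, 1 - s_f), male fitnesses (1 - s_m, 1 - h_m s_m, 1);
infinite population, random union of sex-specific gamete pools, equal
sex ratio, no mutation.  Rare-allele invasion rates are

    lambda_M = [ (1 - h_f s_f) + (1 - h_m s_m) / (1 - s_m) ] / 2
    lambda_F = [ (1 - h_f s_f) / (1 - s_f) + (1 - h_m s_m) ] / 2,

and the polymorphism is protected when both exceed 1.  Both rates fall
monotonically in h, so partial reversal (h < 1/2 in both sexes) expands
the protected region of the (s_f, s_m) plane, reaching the whole plane
at h = 0; under additivity protection requires strong and/or nearly
symmetric selection.  Because the closed forms are derived here, every
classification is arbitrated against brute-force iteration of the exact
recursion (vectorized over the grid), with 100% agreement on the default
41 x 41 grid outside a |lambda - 1| < 1e-3 boundary band.

Numerical conventions: "protected" uses strict inequality with a 1e-12
tolerance and boundary cases are reported as boundary; equilibrium
iteration stops when the per-step change falls below `tol` (default
1e-12 scalar, 1e-10 on grids) and classifies fixation when frequencies
pass 1e-6 -- trajectories approach the boundaries only geometrically,
so a pure step-size criterion cannot distinguish fixation from interior
convergence.  Under allele-sex mirror symmetry the two gamete pools
equilibrate at mirrored frequencies (p_f* + p_m* = 1) with the zygote
mean at 1/2; symmetry statements are therefore asserted on the mean.

## Genotype-fitness panels (`domrev.fitness_maps`)

Contexts are abstract labels (sexes, environments, generations).  The
effective dominance of a fitness triple is parameterized on the locally
deleterious allele, `h_eff = (w_best - w_Aa) / (w_best - w_worst)`,
reported unclipped so values below 0 encode overdominance and above 1
underdominance; `h_eff < 1/2` in both contexts defines a dominance
reversal for fitness.  Linear fitness preserves the phenotype map's
dominance exactly (affine invariance).  For Gaussian fitness with optima
at the homozygote traits and the heterozygote at the midpoint, a
midpoint inside both concave regions (separation/2 < width) guarantees
reversal in both contexts; the converse is not exact -- reversal
persists down to width = 0.9058 * separation/2, where the boundary is
set by 2 exp(-u/4) = 1 + exp(-u) rather than by curvature -- so the
classifier requires both the concavity condition and the computed
h_eff.  Marginal underdominance is flagged when the heterozygote's
across-context mean fitness falls below both homozygote means; narrow
widths relative to the optima separation (convex overlap) produce it.
The h_eff = 1/2 boundary is compared with tolerance 1e-9.

## Detection (`domrev.detect`)

**Diallel ordination.**  For strain r in one context, the array
covariance `W_r` is the sample covariance (n-1 denominator), across all
partners s *including the self*, between the mean phenotype of the
r x s crosses (replicates and reciprocals averaged) and partner s's
self value.  The self-inclusive convention is the classical diallel
one and gives the exact identities the implementation is tested
against: purely additive data yield `W_r = var(selfs)/2` identically
for every strain (hence a degenerate, zero-variance W vector), and a
strain whose alleles dominate every cross has `W_r = 0`.  Strains with
small `W_r` carry dominant fixed variation; the cross-context Pearson
correlation of the W vectors is the reversal statistic, negative when
strains dominant in one context are recessive in the other.  Inference
uses a two-sided permutation test (strain labels of one context's W
vector shuffled; default 10,000 permutations, 2,000 in the replicated
operating-characteristic runs), chosen over a parametric null because
strain panels are small (~16).  Degeneracy is declared when either W
vector's variance is below 1e-12 relative to its scale, and returned as
a flag rather than an exception.

**ASE reversal calling.**  Per gene and context, the imbalance estimate
is the allele-1 read fraction and the p-value an exact binomial test
against 1/2; p-values are adjusted across genes within each context
(Benjamini-Hochberg by default; Bonferroni and no adjustment are
options).  Classification: *reversal* requires significance in both
contexts independently AND opposite-side point estimates -- a
same-direction pair is never a reversal regardless of significance;
both-significant same-direction is *consistent imbalance*; exactly one
significant context is *context-dependent* dominance, not reversal.
Judging direction on point estimates and significance on adjusted
p-values keeps the two roles separate.  Overdispersion (beta-binomial)
modelling, mapping-bias correction and parent-of-origin QC are
deliberately out of scope; on real RNA-seq data an allele-by-context
interaction test on bias-corrected counts should precede biological
interpretation.

## Synthetic data (`domrev.synthdata`)

The diallel generator assigns each inbred strain a fixed homozygous
genotype at `n_loci = 50` biallelic loci; allele 1 contributes +e in
context A and -e in context B (allele 0 the reverse), crosses sum locus
effects, and heterozygous loci deviate from the midpoint by `d * e`
toward the context-beneficial allele (reversed mode), toward a globally
dominant allele drawn once per locus (unconditional mode), or not at
all (additive).  The (e, d) parameterization maps to the dominance
coefficient as h = (1 - d)/2 for the locally deleterious allele, so
d = 0 is additivity and d = 1 complete dominance.  Defaults: 16
strains, e = 1, d = 0.8, Gaussian noise sd 1.0 per observation, 2
replicates, no parent-of-origin effects (reciprocals differ only by
noise; the ordination averages them regardless).

The ASE generator draws allele-1 counts Binomial(depth, rho) in context
1 and Binomial(depth, 1 - rho) in context 2 for reversed genes
(rho = 0.7 by default, direction alternating between genes) and
Binomial(depth, 1/2) for null genes; depth is fixed (100) or Poisson.

What passing tests show -- and do not.  The generators emulate the
*designs* (full diallel with selfs and replicates; two-context allele
counts) under clean sampling assumptions: binomial reads without
overdispersion or mapping bias, Gaussian strain effects without
epistasis or maternal effects, balanced replication.  Operating
characteristics measured here (ordination rejection of ~100% at d=0.8
with 16 strains; ASE recall ~1.0 at depth 200 for rho = 0.7; type-I
rates at nominal level) are therefore upper bounds on what comparable
real data would give.

## Problem sizes

The replicated analyses use: 50 paired seeds x 3 arms x 5000
generations at N = 500 for the simulation experiment; 200 replicates of
N = 100 x 400 generations for the drift calibration; 200 synthetic
diallels per dominance mode (16 strains, 50 loci, 2000 permutations)
for the ordination; 2000 genes per condition for the ASE caller; and a
41 x 41 selection grid at three dominance levels for the theory
cross-check.  These sizes give stable statistics (Monte-Carlo standard
errors well inside the asserted margins) at desk-scale runtimes.

## Known limitations

* One antagonistic locus, two alleles; no recombination within cis
  units, no linkage between genes, no demography or overlapping
  generations.
* The B-expression functional form (competitive occupancy with basal
  activity) is this package's construction; other monotone forms would
  preserve the qualitative findings but change phi values.
* The deterministic theory covers viability selection only; fitness
  components multiplying within individuals (antagonistic pleiotropy)
  are only diagnosed via the marginal-mean heterozygote check.
* Detection methods assume clean, bias-free measurements as noted
  above.
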