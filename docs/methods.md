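# Methods

`ckmrkit` implements close-kin mark-recapture (CKMR) for a long-lived,
late-maturing fish stock sampled on its spawning grounds: juveniles
genetically "mark" their two parents, parent-offspring pairs (POPs) found
among all pairwise adult-juvenile genotype comparisons are the
"recaptures", and an age/length/sex-structured population model turns the
number and covariate pattern of those pairs into estimates of absolute
adult abundance, adult survival and size-dependent fecundity.

## Kinship identification

**Exclusion with null alleles.** A true POP shares at least one allele at
every locus. A pair is accepted as a POP iff no scored locus excludes it.
Because microsatellite null alleles make a visible/null heterozygote look
homozygous, two apparent homozygotes with different alleles (AA vs BB)
never exclude: either fish could be a null carrier. Allele frequencies per
locus, including the null frequency, are estimated by maximum likelihood
(EM) on the observable genotype classes, conditioned on each fish showing
at least one non-null allele; a monomorphic locus leaves the null
frequency unidentifiable and is returned degenerate with a warning.

**False-positive control.** The probability that an unrelated pair shows
zero excluding loci is the product over the jointly scored loci of
(1 − per-locus exclusion probability); the per-locus term is a closed form
over observable genotype classes (verified against brute-force enumeration
to machine precision). Comparisons where the adult was not caught strictly
after the juvenile's birth year are dropped (parentage impossible;
part-year spawners have not made their full reproductive contribution).
Remaining comparisons are retained most-informative-first until the summed
false-positive expectation would exceed `fp_budget_fraction` (default 1%)
of the POPs called among those retained. Because the POP count is a step
function of the threshold, the budget is solved by a monotone
(tightening-only) fixed-point iteration, with ties broken by fish id.

**False negatives.** Sporadic genotyping errors can push a true POP to one
or two apparent exclusions. The low-count cells of the exclusion table are
modelled as Poisson counts mixing `n_pop` true POPs with Binomial(L, eps)
apparent exclusions (independent per-locus errors at one shared rate —
a reconstruction, since the error process is not observable directly) and
the unrelated-pair background computed exactly per pair by a
Poisson-binomial recursion. The reported interval for the expected number
of missed POPs is a profile-likelihood CI (chi-square, 1 df). Pairs with
one or two exclusions are flagged `near_miss` for re-examination,
standing in for a manual blind-rescoring step that is out of scope.

**Quality control.** Three checks: (i) a flexible (cubic-basis) regression
of per-fish homozygosity on the fraction of scorable loci, F-tested for
any trend (a DNA-quality effect); (ii) per-locus apparent-homozygote
excess against null-free Hardy-Weinberg (one-sided binomial test — the
null-allele signature); (iii) long-allele dropout, tested by regressing
per-allele Pearson residuals of apparent-homozygote counts (under the
fitted null-allele model) on within-locus standardized allele length.
Simulations show the single-locus genotype distribution carries almost no
length signal when dropout depends on *absolute* allele length (it is
confounded with null alleles); the generator therefore implements the
mechanistically standard *competitive* dropout — within a heterozygote the
longer allele amplifies worse in proportion to the length difference —
which check (iii) detects with >80% power at n = 8,000 fish for a maximum
dropout probability of 0.15 (slope chosen by pilot).

## Population model

Adults are modelled from age 8 (the youngest observed breeding age), over
calendar years 2002-2010, with constant total mortality `z` across age,
year and sex. Annual age-8 recruitment is log-normal about a constant mean
with random-effect deviations (s.d. `sigma_r`); the first modelled year
starts at the deterministic equilibrium of the mean recruitment. Growth
stops at a plus-group age of 25, but the dynamics are carried (by default)
to an absorbing class at 45 with the 25+ classes acting as a disaggregated
plus group: collapsing every old fish to "exactly 25" would wrongly
hindcast-shrink the lengths of genuinely older fish, distorting the
fecundity attributed to the largest females, and measurably understated
the replicate-to-replicate spread of the survival estimator in simulation.

Length-at-age follows a Student-t distribution with 12 df (heavier-tailed
than a normal, to accommodate occasional very large fish) centred on a
sex-specific von Bertalanffy curve with constant CV across ages; the CV
applies to the t *scale* parameter, not its standard deviation. Each
individual follows its own growth curve with an individual asymptotic
length but sex-shared k and t0, which makes hindcasting an adult's length
from capture back to a juvenile's birth year exact and consistent with the
constant-CV model. Growth stops at the plus-group age.

Spawning-ground selectivity is logistic in length per sex and doubles as
relative residence duration; female annual fecundity is residence duration
times daily egg output (default: a power of length, `alpha * L^beta`, or a
user-supplied table); male fecundity is a logistic curve with free scale
(weakly identified, as expected). Only fecundity *ratios* enter kinship
probabilities, so all outputs that matter are invariant to rescaling the
curves (tested). Expectations over the length-at-age law use a piecewise
Gauss-Legendre rule on the t axis (64 nodes, wide outer panels): power-law
fecundities weight the heavy upper tail strongly enough that simpler
quantile rules showed 1-2% age-dependent error.

The pairwise probability that sampled adult `a` parented a juvenile of
cohort `c` is `E[fec(a at c)] / TRO(sex_a, c)`: the adult's fecundity at
its hindcast length, integrated over its age posterior given length, sex
and capture year when no otolith age exists, divided by the total
reproductive output of its sex in that year. Adults that cannot have been
at least age 8 in the cohort year have probability zero.

## Likelihood and estimation

Four independent components: length/sex composition of adult samples
(multinomial, with a configurable effective-sample-size multiplier,
default 0.1 on real data to absorb interannual overdispersion; 1.0 for
simulator output, which is genuinely multinomial), otolith ages given
length/sex/year (removing the length-stratified sampling bias by
conditioning), daily-fecundity observations (lognormal error), and the
genetic component — a Bernoulli log-likelihood over comparisons grouped
into covariate categories (1-cm length bin x sex x capture year x otolith
age x cohort, each represented by its mean member length). With zero-width
bins the grouped likelihood equals the pairwise one exactly (tested); at
the default width it differs by <0.1 log-units at the true parameters.
Coarser bins are configurable, but with a fecundity curve as steep as
`L^8` and only a handful of adults per category at desk scale, 2-cm bins
already concentrate a few tenths of a log-unit of error in the
parent-bearing categories.

`sigma_r` is estimated by maximizing a Laplace approximation to the
marginal likelihood; all other parameters by penalized maximum likelihood
conditional on it, with standard errors from the inverse penalized
Hessian (central finite differences, relative step 1e-4) and delta-method
(lognormal) 90% intervals for derived series.  The variance search is kept
cheap by two approximations that matter little at its loose (0.1 on the
log scale) resolution: the inner refits move only the deviations
(structural parameters are refreshed in the final fit), and the
log-determinant term reuses the eigenvalues of the data curvature over
deviations measured once at a reference variance, so
log det H(sigma) = sum log(lambda_i + 1/sigma^2).
When the variance estimate sits away from its search bounds, the
parameter covariance receives a Kass-Steffey addition propagating the
uncertainty in the Empirical-Bayes variance estimate.
Parameters are transformed (log for rates, scales and the fecundity
exponent) for unconstrained optimization (L-BFGS-B); starting values come
from the data (a kin-pair Lincoln-Petersen estimate for recruitment,
log-log regression for the fecundity curve, the sample median length for
the selectivity midpoint). Growth parameters are held fixed (externally
estimated, as is standard), which allows the age-given-length densities
and hindcast ratios to be precomputed once per fit.

**Small-count curvature adjustment.** Abundance-scale point estimates
(abundance, biomass, spawning potential) are inverse-kin-count estimators
and carry the classic `+CV^2` small-sample bias — the same curvature that
Chapman's correction removes from Lincoln-Petersen. Reported point
estimates are therefore adjusted by `exp(-se_log^2)`; intervals are left
as plain lognormal intervals. Survival and fecundity ratios are not
inverse-count estimators and are not adjusted. In a 40-replicate pilot at
desk scale the log-scale estimates were unbiased and the natural-scale
bias matched the predicted `+CV^2` before adjustment.

The headline "mean adult abundance" averages the juvenile cohort years —
the years the kinship data inform. Model variants (recruitment trend,
separate plus-group mortality) are config flags, off by default.

## Simulator

The individual-based generator embodies the estimation model's assumptions
exactly, so parameter-recovery tests are tests of the inference machinery,
not of model misspecification. Defaults are the desk-scale study
conditions used throughout testing: ~5,000 adults (annual survival 0.77,
recruitment s.d. 0.25), 80 adults sampled per year 2006-2010 and 70
juveniles per cohort 2003-2007 (~38 expected POPs among ~1.2e5
comparisons), one-third of adults otolith-aged, a 25-locus
microsatellite-like panel (12-24 alleles per locus, Dirichlet
frequencies; null alleles at 20 of 25 loci, 1-8%; per-allele miscall
1e-3; 8% unscored), and a female fecundity exponent solved in closed form
so the per-kg reproductive output of an average age-15 female is exactly
3.2x that of an age-10 female. Parents are drawn per juvenile
proportionally to fecundity, independently for mothers and fathers, so
reproductive skew arises naturally; an optional gamma overdispersion knob
adds within-year family clumping. Annual adult catches are independent
selectivity-weighted draws from all alive adults; a re-caught fish enters
as an aliased, independently re-genotyped record. This keeps the inclusion
probability proportional to selectivity given length in every year — the
estimator's key unbiasedness condition; removing previously caught fish
from later pools instead would deplete large fish measurably at the
desk-scale sampling fraction (8%), an artefact a real fishery (sampling
fraction ~0.1%) does not have. All randomness flows from one master seed
through named substreams.

What the generator does *not* emulate: spatial structure, age-varying or
time-varying mortality, growth measurement error, chimeric plate-swap
genotyping errors, juvenile age misassignment, and fishery removals
feeding back on the population. Passing recovery tests therefore
demonstrates the estimator is correct and calibrated under its own
assumptions at realistic sample sizes — not that those assumptions hold
for any particular real fishery.

## Numerical choices and limitations

* Exclusion-probability closed form vs enumeration: agreement to 1e-12 for
  panels up to 6 visible alleles plus null (property-tested).
* EM for null-allele frequencies: tolerance 1e-12, verified against a
  grid-search oracle of the conditional likelihood.
* The retention fixed point only tightens, so it terminates; an empty
  retained set (no zero-exclusion pairs to fund the budget) returns a
  diagnostic rather than an error.
* The Laplace outer optimization is a bounded 1-D search on log `sigma_r`
  in [0.05, 1.0] with loose tolerance (0.08 on the log scale); with only
  nine deviation years the estimate is weakly identified and often
  shrinks, which is expected Empirical-Bayes behaviour.
* With ~40 POPs the abundance CV floor is ~0.16; single-replicate
  estimates routinely deviate 15-20% from truth, and bias checks are only
  meaningful across replicates.
* Default placeholder values for growth, length-weight and fecundity
  scale are plausible for a large southern-hemisphere tuna but are not
  fitted to any real dataset; biomass outputs inherit the length-weight
  choice.
* The survival estimator retains a small O(1/n) maximum-likelihood bias at
  desk scale (about -0.004 on a survival of 0.77, i.e. a quarter of its
  own standard error, measured over 70 simulation replicates); it vanishes
  at 10x the data and is far below practical significance, but it is real
  and no canonical correction analogous to the abundance curvature
  adjustment exists for it.
* The simulator can freeze demographic stochasticity
  (``demographic_stochasticity=False``: expectation-valued cohort counts
  and stratified-quantile death schedules) for variance-decomposition
  studies.
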