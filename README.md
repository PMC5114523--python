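# ckmrkit

Close-kin mark-recapture (CKMR) from multilocus genotypes: find
parent-offspring pairs (POPs) among genotyped adults and juveniles by
null-tolerant parentage exclusion with controlled false-positive and
false-negative rates, then estimate **absolute adult abundance**, **adult
survival** and **size-dependent fecundity** by fitting an
age/length/sex-structured pairwise-kinship likelihood. An individual-based
simulator generates populations, pedigrees, sampling and error-prone
genotypes so that every stage is testable by parameter recovery at desk
scale.

## The idea

Every juvenile genetically marks its two parents. Comparing `m_J` sampled
juveniles against `m_A` sampled adults, each pairwise comparison is a POP
with probability `2 / N_adult`, so the observed POP count `P` gives a
kin-pair analogue of the Lincoln-Petersen estimate

```
N_adult = 2 m_J m_A / P
```

with achievable CV bounded below by `1 / sqrt(P)`. In a real, structured
population the `2/N` term is replaced by a covariate-specific probability:
the chance that adult `a` (length `l`, sex `s`, caught in year `y`) is a
parent of a juvenile born in year `c < y` is `a`'s share of the total
reproductive output (TRO) of its sex in year `c`,

```
P_ac = E[ fec_s( L_a(c) ) ] / TRO(s, c)
```

where `L_a(c)` hindcasts the adult's length along its individual von
Bertalanffy curve and the expectation integrates over the adult's age
posterior given length when no otolith age exists. Demographic parameters
are estimated from the Bernoulli log-likelihood of all pairwise
comparisons plus adult length/sex compositions, otolith ages and daily
fecundity data, in an Empirical-Bayes framework with Laplace-approximated
recruitment variance. No catch-rate (CPUE) or total-catch data enter.

POPs are identified by the exclusion principle — a true parent and
offspring share an allele at every locus — made robust to microsatellite
null alleles (apparent-homozygote tolerance, null-aware allele-frequency
ML) and to chance matches: pairs are compared only if the adult was caught
after the juvenile's birth year, and only the most informative comparisons
are retained so that expected false positives stay under 1% of the POPs
called.

## Worked example

```python
from ckmrkit import simulate as sim, kinship as kin
from ckmrkit.inference import (BinConfig, CKMRData, CKMRModel, FitConfig,
                               bin_comparisons)

cfg = sim.default_config()                      # the desk-scale study
pop = sim.simulate_population(cfg, seed=3)      # ~5,000 adults, survival 0.77
samples = sim.simulate_sampling(pop, None, seed=3)   # 400 adults, 350 juveniles
panel = sim.simulate_genotypes(pop, samples.fish_id.tolist(), seed=3)

models = {l: kin.estimate_allele_freqs(panel, l) for l in panel.loci}
adults = samples[samples.stage == "adult"]
juv = samples[samples.stage == "juvenile"]
comps = kin.build_comparisons(panel.subset(adults.fish_id.to_numpy()), adults,
                              panel.subset(juv.fish_id.to_numpy()), juv,
                              models)
print(comps.n_pops, int(comps.df.retained.sum()),
      round(comps.expected_false_positives, 5))
# 40 123200 0.00018   -> 40 POPs among 123,200 retained comparisons;
#                        expected false positives 0.0002 (budget: 1% of 40)

binned = bin_comparisons(comps, samples)
fec = sim.simulate_fecundity_observations(pop, samples, seed=3)
data = CKMRData(samples=samples, binned=binned, fecundity_obs=fec)
res = CKMRModel(data, cfg.pop, FitConfig(ess_factor=1.0)).fit()
n = res.derived_value("mean_adult_abundance")
print(f"N = {n.estimate:.0f}  (90% CI {n.lo90:.0f}-{n.hi90:.0f})")
s = res.derived_value("survival")
print(f"survival = {s.estimate:.3f}  (90% CI {s.lo90:.3f}-{s.hi90:.3f})")
# N = 4636  (90% CI 3630-6253)
# survival = 0.780  (90% CI 0.751-0.810)
```

The realized truth in this replicate is a mean adult abundance of `4923`
over the cohort years and survival `0.77`, both inside the intervals
(with 40 pairs the abundance CV floor is `1/sqrt(40) ≈ 0.16`, and the
interval is honest about it). `res.derived` also carries per-year abundance,
adult biomass (ages 10+, via a configurable length-weight relation),
female spawning potential in equivalent-age-16-female units, and the
fecundity-per-kg age ratios.

A command-line surface wraps the same steps
(`ckmrkit simulate | find-pops | qc | fit | design`, each with `--seed`,
`--config`, `--out`); every run writes a manifest with the config hash and
versions. `ckmrkit design -n 1e6 --target-cv 0.15` answers the survey-design
question: ~45 POPs are needed, i.e. `m = sqrt(E[P] N / 2) ≈ 4,750` samples
per group, scaling with the square root of abundance.

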