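"""Individual-based simulator: population, pedigree, sampling and genotypes.

Generates ground truth for every other module: a long-lived adult
population with constant mortality and log-normal recruitment variation,
sex-specific von Bertalanffy growth with individual asymptotic lengths
(constant-CV Student-t length-at-age), fecundity-weighted parent assignment
(each juvenile draws one mother proportional to female fecundity in its
birth year and one father proportional to male fecundity, independently, so
reproductive skew arises naturally), logistic length-based sampling
selectivity for adults, and Mendelian multilocus genotypes with null
alleles, unscored loci and rare per-allele miscalls.

All randomness flows from a single master seed through named substreams,
so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kinship import MISSING, GenotypePanel
from .popdyn import (GrowthParams, Logistic, PopParams, PowerFecundity,
                     SexGrowth, equilibrium_adults_per_recruit, fecundity,
                     fecundity_exponent_for_perkg_ratio, mean_length,
                     LengthWeight)

__all__ = [
    "LocusSpec",
    "SamplingPlan",
    "SimConfig",
    "Population",
    "TruePedigree",
    "default_growth",
    "default_pop_params",
    "default_panel",
    "default_config",
    "simulate_population",
    "simulate_sampling",
    "simulate_genotypes",
    "simulate_founder_panel",
]

_STREAMS = {"panel": 0, "population": 1, "pedigree": 2, "sampling": 3,
            "genotypes": 4, "observation": 5}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(_STREAMS[name],)))


@dataclass(frozen=True)
class LocusSpec:
    """One microsatellite-like locus: allele ladder, frequencies, null rate."""

    locus_id: str
    allele_lengths: tuple      # repeat lengths in bp, 4-bp ladder
    freqs: tuple               # visible-allele frequencies, sum 1 - null_freq
    null_freq: float

    def __post_init__(self):
        if abs(sum(self.freqs) + self.null_freq - 1.0) > 1e-9:
            raise ValueError("locus frequencies must sum to 1 including null")
        if not (0 <= self.null_freq < 1):
            raise ValueError("null frequency must be in [0, 1)")


@dataclass
class SamplingPlan:
    """Annual sampling effort: selectivity-weighted adults, uniform juveniles."""

    adult_years: tuple = (2006, 2007, 2008, 2009, 2010)
    adults_per_year: int = 80
    juvenile_cohorts: tuple = (2003, 2004, 2005, 2006, 2007)
    juveniles_sampled_per_cohort: int = 70
    juvenile_capture_age: int = 3
    ageing_fraction: float = 1 / 3


@dataclass
class SimConfig:
    """Full study-condition configuration for one synthetic dataset."""

    pop: PopParams
    plan: SamplingPlan
    panel: list                      # list[LocusSpec]
    juveniles_per_cohort: int = 1200
    miscall_rate: float = 0.001
    unscored_rate: float = 0.08
    long_allele_dropout: float = 0.0  # max dropout prob at the longest allele
    family_overdispersion: float = 0.0  # extra within-year family clumping
    max_init_age: int = 45
    #: False freezes cohort sizes and death schedules at their expectations
    #: (stratified quantiles) -- for variance-decomposition studies
    demographic_stochasticity: bool = True


def default_growth() -> GrowthParams:
    """Placeholder growth values for a large, long-lived tuna-like fish."""
    return GrowthParams(female=SexGrowth(190.0, 0.16, -0.3),
                        male=SexGrowth(175.0, 0.17, -0.3),
                        cv=0.08, df=12.0, plus_age=25)


def default_pop_params(n_adults: float = 5000.0, survival: float = 0.77,
                       sigma_r: float = 0.25,
                       years=tuple(range(2002, 2011)),
                       perkg_ratio_15_10: float = 3.2,
                       growth: GrowthParams | None = None) -> PopParams:
    """Study-condition truth: ~5,000 adults, annual survival 0.77, and a
    fecundity curve whose per-kg output ratio (average age-15 vs age-10
    female) equals the target (default 3.2)."""
    growth = growth or default_growth()
    z = -np.log(survival)
    rbar = n_adults / equilibrium_adults_per_recruit(z, plus_age=growth.plus_age)
    sel = Logistic(155.0, 0.08)
    lw = LengthWeight()
    beta = fecundity_exponent_for_perkg_ratio(growth, sel, lw,
                                              ratio=perkg_ratio_15_10)
    # alpha scaled so daily output is O(1) at 160 cm (scale is arbitrary)
    alpha = float(160.0 ** -beta)
    return PopParams(growth=growth, z=float(z),
                     mean_log_recruitment=float(np.log(rbar)), years=years,
                     sigma_r=sigma_r, selectivity_female=sel,
                     selectivity_male=sel,
                     female_daily_fecundity=PowerFecundity(alpha, float(beta)),
                     length_weight=lw, max_age=45)


def default_panel(n_loci: int = 25, n_null_loci: int = 20,
                  panel_seed: int = 20160) -> list:
    """Microsatellite-like panel: 12-24 alleles per tetranucleotide locus,
    Dirichlet frequencies, and a small null-allele frequency at most loci."""
    rng = np.random.default_rng(panel_seed)
    loci = []
    for i in range(n_loci):
        k = int(rng.integers(12, 25))
        base = int(rng.integers(100, 220))
        lengths = tuple(range(base, base + 4 * k, 4))
        null = float(rng.uniform(0.01, 0.08)) if i < n_null_loci else 0.0
        freqs = rng.dirichlet(np.ones(k)) * (1.0 - null)
        loci.append(LocusSpec(locus_id=f"L{i + 1:02d}",
                              allele_lengths=lengths,
                              freqs=tuple(freqs.tolist()), null_freq=null))
    return loci


def default_config(**overrides) -> SimConfig:
    """The desk-scale study conditions used throughout testing."""
    cfg = SimConfig(pop=default_pop_params(), plan=SamplingPlan(),
                    panel=default_panel())
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class TruePedigree:
    """Mother and father ids for every simulated juvenile, plus derived kin sets."""

    juveniles: pd.DataFrame  # fish_id, cohort, mother_id, father_id

    def pop_pairs(self) -> set:
        """Set of (adult_id, juvenile_id) true parent-offspring pairs."""
        out = set()
        for row in self.juveniles.itertuples():
            out.add((row.mother_id, row.fish_id))
            out.add((row.father_id, row.fish_id))
        return out

    def parent_of(self) -> dict:
        return {row.fish_id: (row.mother_id, row.father_id)
                for row in self.juveniles.itertuples()}

    def sibling_pairs(self) -> set:
        """Unordered juvenile pairs sharing at least one parent."""
        out = set()
        for col in ("mother_id", "father_id"):
            for _, grp in self.juveniles.groupby(col):
                ids = sorted(grp.fish_id)
                for i in range(len(ids)):
                    for j in range(i + 1, len(ids)):
                        out.add((ids[i], ids[j]))
        return out


@dataclass
class Population:
    """Simulated individuals and realized abundance.

    ``adults`` columns: fish_id, sex ('F'/'M'), recruit_year (year the fish
    turned the minimum adult age), last_year (last year alive),
    growth_mult (individual asymptotic-length multiplier).
    """

    adults: pd.DataFrame
    pedigree: TruePedigree
    config: SimConfig

    def age_in(self, year) -> np.ndarray:
        return self.config.pop.min_age + (int(year) - self.adults.recruit_year.to_numpy())

    def alive_in(self, year) -> np.ndarray:
        y = int(year)
        return ((self.adults.recruit_year.to_numpy() <= y)
                & (self.adults.last_year.to_numpy() >= y))

    def length_in(self, year) -> np.ndarray:
        g = self.config.pop.growth
        age = self.age_in(year)
        mult = self.adults.growth_mult.to_numpy()
        sex = (self.adults.sex.to_numpy() == "M").astype(int)
        mu = np.where(sex == 0, mean_length(age, "F", g), mean_length(age, "M", g))
        return mu * mult

    def abundance(self, year) -> int:
        return int(self.alive_in(year).sum())


def _draw_growth_mult(rng, growth: GrowthParams, n: int) -> np.ndarray:
    mult = 1.0 + growth.cv * rng.standard_t(growth.df, size=n)
    return np.clip(mult, 0.05, None)


def simulate_population(config: SimConfig, seed: int) -> Population:
    """Simulate the adult population, its dynamics, and juvenile pedigrees.

    The initial year starts at the Poisson-sampled equilibrium implied by
    the mean recruitment; each later year adds Poisson(R_y) recruits at the
    minimum adult age (R_y log-normal about the mean via the configured
    deviations, drawn here if not supplied) and kills adults independently
    with probability 1 - exp(-z).  Each cohort of juveniles draws parents
    by fecundity-weighted sampling among the adults alive in its birth
    year.
    """
    pop = config.pop
    g = pop.growth
    rng = substream(seed, "population")
    years = list(pop.years)
    surv = float(np.exp(-pop.z))

    if not pop.recruitment_devs and pop.sigma_r > 0:
        devs = rng.normal(0.0, pop.sigma_r, size=len(years))
        pop = replace(pop, recruitment_devs={y: float(d)
                                             for y, d in zip(years, devs)})
        config = replace(config, pop=pop)

    rbar = float(np.exp(pop.mean_log_recruitment))
    stoch = config.demographic_stochasticity
    draw_count = (lambda lam: int(rng.poisson(lam))) if stoch \
        else (lambda lam: int(round(lam)))
    recruit_years, counts = [], []
    # standing population at the first year (equilibrium, no deviations)
    for a in range(pop.min_age, config.max_init_age + 1):
        ry = years[0] - (a - pop.min_age)
        expected = (0.5 * rbar * surv ** (a - pop.min_age)) * 2  # both sexes
        if ry == years[0]:
            expected = pop.recruitment(ry)
        recruit_years.append(ry)
        counts.append(draw_count(expected))
    for y in years[1:]:
        recruit_years.append(y)
        counts.append(draw_count(pop.recruitment(y)))

    rows_ry = np.repeat(recruit_years, counts)
    n_ind = len(rows_ry)
    if n_ind == 0:
        raise RuntimeError("population extinct before the sampling years")
    sex = np.where(rng.random(n_ind) < 0.5, "F", "M")
    mult = _draw_growth_mult(rng, g, n_ind)
    # alive from max(recruit_year, first model year); geometric extra years
    alive_from = np.maximum(rows_ry, years[0])
    if stoch:
        u = rng.random(n_ind)
    else:
        # stratified quantiles within each entry group: realized survival
        # schedules match the geometric law exactly
        u = np.empty(n_ind)
        for af in np.unique(alive_from):
            idx = np.flatnonzero(alive_from == af)
            u[idx] = rng.permutation((np.arange(len(idx)) + 0.5) / len(idx))
    extra = np.floor(np.log1p(-u) / np.log(surv)).astype(int)
    last_year = alive_from + extra
    adults = pd.DataFrame({
        "fish_id": np.array([f"A{i:06d}" for i in range(n_ind)]),
        "sex": sex,
        "recruit_year": rows_ry.astype(int),
        "last_year": last_year.astype(int),
        "growth_mult": mult,
    })

    ped_rng = substream(seed, "pedigree")
    pop_obj = Population(adults=adults, pedigree=TruePedigree(pd.DataFrame()),
                         config=config)
    jrows = []
    jid = 0
    for cohort in config.plan.juvenile_cohorts:
        alive = pop_obj.alive_in(cohort)
        lengths = pop_obj.length_in(cohort)
        ages = pop_obj.age_in(cohort)
        eligible = alive & (ages >= pop.min_age)
        w = np.zeros(n_ind)
        fem = eligible & (sex == "F")
        mal = eligible & (sex == "M")
        w[fem] = fecundity(lengths[fem], "F", pop)
        wm = np.zeros(n_ind)
        wm[mal] = fecundity(lengths[mal], "M", pop)
        if w.sum() == 0 or wm.sum() == 0:
            raise RuntimeError(f"no eligible parents in cohort year {cohort}")
        if config.family_overdispersion > 0:
            gam = ped_rng.gamma(1.0 / config.family_overdispersion,
                                config.family_overdispersion, size=n_ind)
            w, wm = w * gam, wm * gam
        mothers = ped_rng.choice(n_ind, size=config.juveniles_per_cohort,
                                 p=w / w.sum())
        fathers = ped_rng.choice(n_ind, size=config.juveniles_per_cohort,
                                 p=wm / wm.sum())
        for mo, fa in zip(mothers, fathers):
            jrows.append((f"J{jid:06d}", cohort, adults.fish_id.iloc[mo],
                          adults.fish_id.iloc[fa]))
            jid += 1
    pedigree = TruePedigree(pd.DataFrame(
        jrows, columns=["fish_id", "cohort", "mother_id", "father_id"]))
    return Population(adults=adults, pedigree=pedigree, config=config)


def simulate_sampling(population: Population, plan: SamplingPlan | None,
                      seed: int) -> pd.DataFrame:
    """Draw the sampled fish and their covariate records.

    Adults are sampled without replacement each year with probability
    proportional to length-based selectivity (and never twice -- sampling
    is lethal); juveniles uniformly from each cohort at the capture age.
    Adult sampling is independent of true parentage given length and sex,
    the key unbiasedness condition of the kinship estimator.  A random
    subset of adults carries an otolith age.
    """
    cfg = population.config
    plan = plan or cfg.plan
    pop = cfg.pop
    rng = substream(seed, "sampling")
    n_caught = np.zeros(len(population.adults), dtype=int)
    rows = []
    for y in plan.adult_years:
        # each year's catch is an independent selectivity-weighted draw from
        # every alive adult, so inclusion probability stays proportional to
        # selectivity given length in every year (the estimator's key
        # condition); at desk-scale sampling fractions a fish occasionally
        # recurs and enters as a separately-genotyped aliased record
        alive = population.alive_in(y)
        ages = population.age_in(y)
        eligible = np.flatnonzero(alive & (ages >= pop.min_age))
        lengths = population.length_in(y)
        sexes = population.adults.sex.to_numpy()
        w = np.where(sexes[eligible] == "F",
                     pop.selectivity_female(lengths[eligible]),
                     pop.selectivity_male(lengths[eligible]))
        n_want = plan.adults_per_year
        if n_want > len(eligible):
            import warnings
            warnings.warn(f"requested {n_want} adults in {y}, only "
                          f"{len(eligible)} available; truncating")
            n_want = len(eligible)
        take = rng.choice(eligible, size=n_want, replace=False, p=w / w.sum())
        aged = rng.random(n_want) < plan.ageing_fraction
        for i, idx in enumerate(take):
            fid = population.adults.fish_id.iloc[idx]
            if n_caught[idx]:
                fid = f"{fid}#{n_caught[idx] + 1}"
            n_caught[idx] += 1
            rows.append({"fish_id": fid,
                         "stage": "adult", "capture_year": y,
                         "length": lengths[idx],
                         "sex": sexes[idx],
                         "age": int(ages[idx]) if aged[i] else None,
                         "birth_year": None})
    juv = population.pedigree.juveniles
    for cohort in plan.juvenile_cohorts:
        members = juv[juv.cohort == cohort]
        n_want = min(plan.juveniles_sampled_per_cohort, len(members))
        take = rng.choice(len(members), size=n_want, replace=False)
        for idx in take:
            row = members.iloc[idx]
            rows.append({"fish_id": row.fish_id, "stage": "juvenile",
                         "capture_year": cohort + plan.juvenile_capture_age,
                         "length": None, "sex": None,
                         "age": plan.juvenile_capture_age,
                         "birth_year": cohort})
    df = pd.DataFrame(rows)
    df["age"] = df["age"].astype("Int64")
    df["birth_year"] = df["birth_year"].astype("Int64")
    return df


def simulate_genotypes(population: Population, fish_ids, seed: int,
                       panel: list | None = None,
                       miscall_rate: float | None = None,
                       unscored_rate: float | None = None,
                       long_allele_dropout: float | None = None) -> GenotypePanel:
    """Mendelian genotypes with an error-prone observation layer.

    Founder (adult) genotypes draw two alleles per locus from the panel
    frequencies including the null allele; juveniles inherit one uniformly
    chosen allele from each parent.  Observation then applies, per allele
    copy: length-dependent dropout (optional), null masking (a visible/null
    fish appears homozygous; a null/null or fully dropped fish is
    unscored), a rare miscall to another ladder allele, and per-locus
    unscored dropout.
    """
    cfg = population.config
    panel = panel if panel is not None else cfg.panel
    miscall = cfg.miscall_rate if miscall_rate is None else miscall_rate
    unscored = cfg.unscored_rate if unscored_rate is None else unscored_rate
    dropout = (cfg.long_allele_dropout if long_allele_dropout is None
               else long_allele_dropout)

    rng = substream(seed, "genotypes")
    obs_rng = substream(seed, "observation")
    n_loci = len(panel)

    adult_ids = population.adults.fish_id.to_numpy()
    adult_pos = {fid: i for i, fid in enumerate(adult_ids)}
    # true genotypes for all adults; 0 encodes the null allele
    true_adults = _founder_true_genotypes(panel, len(adult_ids), rng)

    parent_map = population.pedigree.parent_of()
    fish_ids = list(fish_ids)
    true = np.zeros((len(fish_ids), n_loci, 2), dtype=np.int32)
    for i, rec_id in enumerate(fish_ids):
        fid = base_id(rec_id)
        if fid in adult_pos:
            true[i] = true_adults[adult_pos[fid]]
        else:
            mo, fa = parent_map[fid]
            pick = rng.integers(0, 2, size=(2, n_loci))
            true[i, :, 0] = true_adults[adult_pos[mo], np.arange(n_loci), pick[0]]
            true[i, :, 1] = true_adults[adult_pos[fa], np.arange(n_loci), pick[1]]

    obs = _observe_genotypes(true, panel, obs_rng, miscall, unscored, dropout)
    return GenotypePanel(fish_ids=np.asarray(fish_ids),
                         loci=[s.locus_id for s in panel], alleles=obs)


def _founder_true_genotypes(panel, n: int, rng) -> np.ndarray:
    """True genotypes for unrelated founders; 0 encodes the null allele."""
    out = np.zeros((n, len(panel), 2), dtype=np.int32)
    for l, spec in enumerate(panel):
        probs = np.array(list(spec.freqs) + [spec.null_freq])
        ladder = np.array(list(spec.allele_lengths) + [0], dtype=np.int32)
        draws = rng.choice(len(ladder), size=(n, 2), p=probs)
        out[:, l, :] = ladder[draws]
    return out


def _observe_genotypes(true: np.ndarray, panel, obs_rng, miscall: float,
                       unscored: float, dropout: float) -> np.ndarray:
    """Apply the error-prone observation layer to true genotypes."""
    obs = true.copy()
    for l, spec in enumerate(panel):
        lengths = np.asarray(spec.allele_lengths, dtype=float)
        vis_freqs = np.asarray(spec.freqs) / sum(spec.freqs)
        col = obs[:, l, :]
        visible = col > 0
        if dropout > 0 and lengths.max() > lengths.min():
            # competitive long-allele dropout: within a visible heterozygote
            # the longer allele amplifies worse, in proportion to the length
            # difference (PCR competition), and may be missed entirely
            both = visible.all(axis=1) & (col[:, 0] != col[:, 1])
            diff = np.abs(col[:, 0] - col[:, 1]) / (lengths.max() - lengths.min())
            dropped = both & (obs_rng.random(len(col)) < dropout * diff)
            longer = col.argmax(axis=1)
            col[dropped, longer[dropped]] = 0
            visible = col > 0
        if miscall > 0:
            hit = visible & (obs_rng.random(col.shape) < miscall)
            if hit.any():
                repl = obs_rng.choice(np.asarray(spec.allele_lengths, dtype=np.int32),
                                      size=int(hit.sum()), p=vis_freqs)
                col[hit] = repl
        # null/dropout masking: one visible copy shows as apparent homozygote
        n_vis = (col > 0).sum(axis=1)
        single = n_vis == 1
        col[single] = col[single].max(axis=1)[:, None]
        none_vis = n_vis == 0
        col[none_vis] = MISSING
        if unscored > 0:
            miss = obs_rng.random(len(col)) < unscored
            col[miss] = MISSING
        obs[:, l, :] = col
    return obs


def base_id(record_id: str) -> str:
    """Underlying fish id of a sample record (strips re-capture aliases)."""
    return str(record_id).split("#")[0]


def true_pop_comparisons(population: Population,
                         samples: pd.DataFrame) -> pd.DataFrame:
    """Oracle comparison table: every candidate adult-juvenile pair with its
    true parent-offspring status from the pedigree (error-free genotyping
    equivalent).  Columns match the genotype-based comparison output."""
    ad = samples[samples.stage == "adult"]
    ju = samples[samples.stage == "juvenile"]
    tp = population.pedigree.pop_pairs()
    a_ids = ad.fish_id.to_numpy()
    j_ids = ju.fish_id.to_numpy()
    ay = ad.capture_year.to_numpy(dtype=int)
    by = ju.birth_year.to_numpy(dtype=int)
    ai, ji = np.nonzero(ay[:, None] > by[None, :])
    pairs = pd.DataFrame({"adult_id": a_ids[ai], "juvenile_id": j_ids[ji]})
    pairs["pop_call"] = [(base_id(a), j) in tp for a, j in
                         zip(pairs.adult_id, pairs.juvenile_id)]
    return pairs


def simulate_fecundity_observations(population: Population,
                                    samples: pd.DataFrame, seed: int,
                                    n: int = 100,
                                    sigma: float = 0.3) -> pd.DataFrame:
    """Daily-output observations on the true female fecundity curve with
    lognormal observation error, at lengths drawn from the sampled females."""
    rng = substream(seed, "observation")
    p = population.config.pop
    ad = samples[samples.stage == "adult"]
    fem = ad[ad.sex == "F"]
    lengths = rng.choice(fem.length.to_numpy(dtype=float),
                         size=min(n, len(fem)) if len(fem) else 0)
    daily = p.female_daily_fecundity(lengths) * np.exp(
        rng.normal(0, sigma, size=len(lengths)))
    return pd.DataFrame({"length": np.round(lengths, 2),
                         "daily_output": daily})


def simulate_founder_panel(panel, n: int, seed: int, miscall: float = 0.0,
                           unscored: float = 0.0, dropout: float = 0.0,
                           id_prefix: str = "F") -> GenotypePanel:
    """Observed genotypes for ``n`` unrelated fish -- for QC power studies
    and unrelated-pair false-positive checks."""
    rng = substream(seed, "genotypes")
    obs_rng = substream(seed, "observation")
    true = _founder_true_genotypes(panel, n, rng)
    obs = _observe_genotypes(true, panel, obs_rng, miscall, unscored, dropout)
    ids = np.array([f"{id_prefix}{i:06d}" for i in range(n)])
    return GenotypePanel(fish_ids=ids, loci=[s.locus_id for s in panel],
                         alleles=obs)
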