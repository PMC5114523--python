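"""Adult population dynamics, growth, selectivity and fecundity.

This module holds the demographic machinery behind pairwise kinship
probabilities for a long-lived, late-maturing fish stock sampled on its
spawning grounds: a two-sex, age-structured adult model with constant total
mortality ``z``, sex-specific von Bertalanffy growth with individual
variation (constant coefficient of variation of length-at-age, Student-t
distributed to accommodate occasional very large fish), logistic
length-based selectivity interpreted as average residence time on the
spawning grounds, and relative annual fecundity as a function of length and
sex.  The per-year, per-sex total reproductive output (TRO) computed here is
the denominator of every parent-offspring-pair probability: the chance that
a given adult is the parent of a given juvenile is that adult's share of the
TRO of its sex in the juvenile's birth year.

Only fecundity *ratios* matter for kinship probabilities, so fecundity is
relative throughout; absolute outputs (biomass, spawning potential) carry
their own clearly-labelled scale conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MIN_ADULT_AGE",
    "SexGrowth",
    "GrowthParams",
    "Logistic",
    "PowerFecundity",
    "TableFecundity",
    "LengthWeight",
    "PopParams",
    "PopState",
    "sex_index",
    "mean_length",
    "length_at_age_density",
    "hindcast_length",
    "selectivity",
    "fecundity",
    "propagate",
]

#: Youngest age treated as adult (youngest successful breeding age observed).
MIN_ADULT_AGE = 8

_SEX_CODES = {"F": 0, "f": 0, 0: 0, "M": 1, "m": 1, 1: 1}


def sex_index(sex) -> int:
    """Map a sex code ('F'/'M' or 0/1) to the internal index (0=female)."""
    try:
        return _SEX_CODES[sex]
    except KeyError:
        raise ValueError(f"unknown sex code: {sex!r}") from None


@dataclass(frozen=True)
class SexGrowth:
    """Mean von Bertalanffy parameters for one sex: L(a) = linf*(1-exp(-k*(a-t0)))."""

    linf_mean: float
    k: float
    t0: float

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("von Bertalanffy k must be positive")
        if self.linf_mean <= 0:
            raise ValueError("linf_mean must be positive")


@dataclass(frozen=True)
class GrowthParams:
    """Growth model: sex-specific mean von Bertalanffy curve, constant-CV
    Student-t length-at-age, and a plus-group age beyond which growth stops.

    ``cv`` applies to the t-distribution *scale* parameter (not its standard
    deviation, which is larger by sqrt(df/(df-2))); this convention is
    documented and configurable via ``df``.
    """

    female: SexGrowth
    male: SexGrowth
    cv: float = 0.08
    df: float = 12.0
    plus_age: int = 25

    def __post_init__(self):
        if self.cv <= 0:
            raise ValueError("length-at-age CV must be positive")
        if self.df <= 2:
            raise ValueError("t degrees of freedom must exceed 2")
        if self.plus_age <= MIN_ADULT_AGE:
            raise ValueError("plus-group age must exceed the minimum adult age")

    def for_sex(self, sex) -> SexGrowth:
        return (self.female, self.male)[sex_index(sex)]


@dataclass(frozen=True)
class Logistic:
    """Logistic curve in length: 1 / (1 + exp(-slope*(L - l50)))."""

    l50: float
    slope: float

    def __call__(self, length):
        from scipy.special import expit
        x = np.asarray(length, dtype=float)
        return expit(self.slope * (x - self.l50))


@dataclass(frozen=True)
class PowerFecundity:
    """Daily reproductive output as a power function of length: alpha*L**beta."""

    alpha: float
    beta: float

    def __call__(self, length):
        return self.alpha * np.asarray(length, dtype=float) ** self.beta


@dataclass(frozen=True)
class TableFecundity:
    """Daily output supplied as a (length, output) table, log-linearly interpolated."""

    lengths: tuple
    outputs: tuple

    def __call__(self, length):
        x = np.asarray(length, dtype=float)
        return np.exp(np.interp(np.log(x), np.log(np.asarray(self.lengths)),
                                np.log(np.asarray(self.outputs))))


@dataclass(frozen=True)
class LengthWeight:
    """Allometric length-weight relation W = c * L**b (kg when L in cm).

    The default coefficients are literature-style placeholders for a large
    tuna; biomass outputs depend on this choice and are labelled accordingly.
    """

    c: float = 1.6e-5
    b: float = 3.0

    def __call__(self, length):
        return self.c * np.asarray(length, dtype=float) ** self.b


@dataclass
class PopParams:
    """All adult population-dynamics parameters.

    Recruitment is parameterized as log-normal about a constant mean:
    R_y = exp(mean_log_recruitment + dev_y) age-8 (both sexes pooled, split
    1:1) recruits in year y, with dev ~ N(0, sigma_r^2) random effects for
    the modelled years and dev = 0 for earlier (equilibrium) cohorts.
    """

    growth: GrowthParams
    z: float
    mean_log_recruitment: float
    years: tuple
    recruitment_devs: dict = field(default_factory=dict)
    sigma_r: float = 0.25
    selectivity_female: Logistic = field(default_factory=lambda: Logistic(155.0, 0.08))
    selectivity_male: Logistic = field(default_factory=lambda: Logistic(155.0, 0.08))
    female_daily_fecundity: PowerFecundity = field(
        default_factory=lambda: PowerFecundity(1e-3, 7.9))
    male_fecundity: Logistic | None = None  # None -> male selectivity curve
    male_fecundity_scale: float = 1.0
    length_weight: LengthWeight = field(default_factory=LengthWeight)
    min_age: int = MIN_ADULT_AGE
    #: terminal (absorbing) age class of the dynamics; None uses the growth
    #: plus-group age.  Carrying the dynamics past the growth plus-group
    #: (growth stays frozen) keeps hindcast lengths of genuinely old fish
    #: correct instead of shrinking them back through the plus-group age.
    max_age: int | None = None
    biomass_min_age: int = 10
    reference_female_age: int = 16

    def __post_init__(self):
        if self.z <= 0:
            raise ValueError("total mortality z must be positive")
        if not np.isfinite(self.mean_log_recruitment):
            raise ValueError("mean_log_recruitment must be finite")
        if self.sigma_r < 0:
            raise ValueError("sigma_r must be nonnegative")
        self.years = tuple(int(y) for y in self.years)

    def selectivity_curve(self, sex) -> Logistic:
        return (self.selectivity_female, self.selectivity_male)[sex_index(sex)]

    def male_fecundity_curve(self) -> Logistic:
        return self.male_fecundity if self.male_fecundity is not None else self.selectivity_male

    def recruitment(self, year: int) -> float:
        dev = self.recruitment_devs.get(int(year), 0.0)
        return float(np.exp(self.mean_log_recruitment + dev))

    @property
    def ages(self) -> np.ndarray:
        top = self.growth.plus_age if self.max_age is None else self.max_age
        return np.arange(self.min_age, top + 1)


def mean_length(age, sex, growth: GrowthParams):
    """Mean length at age for one sex; constant at and beyond the plus-group age."""
    g = growth.for_sex(sex)
    a = np.minimum(np.asarray(age, dtype=float), growth.plus_age)
    return g.linf_mean * (1.0 - np.exp(-g.k * (a - g.t0)))


def length_at_age_density(length, age, sex, growth: GrowthParams):
    """Student-t density of length at a given age and sex.

    Location is the mean von Bertalanffy length; scale is cv*mean (constant
    CV across ages, applied to the t scale parameter).
    """
    mu = mean_length(age, sex, growth)
    return stats.t.pdf(np.asarray(length, dtype=float), growth.df,
                       loc=mu, scale=growth.cv * mu)


def _vb_factor(age, g: SexGrowth, plus_age):
    a = np.minimum(np.asarray(age, dtype=float), plus_age)
    return 1.0 - np.exp(-g.k * (a - g.t0))


def hindcast_length(length_at_capture, age_at_capture, target_age, sex,
                    growth: GrowthParams):
    """Length at an earlier age, assuming an individual von Bertalanffy curve.

    Each fish follows its own curve with an individual asymptotic length but
    the sex-shared k and t0, so the individual's L-infinity is solved from
    the (length, age) observation and the shared curve re-evaluated at
    ``target_age``.  Ages at or above the plus-group age use the plus-group
    length (no growth).
    """
    length_at_capture = np.asarray(length_at_capture, dtype=float)
    if np.any(length_at_capture <= 0):
        raise ValueError("length_at_capture must be positive")
    g = growth.for_sex(sex)
    if np.any(np.asarray(age_at_capture, dtype=float) <= g.t0):
        raise ValueError("age_at_capture must exceed t0")
    num = _vb_factor(target_age, g, growth.plus_age)
    den = _vb_factor(age_at_capture, g, growth.plus_age)
    return length_at_capture * num / den


def selectivity(length, sex, params: PopParams):
    """Probability of inclusion in the spawning-ground catch at a given length.

    Also interpreted as relative average residence duration on the spawning
    grounds (normalized so the asymptote is 1; only ratios matter downstream).
    """
    return params.selectivity_curve(sex)(length)


def fecundity(length, sex, params: PopParams):
    """Relative annual reproductive output at length for one sex.

    Females: residence duration (the selectivity curve) times daily output
    (by default a power function of length).  Males: a separate logistic
    curve times a free scale (weakly identified in practice).  Output is
    relative -- only ratios enter kinship probabilities.
    """
    length = np.asarray(length, dtype=float)
    if sex_index(sex) == 0:
        return params.selectivity_female(length) * params.female_daily_fecundity(length)
    return params.male_fecundity_scale * params.male_fecundity_curve()(length)


# piecewise Gauss-Legendre quadrature on the standardized-t axis, with the
# t density folded into the weights; the wide outer panels capture the heavy
# upper tail that power-law fecundities weight strongly
_T_PANELS = ((-8, -3, 8), (-3, 3, 24), (3, 8, 10), (8, 20, 10), (20, 60, 12))
_t_quad_cache: dict = {}


def _t_quadrature(df):
    key = float(df)
    if key not in _t_quad_cache:
        ts, ws = [], []
        for a, b, n in _T_PANELS:
            x, w = np.polynomial.legendre.leggauss(n)
            t = 0.5 * (b - a) * x + 0.5 * (a + b)
            ts.append(t)
            ws.append(0.5 * (b - a) * w * stats.t.pdf(t, df))
        t = np.concatenate(ts)
        w = np.concatenate(ws)
        _t_quad_cache[key] = (t, w / w.sum())
    return _t_quad_cache[key]


@dataclass
class PopState:
    """Expected numbers-at-age/sex/year and derived reproductive summaries.

    ``numbers`` has shape (n_ages, 2, n_years): ages min_age..plus_age
    (plus-group last), sexes (female, male), calendar years.  ``tro`` is the
    total reproductive output by sex and year -- the kinship-probability
    denominator.  ``mean_fecundity`` is E[fec | age, sex] over the
    length-at-age distribution.
    """

    params: PopParams
    ages: np.ndarray
    years: np.ndarray
    numbers: np.ndarray
    mean_fecundity: np.ndarray  # (n_ages, 2)
    tro: np.ndarray             # (2, n_years)

    def year_idx(self, year) -> int:
        idx = int(year) - int(self.years[0])
        if idx < 0 or idx >= len(self.years):
            raise KeyError(f"year {year} outside model range {self.years[0]}..{self.years[-1]}")
        return idx

    def age_idx(self, age) -> int:
        a = min(int(age), int(self.ages[-1]))
        if a < self.ages[0]:
            raise KeyError(f"age {age} below the minimum adult age {self.ages[0]}")
        return a - int(self.ages[0])

    def total_adults(self, year=None) -> float | np.ndarray:
        if year is None:
            return self.numbers.sum(axis=(0, 1))
        return float(self.numbers[:, :, self.year_idx(year)].sum())

    def _mean_over_length(self, fn, sex):
        """E[fn(L) | age, sex] over the t length-at-age law, per age."""
        g = self.params.growth
        tq, w = _t_quadrature(g.df)
        mu = mean_length(self.ages, sex, g)
        lengths = mu[:, None] * (1.0 + g.cv * tq[None, :])
        lengths = np.maximum(lengths, 1e-6)
        return fn(lengths) @ w

    def biomass(self, min_age=None) -> np.ndarray:
        """Adult biomass time series (default ages biomass_min_age and older).

        Depends on the configured length-weight relation.
        """
        p = self.params
        if min_age is None:
            min_age = p.biomass_min_age
        sel_ages = self.ages >= min_age
        out = np.zeros(len(self.years))
        for s in (0, 1):
            mean_w = self._mean_over_length(p.length_weight, s)
            out += (self.numbers[sel_ages, s, :] * mean_w[sel_ages, None]).sum(axis=0)
        return out

    def spawning_potential(self) -> np.ndarray:
        """Female reproductive output in units of equivalent reference-age females.

        Female TRO divided by the expected fecundity of one reference-age
        (default 16) female; invariant to rescaling of the fecundity curve.
        """
        p = self.params
        ref = self.mean_fecundity[self.age_idx(p.reference_female_age), 0]
        return self.tro[0] / ref


def propagate(params: PopParams) -> PopState:
    """Fill expected numbers-at-age/sex/year from recruitment and survival.

    Cohorts enter at the minimum adult age, survive at exp(-z) per year, and
    accumulate in the plus group.  The first modelled year starts at the
    deterministic equilibrium implied by the mean recruitment (earlier
    cohorts carry no random-effect deviations).  Also computes per-age mean
    fecundities and the per-sex, per-year total reproductive output.
    """
    ages = params.ages
    years = np.asarray(params.years, dtype=int)
    n_age, n_year = len(ages), len(years)
    surv = np.exp(-params.z)
    numbers = np.zeros((n_age, 2, n_year))

    rbar = float(np.exp(params.mean_log_recruitment))
    # equilibrium start: age a entered (a - min_age) years before years[0]
    k = ages - params.min_age
    eq = 0.5 * rbar * surv ** k
    eq[-1] = 0.5 * rbar * surv ** k[-1] / (1.0 - surv)  # plus-group absorbs elders
    numbers[:, 0, 0] = numbers[:, 1, 0] = eq
    numbers[0, :, 0] = 0.5 * params.recruitment(years[0])

    for t in range(1, n_year):
        numbers[1:, :, t] = numbers[:-1, :, t - 1] * surv
        numbers[-1, :, t] += numbers[-1, :, t - 1] * surv
        numbers[0, :, t] = 0.5 * params.recruitment(years[t])

    state = PopState(params=params, ages=ages, years=years, numbers=numbers,
                     mean_fecundity=np.zeros((n_age, 2)), tro=np.zeros((2, n_year)))
    for s in (0, 1):
        state.mean_fecundity[:, s] = state._mean_over_length(
            lambda L, s=s: fecundity(L, s, params), s)
    state.tro = np.einsum("asy,as->sy", numbers, state.mean_fecundity)
    return state


def equilibrium_adults_per_recruit(z: float, min_age: int = MIN_ADULT_AGE,
                                   plus_age: int = 25) -> float:
    """Equilibrium adult numbers per unit annual recruitment (geometric series)."""
    s = np.exp(-z)
    k = plus_age - min_age
    return float((1.0 - s ** k) / (1.0 - s) + s ** k / (1.0 - s))


def fecundity_exponent_for_perkg_ratio(growth: GrowthParams,
                                       sel: Logistic,
                                       lw: LengthWeight,
                                       ratio: float,
                                       age_hi: int = 15,
                                       age_lo: int = 10) -> float:
    """Solve the female daily-output power exponent giving a target per-kg ratio.

    The per-kg annual output of an average female of age a is
    sel(L_a) * L_a**beta / (c * L_a**b); the exponent beta is solved so that
    the age_hi : age_lo ratio equals ``ratio``.
    """
    l_hi = float(mean_length(age_hi, "F", growth))
    l_lo = float(mean_length(age_lo, "F", growth))
    sel_ratio = float(sel(l_hi) / sel(l_lo))
    return lw.b + (np.log(ratio) - np.log(sel_ratio)) / np.log(l_hi / l_lo)


def perkg_ratio(params: PopParams, age_hi: int = 15, age_lo: int = 10) -> float:
    """Reproductive output per kg bodyweight of an average female of age_hi
    relative to an average female of age_lo."""
    g = params.growth
    l_hi = float(mean_length(age_hi, "F", g))
    l_lo = float(mean_length(age_lo, "F", g))
    num = float(fecundity(l_hi, "F", params)) / float(params.length_weight(l_hi))
    den = float(fecundity(l_lo, "F", params)) / float(params.length_weight(l_lo))
    return num / den
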