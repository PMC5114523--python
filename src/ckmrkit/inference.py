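"""Close-kin mark-recapture likelihood and parameter estimation.

The estimation model combines four independent log-likelihood components:
length/sex composition of the adult samples, otolith ages conditional on
length and sex, daily-fecundity observations, and the genetic component --
a sum of Bernoulli log-likelihoods over all retained pairwise
parent-offspring comparisons.  The probability that a sampled adult is a
parent of a juvenile born in year c is the adult's share of the total
reproductive output (TRO) of its sex in year c, with the adult's length
hindcast to year c along its individual growth curve and its age, when not
otolith-read, integrated over the model's age-given-length posterior.

Comparisons are binned by covariate category (length bin x sex x capture
year x age x cohort); within a category every pair shares the same
parentage probability, so the binned likelihood equals the exact pairwise
likelihood in the limit of zero-width bins and is orders of magnitude
faster to evaluate.

Parameters are estimated in an Empirical-Bayes random-effects paradigm:
the recruitment-deviation variance is estimated by maximizing a Laplace
approximation to the marginal likelihood, all other parameters by
penalized maximum likelihood conditional on it, with standard errors from
the inverse penalized Hessian (central finite differences).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import popdyn
from .popdyn import (Logistic, PopParams, PopState, PowerFecundity, fecundity,
                     hindcast_length, propagate, sex_index)

__all__ = [
    "lincoln_petersen",
    "design_sample_size",
    "DesignResult",
    "pop_probability",
    "BinConfig",
    "BinnedComparisons",
    "bin_comparisons",
    "loglik_genetic",
    "loglik_lengthsex",
    "loglik_age_given_ls",
    "loglik_fecundity",
    "CKMRData",
    "FitConfig",
    "CKMRModel",
    "FitResult",
    "fit",
]


# ---------------------------------------------------------------------------
# simple estimators and design calculations

def lincoln_petersen(m_j: float, m_a: float, p: float) -> float:
    """Kin-pair analogue of the Lincoln-Petersen abundance estimate.

    Each juvenile marks its two parents, so with m_j juveniles and m_a
    adults sampled and P parent-offspring pairs found among all pairwise
    comparisons, adult abundance is estimated as 2 * m_j * m_a / P.
    """
    if p <= 0:
        raise ValueError("no parent-offspring pairs found: the simple "
                         "estimator is undefined; use the full pairwise "
                         "likelihood model instead")
    return 2.0 * m_j * m_a / p


@dataclass
class DesignResult:
    """Sample sizes required to hit a target kin-pair count or precision."""

    n_target: float
    expected_pops: float
    sample_size: float  # per group, with m_J = m_A = m
    target_cv: float | None = None

    def scaling_curve(self, n_values) -> pd.DataFrame:
        n = np.asarray(n_values, dtype=float)
        return pd.DataFrame({"abundance": n,
                             "sample_size": np.sqrt(self.expected_pops * n / 2.0)})


def design_sample_size(n_target: float, target_pop_count: float | None = None,
                       target_cv: float | None = None) -> DesignResult:
    """Required sample size for a target POP count or abundance CV.

    Inverts E[P] = 2 m^2 / N for equal adult and juvenile sample sizes m,
    so m = sqrt(E[P] * N / 2): required effort scales with the square root
    of abundance.  A target CV is converted through the kin-count
    information floor CV ~ 1/sqrt(E[P]).
    """
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    if (target_pop_count is None) == (target_cv is None):
        raise ValueError("give exactly one of target_pop_count / target_cv")
    if target_cv is not None:
        expected = 1.0 / target_cv ** 2
    else:
        expected = float(target_pop_count)
    m = np.sqrt(expected * n_target / 2.0)
    return DesignResult(n_target=float(n_target), expected_pops=float(expected),
                        sample_size=float(m), target_cv=target_cv)


def min_abundance_cv(n_pops: float) -> float:
    """Information floor on the CV of an abundance estimate given a POP count."""
    return 1.0 / np.sqrt(n_pops)


# ---------------------------------------------------------------------------
# the pairwise parent-offspring probability

def pop_probability(adult, cohort_year: int, params: PopParams,
                    state: PopState, tro: float | None = None) -> float:
    """Probability that one sampled adult is a parent of a juvenile from a cohort.

    ``adult`` is a mapping/Series with capture_year, length, sex and
    (optionally) age.  The probability is the adult's expected fecundity at
    the cohort year -- hindcasting its length along its individual growth
    curve, and integrating over its unknown age when no otolith age is
    present -- divided by the total reproductive output of its sex in that
    year.  An adult that cannot have reached the minimum breeding age in
    the cohort year has probability zero.  ``tro`` optionally overrides the
    model TRO denominator (used by census-level normalization checks).
    """
    cap = int(adult["capture_year"])
    if cap <= cohort_year:
        raise ValueError("adult must be caught strictly after the cohort year")
    s = sex_index(adult["sex"])
    length = float(adult["length"])
    g = params.growth
    delta = cap - cohort_year
    ages = np.asarray(state.ages)
    denom = state.tro[s, state.year_idx(cohort_year)] if tro is None else tro

    age = adult.get("age") if hasattr(adult, "get") else adult["age"]
    if age is not None and not (isinstance(age, float) and np.isnan(age)):
        a_cap = min(int(age), g.plus_age)
        a_coh = int(age) - delta
        if a_coh < params.min_age:
            return 0.0
        lh = hindcast_length(length, a_cap, min(a_coh, g.plus_age), s, g)
        return float(fecundity(lh, s, params)) / denom

    # unknown age: posterior over age given length, sex and capture year
    yi = state.year_idx(cap)
    w = state.numbers[:, s, yi] * popdyn.length_at_age_density(length, ages, s, g)
    a_coh = ages - delta
    valid = a_coh >= params.min_age
    if w.sum() <= 0 or not valid.any():
        return 0.0
    w = w / w.sum()
    lh = hindcast_length(length, ages[valid], np.minimum(a_coh[valid], g.plus_age), s, g)
    fec = fecundity(lh, s, params)
    return float(np.sum(w[valid] * fec)) / denom


# ---------------------------------------------------------------------------
# binning

@dataclass(frozen=True)
class BinConfig:
    """Covariate binning for the genetic likelihood.

    ``length_bin_width`` of zero keeps exact lengths (one category per
    distinct covariate combination), under which the binned likelihood
    equals the pairwise likelihood exactly.
    """

    length_bin_width: float = 1.0


@dataclass
class BinnedComparisons:
    """Comparison and POP counts by covariate category.

    ``df`` columns: length (bin representative), sex, capture_year, age
    (NaN when unknown), cohort, n (comparisons), k (POPs).
    """

    df: pd.DataFrame
    bin_width: float

    @property
    def n_total(self) -> int:
        return int(self.df.n.sum())

    @property
    def k_total(self) -> int:
        return int(self.df.k.sum())


def bin_comparisons(comparisons, samples: pd.DataFrame,
                    config: BinConfig = BinConfig()) -> BinnedComparisons:
    """Group retained comparisons into covariate categories.

    Within a category all pairs share the same parentage probability under
    the model, so only (n, k) per category is needed.
    """
    ret = comparisons.retained if hasattr(comparisons, "retained") else comparisons
    ret = ret[["adult_id", "juvenile_id", "pop_call"]].copy()
    meta = samples.set_index("fish_id")
    ad = meta.loc[ret.adult_id, ["capture_year", "length", "sex", "age"]]
    ret["capture_year"] = ad["capture_year"].to_numpy(dtype=int)
    ret["length"] = ad["length"].to_numpy(dtype=float)
    ret["sex"] = ad["sex"].to_numpy()
    age = ad["age"].to_numpy(dtype=object)
    ret["age"] = np.array([np.nan if pd.isna(a) else float(a) for a in age])
    ret["cohort"] = meta.loc[ret.juvenile_id, "birth_year"].to_numpy(dtype=int)
    w = config.length_bin_width
    if w > 0:
        ret["length_bin"] = np.floor(ret["length"] / w).astype(int)
    else:
        ret["length_bin"] = ret["length"]
    grouped = (ret.groupby(["length_bin", "sex", "capture_year", "age", "cohort"],
                           dropna=False)
               .agg(length=("length", "mean"),  # category representative
                    n=("pop_call", "size"), k=("pop_call", "sum"))
               .reset_index()
               .drop(columns="length_bin"))
    grouped["k"] = grouped["k"].astype(int)
    return BinnedComparisons(df=grouped, bin_width=w)


# ---------------------------------------------------------------------------
# likelihood components (standalone functional forms)

def loglik_genetic(p: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    """Bernoulli log-likelihood over comparison categories.

    Sum of k*log(P) + (n-k)*log(1-P); a category with P = 0 but k > 0 is a
    data/model conflict and yields -inf.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any((p <= 0) & (k > 0)):
        return -np.inf
    p = np.clip(p, 0.0, 1.0 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(k > 0, k * np.log(np.maximum(p, 1e-300)), 0.0)
    return float(np.sum(term + (n - k) * np.log1p(-p)))


def loglik_lengthsex(counts: np.ndarray, predicted: np.ndarray,
                     ess_factor: float = 1.0) -> float:
    """Multinomial log-likelihood of length-sex composition counts.

    ``counts`` and ``predicted`` are (n_bins, 2, n_years); predictions are
    normalized per year over bins and sexes.  ``ess_factor`` downweights
    the counts to an effective sample size, absorbing interannual
    overdispersion.
    """
    counts = np.asarray(counts, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    tot = pred.sum(axis=(0, 1), keepdims=True)
    ll = 0.0
    for y in range(counts.shape[2]):
        cy = counts[:, :, y]
        if cy.sum() == 0:
            continue
        py = pred[:, :, y] / tot[0, 0, y]
        ll += float(np.sum(cy * np.log(np.maximum(py, 1e-300))))
    return ess_factor * ll


def loglik_fecundity(lengths, outputs, alpha: float, beta: float,
                     sigma: float) -> float:
    """Lognormal log-likelihood of daily-output observations about alpha*L**beta."""
    lengths = np.asarray(lengths, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if np.any(outputs <= 0):
        raise ValueError("daily outputs must be positive")
    resid = np.log(outputs) - (np.log(alpha) + beta * np.log(lengths))
    return float(np.sum(stats.norm.logpdf(resid, scale=sigma)))


# ---------------------------------------------------------------------------
# data container and model

@dataclass
class CKMRData:
    """Everything the likelihood needs: samples, binned comparisons,
    daily-fecundity observations."""

    samples: pd.DataFrame
    binned: BinnedComparisons
    fecundity_obs: pd.DataFrame | None = None

    @property
    def adults(self) -> pd.DataFrame:
        return self.samples[self.samples.stage == "adult"]

    @property
    def juveniles(self) -> pd.DataFrame:
        return self.samples[self.samples.stage == "juvenile"]


#: default free parameters (shared-selectivity configuration)
_DEFAULT_FREE = ("mean_log_recruitment", "log_z", "sel_l50", "log_sel_slope",
                 "log_fec_beta", "log_fec_alpha", "log_fec_sigma")


@dataclass
class FitConfig:
    """Estimation settings.

    ``ess_factor`` multiplies composition sample sizes (default 0.1,
    absorbing interannual overdispersion in real data; set to 1.0 for
    simulator output, which is genuinely multinomial).  ``share_selectivity``
    ties the male curves to the female ones.  ``estimate_sigma_r`` turns the
    Laplace estimation of the recruitment-deviation s.d. on or off.
    """

    free: tuple = _DEFAULT_FREE
    share_selectivity: bool = True
    estimate_sigma_r: bool = True
    sigma_r_bounds: tuple = (0.05, 1.0)
    sigma_r_fixed: float = 0.25
    ess_factor: float = 0.1
    fec_sigma_init: float = 0.3
    comp_bin_width: float = 5.0
    hessian_step: float = 1e-4
    maxiter: int = 400
    recruitment_trend: bool = False  # model variant, off by default


@dataclass
class FitResult:
    """Penalized-ML estimates, uncertainties and derived series."""

    params: pd.DataFrame           # name, estimate, se (transformed scale)
    pop_params: PopParams
    state: PopState
    sigma_r: float
    loglik: float
    components: dict
    derived: pd.DataFrame          # quantity, year, estimate, lo90, hi90, se
    cov: np.ndarray | None
    converged: bool
    message: str
    n_pops: int

    def derived_value(self, quantity: str, year=None) -> pd.Series:
        d = self.derived
        sel = d.quantity == quantity
        if year is not None:
            sel &= d.year == year
        else:
            sel &= d.year.isna()
        rows = d[sel]
        if len(rows) != 1:
            raise KeyError(f"no unique derived quantity {quantity!r} year={year}")
        return rows.iloc[0]


class CKMRModel:
    """Precomputed likelihood machinery over binned comparisons and
    composition data, with growth parameters held fixed.

    Growth (mean curves, CV, t degrees of freedom) is treated as known from
    external studies, which lets the age-given-length densities and
    hindcast-length ratios be precomputed once; every likelihood evaluation
    is then a handful of dense array operations.
    """

    def __init__(self, data: CKMRData, base_params: PopParams,
                 config: FitConfig = None):
        self.data = data
        self.base = base_params
        self.config = config or FitConfig()
        self.years = np.asarray(base_params.years, dtype=int)
        self.ages = base_params.ages
        self._precompute_genetic()
        self._precompute_composition()
        self._precompute_ages()
        self._precompute_fecundity()
        self.dev_names = [f"dev_{y}" for y in self.years]
        self.free_names = list(self.config.free) + self.dev_names
        # the abundance headline averages over the juvenile cohort years --
        # the years the kinship data actually inform
        self.cohort_years = sorted(set(int(c) for c in data.binned.df.cohort))

    # -- precomputations -------------------------------------------------
    def _precompute_genetic(self):
        df = self.data.binned.df
        g = self.base.growth
        n_cat = len(df)
        self.g_n = df.n.to_numpy(dtype=float)
        self.g_k = df.k.to_numpy(dtype=float)
        self.g_sex = np.array([sex_index(s) for s in df.sex])
        self.g_year = df.capture_year.to_numpy(dtype=int)
        self.g_cohort = df.cohort.to_numpy(dtype=int)
        self.g_yidx = self.g_year - self.years[0]
        self.g_cidx = self.g_cohort - self.years[0]
        lengths = df.length.to_numpy(dtype=float)
        ages = self.ages
        n_age = len(ages)
        delta = self.g_year - self.g_cohort
        a_coh = ages[None, :] - delta[:, None]
        self.g_valid = a_coh >= self.base.min_age

        # hindcast length for each (category, age-at-capture) combination
        self.g_lh = np.zeros((n_cat, n_age))
        self.g_fla = np.zeros((n_cat, n_age))
        age_known = df.age.to_numpy(dtype=float)
        for s in (0, 1):
            rows = self.g_sex == s
            if not rows.any():
                continue
            gr = g.for_sex(s)
            num = popdyn._vb_factor(np.clip(a_coh[rows], None, g.plus_age), gr, g.plus_age)
            den = popdyn._vb_factor(ages, gr, g.plus_age)[None, :]
            self.g_lh[rows] = lengths[rows, None] * num / den
            self.g_fla[rows] = popdyn.length_at_age_density(
                lengths[rows, None], ages[None, :], s, g)
        known = ~np.isnan(age_known)
        if known.any():
            onehot = np.zeros((known.sum(), n_age))
            kidx = np.clip(age_known[known].astype(int), self.base.min_age,
                           int(self.ages[-1])) - self.base.min_age
            onehot[np.arange(len(kidx)), kidx] = 1.0
            self.g_fla[known] = onehot
        self.g_lh = np.maximum(self.g_lh, 1e-6)

    def _precompute_composition(self):
        ad = self.data.adults
        g = self.base.growth
        w = self.config.comp_bin_width
        lengths = ad.length.to_numpy(dtype=float)
        lo = np.floor(lengths.min() / w) * w - 2 * w
        hi = np.ceil(lengths.max() / w) * w + 2 * w
        edges = np.arange(lo, hi + w, w)
        centers = 0.5 * (edges[:-1] + edges[1:])
        self.c_centers = centers
        n_bins = len(centers)
        counts = np.zeros((n_bins, 2, len(self.years)))
        sexi = np.array([sex_index(s) for s in ad.sex])
        yidx = ad.capture_year.to_numpy(dtype=int) - self.years[0]
        bidx = np.clip(np.digitize(lengths, edges) - 1, 0, n_bins - 1)
        np.add.at(counts, (bidx, sexi, yidx), 1.0)
        self.c_counts = counts
        # bin probabilities by 3-point Gauss-Legendre inside each bin:
        # nodes shared between the density (precomputed) and the
        # selectivity curve (evaluated per iteration)
        xg, wg = np.polynomial.legendre.leggauss(3)
        nodes = centers[:, None] + 0.5 * w * xg[None, :]      # (n_bins, 3)
        self.c_nodes = nodes.ravel()
        self.c_quad_w = np.tile(0.5 * w * wg, n_bins)
        self.c_bin_of_node = np.repeat(np.arange(n_bins), 3)
        self.c_density = np.zeros((n_bins * 3, len(self.ages), 2))
        for s in (0, 1):
            self.c_density[:, :, s] = popdyn.length_at_age_density(
                self.c_nodes[:, None], self.ages[None, :], s, g) \
                * self.c_quad_w[:, None]

    def _precompute_ages(self):
        ad = self.data.adults
        aged = ad[ad.age.notna()]
        g = self.base.growth
        self.a_sex = np.array([sex_index(s) for s in aged.sex])
        self.a_yidx = aged.capture_year.to_numpy(dtype=int) - self.years[0]
        a = np.clip(aged.age.to_numpy(dtype=float).astype(int),
                    self.base.min_age, int(self.ages[-1]))
        self.a_aidx = a - self.base.min_age
        lengths = aged.length.to_numpy(dtype=float)
        self.a_f = np.zeros((len(aged), len(self.ages)))
        for s in (0, 1):
            rows = self.a_sex == s
            if rows.any():
                self.a_f[rows] = popdyn.length_at_age_density(
                    lengths[rows, None], self.ages[None, :], s, g)

    def _precompute_fecundity(self):
        obs = self.data.fecundity_obs
        if obs is None or len(obs) == 0:
            self.f_loglen = None
            return
        if np.any(obs.daily_output.to_numpy(dtype=float) <= 0):
            raise ValueError("daily-output observations must be positive")
        self.f_loglen = np.log(obs.length.to_numpy(dtype=float))
        self.f_logout = np.log(obs.daily_output.to_numpy(dtype=float))

    # -- parameter vector mapping ----------------------------------------
    def initial_x(self) -> np.ndarray:
        """Data-driven starting values: a Lincoln-Petersen abundance for
        recruitment, log-log regression for the fecundity curve, and the
        sample median for the selectivity midpoint."""
        b = self.base
        n_a = len(self.data.adults)
        n_j = len(self.data.juveniles)
        k_tot = max(self.data.binned.k_total, 1)
        n_hat = lincoln_petersen(n_j, n_a, k_tot)
        z0 = 0.25
        rbar0 = n_hat / popdyn.equilibrium_adults_per_recruit(
            z0, b.min_age, b.growth.plus_age)
        vals = {
            "mean_log_recruitment": np.log(rbar0),
            "log_z": np.log(z0),
            "sel_l50": float(np.median(self.data.adults.length)),
            "log_sel_slope": np.log(0.1),
            "sel_l50_male": float(np.median(self.data.adults.length)),
            "log_sel_slope_male": np.log(0.1),
            "log_fec_beta": np.log(5.0),
            "log_fec_alpha": -5.0 * np.log(160.0),
            "log_fec_sigma": np.log(self.config.fec_sigma_init),
        }
        if self.f_loglen is not None and len(self.f_loglen) >= 3:
            A = np.column_stack([np.ones_like(self.f_loglen), self.f_loglen])
            coef, *_ = np.linalg.lstsq(A, self.f_logout, rcond=None)
            if coef[1] > 0.1:
                vals["log_fec_beta"] = np.log(coef[1])
                vals["log_fec_alpha"] = coef[0]
                resid = self.f_logout - A @ coef
                vals["log_fec_sigma"] = np.log(max(resid.std(), 0.02))
        x = [vals.get(name, 0.0) for name in self.config.free]
        return np.array(x + [0.0] * len(self.dev_names))

    def params_from_x(self, x: np.ndarray, sigma_r: float) -> PopParams:
        v = dict(zip(self.config.free, x[: len(self.config.free)]))
        devs = dict(zip((int(y) for y in self.years),
                        x[len(self.config.free):]))
        b = self.base
        sel_f = Logistic(v.get("sel_l50", b.selectivity_female.l50),
                         np.exp(v["log_sel_slope"]) if "log_sel_slope" in v
                         else b.selectivity_female.slope)
        if self.config.share_selectivity:
            sel_m = sel_f
        else:
            sel_m = Logistic(v.get("sel_l50_male", b.selectivity_male.l50),
                             np.exp(v["log_sel_slope_male"])
                             if "log_sel_slope_male" in v else b.selectivity_male.slope)
        fec = PowerFecundity(
            np.exp(v["log_fec_alpha"]) if "log_fec_alpha" in v
            else b.female_daily_fecundity.alpha,
            np.exp(v["log_fec_beta"]) if "log_fec_beta" in v
            else b.female_daily_fecundity.beta)
        return replace(
            b,
            z=float(np.exp(v["log_z"])) if "log_z" in v else b.z,
            mean_log_recruitment=float(v.get("mean_log_recruitment",
                                             b.mean_log_recruitment)),
            recruitment_devs=devs, sigma_r=float(sigma_r),
            selectivity_female=sel_f, selectivity_male=sel_m,
            female_daily_fecundity=fec, male_fecundity=None if
            self.config.share_selectivity else b.male_fecundity)

    # -- likelihood ------------------------------------------------------
    def component_logliks(self, params: PopParams, x: np.ndarray) -> dict:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._component_logliks(params, x)

    def _component_logliks(self, params: PopParams, x: np.ndarray) -> dict:
        state = propagate(params)
        N = state.numbers  # (n_age, 2, n_year)

        # genetic component
        Ncat = N[:, self.g_sex, self.g_yidx].T          # (n_cat, n_age)
        w = self.g_fla * Ncat
        wsum = w.sum(axis=1)
        fec = np.empty_like(self.g_lh)
        fem = self.g_sex == 0
        if fem.any():
            fec[fem] = fecundity(self.g_lh[fem], 0, params)
        if (~fem).any():
            fec[~fem] = fecundity(self.g_lh[~fem], 1, params)
        num = np.sum(w * fec * self.g_valid, axis=1)
        tro_cat = state.tro[self.g_sex, self.g_cidx]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(wsum > 0, num / np.maximum(wsum, 1e-300), 0.0) / tro_cat
        ll_g = loglik_genetic(p, self.g_n, self.g_k)

        # length-sex composition
        sel = np.stack([params.selectivity_female(self.c_nodes),
                        params.selectivity_male(self.c_nodes)], axis=1)
        pred_nodes = np.einsum("bas,asy->bsy", self.c_density, N) * sel[:, :, None]
        pred = np.zeros((len(self.c_centers),) + pred_nodes.shape[1:])
        np.add.at(pred, self.c_bin_of_node, pred_nodes)
        ll_ls = loglik_lengthsex(self.c_counts, pred, self.config.ess_factor)

        # age given length and sex
        if len(self.a_f):
            wa = self.a_f * N[:, self.a_sex, self.a_yidx].T
            pa = wa[np.arange(len(wa)), self.a_aidx] / wa.sum(axis=1)
            ll_a = float(np.sum(np.log(np.maximum(pa, 1e-300))))
        else:
            ll_a = 0.0

        # daily fecundity observations (lognormal errors)
        if self.f_loglen is not None:
            v = dict(zip(self.config.free, x[: len(self.config.free)]))
            sigma = np.exp(v.get("log_fec_sigma", np.log(0.3)))
            resid = self.f_logout - (np.log(params.female_daily_fecundity.alpha)
                                     + params.female_daily_fecundity.beta
                                     * self.f_loglen)
            nf = len(resid)
            ll_f = float(-0.5 * np.sum(resid ** 2) / sigma ** 2
                         - nf * np.log(sigma) - 0.5 * nf * np.log(2 * np.pi))
        else:
            ll_f = 0.0
        return {"genetic": ll_g, "lengthsex": ll_ls, "age_given_ls": ll_a,
                "fecundity": ll_f, "state": state}

    def penalized_loglik(self, x: np.ndarray, sigma_r: float) -> float:
        params = self.params_from_x(x, sigma_r)
        comp = self.component_logliks(params, x)
        ll = (comp["genetic"] + comp["lengthsex"] + comp["age_given_ls"]
              + comp["fecundity"])
        devs = x[len(self.config.free):]
        pen = (-0.5 * np.sum(devs ** 2) / sigma_r ** 2
               - len(devs) * np.log(sigma_r)
               - 0.5 * len(devs) * np.log(2 * np.pi))
        total = ll + pen
        return total if np.isfinite(total) else -1e12

    # -- optimization ----------------------------------------------------
    def _maximize(self, sigma_r: float, x0: np.ndarray, maxiter=None):
        res = optimize.minimize(
            lambda x: -self.penalized_loglik(x, sigma_r), x0,
            method="L-BFGS-B",
            options={"maxiter": maxiter or self.config.maxiter,
                     "maxcor": 25, "ftol": 5e-10, "gtol": 1e-5})
        return res

    def _maximize_devs(self, sigma_r: float, x0: np.ndarray, maxiter=60):
        """Refit the recruitment deviations only (structural parameters
        frozen) -- the cheap inner step of the variance search."""
        n_fix = len(self.config.free)
        x = x0.copy()

        def nll(u):
            x[n_fix:] = u
            return -self.penalized_loglik(x, sigma_r)

        res = optimize.minimize(nll, x0[n_fix:], method="L-BFGS-B",
                                options={"maxiter": maxiter, "ftol": 5e-10})
        x[n_fix:] = res.x
        return -res.fun, x

    def _dev_hessian_logdet(self, x: np.ndarray, sigma_r: float) -> float:
        """log det of the negative Hessian over recruitment deviations."""
        n_fix = len(self.config.free)
        idx = np.arange(n_fix, len(x))
        H = _fd_hessian(lambda z: -self.penalized_loglik(z, sigma_r), x,
                        self.config.hessian_step, idx)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return np.inf
        return float(logdet)

    def laplace_marginal(self, sigma_r: float, x0: np.ndarray, maxiter=None):
        """Laplace-approximated marginal log-likelihood at one sigma_r."""
        res = self._maximize(sigma_r, x0, maxiter=maxiter)
        n_dev = len(self.dev_names)
        logdet = self._dev_hessian_logdet(res.x, sigma_r)
        marg = (-res.fun) + 0.5 * n_dev * np.log(2 * np.pi) - 0.5 * logdet
        return marg, res

    def fit(self) -> FitResult:
        cfg = self.config
        x0 = self.initial_x()
        ks_info = None
        if cfg.estimate_sigma_r:
            # one full fit at a reference variance, then profile the
            # marginal over the deviations only: the data curvature over
            # deviations barely moves with sigma_r, so its eigenvalues give
            # the log-determinant at any sigma_r for free
            sigma_ref = cfg.sigma_r_fixed
            base = self._maximize(sigma_ref, x0)
            x_base = base.x
            n_fix = len(self.config.free)
            n_dev = len(self.dev_names)
            H_pen = _fd_hessian(lambda z: -self.penalized_loglik(z, sigma_ref),
                                x_base, cfg.hessian_step,
                                np.arange(n_fix, len(x_base)))
            lam = np.linalg.eigvalsh(H_pen - np.eye(n_dev) / sigma_ref ** 2)
            lam = np.maximum(lam, 1e-10)
            cache = {"x": x_base}

            def neg_marginal(log_sigma):
                s = float(np.exp(log_sigma))
                pen, x_new = self._maximize_devs(s, cache["x"])
                cache["x"] = x_new
                logdet = float(np.sum(np.log(lam + np.exp(-2 * log_sigma))))
                return -(pen + 0.5 * n_dev * np.log(2 * np.pi) - 0.5 * logdet)

            lo, hi = (np.log(cfg.sigma_r_bounds[0]),
                      np.log(cfg.sigma_r_bounds[1]))
            opt = optimize.minimize_scalar(
                neg_marginal, bounds=(lo, hi),
                method="bounded", options={"xatol": 0.1, "maxiter": 12})
            sigma_r = float(np.exp(opt.x))
            x0 = cache["x"]
            # Kass-Steffey ingredients: curvature of the marginal in
            # log sigma_r, and the sensitivity of the penalized optimum to
            # it, evaluated away from the search bounds
            h = 0.3
            if lo + h < opt.x < hi - h:
                m0 = -neg_marginal(opt.x)
                mp = -neg_marginal(opt.x + h)
                mm = -neg_marginal(opt.x - h)
                curv = -(mp - 2 * m0 + mm) / h ** 2
                if curv > 0:
                    rp = self._maximize(float(np.exp(opt.x + h)), x0, maxiter=40)
                    rm = self._maximize(float(np.exp(opt.x - h)), x0, maxiter=40)
                    ks_info = ((rp.x - rm.x) / (2 * h), 1.0 / curv)
        else:
            sigma_r = cfg.sigma_r_fixed
        res = self._maximize(sigma_r, x0)
        x_hat = res.x
        params = self.params_from_x(x_hat, sigma_r)
        comp = self.component_logliks(params, x_hat)
        state = comp.pop("state")

        H = _fd_hessian(lambda z: -self.penalized_loglik(z, sigma_r), x_hat,
                        cfg.hessian_step)
        cov, se, message = None, np.full(len(x_hat), np.nan), ""
        try:
            cov = np.linalg.inv(H)
            if ks_info is not None:
                # Kass-Steffey: conditional-on-sigma covariance plus the
                # variance propagated through the Empirical-Bayes estimate
                # of the random-effect scale
                dxdm, var_m = ks_info
                cov = cov + var_m * np.outer(dxdm, dxdm)
            d = np.diag(cov)
            if np.any(d <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
            se = np.sqrt(d)
        except np.linalg.LinAlgError as e:
            message = f"penalized Hessian not positive definite: {e}; SEs unavailable"
            cov = None
        if not res.success:
            message = (message + "; " if message else "") + \
                f"optimizer: {res.message} (|grad| unavailable, best point kept)"

        par_df = pd.DataFrame({"name": self.free_names, "estimate": x_hat,
                               "se": se})
        derived = self._derived_frame(x_hat, sigma_r, cov)
        return FitResult(params=par_df, pop_params=params, state=state,
                         sigma_r=sigma_r, loglik=float(-res.fun),
                         components=comp, derived=derived, cov=cov,
                         converged=bool(res.success), message=message,
                         n_pops=self.data.binned.k_total)

    # -- derived quantities ----------------------------------------------
    def _derived_raw(self, x: np.ndarray, sigma_r: float) -> np.ndarray:
        """Log-scale derived quantities for delta-method CIs."""
        params = self.params_from_x(x, sigma_r)
        state = propagate(params)
        out = [np.log(state.total_adults(int(y))) for y in self.years]
        out.append(np.log(np.mean([state.total_adults(int(y))
                                   for y in self.cohort_years])))
        out.extend(np.log(state.biomass()))
        out.extend(np.log(state.spawning_potential()))
        out.append(-params.z)                       # log survival
        out.append(np.log(popdyn.perkg_ratio(params, 15, 10)))
        out.append(np.log(popdyn.perkg_ratio(params, 25, 15)))
        return np.array(out)

    def _derived_frame(self, x, sigma_r, cov) -> pd.DataFrame:
        vals = self._derived_raw(x, sigma_r)
        n_y = len(self.years)
        labels = ([("adult_abundance", int(y)) for y in self.years]
                  + [("mean_adult_abundance", None)]
                  + [("biomass_10plus", int(y)) for y in self.years]
                  + [("spawning_potential", int(y)) for y in self.years]
                  + [("survival", None), ("perkg_ratio_15_10", None),
                     ("perkg_ratio_25_15", None)])
        se_log = np.full(len(vals), np.nan)
        if cov is not None:
            J = _fd_jacobian(lambda z: self._derived_raw(z, sigma_r), x,
                             self.config.hessian_step)
            var = np.einsum("ij,jk,ik->i", J, cov, J)
            se_log = np.sqrt(np.maximum(var, 0.0))
        zq = stats.norm.ppf(0.95)  # 90% intervals
        # abundance-scale quantities are inverse-kin-count estimators and
        # carry the classic +CV^2 small-count bias (the reason Chapman
        # modified Lincoln-Petersen); the point estimate gets the standard
        # second-order curvature adjustment exp(-se_log^2)
        abundance_scale = np.array(
            [l[0] in ("adult_abundance", "mean_adult_abundance",
                      "biomass_10plus", "spawning_potential")
             for l in labels])
        adj = np.where(abundance_scale & np.isfinite(se_log), se_log ** 2, 0.0)
        est = np.exp(vals - adj)
        lo = np.exp(vals - zq * se_log)
        hi = np.exp(vals + zq * se_log)
        return pd.DataFrame({
            "quantity": [l[0] for l in labels],
            "year": [l[1] for l in labels],
            "estimate": est, "lo90": lo, "hi90": hi,
            "se_log": se_log, "cv": se_log,
        })


def loglik_age_given_ls(model: CKMRModel, params: PopParams) -> float:
    """Age-given-length-and-sex log-likelihood at given parameters."""
    comp = model.component_logliks(params, model.initial_x() * 0)
    return comp["age_given_ls"]


def fit(data: CKMRData, base_params: PopParams,
        config: FitConfig | None = None) -> FitResult:
    """Fit the full close-kin model; see :class:`CKMRModel`."""
    model = CKMRModel(data, base_params, config)
    return model.fit()


# ---------------------------------------------------------------------------
# finite-difference helpers (central differences, relative step)

def _steps(x, rel):
    return rel * np.maximum(1.0, np.abs(x))


def _fd_hessian(f, x, rel_step, idx=None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if idx is None:
        idx = np.arange(len(x))
    h = _steps(x, rel_step)
    n = len(idx)
    H = np.zeros((n, n))
    f0 = f(x)
    fp = np.zeros(n)
    fm = np.zeros(n)
    for a, i in enumerate(idx):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        fp[a], fm[a] = f(xp), f(xm)
        H[a, a] = (fp[a] - 2 * f0 + fm[a]) / h[i] ** 2
    for a, i in enumerate(idx):
        for b_, j in enumerate(idx):
            if b_ <= a:
                continue
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            val = (f(xpp) - fp[a] - fp[b_] + 2 * f0 - fm[a] - fm[b_] + f(xmm)) \
                / (2 * h[i] * h[j])
            H[a, b_] = H[b_, a] = val
    return H


def _fd_jacobian(f, x, rel_step) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    h = _steps(x, rel_step)
    cols = []
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        cols.append((f(xp) - f(xm)) / (2 * h[i]))
    return np.column_stack(cols)
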