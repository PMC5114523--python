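"""Parentage-exclusion kinship analysis for multilocus microsatellite panels.

Parent-offspring pairs (POPs) are found by the exclusion principle: a true
parent and offspring must share at least one allele at every locus, so a
pair is accepted as a POP if and only if no scored locus excludes it.  Two
practical complications of real microsatellite data are handled throughout:

* **Null alleles** -- heritable alleles that fail to amplify, so a true
  heterozygote A/null is scored as an apparent homozygote AA.  Allele
  frequencies are therefore estimated by maximum likelihood with an explicit
  null-allele frequency, conditioned on each fish showing at least one
  non-null allele (null/null homozygotes are unscorable), and the exclusion
  criterion is relaxed so that two *apparent homozygotes* with different
  alleles (AA vs BB) never exclude: either fish could be a null carrier.
* **False positives** -- unrelated pairs may share an allele at every scored
  locus by chance.  The a-priori probability of that event is computed per
  pair from the scored-locus set, and comparisons are retained (most
  informative first) only while the summed false-positive expectation stays
  under a configurable fraction of the POPs actually called.

False negatives (true POPs lost to sporadic genotyping errors) are bounded
by modelling the low-exclusion-count cells of the exclusion table as a
mixture of error-afflicted true POPs and the unrelated-pair background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MISSING",
    "GenotypePanel",
    "LocusModel",
    "Comparisons",
    "ExclusionTable",
    "FalseNegativeBound",
    "QCReport",
    "estimate_allele_freqs",
    "locus_excludes",
    "per_locus_exclusion_prob",
    "pair_fp_prob",
    "build_comparisons",
    "exclusion_table",
    "false_negative_bound",
    "homozygosity_qc",
]

#: Sentinel allele value for an unscored locus.
MISSING = -1


@dataclass
class GenotypePanel:
    """Multilocus genotypes for a set of fish.

    ``alleles`` has shape (n_fish, n_loci, 2) with integer allele labels
    (repeat lengths in base pairs); an unscored locus carries ``MISSING`` in
    both slots, and an apparent homozygote carries the same label twice.
    Allele order within a locus is not meaningful and is kept sorted.
    """

    fish_ids: np.ndarray
    loci: list
    alleles: np.ndarray

    def __post_init__(self):
        self.fish_ids = np.asarray(self.fish_ids)
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        if self.alleles.shape != (len(self.fish_ids), len(self.loci), 2):
            raise ValueError("alleles must have shape (n_fish, n_loci, 2)")
        scored = self.scored
        half = (self.alleles >= 0).sum(axis=2)
        if np.any((half == 1)):
            raise ValueError("a scored locus must carry exactly two allele slots")
        self.alleles = np.sort(self.alleles, axis=2)
        self.alleles[~scored] = MISSING

    @property
    def n_fish(self) -> int:
        return len(self.fish_ids)

    @property
    def scored(self) -> np.ndarray:
        """Boolean (n_fish, n_loci): locus successfully scored."""
        return (self.alleles >= 0).all(axis=2)

    def subset(self, fish_ids) -> "GenotypePanel":
        idx = pd.Index(self.fish_ids).get_indexer(np.asarray(fish_ids))
        if np.any(idx < 0):
            missing = np.asarray(fish_ids)[idx < 0]
            raise KeyError(f"fish ids not in panel: {missing[:5]}")
        return GenotypePanel(np.asarray(fish_ids), list(self.loci),
                             self.alleles[idx].copy())

    def locus_calls(self, locus_id) -> np.ndarray:
        return self.alleles[:, self.loci.index(locus_id), :]


@dataclass(frozen=True)
class LocusModel:
    """Estimated allele frequencies at one locus, including a null allele.

    ``freqs`` are the visible-allele frequencies; together with
    ``null_freq`` they sum to one.  Genotype-class probabilities are always
    conditioned on the fish being scorable (at least one non-null allele).
    ``null_identifiable`` is False for degenerate (monomorphic) loci where
    the null frequency cannot be estimated.
    """

    locus_id: object
    alleles: tuple
    freqs: tuple
    null_freq: float
    null_identifiable: bool = True

    def __post_init__(self):
        total = float(np.sum(self.freqs)) + self.null_freq
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"frequencies must sum to 1 (got {total!r})")
        if self.null_freq < 0 or np.any(np.asarray(self.freqs) < 0):
            raise ValueError("frequencies must be nonnegative")
        if self.null_freq >= 1.0 - 1e-12:
            raise ValueError("null frequency leaves no fish scorable")

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)

    def observable_class_probs(self):
        """Probabilities of observable genotype classes, summing to one.

        Returns (het_probs, hom_probs): het_probs[i, j] (i<j) for visible
        heterozygotes, hom_probs[i] for apparent homozygotes (true AA or
        A/null), conditioned on scorability.
        """
        p, p0 = self.p, self.null_freq
        scorable = 1.0 - p0 ** 2
        hom = (p ** 2 + 2.0 * p * p0) / scorable
        het = 2.0 * np.outer(p, p) / scorable
        het[np.diag_indices_from(het)] = 0.0
        return np.triu(het), hom

    def exclusion_prob(self) -> float:
        return per_locus_exclusion_prob(self)


def estimate_allele_freqs(genotypes, locus_id=None, *, tol=1e-12,
                          max_iter=10000) -> LocusModel:
    """Maximum-likelihood allele frequencies at one locus, allowing nulls.

    Accepts either a :class:`GenotypePanel` plus ``locus_id``, or a raw
    (n, 2) array of calls for one locus.  The multinomial likelihood of the
    observable genotype classes (visible heterozygotes; apparent homozygotes
    arising from true homozygotes or visible/null heterozygotes) is
    maximized under Hardy-Weinberg with one null allele, conditioned on each
    fish being scorable.  Fitting is by EM, treating the true state of each
    apparent homozygote and the unobservable null/null class as missing
    data.

    A locus monomorphic among scored fish leaves the null frequency
    unidentifiable; a degenerate model is returned with
    ``null_identifiable=False`` and a warning.
    """
    if isinstance(genotypes, GenotypePanel):
        calls = genotypes.locus_calls(locus_id)
    else:
        calls = np.asarray(genotypes, dtype=np.int64)
    scored = (calls >= 0).all(axis=1)
    calls = calls[scored]
    n = len(calls)
    if n < 2:
        raise ValueError("need at least 2 fish scored at the locus")

    alleles, flat = np.unique(calls, return_inverse=True)
    flat = flat.reshape(calls.shape)
    k = len(alleles)
    is_hom = flat[:, 0] == flat[:, 1]
    hom_counts = np.bincount(flat[is_hom, 0], minlength=k).astype(float)
    het_counts = np.bincount(flat[~is_hom].ravel(), minlength=k).astype(float)

    if k == 1:
        warnings.warn(f"locus {locus_id!r} is monomorphic among scored fish; "
                      "null frequency unidentifiable", stacklevel=2)
        return LocusModel(locus_id, tuple(alleles.tolist()), (1.0,), 0.0,
                          null_identifiable=False)

    p = (hom_counts * 2 + het_counts)
    p = p / p.sum()
    p0 = 0.02
    for _ in range(max_iter):
        # E-step: split apparent homozygotes into true AA vs A/null, and
        # impute the unobservable null/null count.
        with np.errstate(invalid="ignore", divide="ignore"):
            w_true_hom = np.where(p > 0, p / (p + 2.0 * p0), 0.0)
        n00 = n * p0 ** 2 / (1.0 - p0 ** 2)
        counts = het_counts + hom_counts * (1.0 + w_true_hom)
        count0 = (hom_counts * (1.0 - w_true_hom)).sum() + 2.0 * n00
        total = 2.0 * (n + n00)
        new_p = counts / total
        new_p0 = count0 / total
        if abs(new_p0 - p0) + np.abs(new_p - p).sum() < tol:
            p, p0 = new_p, new_p0
            break
        p, p0 = new_p, new_p0
    scale = p.sum() + p0
    return LocusModel(locus_id, tuple(alleles.tolist()),
                      tuple((p / scale).tolist()), float(p0 / scale))


def loglik_allele_freqs(calls, freqs, null_freq) -> float:
    """Conditional log-likelihood of one locus' scored calls given frequencies.

    Exposed for the grid-search oracle used in testing the EM fit.
    """
    calls = np.asarray(calls)
    scored = (calls >= 0).all(axis=1)
    calls = calls[scored]
    alleles = np.unique(calls)
    lookup = {a: i for i, a in enumerate(alleles)}
    p = np.asarray(freqs, dtype=float)
    p0 = float(null_freq)
    scorable = 1.0 - p0 ** 2
    ll = 0.0
    for a, b in calls:
        i, j = lookup[a], lookup[b]
        if i == j:
            ll += np.log((p[i] ** 2 + 2 * p[i] * p0) / scorable)
        else:
            ll += np.log(2 * p[i] * p[j] / scorable)
    return float(ll)


def locus_excludes(g1, g2) -> bool:
    """Null-tolerant single-locus parentage-exclusion test.

    Returns True (excluding) iff the two scored calls share no allele AND
    they are not both apparent homozygotes; AA vs BB is tolerated because
    either fish could be a visible/null heterozygote.
    """
    a1, a2 = int(g1[0]), int(g1[1])
    b1, b2 = int(g2[0]), int(g2[1])
    if min(a1, a2, b1, b2) < 0:
        raise ValueError("both loci must be scored")
    shares = a1 in (b1, b2) or a2 in (b1, b2)
    both_hom = (a1 == a2) and (b1 == b2)
    return (not shares) and (not both_hom)


def per_locus_exclusion_prob(model: LocusModel) -> float:
    """Probability that two independent fish exclude at this locus.

    Closed form over observable genotype classes (conditioned on
    scorability), honouring the apparent-homozygote tolerance rule.
    Verified elsewhere against brute-force enumeration.
    """
    p = model.p
    p0 = model.null_freq
    k = len(p)
    if k == 1:
        return 0.0
    scorable = 1.0 - p0 ** 2
    hom = (p ** 2 + 2.0 * p * p0) / scorable

    def avoid(p_in):
        # P(second fish shows no visible allele from a set with total
        # visible frequency p_in | scorable)
        pc = 1.0 - p0 - p_in
        return ((p0 + pc) ** 2 - p0 ** 2) / scorable

    # apparent homozygote A vs anything avoiding {A}
    no_share = float(np.sum(hom * avoid(p)))
    # visible heterozygote {A,B} vs anything avoiding {A,B}
    pi, pj = np.meshgrid(p, p, indexing="ij")
    het = 2.0 * pi * pj / scorable
    av = avoid(pi + pj)
    iu = np.triu_indices(k, 1)
    no_share += float(np.sum(het[iu] * av[iu]))
    # both apparent homozygotes with different alleles are tolerated
    both_hom_diff = float(np.sum(hom) ** 2 - np.sum(hom ** 2))
    return no_share - both_hom_diff


def pair_fp_prob(loci_scored_in_both, models: dict) -> float:
    """A-priori probability that an unrelated pair shows zero excluding loci.

    The product over the jointly scored locus set of (1 - per-locus
    exclusion probability); non-increasing as loci are added.
    """
    loci = list(loci_scored_in_both)
    if not loci:
        raise ValueError("empty locus set: comparison is uninformative")
    out = 1.0
    for locus in loci:
        out *= 1.0 - per_locus_exclusion_prob(models[locus])
    return out


def _pairwise_exclusions(adult_panel: GenotypePanel, juv_panel: GenotypePanel,
                         block=256):
    """Vectorized all-pairs exclusion counts and jointly-scored masks.

    Returns (n_excluding, n_loci) int arrays of shape (n_adults, n_juv) plus
    the per-locus jointly-scored boolean used for fp products.
    """
    if adult_panel.loci != juv_panel.loci:
        raise ValueError("panels must share the same locus list")
    n_a, n_j = adult_panel.n_fish, juv_panel.n_fish
    n_loci = len(adult_panel.loci)
    a = adult_panel.alleles
    b = juv_panel.alleles
    a_scored = adult_panel.scored
    b_scored = juv_panel.scored
    n_excl = np.zeros((n_a, n_j), dtype=np.int16)
    n_cmp = np.zeros((n_a, n_j), dtype=np.int16)
    for lo in range(0, n_a, block):
        hi = min(lo + block, n_a)
        for l in range(n_loci):
            a1 = a[lo:hi, l, 0][:, None]
            a2 = a[lo:hi, l, 1][:, None]
            b1 = b[:, l, 0][None, :]
            b2 = b[:, l, 1][None, :]
            shares = (a1 == b1) | (a1 == b2) | (a2 == b1) | (a2 == b2)
            both_hom = (a1 == a2) & (b1 == b2)
            joint = a_scored[lo:hi, l][:, None] & b_scored[:, l][None, :]
            n_cmp[lo:hi] += joint
            n_excl[lo:hi] += joint & ~shares & ~both_hom
    return n_excl, n_cmp


@dataclass
class Comparisons:
    """All candidate adult-juvenile comparisons with retention and POP flags.

    ``df`` columns: adult_id, juvenile_id, n_loci_compared, n_excluding,
    fp_prob, retained, pop_call, near_miss.  ``pop_call`` means retained
    with zero excluding loci; ``near_miss`` (1-2 excluding loci among
    retained pairs) marks pairs for re-examination.
    """

    df: pd.DataFrame
    fp_budget_fraction: float
    n_candidates: int
    converged: bool
    threshold: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def retained(self) -> pd.DataFrame:
        return self.df[self.df.retained]

    @property
    def n_pops(self) -> int:
        return int(self.df.pop_call.sum())

    @property
    def expected_false_positives(self) -> float:
        return float(self.df.fp_prob[self.df.retained].sum())


def build_comparisons(adult_panel: GenotypePanel, adult_meta: pd.DataFrame,
                      juv_panel: GenotypePanel, juv_meta: pd.DataFrame,
                      models: dict, fp_budget_fraction: float | None = 0.01,
                      near_miss_max: int = 2) -> Comparisons:
    """All pairwise parentage comparisons with false-positive-budget retention.

    Pairs whose adult was not caught strictly after the juvenile's birth
    year are dropped outright (parentage impossible, and an adult caught
    part-way through its season has not made its full reproductive
    contribution).  Each remaining pair's false-positive probability is the
    product over its jointly scored loci of (1 - exclusion probability);
    pairs are retained most-informative-first until the cumulative expected
    false positives would exceed ``fp_budget_fraction`` times the number of
    zero-exclusion pairs among those retained.  Because the POP count is a
    step function of the threshold, the budget is solved by a fixed-point
    iteration (tightening only), with ties broken by fish id for
    determinism.

    ``adult_meta`` needs columns fish_id, capture_year; ``juv_meta`` needs
    fish_id, birth_year, aligned with the respective panels.
    """
    adult_meta = adult_meta.set_index("fish_id").loc[adult_panel.fish_ids]
    juv_meta = juv_meta.set_index("fish_id").loc[juv_panel.fish_ids]
    cap_year = adult_meta["capture_year"].to_numpy(dtype=int)
    birth_year = juv_meta["birth_year"].to_numpy(dtype=int)

    n_excl, n_cmp = _pairwise_exclusions(adult_panel, juv_panel)
    log_keep = np.array([np.log1p(-per_locus_exclusion_prob(models[l]))
                         for l in adult_panel.loci])
    a_scored = adult_panel.scored.astype(float)
    j_scored = juv_panel.scored.astype(float)
    log_fp = (a_scored * log_keep) @ j_scored.T  # joint loci only

    valid = (cap_year[:, None] > birth_year[None, :]) & (n_cmp > 0)
    # a fish can appear in both sets (e.g. juvenile-juvenile sanity runs);
    # never compare a genotype with itself
    valid &= adult_panel.fish_ids[:, None] != juv_panel.fish_ids[None, :]
    ai, ji = np.nonzero(valid)
    fp = np.exp(log_fp[ai, ji])
    excl = n_excl[ai, ji].astype(int)
    nloci = n_cmp[ai, ji].astype(int)

    order = np.lexsort((juv_panel.fish_ids[ji], adult_panel.fish_ids[ai], fp))
    ai, ji, fp, excl, nloci = (x[order] for x in (ai, ji, fp, excl, nloci))
    cum_fp = np.cumsum(fp)
    is_zero = (excl == 0)
    cum_pop = np.cumsum(is_zero)

    n_ret = len(fp)
    converged = True
    if fp_budget_fraction is None:  # sanity-table mode: no retention filter
        fp_budget_fraction = np.inf
    for _ in range(100):
        converged = False
        n_pop = int(cum_pop[n_ret - 1]) if n_ret else 0
        budget = np.inf if not np.isfinite(fp_budget_fraction) \
            else fp_budget_fraction * n_pop
        new_ret = int(np.searchsorted(cum_fp, budget, side="right"))
        new_ret = min(new_ret, n_ret)  # tighten only: guarantees convergence
        if new_ret == n_ret:
            converged = True
            break
        n_ret = new_ret
        if n_ret == 0:
            converged = True
            break

    retained = np.zeros(len(fp), dtype=bool)
    retained[:n_ret] = True
    pop_call = retained & is_zero
    near_miss = retained & (excl >= 1) & (excl <= near_miss_max)
    df = pd.DataFrame({
        "adult_id": adult_panel.fish_ids[ai],
        "juvenile_id": juv_panel.fish_ids[ji],
        "n_loci_compared": nloci,
        "n_excluding": excl,
        "fp_prob": fp,
        "retained": retained,
        "pop_call": pop_call,
        "near_miss": near_miss,
    })
    diagnostics = {}
    if n_ret == 0:
        diagnostics["empty"] = ("no comparison set satisfies the false-positive "
                                "budget (no zero-exclusion pairs found)")
    return Comparisons(df=df, fp_budget_fraction=fp_budget_fraction,
                       n_candidates=len(fp), converged=converged,
                       threshold=float(fp[n_ret - 1]) if n_ret else 0.0,
                       diagnostics=diagnostics)


@dataclass
class ExclusionTable:
    """Counts of retained comparisons by number of excluding loci.

    ``expected_unrelated[k]`` is the a-priori expected number of unrelated
    pairs among the same comparisons showing exactly k excluding loci
    (Poisson-binomial across each pair's scored loci), used as the
    background when bounding false negatives.  ``mean_loci`` is the average
    number of jointly scored loci per retained comparison.
    """

    ks: np.ndarray
    counts: np.ndarray
    expected_unrelated: np.ndarray
    n_comparisons: int
    mean_loci: float
    label: str = "adult-juvenile"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_excluding": self.ks, "count": self.counts})


def exclusion_table(comparisons: Comparisons, models: dict,
                    adult_panel: GenotypePanel | None = None,
                    juv_panel: GenotypePanel | None = None,
                    k_background: int = 6,
                    label: str = "adult-juvenile") -> ExclusionTable:
    """Tabulate retained comparisons by excluding-locus count.

    When the panels are supplied, the expected unrelated-pair background at
    each low exclusion count is computed exactly per pair by a
    Poisson-binomial recursion over that pair's jointly scored loci;
    otherwise only the zero-exclusion background (the summed fp_prob) is
    available.
    """
    ret = comparisons.retained
    counts = np.bincount(ret.n_excluding.to_numpy()) if len(ret) else np.zeros(1, int)
    ks = np.arange(len(counts))
    mean_loci = float(ret.n_loci_compared.mean()) if len(ret) else 0.0

    expected = np.zeros(k_background + 1)
    if adult_panel is not None and juv_panel is not None and len(ret):
        q = np.array([per_locus_exclusion_prob(models[l])
                      for l in adult_panel.loci])
        ai = pd.Index(adult_panel.fish_ids).get_indexer(ret.adult_id)
        ji = pd.Index(juv_panel.fish_ids).get_indexer(ret.juvenile_id)
        joint = adult_panel.scored[ai] & juv_panel.scored[ji]
        B = np.zeros((len(ret), k_background + 1))
        B[:, 0] = 1.0
        for l in range(joint.shape[1]):
            m = joint[:, l]
            ql = q[l]
            Bm = B[m]
            B[m, 1:] = Bm[:, 1:] * (1 - ql) + Bm[:, :-1] * ql
            B[m, 0] = Bm[:, 0] * (1 - ql)
        expected = B.sum(axis=0)
    elif len(ret):
        expected[0] = float(ret.fp_prob.sum())
    return ExclusionTable(ks=ks, counts=counts, expected_unrelated=expected,
                          n_comparisons=int(len(ret)), mean_loci=mean_loci,
                          label=label)


@dataclass
class FalseNegativeBound:
    """Profile-likelihood bound on missed POPs from the exclusion table."""

    missed_mle: float
    ci: tuple
    n_pop_mle: float
    error_rate_mle: float
    confidence: float


def _fn_loglik(n_pop, eps, table: ExclusionTable, k_max: int) -> float:
    L = max(int(round(table.mean_loci)), 1)
    kk = np.arange(k_max + 1)
    pois_mean = n_pop * stats.binom.pmf(kk, L, eps)
    pois_mean = pois_mean + table.expected_unrelated[: k_max + 1]
    obs = np.zeros(k_max + 1)
    upto = min(k_max + 1, len(table.counts))
    obs[:upto] = table.counts[:upto]
    pois_mean = np.maximum(pois_mean, 1e-300)
    return float(np.sum(obs * np.log(pois_mean) - pois_mean))


def false_negative_bound(table: ExclusionTable, per_locus_error_model=None,
                         confidence: float = 0.95,
                         k_max: int = 4) -> FalseNegativeBound:
    """Bound the number of true POPs lost to apparent exclusions.

    The low-k cells of the exclusion table are modelled as independent
    Poisson counts whose means mix (a) ``n_pop`` true POPs each showing
    k apparent exclusions with Binomial(L, eps) probability -- independent
    per-locus scoring errors at a single shared rate eps -- and (b) the
    unrelated-pair background expected from the false-positive machinery.
    ``per_locus_error_model`` may fix eps (a float); otherwise eps is
    estimated jointly with n_pop.  The returned interval is a
    profile-likelihood CI for the expected number of missed POPs,
    M = n_pop * (1 - (1-eps)**L).
    """
    if table.n_comparisons == 0:
        raise ValueError("no comparisons in the exclusion table")
    L = max(int(round(table.mean_loci)), 1)

    def nll(x):
        n_pop = np.exp(x[0])
        eps = 1.0 / (1.0 + np.exp(-x[1]))
        return -_fn_loglik(n_pop, eps, table, k_max)

    n0 = max(float(table.counts[0] - table.expected_unrelated[0]), 1.0)
    if per_locus_error_model is not None:
        eps_hat = float(per_locus_error_model)
        res = optimize.minimize_scalar(
            lambda lx: -_fn_loglik(np.exp(lx), eps_hat, table, k_max),
            bounds=(np.log(n0) - 5, np.log(n0) + 5), method="bounded")
        n_hat, ll_hat = float(np.exp(res.x)), -res.fun
    else:
        res = optimize.minimize(nll, x0=[np.log(n0), np.log(0.002)],
                                method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9,
                                         "maxiter": 2000})
        n_hat = float(np.exp(res.x[0]))
        eps_hat = float(1.0 / (1.0 + np.exp(-res.x[1])))
        ll_hat = -res.fun
    m_hat = n_hat * (1.0 - (1.0 - eps_hat) ** L)

    def profile_ll(m):
        """Maximized log-likelihood with the expected missed count fixed at m."""
        if m <= 0:
            # eps=0: all POPs sit at k=0; n_pop free
            res0 = optimize.minimize_scalar(
                lambda lx: -_fn_loglik(np.exp(lx), 0.0, table, k_max),
                bounds=(np.log(max(n0, 1e-6)) - 5, np.log(max(n0, 1e-6)) + 5),
                method="bounded")
            return -res0.fun

        def inner(logit_eps):
            eps = 1.0 / (1.0 + np.exp(-logit_eps))
            denom = 1.0 - (1.0 - eps) ** L
            n_pop = m / denom
            return -_fn_loglik(n_pop, eps, table, k_max)

        res1 = optimize.minimize_scalar(inner, bounds=(-45.0, 0.0),
                                        method="bounded",
                                        options={"xatol": 1e-6})
        return -res1.fun

    crit = stats.chi2.ppf(confidence, 1) / 2.0

    def deviance(m):
        return ll_hat - profile_ll(m)

    # upper bound: scan outward then bisect
    hi = max(m_hat, 0.5)
    while deviance(hi) < crit and hi < 1e4:
        hi *= 2.0
    upper = optimize.brentq(lambda m: deviance(m) - crit, max(m_hat, 1e-9), hi) \
        if deviance(hi) >= crit else float(hi)
    # lower bound
    if deviance(0.0) < crit or m_hat <= 1e-9:
        lower = 0.0
    else:
        lower = optimize.brentq(lambda m: deviance(m) - crit, 1e-9, m_hat)
    return FalseNegativeBound(missed_mle=float(m_hat), ci=(float(lower), float(upper)),
                              n_pop_mle=n_hat, error_rate_mle=eps_hat,
                              confidence=confidence)


@dataclass
class QCReport:
    """Genotype quality-control summary.

    ``quality_trend``: smooth-trend test of per-fish homozygosity against
    scored-locus fraction (a DNA-quality proxy).  ``locus_excess``: per-locus
    apparent-homozygote excess versus null-free Hardy-Weinberg expectation.
    ``long_allele``: test for a relationship between allele length and
    homozygote excess after accounting for allele frequency (long-allele
    dropout).  Each check carries a p-value and a pass/flag verdict.
    """

    quality_trend_p: float
    quality_trend_pass: bool
    locus_excess: pd.DataFrame
    long_allele_slope: float
    long_allele_p: float
    long_allele_pass: bool
    alpha: float

    @property
    def n_loci_flagged(self) -> int:
        return int(self.locus_excess["excess_flag"].sum())

    def summary(self) -> str:
        lines = [
            "genotype QC report",
            f"  quality/homozygosity trend: p={self.quality_trend_p:.3g} "
            f"({'pass' if self.quality_trend_pass else 'FLAG'})",
            f"  loci with homozygote excess: {self.n_loci_flagged} of "
            f"{len(self.locus_excess)}",
            f"  long-allele dropout: slope={self.long_allele_slope:.3g}, "
            f"p={self.long_allele_p:.3g} "
            f"({'pass' if self.long_allele_pass else 'FLAG'})",
        ]
        return "\n".join(lines)


def homozygosity_qc(panel: GenotypePanel, models: dict | None = None,
                    alpha: float = 0.01) -> QCReport:
    """Run the three genotype-quality checks on a panel.

    (a) flexible (cubic-polynomial) regression of per-fish homozygote
    fraction on scorable-locus fraction, with an F-test of any trend;
    (b) per-locus apparent-homozygote excess against the null-free
    Hardy-Weinberg expectation (one-sided binomial test); (c) long-allele
    dropout: Pearson residuals of per-allele apparent-homozygote counts
    under the fitted null-allele model, regressed on within-locus
    standardized allele length.
    """
    import statsmodels.api as sm

    if len(panel.loci) < 2:
        raise ValueError("QC needs at least 2 loci")
    if models is None:
        models = {l: estimate_allele_freqs(panel, l) for l in panel.loci}

    scored = panel.scored
    hom = (panel.alleles[:, :, 0] == panel.alleles[:, :, 1]) & scored
    n_scored = scored.sum(axis=1)
    keep = n_scored > 0
    frac_scored = n_scored[keep] / len(panel.loci)
    frac_hom = hom.sum(axis=1)[keep] / n_scored[keep]

    x = frac_scored - frac_scored.mean()
    if len(frac_hom) > 4 and x.std() > 1e-6:
        xs = x / x.std()
        X = np.column_stack([np.ones_like(xs), xs, xs ** 2, xs ** 3])
        w = n_scored[keep]
        full = sm.WLS(frac_hom, X, weights=w).fit()
        null_fit = sm.WLS(frac_hom, X[:, :1], weights=w).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            quality_p = float(full.compare_f_test(null_fit)[1])
        if not np.isfinite(quality_p):
            quality_p = 1.0
    else:
        quality_p = 1.0  # no variation in scoring success: nothing to test

    rows = []
    resid_rows = []
    for li, locus in enumerate(panel.loci):
        calls = panel.alleles[scored[:, li], li, :]
        n = len(calls)
        if n == 0:
            continue
        alleles, flat = np.unique(calls, return_inverse=True)
        flat = flat.reshape(calls.shape)
        counts = np.bincount(flat.ravel(), minlength=len(alleles)).astype(float)
        p_naive = counts / counts.sum()
        exp_hom = float(np.sum(p_naive ** 2))
        obs_hom = int((calls[:, 0] == calls[:, 1]).sum())
        bt = stats.binomtest(obs_hom, n, exp_hom, alternative="greater")
        m = models[locus]
        rows.append({"locus": locus, "n_scored": n, "obs_hom_frac": obs_hom / n,
                     "exp_hom_frac_no_null": exp_hom,
                     "null_freq": m.null_freq, "p_excess": bt.pvalue,
                     "excess_flag": bt.pvalue < alpha})
        # per-allele homozygote residuals vs allele length
        if len(alleles) >= 3 and m.null_identifiable:
            is_hom = flat[:, 0] == flat[:, 1]
            obs_a = np.bincount(flat[is_hom, 0], minlength=len(alleles)).astype(float)
            pm = np.zeros(len(alleles))
            for ai, a in enumerate(alleles):
                if a in m.alleles:
                    pm[ai] = m.p[m.alleles.index(a)]
            scorable = 1.0 - m.null_freq ** 2
            exp_a = n * (pm ** 2 + 2 * pm * m.null_freq) / scorable
            ok = exp_a > 0.5
            if ok.sum() >= 3:
                r = (obs_a[ok] - exp_a[ok]) / np.sqrt(exp_a[ok])
                z_len = (alleles[ok] - alleles[ok].mean()) / max(alleles[ok].std(), 1e-9)
                resid_rows.append(np.column_stack([z_len, r]))

    locus_excess = pd.DataFrame(rows)
    if resid_rows:
        all_r = np.vstack(resid_rows)
        Xl = np.column_stack([np.ones(len(all_r)), all_r[:, 0]])
        fit_l = sm.OLS(all_r[:, 1], Xl).fit()
        slope = float(fit_l.params[1])
        slope_p = float(fit_l.pvalues[1])
    else:
        slope, slope_p = 0.0, 1.0
    return QCReport(quality_trend_p=quality_p,
                    quality_trend_pass=quality_p >= alpha,
                    locus_excess=locus_excess,
                    long_allele_slope=slope, long_allele_p=slope_p,
                    long_allele_pass=slope_p >= alpha, alpha=alpha)
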