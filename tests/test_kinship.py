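"""Allele-frequency estimation with nulls, exclusion logic and retention."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ckmrkit import kinship as kin
from ckmrkit import simulate as sim
from ckmrkit.kinship import (GenotypePanel, LocusModel, build_comparisons,
                             estimate_allele_freqs, exclusion_table,
                             false_negative_bound, homozygosity_qc,
                             locus_excludes, pair_fp_prob,
                             per_locus_exclusion_prob)


def brute_force_exclusion_prob(freqs, null_freq):
    """Enumerate every ordered pair of observable genotypes and apply the
    null-tolerant exclusion rule -- the independent oracle for the closed
    form."""
    alleles = list(range(1, len(freqs) + 1)) + [0]  # 0 = null
    p = list(freqs) + [null_freq]
    classes = {}
    for (i, a), (j, b) in itertools.product(enumerate(alleles), repeat=2):
        prob = p[i] * p[j]
        visible = [x for x in (a, b) if x != 0]
        if not visible:
            continue  # null homozygote: unscorable
        obs = (visible[0], visible[0]) if len(visible) == 1 else \
            (min(visible), max(visible))
        classes[obs] = classes.get(obs, 0.0) + prob
    norm = sum(classes.values())
    out = 0.0
    for g1, p1 in classes.items():
        for g2, p2 in classes.items():
            if locus_excludes(g1, g2):
                out += (p1 / norm) * (p2 / norm)
    return out


def _model(freqs, null):
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs / freqs.sum() * (1 - null)
    return LocusModel("L", tuple(range(1, len(freqs) + 1)),
                      tuple(freqs.tolist()), null)


class TestLocusExcludes:
    @pytest.mark.parametrize("g1,g2,expected", [
        ((1, 2), (2, 3), False),   # share an allele
        ((1, 2), (3, 4), True),    # heterozygotes sharing nothing
        ((1, 1), (2, 2), False),   # AA vs BB tolerated: possible null carriers
        ((1, 1), (2, 3), True),    # apparent homozygote vs non-matching het
        ((1, 1), (1, 2), False),
    ])
    def test_rule(self, g1, g2, expected):
        assert locus_excludes(g1, g2) is expected
        assert locus_excludes(g2, g1) is expected

    def test_unscored_rejected(self):
        with pytest.raises(ValueError):
            locus_excludes((-1, -1), (1, 2))


class TestExclusionProb:
    def test_monomorphic_zero(self):
        assert per_locus_exclusion_prob(_model([1.0], 0.0)) == 0.0

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_matches_enumeration_equifrequent_no_null(self, k):
        m = _model(np.ones(k), 0.0)
        assert per_locus_exclusion_prob(m) == pytest.approx(
            brute_force_exclusion_prob(m.freqs, 0.0), abs=1e-12)

    @pytest.mark.parametrize("k,null", [(2, 0.1), (3, 0.25), (4, 0.05),
                                        (5, 0.15), (6, 0.3)])
    def test_matches_enumeration_with_null(self, k, null):
        rng = np.random.default_rng(k)
        m = _model(rng.dirichlet(np.ones(k)), null)
        assert per_locus_exclusion_prob(m) == pytest.approx(
            brute_force_exclusion_prob(m.freqs, m.null_freq), abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(2, 6), st.floats(0.0, 0.4), st.integers(0, 10 ** 6))
    def test_enumeration_property(self, k, null, seed):
        rng = np.random.default_rng(seed)
        m = _model(rng.dirichlet(np.ones(k) * 2), null)
        assert per_locus_exclusion_prob(m) == pytest.approx(
            brute_force_exclusion_prob(m.freqs, m.null_freq), abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(2, 8), st.floats(0, 0.3), st.integers(0, 10 ** 6))
    def test_class_probs_sum_to_one(self, k, null, seed):
        # conditioning correctness: observable classes are a distribution
        rng = np.random.default_rng(seed)
        m = _model(rng.dirichlet(np.ones(k)), null)
        het, hom = m.observable_class_probs()
        assert het.sum() + hom.sum() == pytest.approx(1.0, abs=1e-12)


class TestPairFpProb:
    def test_single_locus(self):
        m = _model([1, 1, 1], 0.0)
        q = per_locus_exclusion_prob(m)
        assert pair_fp_prob(["L"], {"L": m}) == pytest.approx(1 - q)

    def test_product_rule_twenty_loci(self):
        # twenty loci each excluding with probability 0.6 leave a 0.4^20
        # chance that an unrelated pair shows no excluding locus
        class Fake:
            pass
        models = {}
        for i in range(20):
            m = _model(np.ones(10), 0.0)
            models[i] = m
        q = per_locus_exclusion_prob(_model(np.ones(10), 0.0))
        expected = (1 - q) ** 20
        assert pair_fp_prob(range(20), models) == pytest.approx(expected, rel=1e-12)

    def test_empty_set_error(self):
        with pytest.raises(ValueError):
            pair_fp_prob([], {})

    @settings(deadline=None, max_examples=40)
    @given(st.integers(1, 10), st.integers(0, 10 ** 6))
    def test_monotone_in_locus_set(self, n_loci, seed):
        rng = np.random.default_rng(seed)
        models = {i: _model(rng.dirichlet(np.ones(rng.integers(2, 8))),
                            rng.uniform(0, 0.2)) for i in range(n_loci + 1)}
        subset = pair_fp_prob(range(n_loci), models)
        superset = pair_fp_prob(range(n_loci + 1), models)
        assert superset <= subset + 1e-15

    def test_realized_zero_exclusion_rate_matches_prediction(self):
        # weak 4-locus panel so that zero-exclusion unrelated pairs actually
        # occur; pairing disjoint founders one-to-one keeps the pairs
        # independent, so the realized count must sit within 3 Poisson s.d.
        # of the summed pair probabilities
        rng = np.random.default_rng(7)
        panel = [sim.LocusSpec(f"W{i}", tuple(range(100, 116, 4)),
                               tuple(rng.dirichlet(np.ones(4)) * 0.95),
                               0.05) for i in range(4)]
        n = 4000
        g1 = sim.simulate_founder_panel(panel, n, 1, id_prefix="X")
        g2 = sim.simulate_founder_panel(panel, n, 2, id_prefix="Y")
        models = {s.locus_id: LocusModel(s.locus_id, s.allele_lengths,
                                         s.freqs, s.null_freq) for s in panel}
        n_excl = np.zeros(n, dtype=int)
        for li in range(len(panel)):
            a1, a2 = g1.alleles[:, li, 0], g1.alleles[:, li, 1]
            b1, b2 = g2.alleles[:, li, 0], g2.alleles[:, li, 1]
            shares = (a1 == b1) | (a1 == b2) | (a2 == b1) | (a2 == b2)
            both_hom = (a1 == a2) & (b1 == b2)
            n_excl += ~shares & ~both_hom
        realized = int((n_excl == 0).sum())
        expected = n * pair_fp_prob([s.locus_id for s in panel], models)
        assert abs(realized - expected) <= 3 * np.sqrt(expected)


class TestEstimateAlleleFreqs:
    def test_zero_null_limit(self):
        rng = np.random.default_rng(3)
        p = np.array([0.5, 0.3, 0.2])
        draws = rng.choice(3, size=(4000, 2), p=p) + 101
        m = estimate_allele_freqs(draws)
        assert m.null_freq < 0.01
        assert np.allclose(sorted(m.freqs, reverse=True), p, atol=0.03)

    def test_null_recovery_large_sample(self):
        # two visible alleles at 0.45 each plus a 0.10 null: the fitted
        # null frequency sits within 3 Monte-Carlo s.e. of truth
        panel = [sim.LocusSpec("L1", (100, 104), (0.45, 0.45), 0.10)]
        fits = []
        for s in range(5):
            gp = sim.simulate_founder_panel(panel, 8000, s)
            fits.append(estimate_allele_freqs(gp, "L1").null_freq)
        fits = np.asarray(fits)
        mc_se = fits.std(ddof=1) / np.sqrt(len(fits))
        assert abs(fits.mean() - 0.10) <= 3 * max(mc_se, 1e-3)

    def test_em_matches_grid_search(self):
        # exhaustive grid over (p1, p0) for a 2-visible-allele locus: the
        # EM optimum must match the grid maximum of the conditional
        # likelihood to 1e-4
        panel = [sim.LocusSpec("L1", (100, 104), (0.55, 0.25), 0.20)]
        gp = sim.simulate_founder_panel(panel, 500, 9)
        calls = gp.locus_calls("L1")
        m = estimate_allele_freqs(gp, "L1")
        ll_em = kin.loglik_allele_freqs(calls, m.freqs, m.null_freq)
        best = (-np.inf, None)
        for p1 in np.arange(0.02, 0.98, 0.004):
            for p0 in np.arange(0.0, 0.6, 0.004):
                if p1 + p0 >= 1:
                    continue
                ll = kin.loglik_allele_freqs(calls, (p1, 1 - p1 - p0), p0)
                if ll > best[0]:
                    best = (ll, (p1, p0))
        assert ll_em >= best[0] - 1e-4

    def test_monomorphic_degenerate(self):
        calls = np.full((10, 2), 117)
        with pytest.warns(UserWarning, match="monomorphic"):
            m = estimate_allele_freqs(calls, "LX")
        assert not m.null_identifiable
        assert m.freqs == (1.0,)

    def test_too_few_fish(self):
        with pytest.raises(ValueError):
            estimate_allele_freqs(np.array([[101, 102]]))


class TestBuildComparisons:
    def test_birth_year_filter(self):
        alleles = np.full((1, 3, 2), 101, dtype=np.int32)
        ad = GenotypePanel(["A1"], ["L1", "L2", "L3"], alleles)
        ju = GenotypePanel(["J1"], ["L1", "L2", "L3"], alleles.copy())
        models = {l: _model([1, 1, 1, 1], 0.0) for l in ad.loci}
        am = pd.DataFrame({"fish_id": ["A1"], "capture_year": [2005]})
        # adult caught the year the juvenile was born: impossible parent,
        # and a part-year spawner has not made its full contribution
        jm = pd.DataFrame({"fish_id": ["J1"], "birth_year": [2005]})
        comps = build_comparisons(ad, am, ju, jm, models)
        assert comps.n_candidates == 0
        jm2 = pd.DataFrame({"fish_id": ["J1"], "birth_year": [2004]})
        comps2 = build_comparisons(ad, am, ju, jm2, models)
        assert comps2.n_candidates == 1

    def test_strong_panel_retains_everything(self, genotyped_dataset):
        pop, samples, panel = genotyped_dataset
        ad = samples[samples.stage == "adult"]
        ju = samples[samples.stage == "juvenile"]
        models = {l: estimate_allele_freqs(panel, l) for l in panel.loci}
        comps = build_comparisons(panel.subset(ad.fish_id.to_numpy()), ad,
                                  panel.subset(ju.fish_id.to_numpy()), ju,
                                  models)
        assert comps.converged
        assert comps.df.retained.all()
        # invariant: a POP call is a retained, zero-exclusion comparison
        assert (comps.df.pop_call <= (comps.df.retained
                                      & (comps.df.n_excluding == 0))).all()
        assert comps.expected_false_positives <= 0.01 * comps.n_pops

    def test_true_pops_all_called_with_zero_error(self, genotyped_dataset):
        # Mendelian inheritance guarantees a shared allele at every locus
        # (nulls handled by the tolerance rule): no true pair is lost
        pop, samples, panel = genotyped_dataset
        ad = samples[samples.stage == "adult"]
        ju = samples[samples.stage == "juvenile"]
        models = {l: estimate_allele_freqs(panel, l) for l in panel.loci}
        comps = build_comparisons(panel.subset(ad.fish_id.to_numpy()), ad,
                                  panel.subset(ju.fish_id.to_numpy()), ju,
                                  models)
        truth = pop.pedigree.pop_pairs()
        df = comps.df
        is_true = np.array([(sim.base_id(a), j) in truth
                            for a, j in zip(df.adult_id, df.juvenile_id)])
        assert (df.n_excluding[is_true] == 0).all()
        assert df.pop_call[is_true].all()

    def test_weak_panel_empty_with_diagnostic(self):
        rng = np.random.default_rng(5)
        panel = [sim.LocusSpec(f"W{i}", (100, 104, 108),
                               tuple(rng.dirichlet(np.ones(3))), 0.0)
                 for i in range(2)]
        g1 = sim.simulate_founder_panel(panel, 100, 1, id_prefix="X")
        g2 = sim.simulate_founder_panel(panel, 100, 2, id_prefix="Y")
        models = {s.locus_id: LocusModel(s.locus_id, s.allele_lengths,
                                         s.freqs, 0.0) for s in panel}
        m1 = pd.DataFrame({"fish_id": g1.fish_ids, "capture_year": 2010})
        m2 = pd.DataFrame({"fish_id": g2.fish_ids, "birth_year": 2000})
        comps = build_comparisons(g1, m1, g2, m2, models)
        assert not comps.df.retained.any()
        assert "empty" in comps.diagnostics


class TestExclusionTableAndFalseNegatives:
    def test_totals_match_retained(self, genotyped_dataset):
        pop, samples, panel = genotyped_dataset
        ad = samples[samples.stage == "adult"]
        ju = samples[samples.stage == "juvenile"]
        models = {l: estimate_allele_freqs(panel, l) for l in panel.loci}
        ap = panel.subset(ad.fish_id.to_numpy())
        jp = panel.subset(ju.fish_id.to_numpy())
        comps = build_comparisons(ap, ad, jp, ju, models)
        tab = exclusion_table(comps, models, ap, jp)
        assert tab.counts.sum() == int(comps.df.retained.sum())
        assert tab.expected_unrelated[0] == pytest.approx(
            comps.expected_false_positives, rel=1e-6)

    def test_juvenile_juvenile_zero_column_consistent(self, genotyped_dataset):
        # juveniles compared only with other juveniles cannot contain true
        # parent-offspring pairs: the zero-exclusion column must be
        # explained by the false-positive prediction alone
        pop, samples, panel = genotyped_dataset
        ju = samples[samples.stage == "juvenile"]
        jp = panel.subset(ju.fish_id.to_numpy())
        models = {l: estimate_allele_freqs(panel, l) for l in panel.loci}
        pseudo_adult = ju[["fish_id", "capture_year"]].copy()
        comps = build_comparisons(jp, pseudo_adult, jp, ju, models,
                                  fp_budget_fraction=None)
        observed = int((comps.df.n_excluding == 0).sum())
        expected = comps.df.fp_prob.sum()
        from scipy import stats
        assert observed <= stats.poisson.ppf(0.999, max(expected, 1e-6)) + 1

    def test_clean_table_bound_near_zero(self):
        tab = kin.ExclusionTable(ks=np.arange(5),
                                 counts=np.array([40, 0, 0, 0, 0]),
                                 expected_unrelated=np.zeros(7),
                                 n_comparisons=100000, mean_loci=22.0)
        b = false_negative_bound(tab)
        assert b.missed_mle < 0.5
        assert b.ci[0] == 0.0
        assert b.ci[1] < 5.0

    def test_bound_covers_single_realization(self, small_population):
        pop, samples = small_population
        panel = sim.simulate_genotypes(pop, samples.fish_id.tolist(), 13,
                                       miscall_rate=0.002)
        ad = samples[samples.stage == "adult"]
        ju = samples[samples.stage == "juvenile"]
        models = {l: estimate_allele_freqs(panel, l) for l in panel.loci}
        ap = panel.subset(ad.fish_id.to_numpy())
        jp = panel.subset(ju.fish_id.to_numpy())
        comps = build_comparisons(ap, ad, jp, ju, models)
        tab = exclusion_table(comps, models, ap, jp)
        bound = false_negative_bound(tab)
        truth = pop.pedigree.pop_pairs()
        df = comps.df
        is_true = np.array([(sim.base_id(a), j) in truth
                            for a, j in zip(df.adult_id, df.juvenile_id)])
        missed = int((df.n_excluding[is_true] > 0).sum())
        assert bound.ci[0] <= missed <= bound.ci[1]

    def test_no_comparisons_error(self):
        tab = kin.ExclusionTable(ks=np.arange(1), counts=np.zeros(1, int),
                                 expected_unrelated=np.zeros(7),
                                 n_comparisons=0, mean_loci=0.0)
        with pytest.raises(ValueError):
            false_negative_bound(tab)


class TestHomozygosityQC:
    def test_clean_panel_passes(self):
        panel = [sim.LocusSpec(f"C{i}", tuple(range(100, 100 + 4 * 12, 4)),
                               tuple(np.full(12, 1 / 12)), 0.0)
                 for i in range(10)]
        gp = sim.simulate_founder_panel(panel, 3000, 21, unscored=0.05)
        rep = homozygosity_qc(gp)
        assert rep.quality_trend_pass
        assert rep.long_allele_pass
        assert rep.n_loci_flagged <= 1

    def test_null_loci_show_homozygote_excess(self):
        # most loci carry nulls in the default panel; the per-locus excess
        # check must find them at large sample size
        panel = sim.default_panel()
        gp = sim.simulate_founder_panel(panel, 8000, 11, unscored=0.05)
        rep = homozygosity_qc(gp)
        flags = rep.locus_excess.set_index("locus").excess_flag
        null_loci = [s.locus_id for s in panel if s.null_freq > 0]
        clean_loci = [s.locus_id for s in panel if s.null_freq == 0]
        assert flags[null_loci].sum() >= 18
        assert flags[clean_loci].sum() <= 2

    def test_long_allele_dropout_detected(self):
        # competitive long-allele dropout at the pilot-chosen slope is
        # flagged in at least 4 of 5 replicates (>=80% power)
        panel = sim.default_panel()
        hits = 0
        for s in range(5):
            gp = sim.simulate_founder_panel(panel, 8000, 60 + s, dropout=0.15)
            hits += not homozygosity_qc(gp).long_allele_pass
        assert hits >= 4
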