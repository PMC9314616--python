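"""Segregation testing, cross back-trace and pedigree genotype propagation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tigermoth.genetics import CROSS_TYPES, cross_label, male_phenotype_distribution
from tigermoth.mendel import (
    DataError,
    ImpossibleObservationError,
    MendelianInheritanceModel,
    chi_square_gof,
    chi_square_independence,
    families_from_pedigree,
    infer_cross_from_offspring,
    pooled_segregation_test,
    propagate_pedigree_genotypes,
)
from tigermoth.simulate import SimConfig, simulate_families

from conftest import brute_force_marginals, random_pedigree


class TestChiSquareGof:
    def test_perfect_fit_is_zero(self):
        res = chi_square_gof({"white": 75, "yellow": 25}, {"white": 0.75, "yellow": 0.25})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # O=(70,30), E=(75,25): 25/75 + 25/25 = 4/3
        res = chi_square_gof({"white": 70, "yellow": 30}, {"white": 0.75, "yellow": 0.25})
        assert res.statistic == pytest.approx(4.0 / 3.0, rel=1e-12)
        assert res.df == 1

    def test_impossible_observation_raises(self):
        with pytest.raises(ImpossibleObservationError):
            chi_square_gof({"white": 0, "yellow": 30}, {"white": 1.0, "yellow": 0.0})

    def test_against_naive_pearson_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 5)
            probs = rng.dirichlet(np.ones(k))
            obs = rng.integers(1, 60, size=k)
            cells = [f"c{i}" for i in range(k)]
            res = chi_square_gof(dict(zip(cells, obs)), dict(zip(cells, probs)))
            total = obs.sum()
            stat = sum((o - p * total) ** 2 / (p * total) for o, p in zip(obs, probs))
            assert res.statistic == pytest.approx(stat, rel=1e-10)
            sp = stats.chisquare(obs, probs * total)
            assert res.statistic == pytest.approx(sp.statistic, rel=1e-10)
            assert res.p_value == pytest.approx(sp.pvalue, rel=1e-8)

    def test_independence_variant_matches_scipy(self):
        tab = np.array([[30, 10], [20, 40]])
        res = chi_square_independence(tab)
        stat, p, df, _ = stats.chi2_contingency(tab, correction=False)
        assert res.statistic == pytest.approx(stat)
        assert res.df == df


class TestPooledSegregation:
    def test_single_family_perfect_ratio(self):
        fams = pd.DataFrame([dict(family="F1", cross="WyxWy",
                                  n_male_white=75, n_male_yellow=25)])
        res = pooled_segregation_test(fams)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_excluded_families_are_skipped(self):
        fams = pd.DataFrame([
            dict(family="F1", cross="WyxWy", n_male_white=75, n_male_yellow=25, excluded=False),
            dict(family="F2", cross="WyxWy", n_male_white=0, n_male_yellow=99, excluded=True),
        ])
        res = pooled_segregation_test(fams)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_missing_cross_raises(self):
        fams = pd.DataFrame([dict(family="F1", cross=None, n_male_white=3, n_male_yellow=1)])
        with pytest.raises(ValueError):
            pooled_segregation_test(fams)

    def test_power_against_distorted_ratio(self):
        # true white fraction 0.6 under an assumed 3:1 model: rejection certain at n=2000
        rng = np.random.default_rng(1)
        nw = rng.binomial(2000, 0.6)
        fams = pd.DataFrame([dict(family="F1", cross="WyxWy",
                                  n_male_white=nw, n_male_yellow=2000 - nw)])
        assert pooled_segregation_test(fams).p_value < 1e-6

    def test_type_i_error_near_alpha(self):
        # 300 replicate family sets simulated under the true 3:1 model
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(300):
            nw = rng.binomial(100, 0.75)
            fams = pd.DataFrame([dict(family="F", cross="WyxWy",
                                      n_male_white=nw, n_male_yellow=100 - nw)])
            rejections += pooled_segregation_test(fams).p_value < 0.05
        assert 0.02 <= rejections / 300 <= 0.09


class TestCrossInference:
    def test_all_yellow_pins_both_parents(self):
        inf = infer_cross_from_offspring({"white": 0, "yellow": 28})
        assert inf.ml_labels == ("yyxyy",)
        assert inf.identifiability_class == "yyxyy"

    def test_three_to_one_ratio_points_to_double_heterozygote(self):
        inf = infer_cross_from_offspring({"white": 75, "yellow": 25})
        assert inf.ml_labels == ("WyxWy",)

    def test_all_white_is_exact_three_way_tie(self):
        inf = infer_cross_from_offspring({"white": 40, "yellow": 0})
        assert set(inf.ml_labels) == {"WWxWW", "WWxWy", "WWxyy"}
        assert inf.identifiability_class == "all-white"
        lls = [inf.log_likelihoods[c] for c in ("WWxWW", "WWxWy", "WWxyy")]
        assert max(lls) - min(lls) == 0.0

    def test_zero_offspring_rejected(self):
        with pytest.raises(ValueError):
            infer_cross_from_offspring({"white": 0, "yellow": 0})

    def test_white_offspring_excludes_double_recessive(self):
        # yyxyy and Wyxyy must never be confused when any white male is seen
        for n_yellow in (1, 5, 20):
            inf = infer_cross_from_offspring({"white": 1, "yellow": n_yellow})
            assert "yyxyy" not in inf.ml_labels

    def test_founder_prior_posterior_mode(self):
        inf = infer_cross_from_offspring({"white": 30, "yellow": 0}, founder_prior=0.5)
        assert inf.posterior is not None
        assert abs(sum(inf.posterior.values()) - 1.0) < 1e-12
        # among the tied all-white crosses the HW prior favours WWxWy
        assert inf.posterior_mode == "WWxWy"

    def test_recovery_matches_exact_enumeration_prediction(self):
        """Simulated recovery equals the Bayes error predicted by Bin(n, p)."""
        n, reps = 40, 400
        rng = np.random.default_rng(7)
        classes = {c: male_phenotype_distribution(c)["yellow"] for c in CROSS_TYPES}
        # exact prediction per cross: sum of binomial pmf over correctly classed k
        for cross, p_yel in classes.items():
            truth_class = infer_cross_from_offspring(
                {"white": 0, "yellow": n} if p_yel == 1 else
                {"white": n, "yellow": 0} if p_yel == 0 else
                {"white": int(n * (1 - p_yel)), "yellow": int(n * p_yel)}
            ).identifiability_class
            exact = sum(
                stats.binom.pmf(k, n, p_yel)
                for k in range(n + 1)
                if infer_cross_from_offspring(
                    {"white": n - k, "yellow": k}).identifiability_class == truth_class
            )
            ks = rng.binomial(n, p_yel, size=reps)
            hits = np.mean([
                infer_cross_from_offspring(
                    {"white": n - k, "yellow": k}).identifiability_class == truth_class
                for k in ks
            ])
            assert abs(hits - exact) < 3 * np.sqrt(exact * (1 - exact) / reps) + 1e-9


class TestPropagatePedigree:
    def test_white_father_of_yellow_son_is_heterozygous(self):
        ped = pd.DataFrame([
            dict(id="dad", family="F", sire="", dam="", sex="male", phenotype="white", genotype=""),
            dict(id="mom", family="F", sire="", dam="", sex="female", phenotype="", genotype=""),
            dict(id="son", family="F", sire="dad", dam="mom", sex="male", phenotype="yellow", genotype=""),
        ])
        res = propagate_pedigree_genotypes(ped).set_index("id")
        assert res.loc["dad", "p_Wy"] == pytest.approx(1.0, abs=1e-12)
        assert res.loc["son", "p_yy"] == pytest.approx(1.0, abs=1e-12)

    def test_isolated_founder_keeps_prior(self):
        ped = pd.DataFrame([dict(id="a", family="F", sire="", dam="",
                                 sex="female", phenotype="", genotype="")])
        res = propagate_pedigree_genotypes(ped, founder_prior=0.3)
        np.testing.assert_allclose(
            res[["p_WW", "p_Wy", "p_yy"]].to_numpy()[0],
            [0.09, 0.42, 0.49], atol=1e-12)

    def test_recorded_genotype_phenotype_conflict_raises(self):
        ped = pd.DataFrame([dict(id="a", family="F", sire="", dam="",
                                 sex="male", phenotype="yellow", genotype="WW")])
        with pytest.raises(DataError, match="inconsistent"):
            propagate_pedigree_genotypes(ped)

    def test_cyclic_parentage_raises(self):
        ped = pd.DataFrame([
            dict(id="a", family="F", sire="b", dam="c", sex="male", phenotype="", genotype=""),
            dict(id="b", family="F", sire="a", dam="c", sex="male", phenotype="", genotype=""),
            dict(id="c", family="F", sire="", dam="", sex="female", phenotype="", genotype=""),
        ])
        with pytest.raises(DataError, match="cyclic"):
            propagate_pedigree_genotypes(ped)

    def test_component_cap_raises(self):
        rows = [dict(id="s", family="F", sire="", dam="", sex="male", phenotype="", genotype=""),
                dict(id="d", family="F", sire="", dam="", sex="female", phenotype="", genotype="")]
        rows += [dict(id=f"k{i}", family="F", sire="s", dam="d",
                      sex="male", phenotype="", genotype="") for i in range(6)]
        ped = pd.DataFrame(rows)
        with pytest.raises(DataError, match="too large"):
            propagate_pedigree_genotypes(ped, max_component=4)

    def test_impossible_evidence_flagged_not_raised(self):
        # two yy parents cannot have a white son; evidence has probability zero
        ped = pd.DataFrame([
            dict(id="dad", family="F", sire="", dam="", sex="male", phenotype="", genotype="yy"),
            dict(id="mom", family="F", sire="", dam="", sex="female", phenotype="", genotype="yy"),
            dict(id="son", family="F", sire="dad", dam="mom", sex="male", phenotype="white", genotype=""),
        ])
        res = propagate_pedigree_genotypes(ped)
        assert not res["consistent"].any()

    def test_marginals_match_brute_force_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(15):
            ped = random_pedigree(rng)
            res = propagate_pedigree_genotypes(ped).set_index("id")
            oracle = brute_force_marginals(ped)
            assert oracle, "oracle found pedigree inconsistent"
            for i, marg in oracle.items():
                for g in ("WW", "Wy", "yy"):
                    assert res.loc[i, f"p_{g}"] == pytest.approx(marg[g], abs=1e-12)


class TestModelInterface:
    def test_fit_on_simulated_pedigree(self):
        ped, fams = simulate_families(SimConfig(families=30, offspring_per_family=40, seed=4))
        model = MendelianInheritanceModel.from_pedigree(ped)
        res = model.fit()
        assert 0.0 <= res.segregation.p_value <= 1.0
        assert len(res.inference_table) > 0
        text = res.summary()
        assert "pooled segregation test" in text

    def test_aggregation_respects_exclusion_filter(self):
        ped, fams = simulate_families(SimConfig(families=10, offspring_per_family=8, seed=1))
        agg = families_from_pedigree(ped, min_male=10, min_female=10)
        assert agg["excluded"].all()
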