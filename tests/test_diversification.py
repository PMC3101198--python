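"""Diversification rates, binomial GLMs of threat, and Mantel tests."""

import math

import numpy as np
import pytest
from scipy import stats

from caperisk.diversification import (GenusSummary, diversification_rate,
                                      fit_threat_glm, marginal_deviance,
                                      partial_mantel, read_genus_csv,
                                      spearman_rho, trait_distance_matrix,
                                      write_genus_csv)
from caperisk.synthetic import simulate_glm_dataset
from oracles import irls_binomial


class TestRate:
    @pytest.mark.parametrize("n,age,expect", [
        (1, 5.0, 0.0),
        (2, 1.0, math.log(2)),
        (10, 4.0, math.log(10) / 4),
    ])
    def test_examples(self, n, age, expect):
        assert diversification_rate(n, age) == pytest.approx(expect)

    def test_age_must_be_positive(self):
        with pytest.raises(ValueError):
            diversification_rate(5, 0.0)

    def test_scale_consistency(self):
        g = GenusSummary("g", 12, 6.0, 1, 5)
        g2 = GenusSummary("g", 12, 18.0, 1, 5)
        assert g.div_rate == pytest.approx(3 * g2.div_rate)

    def test_count_ordering_enforced(self):
        with pytest.raises(ValueError):
            GenusSummary("g", 5, 1.0, n_threatened=4, n_listed=3)


class TestGlm:
    def test_intercept_only_closed_form(self):
        # pooled 25 threatened of 100 listed: intercept = logit(0.25)
        data = [GenusSummary(f"g{i}", 10, 5.0, n_threatened=k, n_listed=10)
                for i, k in enumerate([2, 3, 2, 3, 2, 3, 2, 3, 2, 3])]
        fit = fit_threat_glm(data, predictors=())
        assert fit.coefficients["intercept"] == pytest.approx(
            math.log(25 / 75), abs=1e-8)

    def test_matches_irls_oracle(self):
        data = simulate_glm_dataset(n_genera=80, beta_age=-0.4, seed=9)
        for weighting, w in [
            ("none", None),
            ("log_records", np.array([math.log(s.n_listed + 1) for s in data])),
            ("listed_ratio", np.array([s.n_listed / s.richness_n for s in data])),
        ]:
            fit = fit_threat_glm(data, ("richness", "age"), weighting=weighting)
            X = np.column_stack([
                np.ones(len(data)),
                [math.log(s.richness_n) for s in data],
                [math.sqrt(s.age_my) for s in data],
            ])
            beta = irls_binomial(
                X, np.array([s.n_threatened for s in data], float),
                np.array([s.n_listed for s in data], float), prior_weights=w)
            got = [fit.coefficients[k] for k in ("intercept", "ln_richness",
                                                 "sqrt_age")]
            assert got == pytest.approx(list(beta), abs=1e-6)

    def test_planted_negative_age_effect_recovered(self):
        hits = 0
        for seed in range(30):
            data = simulate_glm_dataset(n_genera=200, beta_age=-0.5, seed=seed)
            fit = fit_threat_glm(data, ("age",))
            hits += (fit.coefficients["sqrt_age"] < 0 and fit.p["sqrt_age"] < 0.05)
        assert hits >= 29

    def test_constant_weights_match_unweighted(self):
        data = simulate_glm_dataset(n_genera=60, seed=4)
        # listed_ratio with all ratios equal reduces to the unweighted fit
        equal = [GenusSummary(s.genus, s.richness_n, s.age_my, s.n_threatened,
                              s.n_listed) for s in data]
        fit_u = fit_threat_glm(equal, ("age",))
        scaled = fit_threat_glm(equal, ("age",), weighting="none")
        assert fit_u.coefficients == pytest.approx(scaled.coefficients)

    def test_monotypic_genera_dropped_from_rate_models(self):
        data = simulate_glm_dataset(n_genera=50, seed=5)
        data.append(GenusSummary("mono", 1, 5.0, 0, 1))
        fit = fit_threat_glm(data, ("rate",))
        assert fit.n_dropped_rate_zero == 1
        assert fit.n_genera == 50


class TestDeviance:
    def test_nesting_reduced_at_least_full(self):
        data = simulate_glm_dataset(n_genera=150, beta_age=-0.4, seed=6)
        full = fit_threat_glm(data, ("richness", "age"))
        red = fit_threat_glm(data, ("richness",))
        assert red.deviance >= full.deviance - 1e-8

    def test_null_effect_has_near_zero_marginal_deviance(self):
        data = simulate_glm_dataset(n_genera=400, beta_age=0.0, seed=7,
                                    intercept=-0.5)
        md = marginal_deviance(data, ("richness", "age"), "age")
        assert md < 0.01

    def test_stronger_effect_larger_marginal_deviance(self):
        weak = simulate_glm_dataset(n_genera=400, beta_age=-0.15, seed=8)
        strong = simulate_glm_dataset(n_genera=400, beta_age=-0.6, seed=8)
        assert marginal_deviance(strong, ("richness", "age"), "age") > \
            marginal_deviance(weak, ("richness", "age"), "age")

    def test_two_predictor_model_wins_aic_when_both_effects_present(self):
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            data = []
            for i in range(200):
                n = int(round(math.exp(rng.uniform(math.log(2), math.log(200)))))
                age = rng.uniform(1.0, 40.0)
                eta = 0.5 + 0.35 * math.log(n) - 0.45 * math.sqrt(age)
                p = 1 / (1 + math.exp(-eta))
                listed = max(1, int(0.9 * n))
                data.append(GenusSummary(f"g{i}", n, age,
                                         int(rng.binomial(listed, p)), listed))
            both = fit_threat_glm(data, ("richness", "age")).aic
            rich = fit_threat_glm(data, ("richness",)).aic
            age_ = fit_threat_glm(data, ("age",)).aic
            wins += both < rich and both < age_
        assert wins >= 36  # >= 90%


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_rate_age_builtin_negative_correlation(self, rng):
        # richness independent of age, yet rho(age, ln n / age) is strongly
        # negative because the rate shares the 1/age factor
        age = rng.uniform(1, 40, size=200)
        n = np.exp(rng.uniform(np.log(2), np.log(200), size=200))
        rho = spearman_rho(age, np.log(n) / age)
        assert rho <= -0.7

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho(np.ones(5), np.arange(5.0))


class TestPartialMantel:
    @staticmethod
    def dist(rng, n):
        return trait_distance_matrix(rng.normal(size=n))

    def test_identical_matrices_r_one(self, rng):
        dx = self.dist(rng, 12)
        dz = self.dist(rng, 12)
        res = partial_mantel(dx, dx, dz, n_perm=99, seed=0)
        assert res["r"] == pytest.approx(1.0)
        assert res["p"] <= 0.05

    def test_conditioning_matrix_equal_to_x_rejected(self, rng):
        dx = self.dist(rng, 10)
        dy = self.dist(rng, 10)
        with pytest.raises(ValueError, match="explains dX entirely"):
            partial_mantel(dx, dy, dx, n_perm=99, seed=0)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(23)
        pvals = []
        for _ in range(200):
            dx = self.dist(rng, 12)
            dy = self.dist(rng, 12)
            dz = self.dist(rng, 12)
            pvals.append(partial_mantel(dx, dy, dz, n_perm=99,
                                        seed=int(rng.integers(2**31)))["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_asymmetric_matrix_rejected(self, rng):
        bad = rng.normal(size=(5, 5))
        good = self.dist(rng, 5)
        with pytest.raises(ValueError, match="symmetric"):
            partial_mantel(bad, good, good)


class TestIO:
    def test_genus_csv_round_trip(self, tmp_path):
        data = simulate_glm_dataset(n_genera=10, seed=3)
        path = tmp_path / "genus.csv"
        write_genus_csv(data, path)
        back = read_genus_csv(path)
        assert [s.genus for s in back] == [s.genus for s in data]
        assert all(a.div_rate == pytest.approx(b.div_rate)
                   for a, b in zip(back, data))
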