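"""ZINB pmf, mixed-model fitting, AIC selection, and fold-change conversion."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cstlong import (fit_count_model, fold_change, select_best_model,
                     simulate_count_model, zinb_pmf)
from cstlong.countmodels import CountModelFit


def make_fit(family, aic, converged=True):
    return CountModelFit(family, 0.1, 0.0, 0.2, 0.05, 0.5, 0.3, 1.0, 0.1,
                         -aic / 2, aic, converged,
                         {"PLME": 3, "NBLME": 4, "ZINBLME": 5}[family])


class TestZINBPmf:
    def test_pi_zero_reduces_to_nb(self):
        from scipy import stats
        mu, theta = 4.0, 2.5
        for y in range(10):
            nb = stats.nbinom.pmf(y, theta, theta / (theta + mu))
            assert zinb_pmf(y, mu, theta, 0.0) == pytest.approx(nb, abs=1e-12)

    def test_zero_probability_formula(self):
        from scipy import stats
        mu, theta, pi = 7.0, 1.5, 0.3
        nb0 = stats.nbinom.pmf(0, theta, theta / (theta + mu))
        assert zinb_pmf(0, mu, theta, pi) == pytest.approx(pi + (1 - pi) * nb0)
        assert zinb_pmf(3, mu, theta, pi) == pytest.approx(
            (1 - pi) * stats.nbinom.pmf(3, theta, theta / (theta + mu)))

    @pytest.mark.parametrize("mu,theta,pi", [(3.0, 1.0, 0.0), (10.0, 0.5, 0.4),
                                             (1.5, 8.0, 0.7)])
    def test_normalises_to_one(self, mu, theta, pi):
        total = zinb_pmf(np.arange(4000), mu, theta, pi).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            zinb_pmf(0, -1.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            zinb_pmf(0, 1.0, 1.0, 1.0)


class TestFoldChange:
    @pytest.mark.parametrize("beta,expected", [
        (1.549, 4.7), (1.704, 5.5), (0.754, 2.1), (-0.726, -2.1), (0.0, 1.0),
    ])
    def test_signed_convention(self, beta, expected):
        assert round(fold_change(beta), 1) == expected

    def test_antisymmetric(self):
        for b in (0.3, 1.2, 2.5):
            assert fold_change(-b) == pytest.approx(-fold_change(b))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fold_change(float("nan"))


class TestSelectBest:
    def test_lowest_aic_wins(self):
        fits = [make_fit("PLME", 3488.3), make_fit("NBLME", 2996.9),
                make_fit("ZINBLME", 2998.9)]
        assert select_best_model(fits).family == "NBLME"

    def test_unconverged_excluded(self):
        fits = [make_fit("PLME", 5864.5), make_fit("NBLME", 4852.6),
                make_fit("ZINBLME", 1000.0, converged=False)]
        assert select_best_model(fits).family == "NBLME"

    def test_tie_prefers_simpler_family(self):
        assert select_best_model([make_fit("NBLME", 100.0),
                                  make_fit("ZINBLME", 100.0)]).family == "NBLME"
        assert select_best_model([make_fit("PLME", 100.0),
                                  make_fit("NBLME", 100.0)]).family == "PLME"

    def test_all_failed_raises(self):
        with pytest.raises(ValueError, match="no converged"):
            select_best_model([make_fit("PLME", 10.0, converged=False)])


class TestFitCountModel:
    def test_null_effect_within_wald_band(self):
        df = simulate_count_model("PLME", 40, 8, beta0=-6.0, beta1=0.0,
                                  sigma_b=0.5, seed=3)
        fit = fit_count_model(df.y, df.group, df.subject, np.log(df.total), "PLME")
        assert fit.converged
        assert abs(fit.beta1) < 3 * fit.se

    def test_nb_effect_recovered(self):
        df = simulate_count_model("NBLME", 50, 8, beta0=-6.0, beta1=1.0,
                                  sigma_b=0.6, theta=2.0, seed=7)
        fit = fit_count_model(df.y, df.group, df.subject, np.log(df.total), "NBLME")
        assert fit.converged
        assert fit.beta1 == pytest.approx(1.0, abs=0.45)
        assert fit.ci_lower <= fit.beta1 <= fit.ci_upper

    def test_zero_variance_limit_matches_fixed_effect_glm(self):
        df = simulate_count_model("PLME", 30, 10, beta0=-6.0, beta1=0.8,
                                  sigma_b=0.0, seed=11)
        fit = fit_count_model(df.y, df.group, df.subject, np.log(df.total), "PLME")
        glm = sm.GLM(df.y, sm.add_constant(df.group.astype(float)),
                     offset=np.log(df.total),
                     family=sm.families.Poisson()).fit()
        assert fit.beta1 == pytest.approx(glm.params.iloc[1], abs=1e-3)

    def test_offset_invariance(self):
        df = simulate_count_model("NBLME", 25, 6, beta0=-6.0, beta1=0.5,
                                  sigma_b=0.4, theta=3.0, seed=13)
        fit1 = fit_count_model(df.y, df.group, df.subject, np.log(df.total), "NBLME")
        # scale every sample's count and total by the same factor
        fit2 = fit_count_model(df.y * 4, df.group, df.subject,
                               np.log(df.total * 4), "NBLME")
        assert fit1.beta1 == pytest.approx(fit2.beta1, abs=0.02)

    def test_zinb_nests_nb_in_likelihood(self):
        df = simulate_count_model("NBLME", 30, 8, beta0=-6.0, beta1=0.3,
                                  sigma_b=0.5, theta=2.0, seed=17)
        nb = fit_count_model(df.y, df.group, df.subject, np.log(df.total), "NBLME")
        zinb = fit_count_model(df.y, df.group, df.subject, np.log(df.total), "ZINBLME")
        assert zinb.loglik >= nb.loglik - 0.05  # free pi can only help

    def test_quadrature_node_stability(self):
        df = simulate_count_model("ZINBLME", 30, 8, beta0=-6.0, beta1=1.0,
                                  sigma_b=0.6, theta=2.0, pi=0.3, seed=19)
        f15 = fit_count_model(df.y, df.group, df.subject, np.log(df.total),
                              "ZINBLME", n_nodes=15)
        f31 = fit_count_model(df.y, df.group, df.subject, np.log(df.total),
                              "ZINBLME", n_nodes=31)
        assert f15.beta1 == pytest.approx(f31.beta1, abs=1e-3)

    def test_aic_orders_poisson_below_nb_on_overdispersed_data(self):
        df = simulate_count_model("NBLME", 40, 8, beta0=-6.0, beta1=0.5,
                                  sigma_b=0.4, theta=0.8, seed=23)
        plme = fit_count_model(df.y, df.group, df.subject, np.log(df.total), "PLME")
        nblme = fit_count_model(df.y, df.group, df.subject, np.log(df.total), "NBLME")
        assert plme.aic >= nblme.aic

    def test_bad_family_and_offsets(self):
        df = simulate_count_model("PLME", 4, 3, beta0=-6, beta1=0, sigma_b=0.1)
        with pytest.raises(ValueError, match="family"):
            fit_count_model(df.y, df.group, df.subject, np.log(df.total), "GLM")
        with pytest.raises(ValueError, match="finite"):
            fit_count_model(df.y, df.group, df.subject,
                            np.full(len(df), -np.inf), "PLME")


class TestDifferentialAbundance:
    def test_rare_taxon_absent_and_signs_recovered(self, small_table):
        from cstlong import differential_abundance, prevalence_filter
        # add a taxon below the prevalence floor
        table = small_table
        counts = table.counts.copy()
        counts["rare_taxon"] = 0
        counts.iloc[0, -1] = 3
        from cstlong import CountTable
        table2 = CountTable(counts, table.metadata)
        kept = prevalence_filter(table2, 0.25)
        assert "rare_taxon" not in kept
        out = differential_abundance(table2, n_restarts=1)
        assert "rare_taxon" not in out.index
        assert {"PLME_aic", "NBLME_aic", "ZINBLME_aic", "best_model",
                "estimate", "fold_change", "q_value"} <= set(out.columns)
        # the four Lactobacillus taxa carrying positive effects come out positive
        for taxon in ("Lactobacillus jensenii", "Lactobacillus vaginalis"):
            if taxon in out.index and out.loc[taxon, "converged"]:
                assert out.loc[taxon, "estimate"] > 0
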