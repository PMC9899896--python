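"""Dose-response fitting, trend testing, BMC solving, and gene-set medians."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from gentox.bmc import (
    DoseResponseData,
    DoseResponseModel,
    ModelFit,
    bmc_quality_filter,
    fit_dose_response_family,
    fit_relative_bmc,
    gene_set_bmc,
    lowest_bmc,
    relative_bmc_from_params,
    williams_trend_test,
)


def design(levels=(0, 0, 0, 0, 10, 10, 32, 32, 100, 100, 316, 316, 1000, 1000)):
    return np.asarray(levels, dtype=float)


def exp5_mean(x, a, b, c, d):
    return a * (c - (c - 1.0) * np.exp(-((b * x) ** d)))


class TestDataValidation:
    def test_control_required(self):
        with pytest.raises(ValueError, match="control"):
            DoseResponseData(np.array([1.0, 10.0, 1.0, 10.0]), np.zeros(4))

    def test_two_positive_levels_required(self):
        with pytest.raises(ValueError):
            DoseResponseData(np.array([0.0, 10.0, 10.0]), np.zeros(3))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            DoseResponseData(
                np.array([0.0, 1.0, 10.0]), np.array([0.0, np.nan, 1.0])
            )


class TestWilliamsTrend:
    def test_strong_trend_minimal_p(self):
        x = np.repeat([0.0, 1.0, 3.0, 10.0], 3)
        y = np.repeat([0.0, 1.0, 2.0, 3.0], 3) + np.tile([0, 1e-4, -1e-4], 4)
        p = williams_trend_test(DoseResponseData(x, y), n_perm=200, rng=0)
        assert p == pytest.approx(1 / 201, abs=0.02)

    def test_null_p_uniform(self):
        """Under exchangeability, permutation p-values are ~Uniform(0,1)."""
        rng = np.random.default_rng(42)
        x = np.repeat([0.0, 1.0, 3.0, 10.0], 3)
        pvals = []
        for _ in range(120):
            y = rng.normal(0, 1, len(x))
            pvals.append(williams_trend_test(DoseResponseData(x, y), n_perm=99, rng=rng))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_matches_exhaustive_enumeration(self):
        """3 groups of n=2 with distinct responses: the permutation p equals
        the exhaustive tail probability over all assignments."""
        x = np.array([0.0, 0.0, 5.0, 5.0, 50.0, 50.0])
        y = np.array([0.1, 0.5, 0.9, 1.4, 2.2, 3.0])
        counts = np.array([2.0, 2.0, 2.0])

        def stat(yv):
            means = np.array([yv[:2].mean(), yv[2:4].mean(), yv[4:].mean()])
            ss = sum(((yv[i * 2 : i * 2 + 2] - means[i]) ** 2).sum() for i in range(3))
            s2 = ss / 3  # df = 6 - 3
            se = math.sqrt(s2 * (1 / 2 + 1 / 2))
            from scipy.optimize import isotonic_regression

            up = isotonic_regression(means, weights=counts, increasing=True).x[-1]
            dn = isotonic_regression(means, weights=counts, increasing=False).x[-1]
            tu, td = (up - means[0]) / se, (dn - means[0]) / se
            return tu if abs(tu) >= abs(td) else td

        t_obs = abs(stat(y))
        hits = sum(
            abs(stat(np.array(perm))) >= t_obs - 1e-12
            for perm in itertools.permutations(y)
        )
        exact_p = hits / math.factorial(6)
        p = williams_trend_test(DoseResponseData(x, y), n_perm=3000, rng=1)
        assert p == pytest.approx(exact_p, abs=0.03)

    def test_zero_variance_rejected(self):
        x = np.repeat([0.0, 1.0, 10.0], 2)
        y = np.repeat([0.0, 1.0, 2.0], 2)
        with pytest.raises(ValueError, match="variance"):
            williams_trend_test(DoseResponseData(x, y), n_perm=10, rng=0)


class TestFamilyFit:
    def test_flat_data_no_bmc(self):
        rng = np.random.default_rng(0)
        x = design()
        y = 5.0 + rng.normal(0, 0.01, len(x))
        fit = fit_dose_response_family(DoseResponseData(x, y), sd=1.0, n_boot=0)
        assert not fit.defined
        assert "no-crossing" in fit.flags

    def test_noiseless_exp5_recovers_analytic_bmc(self):
        """BMC from a noiseless curve matches the 1-SD equation root within 1%."""
        a, b, c, d, sd = 8.0, 1 / 400.0, 1.25, 1.8, 0.25
        x = design()
        y = exp5_mean(x, a, b, c, d)
        fit = fit_dose_response_family(DoseResponseData(x, y), sd=sd, n_boot=0)
        # analytic: a*(c-1)*(1 - exp(-(b x)^d)) = sd
        target = sd / (a * (c - 1.0))
        analytic = (-math.log(1.0 - target)) ** (1.0 / d) / b
        assert fit.bmc == pytest.approx(analytic, rel=0.01)

    def test_nested_models_likelihood_ordering(self):
        rng = np.random.default_rng(3)
        x = design()
        y = exp5_mean(x, 8.0, 1 / 300.0, 1.3, 1.0) + rng.normal(0, 0.2, len(x))
        fits = {}
        for models in (("Exp2",), ("Exp3",), ("Exp4",), ("Exp5",), ("Linear",), ("Poly2",)):
            fits[models[0]] = fit_dose_response_family(
                DoseResponseData(x, y), sd=0.2, n_boot=0, models=models
            )
        # nesting: Exp3 extends Exp2; Exp5 extends Exp4; Poly2 extends Linear
        assert fits["Exp3"].loglik >= fits["Exp2"].loglik - 1e-6
        assert fits["Exp5"].loglik >= fits["Exp4"].loglik - 1e-6
        assert fits["Poly2"].loglik >= fits["Linear"].loglik - 1e-6

    def test_aic_prefers_poorer_generator_large_n(self):
        """Data generated by Exp4 at negligible noise: AIC never picks the
        richer Exp5 over Exp4."""
        rng = np.random.default_rng(4)
        x = np.concatenate([np.zeros(40), np.repeat(np.geomspace(10, 1000, 8), 20)])
        y = exp5_mean(x, 8.0, 1 / 300.0, 1.3, 1.0) + rng.normal(0, 1e-4, len(x))
        m = DoseResponseModel(
            DoseResponseData(x, y), sd=0.25, models=("Exp4", "Exp5")
        ).fit(n_boot=0)
        assert m.model == "Exp4"

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        x = design()
        y = exp5_mean(x, 8.0, 1 / 300.0, 1.3, 1.5) + rng.normal(0, 0.1, len(x))
        k = 7.3
        f1 = fit_dose_response_family(DoseResponseData(x, y), sd=0.1, n_boot=50, rng=1)
        f2 = fit_dose_response_family(DoseResponseData(k * x, y), sd=0.1, n_boot=50, rng=1)
        assert f2.bmc == pytest.approx(k * f1.bmc, rel=0.01)
        assert f2.bmcl == pytest.approx(k * f1.bmcl, rel=0.05)
        assert f2.bmcu == pytest.approx(k * f1.bmcu, rel=0.05)

    def test_bootstrap_limits_bracket_estimate(self):
        rng = np.random.default_rng(6)
        x = design()
        y = exp5_mean(x, 8.0, 1 / 300.0, 1.3, 1.5) + rng.normal(0, 0.15, len(x))
        fit = fit_dose_response_family(DoseResponseData(x, y), sd=0.15, n_boot=80, rng=2)
        assert fit.bmcl <= fit.bmc <= fit.bmcu


class TestRelativeBmc:
    def test_closed_form_b_ln2(self):
        """a=1, c=3, d=1 at CES=1.0: BMC = b ln 2, recovered on noiseless data."""
        b = 20.0
        x = design(levels=(0, 0, 0, 1, 1, 3, 3, 10, 10, 32, 32, 100, 100))
        y = 1.0 * (3.0 - 2.0 * np.exp(-(x / b)))
        fit = fit_relative_bmc(DoseResponseData(x, y, "fold-change"), ces=1.0, n_boot=0)
        assert relative_bmc_from_params(b, 3.0, 1.0, 1.0) == pytest.approx(b * math.log(2))
        assert fit.bmc == pytest.approx(b * math.log(2), rel=1e-3)

    def test_ces_zero_rejected(self):
        x = design()
        y = np.ones_like(x)
        with pytest.raises(ValueError):
            fit_relative_bmc(DoseResponseData(x, y, "fold-change"), ces=0.0)

    def test_plateau_below_ces_flagged(self):
        rng = np.random.default_rng(1)
        x = design()
        y = (1.2 - 0.2 * np.exp(-(x / 50.0))) * rng.lognormal(0, 0.01, len(x))
        fit = fit_relative_bmc(DoseResponseData(x, y, "fold-change"), ces=1.0, n_boot=0)
        assert not fit.defined
        assert "plateau" in fit.flags

    def test_lowest_bmc_selection(self):
        mk = lambda bmc: ModelFit(
            model="Exp5-rel", params={}, loglik=0.0, aic=0.0, fit_pvalue=1.0,
            sigma=0.1, bmc=bmc, bmcl=bmc / 2, bmcu=bmc * 2,
        )
        fits = {"a": mk(120.0), "b": mk(80.0), "c": mk(float("nan"))}
        name, fit = lowest_bmc(fits)
        assert name == "b"
        assert fit.bmc == 80.0

    def test_lowest_bmc_all_undefined(self):
        mk = ModelFit(
            model="Exp5-rel", params={}, loglik=0.0, aic=0.0, fit_pvalue=1.0,
            sigma=0.1, bmc=float("nan"), bmcl=float("nan"), bmcu=float("nan"),
        )
        assert lowest_bmc({"a": mk}) == (None, None)


class TestQualityFilter:
    def _fit(self, bmc=10.0, bmcl=5.0, bmcu=20.0, fit_p=0.5):
        return ModelFit(
            model="Exp5", params={}, loglik=0.0, aic=0.0, fit_pvalue=fit_p,
            sigma=0.1, bmc=bmc, bmcl=bmcl, bmcu=bmcu,
        )

    def test_passing_fit(self):
        assert bmc_quality_filter(self._fit()) is None

    def test_each_rule_fires_alone(self):
        assert bmc_quality_filter(self._fit(bmc=float("nan"))) == "no_bmc"
        assert bmc_quality_filter(self._fit(fit_p=0.05)) == "fit_p"
        # BMC 10, BMCL 0.4: ratio 25 >= 20
        assert bmc_quality_filter(self._fit(bmcl=0.4, bmcu=12.0)) == "bmc_bmcl_ratio"
        assert bmc_quality_filter(self._fit(bmcl=9.0, bmcu=250.0)) == "bmcu_bmc_ratio"
        # ratios 10/0.55=18.2 and 21/10=2.1 pass; 21/0.55=38.2 passes; tighten
        assert (
            bmc_quality_filter(self._fit(bmc=10.0, bmcl=0.51, bmcu=21.0))
            == "bmcu_bmcl_ratio"
        )


class TestGeneSetBmc:
    def test_flat_genes_empty_result(self):
        rng = np.random.default_rng(0)
        x = design()
        data = {
            f"g{i}": DoseResponseData(x, 8.0 + rng.normal(0, 0.25, len(x)))
            for i in range(5)
        }
        out = gene_set_bmc(data, n_perm=50, n_boot=100, n_boot_gene=0, rng=1)
        assert out.empty
        assert math.isnan(out.median_bmc)
        assert out.filter_counts["prefilter"] == 5

    def test_fold_change_floor_blocks_weak_genes(self):
        """A clear trend below the 1.5-fold floor stays prefiltered."""
        rng = np.random.default_rng(2)
        x = design()
        trend = 0.3 * (x / x.max())  # max shift 0.3 log2 = 1.23-fold < 1.5
        data = {"weak": DoseResponseData(x, 8.0 + trend + rng.normal(0, 0.02, len(x)))}
        out = gene_set_bmc(data, n_perm=100, n_boot=100, n_boot_gene=0, rng=1)
        assert out.empty
        assert out.filter_counts["prefilter"] == 1

    def test_median_and_ci_from_responsive_genes(self, bmc_study_config):
        from gentox.pipeline import _expression_gene_data
        from gentox.simulate import true_expression_bmc

        cfg = bmc_study_config
        gene_data = _expression_gene_data(cfg, "DDI-X")
        out = gene_set_bmc(
            gene_data, n_perm=50, n_boot=500, n_boot_gene=30,
            sd=cfg.noise_sd, rng=3,
        )
        true_bmc = true_expression_bmc(cfg, cfg.compounds[0])
        assert not out.empty
        assert out.ci_lower <= out.median_bmc <= out.ci_upper
        # the median lands near the known common BMC of the responsive genes
        assert out.median_bmc == pytest.approx(true_bmc, rel=0.35)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gene_set_bmc({})
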