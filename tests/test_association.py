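"""Association machinery: transforms, regression, stepwise, genomic control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
import statsmodels.api as sm

from splicelocus import assoc
from splicelocus.panel import VariantDef
from splicelocus.sim.genotypes import simulate_haplotypes
from splicelocus.sim.phenotypes import SimPhenoConfig, simulate_phenotypes


class TestInverseNormalTransform:
    def test_three_values(self):
        out = assoc.inverse_normal_transform([1.0, 2.0, 3.0])
        assert out == pytest.approx([-0.67448975, 0.0, 0.67448975])

    def test_monotone_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, size=50)
        assert assoc.inverse_normal_transform(x) == pytest.approx(
            assoc.inverse_normal_transform(np.exp(x) + 5)
        )

    def test_large_sample_moments(self):
        rng = np.random.default_rng(2)
        out = assoc.inverse_normal_transform(rng.normal(size=10_000))
        assert abs(out.mean()) < 0.05
        assert abs(out.std() - 1.0) < 0.03

    def test_ties_and_missing(self):
        out = assoc.inverse_normal_transform([1.0, 1.0, np.nan, 2.0])
        assert np.isnan(out[2])
        assert out[0] == out[1] < out[3]

    def test_all_identical_maps_to_zero(self):
        assert assoc.inverse_normal_transform([5.0, 5.0, 5.0]) == pytest.approx(
            [0.0, 0.0, 0.0]
        )


class TestAdjustPhenotype:
    def test_no_covariates_equals_int(self):
        df = pd.DataFrame({"individual": list("abcd"), "trait": [4.0, 2.0, 3.0, 1.0]})
        out = assoc.adjust_phenotype(df)
        expected = assoc.inverse_normal_transform(df["trait"])
        assert out.to_numpy() == pytest.approx(expected)

    def test_sex_effect_removed(self):
        rng = np.random.default_rng(3)
        n = 5000
        sex = rng.integers(0, 2, n)
        df = pd.DataFrame(
            {
                "individual": [f"i{k}" for k in range(n)],
                "trait": 4.0 + 0.5 * sex + rng.normal(0, 1, n),
                "sex": sex,
            }
        )
        adj = assoc.adjust_phenotype(df, ["sex"])
        res = assoc.linear_assoc(sex, adj.to_numpy())
        assert abs(res.beta_sd) < 3 * res.se

    def test_duplicate_measurements_collapse(self):
        df = pd.DataFrame(
            {"individual": ["a", "a", "b", "b", "c"], "trait": [1, 2, 3, 4, 5.0]}
        )
        out = assoc.adjust_phenotype(df)
        assert len(out) == 3

    def test_single_level_covariate_dropped(self):
        df = pd.DataFrame(
            {"individual": list("abcd"), "trait": [1, 2, 3, 4.0], "site": ["x"] * 4}
        )
        with pytest.warns(UserWarning, match="single level"):
            assoc.adjust_phenotype(df, ["site"])


class TestLinearAssoc:
    def test_matches_normal_equations_oracle(self):
        """On a small dataset the fit agrees with an independent
        statsmodels OLS solve to 1e-8."""
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, 25).astype(float)
        z = rng.normal(size=25)
        y = 0.3 * d - 0.2 * z + rng.normal(size=25)
        res = assoc.linear_assoc(d, y, trait_sd=1.18,
                                 condition_on=pd.DataFrame({"z": z}))
        X = sm.add_constant(np.column_stack([d, z]))
        fit = sm.OLS(y, X).fit()
        assert res.beta_sd == pytest.approx(fit.params[1], abs=1e-8)
        assert res.se == pytest.approx(fit.bse[1], abs=1e-8)
        assert res.beta_units == pytest.approx(res.beta_sd * 1.18)

    def test_exact_fit_underflow_guard(self):
        d = np.arange(100, dtype=float)
        res = assoc.linear_assoc(d, 0.1 * d)
        assert res.beta_sd == pytest.approx(0.1)
        assert 0 < res.p < 1e-100

    def test_null_p_uniform(self):
        """Null P values are uniform: KS over 500 independent simulations."""
        rng = np.random.default_rng(5)
        n = 2000
        d = rng.binomial(2, 0.3, n).astype(float)
        ps = []
        for _ in range(500):
            y = rng.normal(size=n)
            ps.append(assoc.linear_assoc(d, y).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_dosage_rejected(self):
        with pytest.raises(assoc.DegenerateVariantError):
            assoc.linear_assoc(np.ones(10), np.random.default_rng(0).normal(size=10))

    def test_conditional_orthogonality_exclusive_variants(self):
        """Variants on mutually exclusive haplotypes: conditioning moves
        the estimate by less than 2 SE (near-identical adjusted/unadjusted
        effects)."""
        defs = [
            VariantDef("x", "chr1", 1, "G", "A", 0.022),
            VariantDef("y", "chr1", 2, "G", "A", 0.034),
        ]
        panel = simulate_haplotypes(defs, 50_000, [["x", "y"]], seed=6)
        pheno = simulate_phenotypes(
            panel, SimPhenoConfig(effects={"x": -0.44, "y": -0.13}, seed=7)
        )
        y = pheno["trait"].to_numpy()
        dx = panel.genotype("x").astype(float)
        dy = pd.DataFrame({"y": panel.genotype("y").astype(float)})
        plain = assoc.linear_assoc(dx, y)
        conditional = assoc.linear_assoc(dx, y, condition_on=dy)
        assert abs(plain.beta_sd - conditional.beta_sd) < 2 * plain.se
        assert abs(conditional.beta_sd - (-0.44)) < 2 * conditional.se


class TestLogisticAssoc:
    def test_matches_contingency_odds_ratio(self):
        """With one binary predictor and no covariates the ML odds ratio is
        the 2x2 cross-product ratio."""
        rng = np.random.default_rng(8)
        carrier = rng.integers(0, 2, 4000)
        p = np.where(carrier == 1, 0.35, 0.2)
        status = (rng.random(4000) < p).astype(float)
        res = assoc.logistic_assoc(carrier.astype(float), status)
        a = ((carrier == 1) & (status == 1)).sum()
        b = ((carrier == 1) & (status == 0)).sum()
        c = ((carrier == 0) & (status == 1)).sum()
        d = ((carrier == 0) & (status == 0)).sum()
        assert res.beta_units == pytest.approx(a * d / (b * c), abs=1e-6)

    def test_null_log_or_small(self):
        rng = np.random.default_rng(9)
        d = rng.binomial(2, 0.2, 5000).astype(float)
        status = rng.integers(0, 2, 5000).astype(float)
        res = assoc.logistic_assoc(d, status)
        assert abs(res.beta_sd) < 3 * res.se

    def test_complete_separation_flagged(self):
        d = np.array([0.0] * 10 + [1.0] * 10)
        status = np.array([0.0] * 10 + [1.0] * 10)
        res = assoc.logistic_assoc(d, status)
        assert res.flagged is not None
        assert np.isnan(res.beta_sd)


class TestStepwise:
    def test_all_null_region_empty(self):
        rng = np.random.default_rng(10)
        dos = pd.DataFrame(
            rng.binomial(2, 0.2, size=(5000, 20)).astype(float),
            columns=[f"v{i}" for i in range(20)],
        )
        y = rng.normal(size=5000)
        assert assoc.stepwise_select(dos, y, threshold=5e-8) == []

    def test_perfect_duplicate_tie_broken_by_position(self):
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.3, 20_000).astype(float)
        y = 0.2 * g + rng.normal(size=20_000)
        dos = pd.DataFrame({"late": g, "early": g})
        sel = assoc.stepwise_select(
            dos, y, threshold=1e-4, positions={"late": 200, "early": 100}
        )
        assert [r.variant for r in sel] == ["early"]


class TestGenomicControl:
    def test_null_lambda_unity(self):
        rng = np.random.default_rng(12)
        chi2 = rng.chisquare(1, 300_000)
        gc, corrected = assoc.genomic_control(chi2)
        assert gc.lambda_g == pytest.approx(1.0, abs=0.01)
        assert corrected == pytest.approx(chi2 / max(gc.lambda_g, 1.0))

    def test_inflated_lambda_recovered(self):
        """Scale equivariance of the median: 1.4x chi-square draws give
        lambda 1.40."""
        rng = np.random.default_rng(13)
        gc, _ = assoc.genomic_control(1.4 * rng.chisquare(1, 300_000))
        assert gc.lambda_g == pytest.approx(1.40, abs=0.02)

    def test_deflation_clamped(self):
        rng = np.random.default_rng(14)
        chi2 = 0.5 * rng.chisquare(1, 1000)
        gc, corrected = assoc.genomic_control(chi2)
        assert gc.lambda_g < 1
        assert corrected == pytest.approx(chi2)

    def test_gc_monotonicity(self):
        rng = np.random.default_rng(15)
        chi2 = 1.3 * rng.chisquare(1, 10_000)
        _, corrected = assoc.genomic_control(chi2)
        assert (assoc.corrected_p(corrected) >= stats.chi2.sf(chi2, 1) - 1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assoc.genomic_control([])


class TestInfoAndScales:
    def test_hard_calls_info_one(self):
        rng = np.random.default_rng(16)
        g = rng.binomial(1, 0.3, (20_000, 2)).astype(float)
        assert assoc.imputation_info(g, g.mean()) == pytest.approx(1.0, abs=0.02)

    def test_constant_dosage_zero(self):
        assert assoc.imputation_info(np.full(100, 0.6), 0.3) == 0.0

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            assoc.imputation_info(np.zeros(10), 0.0)

    @pytest.mark.parametrize(
        "beta_log,expected", [(0.0, 0.0), (np.log(1.22), 22.0)]
    )
    def test_percent_change(self, beta_log, expected):
        assert assoc.percent_change_effect(beta_log) == pytest.approx(expected)

    def test_percent_change_recovery_lognormal(self):
        """x0.88 multiplicative effect on a log-normal trait recovers
        -12% via the log-scale pipeline."""
        rng = np.random.default_rng(17)
        n = 50_000
        g = rng.binomial(2, 0.2, n).astype(float)
        log_trait = 1.0 + np.log(0.88) * g + rng.normal(0, 0.5, n)
        adj = assoc.inverse_normal_transform(log_trait)
        res = assoc.linear_assoc(g, adj, trait_sd=np.std(log_trait))
        assert assoc.percent_change_effect(res.beta_units) == pytest.approx(
            -12.0, abs=1.5
        )
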