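import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import betafeedback as bf
from betafeedback.stats import GlmeSpec, MODEL_REGISTRY


class TestPairedCompare:
    def test_identical_samples(self):
        x = np.arange(10.0)
        res = bf.paired_compare(x, x)
        assert res.statistic == pytest.approx(0.0, abs=1e-12) or np.isnan(res.statistic)
        assert res.p_corrected == pytest.approx(1.0)

    def test_normal_shift_takes_t_branch_and_detects(self):
        rng = np.random.default_rng(42)
        x = rng.normal(1.0, 1.0, 21)
        y = np.zeros(21)
        res = bf.paired_compare(x, y)
        assert res.test == "paired_t"
        assert res.p_raw < 0.05

    def test_heavy_tails_usually_take_wilcoxon_branch(self):
        branches = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d = rng.standard_cauchy(30)
            branches.append(bf.paired_compare(d, np.zeros(30)).test)
        assert branches.count("wilcoxon") > 10

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 15), rng.normal(0.4, 1, 15)
        a = bf.paired_compare(x, y)
        b = bf.paired_compare(y, x)
        assert a.statistic == pytest.approx(-b.statistic) or a.test == "wilcoxon"
        assert a.p_raw == pytest.approx(b.p_raw)

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 10)
        res = bf.paired_compare(x, x + rng.normal(0, 1, 10) * 0.01, n_comparisons=50)
        assert res.p_corrected <= 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bf.paired_compare([1, 2, 3, 4, 5], [1, 2, 3, 4])


class TestCorrelate:
    def test_exact_lines(self):
        x = np.arange(10.0)
        assert bf.correlate(x, x)[0] == pytest.approx(1.0)
        assert bf.correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_independent_null(self):
        rng = np.random.default_rng(11)
        r, p = bf.correlate(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            bf.correlate(np.ones(10), np.arange(10.0))


def _simulate_ig_trials(n_per_group=100, n_groups=10, k_beta=0.006, k_gamma=-0.009,
                        sigma_b=0.04, lam=25.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        b = rng.normal(0, sigma_b)
        beta = rng.normal(0.0, 3.0, n_per_group)
        gamma = rng.normal(0.0, 3.0, n_per_group)
        mu = 0.5 + b + k_beta * beta + k_gamma * gamma
        mu = np.maximum(mu, 0.05)
        rt = sstats.invgauss.rvs(mu / lam, scale=lam, random_state=rng)
        for j in range(n_per_group):
            rows.append(dict(hemisphere=f"H{g}", rt=rt[j], beta_pre_db=beta[j],
                             gamma_pre_db=gamma[j], valid=True))
    return pd.DataFrame(rows)


class TestFitGlme:
    def test_ig_parameter_recovery_within_2se(self):
        table = _simulate_ig_trials(seed=5)
        spec = GlmeSpec("rec", "rt", ["beta_pre_db", "gamma_pre_db"])
        res = bf.fit_glme(table, spec)
        cs = res.coefficients.set_index("term")
        for term, truth in [("beta_pre_db", 0.006), ("gamma_pre_db", -0.009)]:
            est, se = cs.loc[term, "estimate"], cs.loc[term, "se"]
            assert abs(est - truth) < 2 * se
        assert cs.loc["beta_pre_db", "estimate"] > 0
        assert cs.loc["gamma_pre_db", "estimate"] < 0
        assert res.scale_params["lambda"] > 0
        assert 0.0 <= res.r2 <= 1.0

    def test_ig_matches_statsmodels_glm_when_no_group_variance(self):
        # with zero between-group variance, the mixed fit should approach the
        # plain inverse-Gaussian GLM with identity link (independent oracle)
        import statsmodels.api as sm
        table = _simulate_ig_trials(sigma_b=0.0, n_groups=4, n_per_group=150, seed=9)
        spec = GlmeSpec("x", "rt", ["beta_pre_db", "gamma_pre_db"])
        ours = bf.fit_glme(table, spec).coefficients.set_index("term")
        X = sm.add_constant(table[["beta_pre_db", "gamma_pre_db"]])
        ref = sm.GLM(table["rt"], X,
                     family=sm.families.InverseGaussian(sm.families.links.Identity())
                     ).fit()
        for term, ref_name in [("intercept", "const"), ("beta_pre_db", "beta_pre_db"),
                               ("gamma_pre_db", "gamma_pre_db")]:
            assert ours.loc[term, "estimate"] == pytest.approx(
                ref.params[ref_name], abs=3 * ref.bse[ref_name])

    def test_intercept_only_on_constant_response(self):
        table = pd.DataFrame(dict(
            rt=np.full(40, 0.5), hemisphere=np.repeat(["A", "B"], 20), valid=True))
        res = bf.fit_glme(table, GlmeSpec("c", "rt", []))
        assert res.coef("intercept") == pytest.approx(0.5, rel=1e-3)
        assert res.r2 == 0.0

    def test_null_predictor_pvalues_roughly_uniform(self):
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame(dict(
                y=rng.normal(0, 1, 120),
                x=rng.normal(0, 1, 120),
                hemisphere=np.repeat([f"H{i}" for i in range(6)], 20),
            ))
            res = bf.fit_glme(table, GlmeSpec("n", "y", ["x"], distribution="normal"))
            hits += res.pvalue("x") < 0.05
        assert hits <= 6  # ~5 % expected; allow binomial slack

    def test_aic_prefers_true_model_over_intercept(self):
        table = _simulate_ig_trials(seed=13)
        full = bf.fit_glme(table, MODEL_REGISTRY["m2"].__class__(
            "full", "rt", ["beta_pre_db", "gamma_pre_db"]))
        null = bf.fit_glme(table, GlmeSpec("null", "rt", []))
        assert full.aic < null.aic

    def test_singular_design_names_offender(self):
        table = _simulate_ig_trials(n_groups=3, n_per_group=30, seed=1)
        table["beta_copy"] = table["beta_pre_db"]
        with pytest.raises(ValueError, match="beta_copy"):
            bf.fit_glme(table, GlmeSpec("s", "rt", ["beta_pre_db", "beta_copy"]))

    def test_requires_two_groups(self):
        table = _simulate_ig_trials(n_groups=1, n_per_group=30)
        with pytest.raises(ValueError, match="grouping"):
            bf.fit_glme(table, GlmeSpec("g", "rt", ["beta_pre_db"]))


class TestMatchBetaTrials:
    def test_identical_distributions_balance(self, rng):
        x = rng.normal(0, 1, 80)
        ia, ib = bf.match_beta_trials(x, x.copy())
        assert len(ia) == 60  # 75 % of 80
        assert abs(x[ia].mean() - x[ib].mean()) < 0.05

    def test_disjoint_distributions_fail_with_diagnostic(self, rng):
        with pytest.raises(ValueError, match="balance"):
            bf.match_beta_trials(rng.normal(0, 0.1, 40), rng.normal(10, 0.1, 40))

    def test_matching_attenuates_beta_driven_rt_difference(self, rng):
        # RT depends only on beta; the conditions differ only through beta.
        beta_t = rng.normal(-0.5, 1.0, 200)
        beta_n = rng.normal(+0.5, 1.0, 200)
        rt_t = 0.5 + 0.05 * beta_t
        rt_n = 0.5 + 0.05 * beta_n
        raw_gap = abs(rt_t.mean() - rt_n.mean())
        ia, ib = bf.match_beta_trials(beta_t, beta_n)
        matched_gap = abs(rt_t[ia].mean() - rt_n[ib].mean())
        assert matched_gap < 0.25 * raw_gap

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            bf.match_beta_trials([], [1.0, 2.0])


def test_registry_covers_reaction_time_model_family():
    assert {f"m{i}" for i in range(1, 10)} <= set(MODEL_REGISTRY)
    assert MODEL_REGISTRY["m6"].predictors == \
        ["torn", "beta_pre_db", "gamma_pre_db", "alpha_pre_db"]
    assert all(MODEL_REGISTRY[f"m{i}"].distribution == "inverse_gaussian"
               for i in range(1, 10))
    assert MODEL_REGISTRY["tremor"].distribution == "normal"
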