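import json
import shutil
import subprocess

import numpy as np
import pytest
from scipy.special import gammaln, ndtr

from latmask import (
    MIGRAINE_AURA,
    ModelSpec,
    PopulationParams,
    ProbitGLMM,
    SessionDesign,
    ValidationError,
    baseline_spec,
    build_design,
    flanker_spec,
    simulate_dataset,
)
from latmask.model import ConvergenceError

sm = pytest.importorskip("statsmodels.api")


def _statsmodels_probit(table):
    """Independent plain-probit ML fit on binomially aggregated data."""
    agg = (
        table.groupby(["observer_id", "group", "contrast"])["correct"]
        .agg(["sum", "count"])
        .reset_index()
    )
    g = (agg["group"] == MIGRAINE_AURA).astype(float)
    X = np.column_stack([np.ones(len(agg)), agg["contrast"], g, g * agg["contrast"]])
    y = np.column_stack([agg["sum"], agg["count"] - agg["sum"]])
    fit = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Probit())).fit()
    # constant separating the binomial and Bernoulli loglikelihood conventions
    n, k = agg["count"].to_numpy(), agg["sum"].to_numpy()
    const = float((gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)).sum())
    return fit, const


class TestBuildDesign:
    def test_baseline_spec_has_four_columns(self, baseline_table):
        bundle = build_design(baseline_table, baseline_spec())
        assert bundle.X.shape[1] == 4
        assert bundle.spec.fixed_terms == ("intercept", "contrast", "group", "group:contrast")

    def test_flanker_spec_has_eight_columns(self, small_design, hetero_pop):
        table = simulate_dataset(
            PopulationParams(group_sizes=(3, 3)), small_design, seed=5
        )
        bundle = build_design(table, flanker_spec())
        assert bundle.X.shape[1] == 8
        # distance terms exclude the baseline block
        assert bundle.n_rows == 6 * 3 * 4  # obs x flanker conditions x levels

    def test_binomial_coding_row_count(self, baseline_table):
        bundle = build_design(baseline_table, baseline_spec(), coding="binomial")
        assert bundle.n_rows == 55 * 7

    def test_single_group_with_group_terms_rejected(self, baseline_table):
        controls = baseline_table[baseline_table["group"] == "control"]
        with pytest.raises(ValidationError, match="single group"):
            build_design(controls, baseline_spec())

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec(("intercept", "intercept"))

    def test_unknown_random_term_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec(("intercept",), random_terms=("distance",))


class TestFitAgainstOracles:
    @pytest.fixture(scope="class")
    @staticmethod
    def glmm_fit(zero_sigma_table):
        model = ProbitGLMM.from_trials(zero_sigma_table, baseline_spec())
        return model, model.fit()

    def test_fixed_effects_match_plain_probit_oracle(self, zero_sigma_table, glmm_fit):
        _, res = glmm_fit
        oracle, _ = _statsmodels_probit(zero_sigma_table)
        assert res.converged
        assert np.all(np.abs(res.beta - oracle.params) < 2 * oracle.bse)

    def test_pinned_zero_sigma_equals_glm_likelihood(self, zero_sigma_table):
        model = ProbitGLMM.from_trials(zero_sigma_table, baseline_spec())
        pinned = model.fit(fix_sigma=np.zeros((2, 2)))
        oracle, const = _statsmodels_probit(zero_sigma_table)
        assert pinned.loglik == pytest.approx(oracle.llf - const, abs=1e-6)
        assert np.allclose(pinned.beta, oracle.params, atol=1e-6)

    def test_loglik_never_below_glm_start(self, glmm_fit):
        model, res = glmm_fit
        glm_loglik = model.fit(fix_sigma=np.zeros((2, 2))).loglik
        assert res.loglik >= glm_loglik - 1e-6

    def test_quadrature_order_converged(self, baseline_table):
        model = ProbitGLMM.from_trials(baseline_table, baseline_spec())
        res = model.fit(compute_cov=False)
        ll5 = model.loglike(res.beta, res.sigma_re, n_quad=5)
        ll15 = model.loglike(res.beta, res.sigma_re, n_quad=15)
        assert abs(ll5 - ll15) < 1e-4

    def test_estimated_sigma_is_psd(self, baseline_table):
        res = ProbitGLMM.from_trials(baseline_table, baseline_spec()).fit(
            compute_cov=False
        )
        assert np.linalg.eigvalsh(res.sigma_re).min() >= -1e-12

    def test_codings_share_likelihood_and_estimates(self, zero_sigma_table):
        spec = baseline_spec()
        mb = ProbitGLMM.from_trials(zero_sigma_table, spec, coding="binomial")
        mt = ProbitGLMM.from_trials(zero_sigma_table, spec, coding="bernoulli")
        beta = np.array([-0.5, 29.0, 0.0, 0.0])
        sigma = np.diag([0.04, 4.0])
        assert mt.loglike(beta, sigma) == pytest.approx(mb.loglike(beta, sigma), abs=1e-8)
        rb = mb.fit(compute_cov=False)
        rt = mt.fit(compute_cov=False)
        assert rb.loglik == pytest.approx(rt.loglik, rel=1e-6, abs=1e-3)
        assert np.allclose(rb.beta, rt.beta, atol=2e-3)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestLme4CrossCheck:
    def test_small_fit_agrees_with_glmer(self, tmp_path):
        pop = PopulationParams(
            beta=(-0.3, 25.0, -0.3, 8.0),
            sigma_re=((0.09, 0.0), (0.0, 9.0)),
            group_sizes=(10, 10),
        )
        design = SessionDesign(flanker_distances=())
        table = simulate_dataset(pop, design, seed=31)
        csv = tmp_path / "trials.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(lme4))
            d <- read.csv(commandArgs(TRUE)[1])
            d$g <- as.integer(d$group == "migraine_aura")
            m <- glmer(correct ~ contrast * g + (1 + contrast | observer_id),
                       family = binomial(link = "probit"), data = d)
            cat(jsonlite::toJSON(list(beta = unname(fixef(m)),
                                      se = unname(sqrt(diag(vcov(m))))), digits = 10))
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True, timeout=600
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        beta_r = np.array(ref["beta"], dtype=float)
        se_r = np.array(ref["se"], dtype=float)
        res = ProbitGLMM.from_trials(table, baseline_spec()).fit(compute_cov=False)
        # glmer orders terms 1, contrast, g, contrast:g — same as ours
        assert np.all(np.abs(res.beta - beta_r) < 2 * se_r)


class TestWaldReport:
    def test_t_is_estimate_over_se_and_p_symmetric(self, zero_sigma_table):
        res = ProbitGLMM.from_trials(zero_sigma_table, baseline_spec()).fit(
            fix_sigma=np.zeros((2, 2))
        )
        table = res.wald_table()
        assert np.allclose(table["t"], table["estimate"] / table["se"])
        assert (table["dof"] == res.n_rows - 4).all()
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()

    def test_unconverged_fit_refuses_wald(self, zero_sigma_table):
        res = ProbitGLMM.from_trials(zero_sigma_table, baseline_spec()).fit(
            fix_sigma=np.zeros((2, 2))
        )
        res.converged = False
        with pytest.raises(ConvergenceError):
            res.wald_table()

    def test_null_group_interaction_rejection_rate(self):
        """Wald test of group:contrast holds its size under the null."""
        design = SessionDesign(flanker_distances=())
        pop = PopulationParams(
            beta=(-0.5, 29.0, 0.0, 0.0),
            sigma_re=((0.0, 0.0), (0.0, 0.0)),
            group_sizes=(15, 15),
        )
        zero = np.zeros((2, 2))
        rejections = 0
        n_sim = 200
        for i in range(n_sim):
            table = simulate_dataset(pop, design, seed=10_000 + i)
            res = ProbitGLMM.from_trials(table, baseline_spec()).fit(fix_sigma=zero)
            p = res.wald_table().loc["group:contrast", "p"]
            rejections += p < 0.05
        rate = rejections / n_sim
        assert 0.025 <= rate <= 0.075


class TestPrediction:
    def test_probit_limits(self, zero_sigma_table):
        res = ProbitGLMM.from_trials(zero_sigma_table, baseline_spec()).fit(
            fix_sigma=np.zeros((2, 2))
        )
        res.beta = np.array([0.0, 0.0, 0.0, 0.0])
        assert res.predict_p(0.05) == pytest.approx(0.5)
        res.beta = np.array([50.0, 0.0, 0.0, 0.0])
        assert res.predict_p(0.05) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_contrast(self, zero_sigma_table):
        res = ProbitGLMM.from_trials(zero_sigma_table, baseline_spec()).fit(
            fix_sigma=np.zeros((2, 2))
        )
        c = np.linspace(0.001, 0.2, 50)
        p = res.predict_p(c)
        assert np.all(np.diff(p) > 0)

    def test_observer_effects_enter_linear_predictor(self, zero_sigma_table):
        res = ProbitGLMM.from_trials(zero_sigma_table, baseline_spec()).fit(
            fix_sigma=np.zeros((2, 2))
        )
        base = res.predict_p(0.03)
        better = res.predict_p(0.03, observer_effects=(0.5, 5.0))
        assert better > base


class TestDiagnostics:
    def test_separation_warns(self, baseline_design):
        pop = PopulationParams(
            beta=(5.0, 29.0, 0.0, 0.0),  # ceiling performance
            sigma_re=((0.0, 0.0), (0.0, 0.0)),
            group_sizes=(2, 2),
        )
        table = simulate_dataset(pop, baseline_design, seed=8)
        with pytest.warns(UserWarning, match="all-correct"):
            ProbitGLMM.from_trials(table, baseline_spec())

    def test_summary_mentions_convergence_and_terms(self, zero_sigma_table):
        res = ProbitGLMM.from_trials(zero_sigma_table, baseline_spec()).fit(
            fix_sigma=np.zeros((2, 2))
        )
        text = res.summary()
        assert "converged: True" in text
        assert "group:contrast" in text
        payload = res.to_dict()
        assert payload["converged"] and "wald" in payload
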