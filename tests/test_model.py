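"""Model operations: probabilities, likelihood, priors, sampler, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import approx_fprime
from scipy.stats import norm

import choicemix as cm
from choicemix._hmc import nuts_chain
from choicemix.model import (MixedLogitPosterior, effective_sample_size,
                             lkj_normalizer, split_rhat)
from tests.conftest import TABLE3_MEANS


class TestChoiceProbability:
    def test_indifference(self):
        assert cm.choice_probability(np.zeros(3), np.ones(3)) == 0.5

    def test_printed_example_card_probability(self, attrs, table1_pair):
        # fitted population means against the printed example card:
        # utility 0.944, choice probability ~0.720
        x = np.r_[1.0, cm.code_choice_pair(table1_pair, attrs)]
        p = cm.choice_probability(TABLE3_MEANS, x)
        assert TABLE3_MEANS @ x == pytest.approx(0.944, abs=1e-12)
        assert p == pytest.approx(0.7199, abs=5e-4)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_logistic_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        b, x = rng.normal(size=8), rng.normal(size=8)
        assert cm.choice_probability(b, x) + cm.choice_probability(b, -x) == \
            pytest.approx(1.0, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            cm.choice_probability(np.ones(3), np.ones(4))


class TestLogLikelihood:
    def _naive(self, panel, b):
        total = 0.0
        for _, row in panel.rows.reset_index(drop=True).iterrows():
            i = np.flatnonzero(panel.indiv_ids == row["indiv_id"])[0]
            x = panel.X[(panel.rows["indiv_id"] == row["indiv_id"]).to_numpy()
                        & (panel.rows["choice_id"] == row["choice_id"]).to_numpy()][0]
            p = cm.choice_probability(b[i], x)
            total += math.log(p) if row["choice"] == 1 else math.log(1 - p)
        return total

    def test_single_indifferent_row(self, small_study):
        _, _, _, panel = small_study
        params = cm.Parameters(m=np.zeros(8), b=np.zeros((panel.n_individuals, 8)))
        assert cm.log_likelihood(panel, params) == pytest.approx(
            panel.n_rows * math.log(0.5))

    def test_matches_naive_oracle(self, small_study):
        _, _, _, panel = small_study
        rng = np.random.default_rng(0)
        for _ in range(5):
            b = rng.normal(size=(panel.n_individuals, 8))
            fast = cm.log_likelihood(panel, cm.Parameters(m=np.zeros(8), b=b))
            assert fast == pytest.approx(self._naive(panel, b), abs=1e-10)

    def test_row_order_invariance(self, small_study):
        truth, respondents, choices, panel = small_study
        rng = np.random.default_rng(1)
        b = rng.normal(size=(panel.n_individuals, 8))
        shuffled = cm.assemble_panel(
            choices.sample(frac=1, random_state=3), respondents)
        # align b with the shuffled panel's individual order
        order = [np.flatnonzero(panel.indiv_ids == i)[0]
                 for i in shuffled.indiv_ids]
        a = cm.log_likelihood(panel, cm.Parameters(m=np.zeros(8), b=b))
        c = cm.log_likelihood(shuffled, cm.Parameters(m=np.zeros(8), b=b[order]))
        assert a == pytest.approx(c, rel=1e-12)

    def test_stable_at_extreme_utilities(self, small_study):
        _, _, _, panel = small_study
        b = np.full((panel.n_individuals, 8), 500.0)
        val = cm.log_likelihood(panel, cm.Parameters(m=np.zeros(8), b=b))
        assert np.isfinite(val)

    def test_saturated_row_adds_nothing(self, small_study):
        # a correctly predicted row with p ~ 1 contributes ~ log(1) = 0
        _, _, _, panel = small_study
        x = panel.X[0]
        b = 1000.0 * x / (x @ x)
        eta = b @ x
        assert eta == pytest.approx(1000.0)
        contribution = math.log(1 / (1 + math.exp(-eta))) if eta < 700 else 0.0
        assert contribution == pytest.approx(0.0, abs=1e-12)


class TestLogPrior:
    def test_normal_at_zero(self):
        params = cm.Parameters(m=np.zeros(8))
        base = cm.log_prior(params)
        one = cm.Parameters(m=np.r_[1.0, np.zeros(7)])
        # moving one mean entry from 0 to 1 changes the Normal(0,5) term
        assert base - cm.log_prior(one) == pytest.approx(
            norm.logpdf(0, scale=5) - norm.logpdf(1, scale=5))

    def test_lkj_k2_identity_closed_form(self):
        # density of LKJ(eta=2) at the 2x2 identity is 3/4
        assert cm.lkj_logpdf(np.eye(2), eta=2.0) == pytest.approx(math.log(0.75))

    def test_lkj_k3_uniform_volume(self):
        # eta=1 is the uniform density: 1 / volume of the 3x3 elliptope
        assert lkj_normalizer(3, 1.0) == pytest.approx(math.log(math.pi ** 2 / 2))

    def test_negative_sd_sentinel(self):
        params = cm.Parameters(m=np.zeros(8), s=np.r_[-1.0, np.ones(7)])
        assert cm.log_prior(params) == -math.inf

    def test_non_positive_definite_R_sentinel(self):
        R = np.eye(8)
        R[0, 1] = R[1, 0] = 1.5
        params = cm.Parameters(m=np.zeros(8), R=R)
        assert cm.log_prior(params) == -math.inf

    def test_b_term_matches_scipy(self, table3_params):
        from scipy.stats import multivariate_normal
        rng = np.random.default_rng(2)
        p = table3_params
        b = rng.normal(size=(5, 8))
        with_b = cm.Parameters(m=p.m, s=p.s, b=b)
        base = cm.log_prior(cm.Parameters(m=p.m, s=p.s))
        manual = multivariate_normal(mean=p.m, cov=np.diag(p.s ** 2)).logpdf(b).sum()
        assert cm.log_prior(with_b) - base == pytest.approx(manual, rel=1e-10)


class TestPosteriorGradient:
    def test_analytic_matches_finite_differences(self, small_study):
        _, _, _, panel = small_study
        rng = np.random.default_rng(3)
        for spec in [cm.ModelSpec(seed=0, covariates=("sexF", "consY")),
                     cm.ModelSpec(seed=0, fix_s=0.01, fix_R=np.eye(8))]:
            post = MixedLogitPosterior(panel, spec)
            theta = 0.3 * rng.standard_normal(post.n_params)
            _, grad = post.logp_grad(theta)
            num = approx_fprime(theta, lambda t: post.logp_grad(t)[0], 1e-6)
            np.testing.assert_allclose(grad, num, rtol=5e-4, atol=5e-4)

    def test_correlation_transform_is_valid(self, small_study):
        _, _, _, panel = small_study
        post = MixedLogitPosterior(panel, cm.ModelSpec(seed=0))
        rng = np.random.default_rng(4)
        theta = rng.standard_normal(post.n_params)
        out = post.constrain(theta[None, :])
        R = out["R"][0]
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)
        np.testing.assert_allclose(R, R.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(R) > 0)


class TestSampler:
    def test_recovers_correlated_gaussian(self):
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        prec = np.linalg.inv(cov)
        rng = np.random.default_rng(0)
        draws, stats = nuts_chain(lambda q: (-0.5 * q @ prec @ q, -prec @ q),
                                  np.zeros(2), 500, 2000, rng)
        np.testing.assert_allclose(draws.mean(0), 0.0, atol=0.15)
        np.testing.assert_allclose(np.cov(draws.T), cov, atol=0.25)
        assert stats.divergences == 0

    def test_prior_only_reproduces_prior(self):
        # zero-information data: posterior of m must match Normal(0, 5)
        spec = cm.ModelSpec(seed=1, chains=2, warmup=300, draws=300)
        pr = cm.sample_prior(spec)
        m = pr.stacked("m")
        assert abs(m.mean()) < 5 * 5 / math.sqrt(m.size)      # ~MC error
        assert m.std() == pytest.approx(5.0, rel=0.1)
        s = pr.stacked("s")
        assert s.min() > 0
        assert s.mean() == pytest.approx(2.5 * math.sqrt(2 / math.pi), rel=0.1)

    def test_degenerate_panel_rejected(self, small_study):
        truth, respondents, choices, _ = small_study
        one = choices[choices.indiv_id == 1]
        panel = cm.assemble_panel(one, respondents[respondents.indiv_id == 1])
        with pytest.raises(ValueError, match="individual"):
            cm.fit_model(panel, cm.ModelSpec.model1(seed=0))


class TestDiagnostics:
    def test_hand_computed_split_rhat(self):
        # 2 chains x 4 draws -> 4 half-chains of 2
        x = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]])
        halves = np.array([[1, 2], [3, 4], [2, 3], [4, 5]], dtype=float)
        n = 2
        W = halves.var(axis=1, ddof=1).mean()
        B = n * halves.mean(axis=1).var(ddof=1)
        expected = math.sqrt(((n - 1) / n * W + B / n) / W)
        assert split_rhat(x) == pytest.approx(expected, rel=1e-12)

    def test_rhat_near_one_for_iid_chains(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((4, 4000))
        assert split_rhat(x) == pytest.approx(1.0, abs=0.01)

    def test_ess_bounds_and_iid_behaviour(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((4, 500))
        ess = effective_sample_size(x)
        assert 0 < ess <= 2000
        assert ess > 1000  # iid draws: close to the total

    def test_ess_detects_autocorrelation(self):
        rng = np.random.default_rng(7)
        n = 2000
        x = np.empty((2, n))
        for c in range(2):
            e = rng.standard_normal(n)
            for t in range(1, n):
                e[t] += 0.9 * e[t - 1]
            x[c] = e
        # AR(1) with phi=0.9 has tau = 19: ESS should be far below 2n
        assert effective_sample_size(x) < 0.2 * 2 * n

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(8)
        x = rng.standard_normal((4, 400)).cumsum(axis=1) * 0.05 \
            + rng.standard_normal((4, 400))
        ds = az.convert_to_dataset(x[:, :, None])
        assert split_rhat(x) == pytest.approx(
            float(az.rhat(ds, method="split")["x"].values.squeeze()), rel=0.02)
        assert effective_sample_size(x) == pytest.approx(
            float(az.ess(ds, method="mean")["x"].values.squeeze()), rel=0.25)

    def test_single_chain_rejected(self, small_study):
        draws = cm.PosteriorDraws(params={"m": np.zeros((1, 10, 8))})
        with pytest.raises(ValueError, match="chains"):
            cm.diagnose(draws)


class TestDrawsPersistence:
    def test_save_load_roundtrip(self, tmp_path, table3_params):
        draws = cm.PosteriorDraws.constant(table3_params, n_draws=6)
        draws.params["m"] = draws.params["m"] + 0.01 * np.arange(6)[None, :, None]
        draws.meta["seed"] = 3
        draws.save(tmp_path / "draws")
        back = cm.PosteriorDraws.load(tmp_path / "draws")
        for name in ("m", "s", "R"):
            np.testing.assert_allclose(back.params[name], draws.params[name])
        assert back.meta["seed"] == 3
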