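"""Likelihood oracles, draw machinery, and fit statistics."""

import numpy as np
import pytest
from scipy import stats

import dcelogit as d
from dcelogit.estimation import (
    DrawSet,
    ModelSpec,
    ParamBundle,
    _Layout,
    _radical_inverse,
    build_panel,
    fit_mnl,
    fit_mixed,
    halton_draws,
    loglik_mnl,
    loglik_sml,
    significance_stars,
)


class TestHaltonDraws:
    def test_base2_radical_inverse_definition(self):
        got = _radical_inverse(np.arange(1, 6), 2)
        assert got == pytest.approx([1 / 2, 1 / 4, 3 / 4, 1 / 8, 5 / 8])

    def test_transformed_draw_means_are_near_zero(self):
        ds = halton_draws(1, 500, 3, seed=0)
        assert np.abs(ds.v[0].mean(axis=0)).max() < 0.02

    def test_same_sizes_reproduce_identical_draws(self):
        a = halton_draws(4, 50, 2, seed=1)
        b = halton_draws(4, 50, 2, seed=1)
        assert np.array_equal(a.v, b.v) and np.array_equal(a.w, b.w)

    def test_too_many_dimensions_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            halton_draws(1, 10, 60)


def brute_force_mnl_loglik(dataset, beta, asc):
    """Independent softmax oracle over raw long-format rows."""
    total = 0.0
    obs, coded = dataset.obs, dataset.coded
    for (_, _), rows in obs.groupby(["respondent_id", "task_id"], sort=False):
        idx = rows.index.to_numpy()
        v = coded[idx] @ beta + asc * rows["optout"].to_numpy(dtype=float)
        p = np.exp(v - v.max())
        p /= p.sum()
        total += np.log(p[rows["chosen"].to_numpy(dtype=bool)][0])
    return total


def brute_force_sml_loglik(dataset, params, draws, family):
    """Naive triple loop (respondent, draw, task) panel likelihood."""
    from dcelogit.choice_data import sdc_dummies

    obs, coded = dataset.obs, dataset.coded
    rids = list(dict.fromkeys(obs["respondent_id"]))
    dummies = sdc_dummies(dataset.respondents)
    total = 0.0
    for i, rid in enumerate(rids):
        probs = []
        for r in range(draws.n_draws):
            beta_ir = params.beta.copy()
            if params.delta is not None:
                z = dummies.loc[rid].to_numpy()[: params.delta.shape[1]]
                beta_ir = beta_ir + params.delta @ z
            gv = params.chol @ draws.v[i, r] if params.chol is not None else 0.0
            if family == "rpl":
                beta_ir = beta_ir + gv
            elif family == "gmxl":
                sigma = np.exp(-params.tau**2 / 2 + params.tau * draws.w[i, r])
                beta_ir = sigma * beta_ir + (params.gamma + sigma * (1 - params.gamma)) * gv
            prod = 1.0
            sub = obs[obs["respondent_id"] == rid]
            for _, rows in sub.groupby("task_id", sort=False):
                idx = rows.index.to_numpy()
                v = coded[idx] @ beta_ir + params.asc * rows["optout"].to_numpy(dtype=float)
                p = np.exp(v - v.max())
                p /= p.sum()
                prod *= p[rows["chosen"].to_numpy(dtype=bool)][0]
            probs.append(prod)
        total += np.log(np.mean(probs))
    return total


class TestLoglikMNL:
    def test_uniform_choice_gives_n_log_third(self, small_dataset):
        n_tasks = 25 * 6
        ll = loglik_mnl(np.zeros(8), 0.0, small_dataset)
        assert ll == pytest.approx(n_tasks * np.log(1 / 3))

    def test_matches_brute_force_softmax_oracle(self, schema, simple_prefs):
        design = d.generate_design(schema, n_tasks=3, n_alts=2, seed=20)
        resp = d.generate_respondents(5, seed=21)
        ds = d.simulate_choices(design, resp, simple_prefs, family="mnl", seed=22)
        rng = np.random.default_rng(23)
        beta = rng.normal(scale=0.5, size=8)
        beta[-1] = -0.004
        asc = -1.3
        want = brute_force_mnl_loglik(ds, beta, asc)
        got = loglik_mnl(beta, asc, ds)
        assert got == pytest.approx(want, rel=1e-12)


class TestSimulateBetaI:
    def test_rpl_with_zero_spread_returns_means(self, tiny_dataset):
        panel = build_panel(tiny_dataset)
        draws = halton_draws(3, 10, 8, seed=0)
        p = ParamBundle(beta=np.arange(8.0), chol=np.zeros((8, 8)))
        beta_i, *_ = d.simulate_beta_i(p, draws, np.zeros((3, 0)), "rpl")
        assert np.allclose(beta_i, np.arange(8.0))

    def test_gmxl_with_zero_tau_equals_rpl_draw_for_draw(self):
        draws = halton_draws(4, 25, 8, seed=0)
        chol = np.diag(np.linspace(0.1, 0.8, 8))
        p_rpl = ParamBundle(beta=np.ones(8), chol=chol)
        p_gmxl = ParamBundle(beta=np.ones(8), chol=chol, tau=0.0, gamma=0.3)
        a, *_ = d.simulate_beta_i(p_rpl, draws, np.zeros((4, 0)), "rpl")
        b, *_ = d.simulate_beta_i(p_gmxl, draws, np.zeros((4, 0)), "gmxl")
        assert np.allclose(a, b)

    def test_rpl_moments_match_mean_and_covariance(self):
        """Empirical mean and covariance over many draws reproduce
        (beta + delta z, Gamma Gamma^T)."""
        rng = np.random.default_rng(5)
        K = 3
        chol = np.tril(rng.normal(size=(K, K)))
        np.fill_diagonal(chol, np.abs(np.diag(chol)))
        beta = rng.normal(size=K)
        delta = rng.normal(size=(K, 1))
        z = np.array([[1.0]])
        n = 400_000
        draws = DrawSet(v=rng.standard_normal((1, n, K)), w=rng.standard_normal((1, n)), seed=0)
        p = ParamBundle(beta=beta, delta=delta, chol=chol)
        beta_i, *_ = d.simulate_beta_i(p, draws, z, "rpl")
        sample = beta_i[0]
        assert np.allclose(sample.mean(axis=0), beta + delta[:, 0], atol=0.01)
        assert np.allclose(np.cov(sample.T), chol @ chol.T, atol=0.02)

    def test_invalid_scale_parameters_rejected(self):
        draws = halton_draws(1, 5, 2, seed=0)
        with pytest.raises(ValueError, match="tau"):
            p = ParamBundle(beta=np.zeros(2), chol=np.eye(2), tau=-0.5, gamma=0.2)
            d.simulate_beta_i(p, draws, np.zeros((1, 0)), "gmxl")


class TestLoglikSML:
    def test_zero_spread_collapses_to_mnl(self, small_dataset):
        p = ParamBundle(beta=np.full(8, 0.2) * np.array([1, 1, 1, 1, 1, 1, 1, 0.01]),
                        asc=-1.0, chol=np.zeros((8, 8)))
        draws = halton_draws(25, 10, 8, seed=0)
        ll_mix = loglik_sml(p, small_dataset, draws, family="rpl")
        ll_mnl = loglik_mnl(p.beta, p.asc, small_dataset)
        assert ll_mix == pytest.approx(ll_mnl, abs=1e-10)

    def test_matches_triple_loop_oracle(self, tiny_dataset):
        rng = np.random.default_rng(3)
        chol = np.tril(rng.normal(scale=0.3, size=(8, 8)))
        p = ParamBundle(
            beta=rng.normal(scale=0.4, size=8) * np.array([1, 1, 1, 1, 1, 1, 1, 0.01]),
            asc=-0.8,
            chol=chol * np.array([1, 1, 1, 1, 1, 1, 1, 0.01])[:, None],
        )
        draws = halton_draws(3, 5, 8, seed=0)
        for family in ("rpl", "gmxl"):
            params = p if family == "rpl" else ParamBundle(
                beta=p.beta, asc=p.asc, chol=p.chol, tau=0.6, gamma=0.25
            )
            want = brute_force_sml_loglik(tiny_dataset, params, draws, family)
            got = loglik_sml(params, tiny_dataset, draws, family=family)
            assert got == pytest.approx(want, rel=1e-10)

    def test_degeneracy_chain_gmxl_rpl_mnl(self, small_dataset):
        """GMXL(tau=0) == RPL and RPL(Gamma=0) == MNL at matched parameters."""
        beta = np.array([0.3, -0.2, 0.8, 0.4, 0.2, -0.1, 0.2, -0.002])
        chol = np.diag([0.2, 0.1, 0.5, 0.3, 0.2, 0.2, 0.1, 0.001])
        draws = halton_draws(25, 20, 8, seed=1)
        p_rpl = ParamBundle(beta=beta, asc=-1.5, chol=chol)
        p_gmxl = ParamBundle(beta=beta, asc=-1.5, chol=chol, tau=0.0, gamma=0.4)
        ll_rpl = loglik_sml(p_rpl, small_dataset, draws, family="rpl")
        ll_gmxl = loglik_sml(p_gmxl, small_dataset, draws, family="gmxl")
        assert ll_gmxl == pytest.approx(ll_rpl, abs=1e-8)
        p_flat = ParamBundle(beta=beta, asc=-1.5, chol=np.zeros((8, 8)))
        ll_flat = loglik_sml(p_flat, small_dataset, draws, family="rpl")
        assert ll_flat == pytest.approx(loglik_mnl(beta, -1.5, small_dataset), abs=1e-8)

    def test_invariance_to_respondent_reordering(self, small_dataset):
        p = ParamBundle(
            beta=np.array([0.3, -0.2, 0.8, 0.4, 0.2, -0.1, 0.2, -0.002]),
            asc=-1.5,
            chol=np.diag([0.2, 0.1, 0.5, 0.3, 0.2, 0.2, 0.1, 0.001]),
        )
        draws = halton_draws(25, 10, 8, seed=2)
        ll = loglik_sml(p, small_dataset, draws, family="rpl")
        # reverse respondent blocks in both the data and the draw set
        obs = small_dataset.obs
        order = np.concatenate(
            [obs.index[obs["respondent_id"] == rid] for rid in
             list(dict.fromkeys(obs["respondent_id"]))[::-1]]
        )
        flipped = d.ChoiceDataset(
            schema=small_dataset.schema,
            obs=obs.loc[order].reset_index(drop=True),
            respondents=small_dataset.respondents,
            coded=small_dataset.coded[order],
        )
        draws_flip = DrawSet(v=draws.v[::-1].copy(), w=draws.w[::-1].copy(), seed=2)
        ll_flip = loglik_sml(p, flipped, draws_flip, family="rpl")
        assert ll_flip == pytest.approx(ll, rel=1e-12)

    def test_invariance_to_permuting_draws_within_respondent(self, small_dataset):
        p = ParamBundle(
            beta=np.array([0.3, -0.2, 0.8, 0.4, 0.2, -0.1, 0.2, -0.002]),
            asc=-1.5,
            chol=np.diag([0.2, 0.1, 0.5, 0.3, 0.2, 0.2, 0.1, 0.001]),
        )
        draws = halton_draws(25, 10, 8, seed=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(10)
        shuffled = DrawSet(v=draws.v[:, perm].copy(), w=draws.w[:, perm].copy(), seed=2)
        a = loglik_sml(p, small_dataset, draws, family="rpl")
        b = loglik_sml(p, small_dataset, shuffled, family="rpl")
        assert a == pytest.approx(b, rel=1e-12)


@pytest.fixture(scope="module")
def recovered(schema, mnl_prefs):
    design = d.generate_design(schema, n_tasks=12, n_alts=2, seed=30)
    resp = d.generate_respondents(20_000, seed=31)
    ds = d.simulate_choices(design, resp, mnl_prefs, family="mnl", seed=32)
    panel = build_panel(ds)
    fit = fit_mnl(panel)
    fit = d.std_errors(fit, panel)
    return fit, panel, mnl_prefs


class TestFitMNL:
    def test_estimates_within_three_asymptotic_ses_of_truth(self, recovered):
        fit, _, prefs = recovered
        se = fit.se["beta"]
        assert np.all(np.abs(fit.params.beta - prefs.beta) < 3 * se)
        assert abs(fit.params.asc - prefs.asc) < 3 * fit.se["asc"][0]

    def test_optimum_beats_truth_and_is_stationary(self, recovered):
        fit, panel, prefs = recovered
        ll_truth = loglik_mnl(prefs.beta, prefs.asc, panel)
        assert fit.loglik >= ll_truth
        refit = fit_mnl(panel)
        assert abs(refit.loglik - fit.loglik) < 1e-6

    def test_non_varying_column_rejected(self, schema, small_respondents, simple_prefs):
        design = d.generate_design(schema, n_tasks=6, n_alts=2, seed=33)
        # force provider_age constant everywhere
        tasks = tuple(
            tuple(dict(p, provider_age="<30") for p in task) for task in design.tasks
        )
        from dcelogit.synthetic_data import ChoiceDesign

        bad = ChoiceDesign(schema=schema, tasks=tasks)
        ds = d.simulate_choices(bad, small_respondents, simple_prefs, family="mnl", seed=34)
        with pytest.raises(Exception, match="provider_age"):
            fit_mnl(ds)


class TestFitMixed:
    def test_small_rpl_fit_converges_and_improves_on_mnl(self, small_dataset):
        spec = ModelSpec(family="rpl", n_draws=30, seed=3, maxiter=300)
        fit = fit_mixed(small_dataset, spec)
        mnl = fit_mnl(small_dataset)
        assert fit.converged
        assert fit.loglik >= mnl.loglik - 1e-6

    def test_iteration_cap_flags_non_convergence(self, small_dataset):
        spec = ModelSpec(family="rpl", n_draws=10, seed=3, maxiter=1)
        fit = fit_mixed(small_dataset, spec)
        assert not fit.converged

    def test_wtp_space_requires_price_column(self, small_dataset):
        spec = ModelSpec(family="gmxl_wtp", price_column="no_such_column")
        with pytest.raises(ValueError, match="WTP-space"):
            fit_mixed(small_dataset, spec)


class TestInference:
    def test_standard_errors_shrink_as_root_n(self, schema, mnl_prefs):
        """SEs scale approximately as 1/sqrt(n) across simulated samples."""
        design = d.generate_design(schema, n_tasks=8, n_alts=2, seed=40)
        ses = {}
        for n in (250, 1000):
            resp = d.generate_respondents(n, seed=41)
            ds = d.simulate_choices(design, resp, mnl_prefs, family="mnl", seed=42)
            fit = d.std_errors(fit_mnl(ds), ds)
            ses[n] = fit.se["beta"].mean()
        assert ses[250] / ses[1000] == pytest.approx(2.0, rel=0.25)

    def test_star_thresholds(self):
        assert significance_stars(0.005) == "***"
        assert significance_stars(0.03) == "**"
        assert significance_stars(0.07) == "*"
        assert significance_stars(0.2) == ""

    def test_zero_estimate_with_unit_se_has_p_value_one(self):
        assert 2 * stats.norm.sf(abs(0.0 / 1.0)) == pytest.approx(1.0)


class TestFitStatistics:
    def _stub(self, ll, k):
        from types import SimpleNamespace

        return SimpleNamespace(loglik=ll, k_params=k)

    def test_lr_identical_likelihoods(self):
        stat, df, p = d.lr_test(self._stub(-50.0, 2), self._stub(-50.0, 4))
        assert stat == 0 and df == 2 and p == pytest.approx(1.0)

    def test_lr_arithmetic(self):
        stat, df, p = d.lr_test(self._stub(-100.0, 3), self._stub(-90.0, 5))
        assert stat == pytest.approx(20.0) and df == 2
        assert p == pytest.approx(stats.chi2.sf(20, 2))

    def test_lr_rejects_non_nested_counts(self):
        with pytest.raises(ValueError, match="nested"):
            d.lr_test(self._stub(-50.0, 5), self._stub(-49.0, 5))

    def test_lr_rejects_worse_general_model(self):
        with pytest.raises(ValueError, match="lower log-likelihood"):
            d.lr_test(self._stub(-50.0, 2), self._stub(-60.0, 4))

    def test_aic_definition_and_monotonicity(self):
        assert d.aic(self._stub(0.0, 0)) == 0.0
        assert d.aic(self._stub(-1.0, 1)) == 4.0
        assert d.aic(self._stub(-1.0, 2)) - d.aic(self._stub(-1.0, 1)) == 2.0


class TestPctCorrect:
    def test_perfectly_separated_choices_hit_100(self, schema, small_respondents):
        design = d.generate_design(schema, n_tasks=6, n_alts=2, seed=50)
        strong = d.TruePreferences(beta=np.array([0, 0, 50.0, 0, 0, 0, 0, 0.0]), asc=-1e6)
        ds = d.simulate_choices(design, small_respondents, strong, family="mnl", seed=51)
        fit = fit_mnl(ds)
        assert d.pct_correct(fit, ds) == pytest.approx(100.0)

    def test_flat_model_on_balanced_alternatives_predicts_a_third(self, schema, mnl_prefs):
        design = d.generate_design(schema, n_tasks=6, n_alts=2, seed=52)
        resp = d.generate_respondents(3000, seed=53)
        flat = d.TruePreferences(beta=np.zeros(8), asc=0.0)
        ds = d.simulate_choices(design, resp, flat, family="mnl", seed=54)
        panel = build_panel(ds)
        spec = ModelSpec(family="mnl")
        layout = _Layout(spec, panel)
        fit = d.FitResult(
            spec=spec, params=ParamBundle(beta=np.zeros(8), asc=0.0),
            theta=np.zeros(layout.n_params), loglik=0.0, k_params=9,
            n_obs=panel.n_resp * panel.n_tasks, n_respondents=panel.n_resp,
            converged=True, n_iter=0, message="stub", column_names=panel.column_names,
        )
        # flat parameters predict alternative 0 everywhere (tie -> lowest index)
        assert d.pct_correct(fit, panel) == pytest.approx(100 / 3, abs=2.0)

    def test_matches_hand_count_on_printed_fixture(self, schema, simple_prefs):
        design = d.generate_design(schema, n_tasks=4, n_alts=2, seed=55)
        resp = d.generate_respondents(1, seed=56)
        ds = d.simulate_choices(design, resp, simple_prefs, family="mnl", seed=57)
        panel = build_panel(ds)
        fit = fit_mnl(panel)
        P = d.estimation.predicted_probabilities(fit, panel)
        by_hand = sum(
            int(np.argmax(P[0, t]) == panel.chosen[0, t]) for t in range(4)
        )
        assert d.pct_correct(fit, panel) == pytest.approx(100 * by_hand / 4)
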