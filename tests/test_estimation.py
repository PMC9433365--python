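"""Estimation tests: transforms, the mixture likelihood against exhaustive
enumeration, fitting, exogeneity of censoring, posteriors, BIC, and segment
selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from censmix import (
    GameConfig,
    ModelParams,
    ParamSpace,
    SimConfig,
    bic,
    fit,
    select_segments,
    simulate,
    total_loglik,
    transform,
    untransform,
)
from censmix.estimation import FitResult, build_model, start_values
from censmix.outcome import InflationSpec, OutcomeParams, inflated_pmf, theta
from censmix.simulation import game_contrast_schema

from conftest import enumerate_joint


def toy_table(rows):
    """rows: list of (person, trial, y, censored) under gain 10/loss 250/1."""
    return pd.DataFrame(
        [
            {
                "person_id": p, "trial": t, "gain": 10, "loss": 250,
                "n_loss": 1, "y": y, "censored": c,
            }
            for p, t, y, c in rows
        ]
    )


def plain_params(S=1, **kw):
    defaults = dict(
        alpha=np.linspace(8, 16, S),
        beta=np.zeros(0),
        delta=3.0,
        phi=np.array([0.05, 0.1, 0.05, 0.8]),
        pi=np.full(S, 1.0 / S),
    )
    defaults.update(kw)
    return ModelParams(**defaults)


class TestTransforms:
    def test_softmax_examples(self):
        space = ParamSpace(n_segments=2, n_common=3)
        vec = np.array([3.39, 2.92, 2, -3, -6, np.log(3.0), -3.5, -1.9, -2.1, -0.4])
        p = untransform(vec, space)
        np.testing.assert_allclose(p.alpha, [11.4921, 20.0185], atol=1e-10)
        np.testing.assert_allclose(
            p.phi, [0.02319, 0.11486, 0.09404, 0.76792], atol=5e-6
        )
        assert p.pi[0] == pytest.approx(0.40131, abs=5e-6)
        assert p.delta == pytest.approx(3.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_roundtrip_bijection(self, seed):
        rng = np.random.default_rng(seed)
        space = ParamSpace(n_segments=3, n_common=2, n_seg_specific=1)
        vec = rng.normal(scale=1.5, size=space.size)
        vec[:3] = np.abs(vec[:3]) + 0.01  # alpha_tilde sign is not identified
        p = untransform(vec, space)
        np.testing.assert_allclose(transform(p), vec, atol=1e-10)

    def test_boundary_rejected(self):
        p = plain_params(S=2, pi=np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            transform(p)

    def test_parameter_count(self):
        # adding a segment adds one intercept and one mixture logit
        assert ParamSpace(2, 3).size - ParamSpace(1, 3).size == 2
        # ... plus q segment-specific effects
        assert (
            ParamSpace(3, 0, n_seg_specific=2).size
            - ParamSpace(2, 0, n_seg_specific=2).size
            == 4
        )


class TestLikelihood:
    def test_single_trial_is_log_pmf(self):
        model, _ = build_model(toy_table([("a", 1, 5, 0)]), 1)
        p = plain_params()
        op = OutcomeParams(
            mu=float(np.logaddexp(0, p.alpha[0])), delta=p.delta, phi=tuple(p.phi)
        )
        ll = model.person_segment_loglik(p)
        assert ll[0, 0] == pytest.approx(np.log(inflated_pmf(5, op)), abs=1e-10)

    def test_trials_add(self):
        m1, _ = build_model(toy_table([("a", 1, 5, 0)]), 1)
        m2, _ = build_model(toy_table([("a", 1, 3, 1)]), 1)
        m12, _ = build_model(toy_table([("a", 1, 5, 0), ("a", 2, 3, 1)]), 1)
        p = plain_params()
        assert m12.person_segment_loglik(p)[0, 0] == pytest.approx(
            m1.person_segment_loglik(p)[0, 0] + m2.person_segment_loglik(p)[0, 0]
        )

    def test_one_segment_total_is_sum(self):
        table = toy_table([("a", 1, 5, 0), ("b", 1, 2, 1), ("b", 2, 0, 0)])
        model, _ = build_model(table, 1)
        p = plain_params()
        assert total_loglik(p, model) == pytest.approx(
            model.person_segment_loglik(p).sum()
        )

    def test_degenerate_mixture_weight(self):
        table = toy_table([("a", 1, 5, 0), ("b", 1, 2, 1)])
        model, _ = build_model(table, 2)
        p2 = plain_params(S=2, alpha=np.array([8.0, 20.0]), pi=np.array([1.0, 0.0]))
        p1 = plain_params(S=1, alpha=np.array([8.0]), pi=np.array([1.0]))
        assert total_loglik(p2, model) == pytest.approx(
            build_model(table, 1)[0].total_loglik(p1)
        )

    @pytest.mark.parametrize("n_loss", [1, 3])
    def test_marginal_matches_enumeration(self, n_loss):
        """P(Y=k, C=c) = sum_l Omega_{kl,c} P(Z=l) agrees exactly with
        enumeration over intentions and loss-card placements."""
        cfg = GameConfig(gain=10, loss=250, n_loss=n_loss)
        p = plain_params(alpha=np.array([6.0]), phi=np.array([0.1, 0.2, 0.1, 0.6]))
        op = OutcomeParams(
            mu=float(np.logaddexp(0, 6.0)), delta=p.delta, phi=tuple(p.phi)
        )
        from censmix.outcome import inflated_pmf_matrix

        z_pmf = inflated_pmf_matrix(np.array(op.mu), op.delta, np.asarray(p.phi))
        oracle = enumerate_joint(z_pmf, cfg)
        from censmix.game import omega

        for k in range(33):
            for c in (0, 1):
                model_val = sum(
                    omega(k, c, l, cfg) * z_pmf[l] for l in range(33)
                )
                assert model_val == pytest.approx(oracle[k, c], abs=1e-12)
                # the Omega * Theta factorization gives the same number
                if (c == 1 and k >= 1) or c == 0:
                    fact = omega(k, c, max(k, 0) if c == 0 else k, cfg) * theta(
                        k, c, op
                    )
                    assert fact == pytest.approx(oracle[k, c], abs=1e-12)

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="censored"):
            build_model(toy_table([("a", 1, 0, 1)]), 1)
        with pytest.raises(ValueError, match="missing"):
            build_model(toy_table([("a", 1, 1, 0)]).drop(columns=["gain"]), 1)
        with pytest.raises(ValueError, match="empty"):
            build_model(toy_table([]).reindex(columns=toy_table([("a", 1, 1, 0)]).columns), 1)


class TestStartValues:
    def test_alpha_equally_spaced(self):
        model, _ = build_model(toy_table([("a", 1, 5, 0)]), 4)
        vec = start_values(model)
        alpha = np.cumsum(vec[:4] ** 2)
        np.testing.assert_allclose(alpha, [6.4, 12.8, 19.2, 25.6], atol=1e-12)

    def test_zero_spike_boosts_phi1(self):
        rows = [("p%d" % i, 1, 0, 0) for i in range(30)]
        rows += [("p%d" % i, 2, int(k), 0) for i, k in enumerate(np.arange(30) % 7 + 1)]
        model, _ = build_model(toy_table(rows), 1)
        vec = start_values(model)
        tau = vec[-3:]
        phi = np.exp(np.concatenate([tau, [0.0]]))
        phi /= phi.sum()
        assert phi[0] > phi[2]


class TestFit:
    def test_one_segment_recovery_within_three_se(self):
        truth = plain_params(
            S=1, alpha=np.array([10.0]), phi=np.array([0.05, 0.12, 0.08, 0.75])
        )
        sim = simulate(SimConfig(n_persons=800, n_trials=8, params=truth, seed=5))
        res = fit(sim, 1)
        assert res.converged
        est, se = res.report["alpha_1"]
        assert abs(est - 10.0) < 3 * se
        d_est, d_se = res.report["delta"]
        assert abs(d_est - 3.0) < 3 * d_se

    def test_refit_from_optimum_is_fixed_point(self, set1_params, small_sim):
        schema = game_contrast_schema()
        res = fit(small_sim, 2, schema, start=set1_params, compute_se=False)
        res2 = fit(small_sim, 2, schema, start=res.theta_t, compute_se=False)
        assert res2.loglik == pytest.approx(res.loglik, abs=1e-6)
        assert res2.loglik >= res.loglik - 1e-6  # polish never loses ground

    def test_exogeneity_of_censoring(self, set1_params):
        """Estimates are unchanged (to optimizer tolerance) whether or not
        the constant mechanics term enters the objective."""
        sim = simulate(SimConfig(n_persons=80, n_trials=8, params=set1_params, seed=9))
        schema = game_contrast_schema()
        r0 = fit(sim, 1, schema, compute_se=False, include_omega=False)
        r1 = fit(sim, 1, schema, compute_se=False, include_omega=True)
        np.testing.assert_allclose(r0.theta_t, r1.theta_t, atol=1e-4)
        assert r1.loglik == pytest.approx(r0.loglik, abs=1e-6)

    def test_label_invariance_of_start_order(self, set1_params, small_sim):
        schema = game_contrast_schema()
        v = transform(set1_params)
        swapped = v.copy()
        swapped[[0, 1]] = v[[1, 0]]  # permute the segment increments
        r1 = fit(small_sim, 2, schema, start=v, compute_se=False)
        r2 = fit(small_sim, 2, schema, start=swapped, compute_se=False)
        assert r2.loglik == pytest.approx(r1.loglik, abs=1e-5)
        assert np.all(np.diff(r1.params.alpha) >= 0)
        assert np.all(np.diff(r2.params.alpha) >= 0)


class TestPosteriors:
    def test_equal_intercepts_give_prior_rows(self, small_sim):
        model, _ = build_model(small_sim, 2)
        p = plain_params(S=2, alpha=np.array([9.0, 9.0]), pi=np.array([0.3, 0.7]))
        from censmix.estimation import _posterior

        post = _posterior(p, model)
        np.testing.assert_allclose(post, np.tile([0.3, 0.7], (model.n_persons, 1)))

    def test_rows_sum_to_one_and_segments_recovered(self, set1_params, small_sim):
        res = fit(small_sim, 2, game_contrast_schema(), start=set1_params,
                  compute_se=False)
        np.testing.assert_allclose(res.posterior.sum(axis=1), 1.0, atol=1e-10)
        truth = (
            small_sim.groupby("person_id")["segment"].first().loc[res.person_ids]
        )
        agree = (res.posterior.argmax(axis=1) == truth.to_numpy()).mean()
        assert agree > 0.9


class TestLagEffects:
    def _simulate_lag1(self, n_persons=400, n_trials=16, beta_lag=-3.0, seed=13):
        """Sequential generator with a loss-experience effect at lag one
        only: eta drops by |beta_lag| in the trial after a censored one."""
        from censmix.game import GameConfig
        from censmix.outcome import inflated_pmf_matrix, inv_link
        from censmix.simulation import _first_loss_cdf

        rng = np.random.default_rng(seed)
        cfg = GameConfig(gain=30, loss=250, n_loss=3)
        cdf = _first_loss_cdf(cfg)
        prev_c = np.zeros(n_persons)
        rows = []
        for t in range(1, n_trials + 1):
            eta = 12.0 + beta_lag * prev_c
            pmf = inflated_pmf_matrix(inv_link(eta), 3.0, (0.0, 0.0, 0.0, 1.0))
            z = np.sum(pmf.cumsum(axis=1) < rng.random((n_persons, 1)), axis=1)
            first = 1 + np.searchsorted(cdf, rng.random(n_persons))
            c = (first <= z).astype(int)
            y = np.where(c == 1, first, z)
            rows.append(
                pd.DataFrame(
                    {
                        "person_id": np.arange(n_persons), "trial": t,
                        "gain": 30, "loss": 250, "n_loss": 3,
                        "y": y, "censored": c,
                    }
                )
            )
            prev_c = c.astype(float)
        return pd.concat(rows, ignore_index=True)

    def test_lag_effect_concentrates_at_lag_one(self):
        from censmix import CovariateSchema, build_lag_covariates, effect_span

        data = self._simulate_lag1()
        data, lag_vars = build_lag_covariates(data, max_lag=3)
        schema = CovariateSchema(variables=lag_vars)
        res = fit(data, 1, schema, compute_se=False)
        coefs = {k: v for k, (v, _) in (res.report or {}).items()}
        if not coefs:  # compute_se=False leaves report empty
            from censmix.estimation import standard_errors

            coefs = {k: v for k, (v, _) in standard_errors(res).items()}
        spans = [
            effect_span(coefs, schema, f"loss_lag{j}") for j in (1, 2, 3)
        ]
        assert spans[0] > 2.0  # true span is |beta_lag| = 3
        assert spans[0] > spans[1] and spans[0] > spans[2]
        assert max(spans[1], spans[2]) < 0.5  # no true dependence beyond lag 1


class TestModelSelection:
    def test_bic_formula_and_monotonicity(self):
        assert bic(-100.0, 5, 50) == pytest.approx(200 + 5 * np.log(50))
        assert bic(-100.0, 7, 50) > bic(-100.0, 5, 50)

    def _mock_fit(self, S, bic_value, pi, alpha):
        return FitResult(
            params=ModelParams(
                alpha=np.asarray(alpha, float), beta=np.zeros(0), delta=3.0,
                phi=np.array([0.1, 0.1, 0.1, 0.7]), pi=np.asarray(pi, float),
            ),
            theta_t=np.zeros(1), cov_t=None, labels_t=[], loglik=0.0,
            bic=bic_value, n_free=0, n_persons=100, n_trials=800,
            converged=True, n_iter=1, grad_norm=0.0,
            posterior=np.ones((1, S)) / S, person_ids=np.array([0]),
            space=ParamSpace(S, 0),
        )

    def test_small_segment_stops_growth(self):
        fits = [
            self._mock_fit(3, 1000.0, [0.15, 0.43, 0.42], [6.8, 13.9, 30.9]),
            self._mock_fit(4, 990.0, [0.10, 0.27, 0.36, 0.27], [5.8, 11.0, 18.7, 37.5]),
            self._mock_fit(
                5, 985.0, [0.023, 0.119, 0.284, 0.331, 0.243],
                [3.1, 6.9, 11.7, 19.4, 38.4],
            ),
        ]
        sel = select_segments(fits)
        assert sel.chosen == 4
        assert not sel.diagnostics.loc[sel.diagnostics.S == 5, "share_ok"].item()

    def test_single_fit_returned(self):
        sel = select_segments([self._mock_fit(2, 500.0, [0.4, 0.6], [9.9, 26.4])])
        assert sel.chosen == 2

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_segments([])

    def test_two_segment_truth_selected(self, set1_params):
        sim = simulate(
            SimConfig(n_persons=250, n_trials=8, params=set1_params, seed=21)
        )
        schema = game_contrast_schema()
        fits = [
            fit(sim, S, schema, compute_se=False, max_iter=300) for S in (1, 2, 3)
        ]
        assert select_segments(fits).chosen == 2
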