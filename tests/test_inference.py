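"""Proxy-likelihood model, MCMC fitting, and decision statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from rezddm import (
    DDMParams,
    forward_moments,
    ModelSpec,
    build_model,
    fit,
    decision_statistic,
    summarize_dataset,
)


@pytest.fixture(scope="module")
def small_model(small_dataset):
    _, _, data = small_dataset
    cells = summarize_dataset(data, "standard", rt_scope="all")
    return build_model(cells, ModelSpec(rt_scope="all"))


def _reference_logpdf(model, point):
    """Brute-force reimplementation: sum of the three per-cell terms + priors."""
    sp = model.spec
    lp = 0.0
    lp += stats.norm.logpdf(point["mu_nu"], *sp.mu_nu_prior)
    lp += stats.norm.logpdf(point["beta"], *sp.beta_prior)
    for name, prior in (("mu_alpha", sp.mu_alpha_prior), ("mu_tau", sp.mu_tau_prior)):
        m, sd = prior
        lp += stats.truncnorm.logpdf(point[name], -m / sd, np.inf, loc=m, scale=sd)
    for name, sc in (
        ("sigma_nu", sp.sigma_nu_scale),
        ("sigma_alpha", sp.sigma_alpha_scale),
        ("sigma_tau", sp.sigma_tau_scale),
    ):
        lp += stats.halfnorm.logpdf(point[name], scale=sc)
    nu, alpha, tau = point["nu"], point["alpha"], point["tau"]
    for p in range(model.P):
        for k in range(2):
            lp += stats.norm.logpdf(
                nu[p, k], point["mu_nu"] + point["beta"] * k, point["sigma_nu"]
            )
        lp += stats.norm.logpdf(alpha[p], point["mu_alpha"], point["sigma_alpha"])
        lp += stats.norm.logpdf(tau[p], point["mu_tau"], point["sigma_tau"])
        for k in range(2):
            m = forward_moments(DDMParams(nu[p, k], alpha[p], tau[p], sp.s))
            n = model.nrt[p, k]
            lp += stats.binom.logpmf(model.nc[p, k], model.ntot[p, k], m.pc)
            lp += stats.norm.logpdf(model.loc[p, k], m.mrt, np.sqrt(m.vrt / n))
            lp += stats.norm.logpdf(
                model.scale[p, k], m.vrt, np.sqrt(2 * m.vrt**2 / (n - 1))
            )
    return float(lp)


def _random_point(model, rng):
    P = model.P
    return {
        "mu_nu": rng.normal(0.5, 1.0),
        "beta": rng.normal(0, 0.5),
        "sigma_nu": rng.uniform(0.5, 1.5),
        "mu_alpha": rng.uniform(2, 4),
        "sigma_alpha": rng.uniform(0.3, 1.0),
        "mu_tau": rng.uniform(0.2, 0.4),
        "sigma_tau": rng.uniform(0.1, 0.5),
        "nu": rng.normal(0.5, 1.0, (P, 2)),
        "alpha": rng.uniform(2, 4, P),
        "tau": rng.uniform(0.1, 0.5, P),
    }


def test_logpdf_matches_brute_force_oracle(small_model, rng):
    """Joint density equals an independently coded per-cell sum (tol 1e-10)."""
    for _ in range(5):
        pt = _random_point(small_model, rng)
        mine = small_model.logpdf(pt)
        ref = _reference_logpdf(small_model, pt)
        assert mine == pytest.approx(ref, abs=1e-10 * max(1, abs(ref)))


def test_logpdf_finite_at_generating_values(small_dataset, small_model):
    pop, ind, _ = small_dataset
    pt = {
        "mu_nu": pop.mu_nu, "beta": pop.beta,
        "sigma_nu": math.sqrt(pop.sigma2_nu),
        "mu_alpha": pop.mu_alpha, "sigma_alpha": math.sqrt(pop.sigma2_alpha),
        "mu_tau": pop.mu_tau, "sigma_tau": math.sqrt(pop.sigma2_tau),
        "nu": ind.nu, "alpha": ind.alpha, "tau": ind.tau,
    }
    assert np.isfinite(small_model.logpdf(pt))


def test_logpdf_outside_support(small_model, rng):
    pt = _random_point(small_model, rng)
    pt["sigma_nu"] = -0.1
    assert small_model.logpdf(pt) == -np.inf
    pt = _random_point(small_model, rng)
    pt["alpha"] = pt["alpha"].copy()
    pt["alpha"][0] = -1.0
    assert small_model.logpdf(pt) == -np.inf


def test_model_requires_both_conditions_and_min_cells(small_dataset):
    _, _, data = small_dataset
    cells = summarize_dataset(data, "standard", rt_scope="all")
    with pytest.raises(ValueError, match="both conditions"):
        build_model([c for c in cells if not (c.participant == 0 and c.condition == 1)])
    import dataclasses

    broken = [dataclasses.replace(cells[0], n=3)] + cells[1:]
    with pytest.raises(ValueError, match="n=3"):
        build_model(broken)


@pytest.fixture(scope="module")
def fitted(small_model):
    return fit(small_model, chains=4, warmup=600, draws=600, seed=3)


class TestFit:

    def test_diagnostics_recorded_for_every_hyperparameter(self, fitted):
        from rezddm.inference import HYPER_NAMES

        assert set(fitted.rhat) == set(HYPER_NAMES)
        assert all(np.isfinite(v) for v in fitted.rhat.values())
        assert all(np.isfinite(v) for v in fitted.ess.values())

    def test_posterior_shapes_and_finiteness(self, fitted, small_model):
        post = fitted.posterior
        assert post.hyper.shape == (4, 600, 7)
        assert post.individual.shape == (4, 600, 4 * small_model.P)
        assert np.all(np.isfinite(post.hyper))

    def test_same_seed_identical_draws(self, small_model, fitted):
        again = fit(small_model, chains=4, warmup=600, draws=600, seed=3)
        assert np.array_equal(again.posterior.hyper, fitted.posterior.hyper)

    def test_recovers_realized_effect(self, small_dataset, fitted):
        """Posterior mean of beta lands within 3 posterior sd of the realized
        per-dataset drift difference (the estimable truth at small P)."""
        _, ind, _ = small_dataset
        realized = float((ind.nu[:, 1] - ind.nu[:, 0]).mean())
        assert abs(fitted.beta_mean - realized) < 3 * fitted.beta_sd

    def test_json_serialization(self, fitted, tmp_path):
        import json

        path = tmp_path / "fit.json"
        fitted.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["model_tag"] == "standard/all"
        assert set(payload["rhat"]) == set(fitted.rhat)


class TestDecisionStatistic:
    def _fake_fit(self, mean, sd, prior_sd=1.0):
        from rezddm.inference import FitResult

        return FitResult(
            summary={}, rhat={}, ess={}, beta_mean=mean, beta_sd=sd,
            beta_prior_pdf0=stats.norm.pdf(0, 0, prior_sd),
            converged=True, seed=0, model_tag="t",
        )

    def test_closed_form_values(self):
        """Posterior N(0.4, 0.1^2), prior N(0,1): z=4 and the Savage-Dickey
        ratio equals the ratio of normal densities at zero."""
        f = self._fake_fit(0.4, 0.1)
        assert decision_statistic(f, "z_abs") == pytest.approx(4.0)
        expected_bf = stats.norm.pdf(0, 0, 1) / stats.norm.pdf(0, 0.4, 0.1)
        assert expected_bf == pytest.approx(298.0957, rel=1e-4)
        assert decision_statistic(f, "savage_dickey_bf10") == pytest.approx(
            expected_bf, rel=1e-9
        )

    def test_null_centered_posterior_gives_bf_one(self):
        f = self._fake_fit(0.0, 1.0, prior_sd=1.0)
        assert decision_statistic(f, "savage_dickey_bf10") == pytest.approx(1.0)

    def test_errors(self):
        f = self._fake_fit(0.4, 0.0)
        with pytest.raises(ValueError):
            decision_statistic(f, "z_abs")
        with pytest.raises(ValueError):
            decision_statistic(self._fake_fit(0.4, 0.1), "p_value")


def test_beta_prior_must_be_proper():
    with pytest.raises(ValueError):
        ModelSpec(beta_prior=(0.0, 0.0))
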