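"""Sampler correctness: oracle agreement, reductions, diagnostics, determinism."""

import numpy as np
import pytest

from bayesrct.evidence import credible_interval, threshold_probability
from bayesrct.hierarchical import (
    Diagnostics,
    HalfNormal,
    HalfStudentT,
    McmcSettings,
    ModelError,
    PosteriorDraws,
    PriorSpec,
    convergence_check,
    effect_draws,
    fit_model,
)
from bayesrct.oracle import (
    beta_binomial_posterior,
    normal_approx_probability,
    oracle_threshold_probability,
)
from bayesrct.trial_data import stratified_from_counts

from conftest import CANONICAL_SEED

THRESHOLDS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)


def manual_draws(beta, alpha=None, chains=2):
    """Wrap raw beta draws in a PosteriorDraws for unit-testing transforms."""
    beta = np.asarray(beta, dtype=float).reshape(chains, -1)
    alpha = (
        np.zeros_like(beta) if alpha is None
        else np.asarray(alpha, dtype=float).reshape(chains, -1)
    )
    return PosteriorDraws(
        endpoint="24h", alpha=alpha, beta=beta, site_effects=None, site_sd=None,
        site_ids=[], settings=McmcSettings(seed=0), priors=PriorSpec(),
    )


class TestFitStructure:
    def test_draw_count_and_reduction_to_two_parameters(self, fit_24h):
        s = fit_24h.settings
        assert fit_24h.n_draws == s.chains * s.saved_per_chain
        assert fit_24h.alpha.shape == (s.chains, s.saved_per_chain)
        assert fit_24h.site_sd is None  # single stratum: no site term
        assert fit_24h.site_effects is None

    def test_default_fit_converged(self, fit_24h):
        assert fit_24h.diagnostics.max_rhat < 1.01
        assert not fit_24h.convergence_warning
        assert min(fit_24h.diagnostics.ess.values()) > 1000

    def test_seed_determinism(self, quick_mcmc):
        table = stratified_from_counts("24h", 43, 338, 58, 342)
        a = fit_model(table, mcmc=quick_mcmc)
        b = fit_model(table, mcmc=quick_mcmc)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.alpha, b.alpha)

    def test_hierarchical_fit_has_site_terms(self, quick_mcmc):
        table = stratified_from_counts("24h", 43, 338, 58, 342, n_sites=12)
        d = fit_model(table, mcmc=quick_mcmc)
        assert d.site_sd.shape == d.beta.shape
        assert d.site_effects.shape == (*d.beta.shape, 12)
        assert (d.site_sd >= 0).all()

    def test_empty_arm_rejected(self):
        table = stratified_from_counts("24h", 0, 0, 5, 10)
        with pytest.raises(ModelError):
            fit_model(table)


class TestPosteriorAccuracy:
    def test_flat_fit_matches_conjugate_oracle_and_normal_approx(self, fit_24h):
        """Single-stratum flat-prior sampler vs two independent routes."""
        or_draws = effect_draws(fit_24h, "odds-ratio")
        post = beta_binomial_posterior(43, 338, 58, 342)
        log_or = np.log(43 * 284 / (295 * 58))
        se = np.sqrt(1 / 43 + 1 / 295 + 1 / 58 + 1 / 284)
        for t in THRESHOLDS:
            p_mcmc, se_mcmc = threshold_probability(or_draws, t)
            p_oracle, se_oracle = oracle_threshold_probability(post, t, "odds-ratio")
            p_normal = normal_approx_probability(log_or, se, t)
            tol = 3 * np.hypot(se_mcmc, se_oracle)
            assert abs(p_mcmc - p_oracle) < tol, f"t={t}"
            assert abs(p_mcmc - p_normal) < max(tol, 0.01), f"t={t}"

    def test_median_and_cri_match_normal_oracle(self, fit_24h):
        or_draws = effect_draws(fit_24h, "odds-ratio")
        lo, med, hi = credible_interval(or_draws)
        assert med == pytest.approx(0.714, abs=0.02)  # sample odds ratio
        assert lo == pytest.approx(0.47, abs=0.03)
        assert hi == pytest.approx(1.09, abs=0.03)

    def test_null_data_centers_probability_at_half(self, quick_mcmc):
        table = stratified_from_counts("24h", 1500, 10_000, 1500, 10_000)
        d = fit_model(table, mcmc=quick_mcmc)
        p, _ = threshold_probability(effect_draws(d, "odds-ratio"), 1.0)
        assert abs(p - 0.5) < 0.05

    def test_pooled_and_balanced_site_fits_agree(self, fit_24h, quick_mcmc):
        table12 = stratified_from_counts("24h", 43, 338, 58, 342, n_sites=12)
        mcmc = McmcSettings(seed=CANONICAL_SEED)
        d12 = fit_model(table12, mcmc=mcmc)
        p1, _ = threshold_probability(effect_draws(fit_24h, "odds-ratio"), 1.0)
        p12, _ = threshold_probability(effect_draws(d12, "odds-ratio"), 1.0)
        assert abs(p1 - p12) < 0.02
        m1 = credible_interval(effect_draws(fit_24h, "odds-ratio"))[1]
        m12 = credible_interval(effect_draws(d12, "odds-ratio"))[1]
        assert abs(m1 - m12) < 0.03

    def test_site_sd_prior_choice_barely_moves_superiority(self):
        table = stratified_from_counts("24h", 43, 338, 58, 342, n_sites=12)
        mcmc = McmcSettings(seed=CANONICAL_SEED)
        probs = []
        for sd_prior in (HalfStudentT(3, 2.5), HalfNormal(1.0)):
            d = fit_model(table, PriorSpec(site_sd_prior=sd_prior), mcmc)
            probs.append(threshold_probability(effect_draws(d, "odds-ratio"), 1.0)[0])
        assert abs(probs[0] - probs[1]) < 0.01


class TestEffectScales:
    def test_zero_beta_gives_unit_odds_ratio(self):
        d = manual_draws(np.zeros(200))
        assert (effect_draws(d, "odds-ratio") == 1.0).all()

    def test_risk_scales_use_typical_site(self):
        from scipy.special import expit

        alpha = np.full(200, -1.5)
        beta = np.full(200, -0.4)
        d = manual_draws(beta, alpha)
        rr = effect_draws(d, "risk-ratio")
        rd = effect_draws(d, "risk-difference")
        assert rr[0] == pytest.approx(expit(-1.9) / expit(-1.5))
        assert rd[0] == pytest.approx(expit(-1.9) - expit(-1.5))

    def test_unknown_scale_rejected(self):
        with pytest.raises(ModelError):
            effect_draws(manual_draws(np.zeros(10)), "hazard-ratio")


class TestDiagnostics:
    def test_iid_chains_have_unit_rhat(self):
        rng = np.random.default_rng(0)
        d = manual_draws(rng.standard_normal(4 * 1000), chains=4)
        diag = convergence_check(d)
        assert 1.0 <= diag.rhat["beta"] < 1.01

    def test_nonmixing_chains_flagged(self):
        beta = np.concatenate([np.full(500, -3.0), np.full(500, 3.0)])
        diag = convergence_check(manual_draws(beta, chains=2))
        assert diag.rhat["beta"] > 1.1
        assert not diag.converged

    def test_diagnostics_attached_to_fit(self, fit_30d):
        diag = fit_30d.diagnostics
        assert isinstance(diag, Diagnostics)
        assert set(diag.rhat) == {"alpha", "beta"}
        assert all(r >= 1.0 - 1e-6 for r in diag.rhat.values())


def test_draws_export_round_trip(tmp_path, fit_24h):
    path = tmp_path / "draws.csv"
    fit_24h.export(path)
    import pandas as pd

    frame = pd.read_csv(path)
    assert list(frame.columns) == ["alpha", "beta"]
    assert len(frame) == fit_24h.n_draws
    assert frame["beta"].to_numpy() == pytest.approx(fit_24h.flat("beta"))
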