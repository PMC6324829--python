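"""Frequency estimates, simplex MLE, and the EM mixture."""

import math

import numpy as np
import pytest

from jemge.inference import (
    ALL_MODELS,
    DEFAULT_INITS,
    Dataset,
    DatasetLikelihood,
    ThetaFree,
    build_dataset,
    dataset_neg_log_likelihood,
    estimate_global_equilibria,
    estimate_local_equilibria,
    fit_mle,
    fit_mixture_em,
    percent_error,
    params_for_pair,
)
from jemge.likelihood import HomologousPair, MarkTrack, ModelKind, pair_log_likelihood
from jemge.simulate import SimulationConfig, simulate_dataset
from conftest import random_pair

THETA_TRUE = ThetaFree(mu=0.1, s=0.1, kappa=(1.0,))


def small_dataset(model=ModelKind.N, n_pairs=20, length=100, seed=11):
    sims, _ = simulate_dataset(SimulationConfig(
        model=model, theta=THETA_TRUE, ancestor_length=length,
        n_pairs=n_pairs, seed=seed))
    return build_dataset([s.pair for s in sims])


class TestFrequencyEstimates:
    def test_uniform_base_counts(self):
        p = HomologousPair("x", "AC", "GT",
                           (MarkTrack(1, [0, 0]),), (MarkTrack(1, [0, 0]),))
        nuc, pi1 = estimate_global_equilibria([p])
        assert nuc.as_array() == pytest.approx([0.25] * 4, abs=1e-9)

    def test_all_zero_marks_clamped(self):
        p = HomologousPair("x", "ACGT", "ACGT",
                           (MarkTrack(1, [0] * 4),), (MarkTrack(1, [0] * 4),))
        _, pi1 = estimate_global_equilibria([p])
        assert pi1[0] == pytest.approx(1e-6)

    def test_pooled_fraction(self):
        # 100 ones out of 1000 pooled positions -> 0.1
        a = np.zeros(500, int)
        a[:60] = 1
        b = np.zeros(500, int)
        b[:40] = 1
        p = HomologousPair("x", "A" * 500, "C" * 500,
                           (MarkTrack(1, a),), (MarkTrack(1, b),))
        _, pi1 = estimate_global_equilibria([p])
        assert pi1[0] == pytest.approx(0.1)

    def test_local_equilibria_are_unclamped_fractions(self):
        p = HomologousPair("x", "ACGTACGTAC", "ACGT",
                           (MarkTrack(1, [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]),),
                           (MarkTrack(1, [1, 1, 1, 1]),))
        phi = estimate_local_equilibria(p)
        assert phi.phi_A1 == (0.5,)
        assert phi.phi_B1 == (1.0,)  # mixture weights: 1 is legal

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            estimate_global_equilibria([])


class TestDatasetNLL:
    def test_single_pair_equals_pair_likelihood(self, rng):
        ds = small_dataset(n_pairs=1, length=40)
        theta = ThetaFree(0.05, 0.08, (0.6,))
        for model in ALL_MODELS:
            direct = -pair_log_likelihood(
                ds.pairs[0], model, params_for_pair(ds, ds.pairs[0], theta))
            assert dataset_neg_log_likelihood(ds, model, theta) == pytest.approx(
                direct, abs=1e-9)

    def test_duplication_doubles_nll(self):
        ds = small_dataset(n_pairs=3, length=40)
        doubled = Dataset(pairs=ds.pairs + ds.pairs, nuc=ds.nuc, pi1=ds.pi1)
        theta = ThetaFree(0.05, 0.08, (0.6,))
        one = dataset_neg_log_likelihood(ds, ModelKind.I, theta)
        two = dataset_neg_log_likelihood(doubled, ModelKind.I, theta)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_thread_count_invariance(self):
        ds = small_dataset(n_pairs=6, length=60)
        theta = ThetaFree(0.05, 0.08, (0.6,))
        seq = DatasetLikelihood(ds, threads=1).pair_logliks(theta)
        par = DatasetLikelihood(ds, threads=3).pair_logliks(theta)
        np.testing.assert_array_equal(seq, par)

    def test_truth_beats_perturbed_on_average(self):
        # Monte-Carlo consistency: expected NLL is minimized near the truth
        ds = small_dataset(model=ModelKind.B, n_pairs=30, length=120, seed=5)
        at_truth = dataset_neg_log_likelihood(ds, ModelKind.B, THETA_TRUE)
        worse = ThetaFree(mu=0.15, s=0.15, kappa=(1.5,))
        assert at_truth < dataset_neg_log_likelihood(ds, ModelKind.B, worse)


@pytest.fixture(scope="module")
def fitted():
    ds = small_dataset(model=ModelKind.I, n_pairs=30, length=120, seed=2)
    eng = DatasetLikelihood(ds)
    return ds, eng, fit_mle(ds, ModelKind.I, engine=eng)


class TestMLE:
    def test_trace_monotone_non_increasing(self, fitted):
        _, _, fit = fitted
        trace = np.asarray(fit.nll_trace)
        assert len(trace) > 5
        assert np.all(np.diff(trace) <= 1e-9)

    def test_fixed_point_restart(self, fitted):
        ds, eng, fit = fitted
        again = fit_mle(ds, ModelKind.I, theta_init=fit.theta_hat, engine=eng)
        assert again.nll == pytest.approx(fit.nll, abs=1e-6)
        np.testing.assert_allclose(again.theta_hat.as_array(),
                                   fit.theta_hat.as_array(), rtol=1e-3)

    def test_initial_values_agree(self, fitted):
        # both documented starting points reach the same optimum
        ds, eng, fit = fitted
        other = fit_mle(ds, ModelKind.I, theta_init=DEFAULT_INITS[1], engine=eng)
        assert other.nll == pytest.approx(fit.nll, abs=1e-4)

    def test_recovers_truth_roughly(self, fitted):
        # loose sanity bound at this reduced size; tight bounds live in the
        # acceptance suite
        _, _, fit = fitted
        pe = percent_error(fit.theta_hat, THETA_TRUE)
        assert all(abs(v) < 50 for v in pe.values())


class TestPercentError:
    def test_arithmetic(self):
        e = percent_error(ThetaFree(0.12, 0.09, (1.0,)),
                          ThetaFree(0.10, 0.10, (1.0,)))
        assert e["mu"] == pytest.approx(20.0)
        assert e["s"] == pytest.approx(-10.0)
        assert e["kappa_1"] == pytest.approx(0.0)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            ThetaFree(0.1, 0.1, (0.0,))


class TestEM:
    def test_alpha_fixed_point_when_models_indistinguishable(self):
        # with no marks the four models have identical likelihoods, so the
        # prior update in the E-step must leave alpha unchanged
        rng = np.random.default_rng(3)
        pairs = [random_pair(rng, 30, 30, H=0, identifier=f"p{i}")
                 for i in range(5)]
        ds = build_dataset(pairs)
        alpha0 = {ModelKind.N: 0.4, ModelKind.M: 0.3,
                  ModelKind.I: 0.2, ModelKind.B: 0.1}
        fit = fit_mixture_em(ds, alpha_init=alpha0,
                             theta_init=(0.05, 0.1, ()), max_iter=3)
        for m, v in alpha0.items():
            assert fit.alpha[m] == pytest.approx(v, abs=1e-9)

    def test_responsibilities_are_distributions(self):
        ds = small_dataset(model=ModelKind.N, n_pairs=12, length=80, seed=9)
        fit = fit_mixture_em(ds, max_iter=5, m_step_maxiter=15)
        np.testing.assert_allclose(fit.gamma.sum(axis=1), 1.0, atol=1e-9)
        total = sum(fit.alpha.values())
        assert total == pytest.approx(1.0, abs=1e-9)
        trace = np.asarray(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-7)
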