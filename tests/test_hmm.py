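import itertools

import numpy as np
import pytest
from scipy.stats import norm

from sleepkit import (
    GaussianHMMStager,
    GeneratorSpec,
    HMMParameters,
    em_fit,
    init_params,
    log_likelihood,
    sample_features,
    sample_hypnogram,
    score_sleep,
    synthesize_eeg,
    viterbi_decode,
)
from sleepkit.hmm import _viterbi_path


def random_params(rng, sd_lo=0.1, sd_hi=1.0):
    pi = rng.dirichlet(np.ones(4))
    q = rng.dirichlet(np.ones(4), size=4)
    mu = rng.uniform(0, 1, size=(4, 4))
    sd = rng.uniform(sd_lo, sd_hi, size=(4, 4))
    return HMMParameters(pi, q, mu, sd)


def brute_force_path(x, params):
    """Exhaustive enumeration over all 4^n state sequences."""
    best_lp, best_path = -np.inf, None
    log_pi = np.log(np.where(params.initial_probs > 0, params.initial_probs, 1e-300))
    log_q = np.log(np.where(params.transition > 0, params.transition, 1e-300))
    log_b = np.array([
        [norm.logpdf(x[t], params.emission_means[s], params.emission_stds[s]).sum()
         for s in range(4)]
        for t in range(len(x))
    ])
    for path in itertools.product(range(4), repeat=len(x)):
        lp = log_pi[path[0]] + log_b[0, path[0]]
        for t in range(1, len(x)):
            lp += log_q[path[t - 1], path[t]] + log_b[t, path[t]]
        if lp > best_lp + 1e-12:
            best_lp, best_path = lp, path
    return np.array(best_path)


class TestInitParams:
    def test_initial_mass_concentrated_on_wake(self):
        p = init_params()
        assert p.initial_probs.tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_prior_transition_entries(self):
        q = init_params().transition
        assert q[2, 3] == 0.16  # Light -> Deep
        assert q[0, 3] == 0.0  # no direct Wake -> Deep
        assert q[1, 3] == 0.0  # no direct REM -> Deep
        assert np.allclose(q.sum(axis=1), 1.0, atol=1e-9)

    def test_emission_prior_structure(self):
        p = init_params()
        assert np.allclose(np.diag(p.emission_means), 0.7)
        assert np.allclose(p.emission_means[~np.eye(4, dtype=bool)], 0.1)
        assert np.allclose(p.emission_stds, 1.0)

    def test_json_round_trip_is_bit_exact(self):
        p = init_params()
        q = HMMParameters.from_json(p.to_json())
        for a, b in [(p.initial_probs, q.initial_probs), (p.transition, q.transition),
                     (p.emission_means, q.emission_means), (p.emission_stds, q.emission_stds)]:
            assert np.array_equal(a, b)

    @pytest.mark.parametrize("field,value", [
        ("initial_probs", [0.5, 0.5, 0.5, 0.5]),
        ("transition", np.full((4, 4), 0.3)),
        ("emission_stds", np.zeros((4, 4))),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        kw = dict(
            initial_probs=[1, 0, 0, 0],
            transition=np.full((4, 4), 0.25),
            emission_means=np.zeros((4, 4)),
            emission_stds=np.ones((4, 4)),
        )
        kw[field] = value
        with pytest.raises(ValueError):
            HMMParameters(**kw)


class TestLogLikelihood:
    def test_single_epoch_equals_wake_emission_density(self):
        p = init_params()
        x = np.array([[0.6, 0.2, 0.1, 0.1]])
        expected = norm.logpdf(x[0], p.emission_means[0], p.emission_stds[0]).sum()
        assert log_likelihood(x, p) == pytest.approx(expected, abs=1e-10)

    def test_std_scaling_matches_hand_computed_density(self, rng):
        x = rng.uniform(0, 1, size=(1, 4))
        p = init_params()
        wide = HMMParameters(p.initial_probs, p.transition,
                             p.emission_means, p.emission_stds * 10)
        expected = norm.logpdf(x[0], p.emission_means[0],
                               p.emission_stds[0] * 10).sum()
        assert log_likelihood(x, wide) == pytest.approx(expected, abs=1e-10)

    def test_degenerate_self_loop_chain_sums_per_epoch_densities(self):
        p = init_params()
        stuck = HMMParameters(p.initial_probs, np.eye(4),
                              p.emission_means, p.emission_stds)
        x = np.array([[0.7, 0.1, 0.1, 0.1]] * 3)
        expected = sum(
            norm.logpdf(row, p.emission_means[0], p.emission_stds[0]).sum()
            for row in x
        )
        assert log_likelihood(x, stuck) == pytest.approx(expected, abs=1e-9)

    def test_agrees_with_hmmlearn_reference(self, rng):
        from hmmlearn.hmm import GaussianHMM

        params = random_params(rng)
        x = rng.uniform(0, 1, size=(50, 4))
        ref = GaussianHMM(n_components=4, covariance_type="diag", init_params="")
        ref.startprob_ = params.initial_probs
        ref.transmat_ = params.transition
        ref.means_ = params.emission_means
        ref.covars_ = params.emission_stds**2
        assert log_likelihood(x, params) == pytest.approx(ref.score(x), abs=1e-8)


class TestEMFit:
    def test_single_iteration_does_not_decrease_likelihood(self, rng):
        p = init_params()
        spec = GeneratorSpec(seed=1, n_epochs=200)
        x = sample_features(sample_hypnogram(spec), spec)
        before = log_likelihood(x, p)
        after = log_likelihood(x, em_fit(x, p, max_iter=1))
        assert after >= before - 1e-9

    def test_max_iter_zero_rejected(self, rng):
        with pytest.raises(ValueError, match="max_iter"):
            em_fit(rng.uniform(size=(10, 4)), init_params(), max_iter=0)

    def test_fewer_than_two_epochs_rejected(self):
        with pytest.raises(ValueError, match="2 epochs"):
            em_fit(np.ones((1, 4)) * 0.25, init_params())

    def test_loglik_nondecreasing_and_rows_stochastic_each_run(self, rng):
        for seed in range(5):
            spec = GeneratorSpec(seed=seed, n_epochs=300)
            x = sample_features(sample_hypnogram(spec), spec)
            st = GaussianHMMStager(init=random_params(rng)).fit(x)
            assert np.all(np.diff(st.loglik_history_) >= -1e-7)
            assert np.allclose(st.transmat_.sum(axis=1), 1.0, atol=1e-9)
            assert st.startprob_.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(st.stds_ > 0)

    def test_parameter_recovery_in_separable_regime(self):
        """Data from the prior chain with 4-SD-separated emissions: EM
        started at the truth stays within tight bounds of it."""
        for seed in (1, 2, 3):
            spec = GeneratorSpec(seed=seed, n_epochs=2000)
            hyp = sample_hypnogram(spec)
            x = sample_features(hyp, spec)
            st = GaussianHMMStager().fit(x)
            assert np.max(np.abs(st.means_ - spec.mu_true)) < 0.1
            assert np.max(np.abs(st.transmat_ - spec.q_true)) < 0.08

    def test_alternating_clusters_drive_self_loops_to_zero(self):
        x = np.tile(
            np.array([[0.05, 0.85, 0.05, 0.05], [0.05, 0.05, 0.85, 0.05]]), (100, 1)
        )
        p0 = init_params()
        init = HMMParameters(np.full(4, 0.25), p0.transition,
                             p0.emission_means, p0.emission_stds)
        st = GaussianHMMStager(init=init).fit(x)
        visited = np.unique(st.predict(x))
        assert len(visited) == 2
        assert np.all(np.diag(st.transmat_)[visited] < 0.05)

    def test_startprob_can_be_held_fixed(self, rng):
        spec = GeneratorSpec(seed=4, n_epochs=200)
        x = sample_features(sample_hypnogram(spec), spec)
        st = GaussianHMMStager(update_startprob=False).fit(x)
        assert st.startprob_.tolist() == [1.0, 0.0, 0.0, 0.0]


class TestViterbi:
    def test_single_epoch_decodes_to_wake_under_prior(self, rng):
        x = rng.uniform(0, 1, size=(1, 4))
        hyp = viterbi_decode(x, init_params())
        assert hyp.stages.tolist() == [0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        params = random_params(rng)
        x = rng.uniform(0, 1, size=(n, 4))
        assert np.array_equal(_viterbi_path(x, params), brute_force_path(x, params))

    def test_forbidden_direct_transition_routes_through_light(self):
        p = init_params()
        sharp = HMMParameters(p.initial_probs, p.transition,
                              p.emission_means, np.full((4, 4), 0.05))
        x = np.vstack([np.tile(p.emission_means[0], (3, 1)),
                       np.tile(p.emission_means[3], (5, 1))])
        path = _viterbi_path(x, sharp)
        assert path[0] == 0 and path[-1] == 3
        # Wake->Deep has zero prior probability, so Light must appear between
        first_deep = int(np.argmax(path == 3))
        assert 2 in path[:first_deep]
        assert brute_force_path(x, sharp).tolist() == path.tolist()

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="4 band columns"):
            viterbi_decode(rng.uniform(size=(5, 3)), init_params())


class TestScoreSleep:
    def test_two_half_night_recovers_dominant_stages(self):
        # 10 min Wake-dominant band noise followed by 10 min Deep-dominant
        spec = GeneratorSpec(seed=0, n_epochs=40)
        stages = np.array([0] * 20 + [3] * 20, dtype=np.int8)
        from sleepkit import Hypnogram

        hyp = Hypnogram(stages)
        eeg = synthesize_eeg(hyp, spec)
        decoded = score_sleep(eeg, 100.0)
        assert np.mean(decoded.stages[:20] == 0) >= 0.8
        assert np.mean(decoded.stages[20:] == 3) >= 0.8

    def test_59s_signal_yields_single_epoch(self, rng):
        sig = rng.standard_normal(5900)
        hyp = score_sleep(sig, 100.0)
        assert len(hyp) == 1

    def test_deterministic_given_identical_input(self, rng):
        spec = GeneratorSpec(seed=21, n_epochs=10)
        eeg = synthesize_eeg(sample_hypnogram(spec), spec)
        a = score_sleep(eeg, 100.0)
        b = score_sleep(eeg.copy(), 100.0)
        assert np.array_equal(a.stages, b.stages)
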