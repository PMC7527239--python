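"""Memory-adjusted HMM: oracles, truncation, smoothing, EM, decoding."""
import math
import warnings

import numpy as np
import pytest

from burstkin import (
    build_emission_model,
    decode_promoter,
    dwell_time_check,
    exact_forward_oracle,
    fit_em,
    forward_backward,
    forward_loglik,
    render_trace,
    simulate_promoter_path,
)
from burstkin.mhmm import (
    InsufficientDataError,
    batch_forward_backward,
    emission_mean,
    state_emission_means,
)
from burstkin.types import (
    EmissionModel,
    GlobalParams,
    InvalidParameterError,
    KineticParams,
    PromoterPath,
    Trace,
)

from conftest import DT, enumerate_posterior, make_traces


class TestEmissionModel:
    def test_window_length_from_gene_geometry(self):
        em = build_emission_model(5.0, 1.3, 1.5, DT)
        # elongation time 10/3 min over 1/3-min frames -> 10-frame window
        assert em.K == 10

    def test_tiny_cassette_saturates_immediately(self):
        em = build_emission_model(3.0, 1e-9, 1.5, DT)
        assert np.all(em.weights == 1.0)

    def test_first_weight_midpoint_rule(self):
        em = build_emission_model(3.0, 1.3, 1.5, DT)
        assert em.weights[0] == pytest.approx(0.5 * DT * 1.5 / 1.3, abs=1e-10)
        assert em.weights[0] == pytest.approx(0.1923, abs=1e-4)
        # non-decreasing up to saturation at 1
        assert np.all(np.diff(em.weights) >= 0)
        assert em.weights.max() <= 1.0

    def test_emission_means(self, emission_k6, global_truth):
        amp = global_truth.kinetics.k_ini * DT
        assert emission_mean(0, global_truth, emission_k6) == 0.0
        # only the newest frame ON -> w_0 term
        assert emission_mean(1, global_truth, emission_k6) == pytest.approx(
            amp * emission_k6.weights[0]
        )
        em_sat = EmissionModel(weights=np.ones(4), dt=DT, v=2.0)
        full = (1 << 4) - 1
        assert emission_mean(full, global_truth, em_sat) == pytest.approx(2.0 * amp * 4)
        # table agrees with the scalar routine
        table = state_emission_means(global_truth, emission_k6)
        for s in (0, 1, 5, 63):
            assert table[s] == pytest.approx(emission_mean(s, global_truth, emission_k6))

    def test_invalid_geometry(self):
        with pytest.raises(InvalidParameterError):
            build_emission_model(0.0, 1.3, 1.5, DT)


def _short_trace(emission, params, T, seed, noise_sd=2.0, missing=()):
    path = simulate_promoter_path(params.kinetics, T, emission.dt, seed=seed)
    return render_trace(path, params.kinetics.k_ini, emission, noise_sd=noise_sd,
                        seed=seed + 1, missing_frames=missing)


class TestForward:
    def test_matches_enumeration_oracle(self, emission_k6, global_truth):
        """Untruncated forward equals the brute-force 2^T path sum."""
        for T, seed in ((6, 0), (10, 3), (12, 8)):
            tr = _short_trace(emission_k6, global_truth, T, seed)
            ll_enum, _ = enumerate_posterior(tr, global_truth, emission_k6)
            ll, _ = forward_loglik(tr, global_truth, emission_k6, M=2**emission_k6.K)
            assert ll == pytest.approx(ll_enum, abs=1e-8)

    def test_matches_exact_oracle_at_full_beam(self, emission_k6, global_truth):
        tr = _short_trace(emission_k6, global_truth, 60, 4)
        ll, _ = forward_loglik(tr, global_truth, emission_k6, M=2**emission_k6.K)
        assert ll == pytest.approx(exact_forward_oracle(tr, global_truth, emission_k6), abs=1e-8)

    def test_missing_frames_skip_emission(self, emission_k6, global_truth):
        tr = _short_trace(emission_k6, global_truth, 10, 5, missing=(2, 6))
        ll_enum, _ = enumerate_posterior(tr, global_truth, emission_k6)
        ll, _ = forward_loglik(tr, global_truth, emission_k6, M=2**emission_k6.K)
        assert ll == pytest.approx(ll_enum, abs=1e-8)

    def test_k1_reduces_to_two_state_hmm(self, global_truth):
        """K=1 loglik matches an independent textbook 2-state recursion and hmmlearn."""
        em1 = EmissionModel(weights=np.array([1.0]), dt=DT)
        tr = _short_trace(em1, global_truth, 80, 6)
        ll, _ = forward_loglik(tr, global_truth, em1, M=2)

        p01, p10 = global_truth.kinetics.switch_probabilities(DT)
        occ = global_truth.kinetics.occupancy
        mus = np.array([0.0, global_truth.kinetics.k_ini * DT])
        sig = global_truth.sigma

        def norm(f, mu):
            return math.exp(-0.5 * ((f - mu) / sig) ** 2) / (sig * math.sqrt(2 * math.pi))

        alpha = np.array([(1 - occ) * norm(tr.fluor[0], mus[0]),
                          occ * norm(tr.fluor[0], mus[1])])
        ll_direct = 0.0
        A = np.array([[1 - p01, p01], [p10, 1 - p10]])
        for t in range(1, tr.n_frames):
            alpha = (alpha @ A) * [norm(tr.fluor[t], mus[0]), norm(tr.fluor[t], mus[1])]
            s = alpha.sum()
            ll_direct += math.log(s)
            alpha /= s
        ll_direct += math.log(alpha.sum())  # alpha is normalized; adds 0
        assert ll == pytest.approx(ll_direct, abs=1e-8)

        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        h = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        h.startprob_ = np.array([1 - occ, occ])
        h.transmat_ = A
        h.means_ = mus.reshape(-1, 1)
        h.covars_ = np.array([[sig**2], [sig**2]])
        assert ll == pytest.approx(h.score(tr.fluor.reshape(-1, 1)), abs=1e-6)

    def test_single_frame_closed_form(self, emission_k6, global_truth):
        tr = Trace(0, np.array([0.0]), np.array([3.0]), None)
        occ = global_truth.kinetics.occupancy
        sig = global_truth.sigma
        mu1 = global_truth.kinetics.k_ini * DT * emission_k6.weights[0]
        expected = math.log(
            (1 - occ) * math.exp(-0.5 * (3.0 / sig) ** 2) / (sig * math.sqrt(2 * math.pi))
            + occ * math.exp(-0.5 * ((3.0 - mu1) / sig) ** 2) / (sig * math.sqrt(2 * math.pi))
        )
        ll, _ = forward_loglik(tr, global_truth, emission_k6, M=4)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_truncation_error_non_increasing_in_M(self, emission_k6, global_truth):
        """|L_M - L_exact| shrinks (weakly) as the beam widens."""
        traces = [
            _short_trace(emission_k6, global_truth, 80, s, noise_sd=3.0)
            for s in range(5)
        ]
        exact = [exact_forward_oracle(tr, global_truth, emission_k6) for tr in traces]
        errs = []
        for M in (4, 16, 64, 256):
            ll = [forward_loglik(tr, global_truth, emission_k6, M)[0] for tr in traces]
            errs.append(sum(abs(a - b) for a, b in zip(ll, exact)))
        for lo, hi in zip(errs[1:], errs[:-1]):
            assert lo <= hi + 1e-12
        assert errs[-1] < 1e-8  # M = 256 >= 2^6: no truncation at all


class TestForwardBackward:
    def test_posteriors_match_enumeration(self, emission_k6, global_truth):
        for T, seed in ((8, 1), (12, 9)):
            tr = _short_trace(emission_k6, global_truth, T, seed)
            _, p_on_enum = enumerate_posterior(tr, global_truth, emission_k6)
            post = forward_backward(tr, global_truth, emission_k6, M=2**emission_k6.K)
            assert np.abs(post.p_on - p_on_enum).max() < 1e-8

    def test_transition_counts_sum(self, emission_k6, global_truth):
        tr = _short_trace(emission_k6, global_truth, 40, 2)
        post = forward_backward(tr, global_truth, emission_k6, M=16)
        assert post.transition_counts.sum() == pytest.approx(tr.n_frames - 1)
        assert (post.transition_counts >= 0).all()

    def test_noiseless_trace_recovers_true_path(self, emission_k6, truth_params):
        path = simulate_promoter_path(truth_params, 60, DT, seed=11)
        tr = render_trace(path, truth_params.k_ini, emission_k6, noise_sd=0.0)
        sharp = GlobalParams(truth_params, sigma=1e-3)
        post = forward_backward(tr, sharp, emission_k6, M=2**emission_k6.K)
        on = post.p_on > 0.5
        assert np.array_equal(on.astype(np.int8), path.states)
        assert np.all(np.abs(post.p_on - path.states) < 1e-3)

    def test_batch_sweep_agrees_with_per_trace(self, emission_k6, global_truth, truth_params):
        traces, _ = make_traces(truth_params, emission_k6, 4, 50, 3.0, seed=21)
        ll_b, counts_b, p_on_b = batch_forward_backward(traces, global_truth, emission_k6)
        ll_s, counts_s = 0.0, np.zeros((2, 2))
        for i, tr in enumerate(traces):
            post = forward_backward(tr, global_truth, emission_k6, M=2**emission_k6.K)
            ll_s += post.loglik
            counts_s += post.transition_counts
            assert np.abs(post.p_on - p_on_b[i]).max() < 1e-8
        assert ll_b == pytest.approx(ll_s, abs=1e-6)
        assert np.allclose(counts_b, counts_s, atol=1e-6)


class TestEM:
    def test_parameter_recovery(self, emission_k6, truth_params):
        """EM at modest scale recovers k_on/k_off within 20% relative error."""
        traces, _ = make_traces(truth_params, emission_k6, 80, 150, 3.0, seed=31)
        init = GlobalParams(KineticParams(0.3, 0.6, 10.0), sigma=5.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = fit_em(traces, init, emission_k6, M=64, tol=1e-5, max_iter=60,
                         n_restarts=1, seed=0)
        k = res.params.kinetics
        assert abs(k.k_on - 0.5) / 0.5 < 0.2
        assert abs(k.k_off - 1.0) / 1.0 < 0.2
        assert abs(k.k_ini - 20.0) / 20.0 < 0.2

    def test_loglik_improves_from_init(self, emission_k6, truth_params):
        traces, _ = make_traces(truth_params, emission_k6, 10, 80, 3.0, seed=41)
        init = GlobalParams(KineticParams(0.3, 0.6, 10.0), sigma=5.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = fit_em(traces, init, emission_k6, M=64, tol=1e-5, max_iter=40,
                         n_restarts=1, seed=0)
        assert res.loglik_history[-1] >= res.loglik_history[0]

    def test_truncated_beam_em_close_to_dense(self, emission_k6, truth_params):
        """EM with a pruning beam lands near the untruncated fit."""
        traces, _ = make_traces(truth_params, emission_k6, 25, 120, 3.0, seed=51)
        init = GlobalParams(KineticParams(0.3, 0.6, 10.0), sigma=5.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dense = fit_em(traces, init, emission_k6, M=64, tol=1e-4, max_iter=40,
                           n_restarts=1, seed=0)
            beam = fit_em(traces, init, emission_k6, M=24, tol=1e-4, max_iter=40,
                          n_restarts=1, seed=0)
        assert beam.params.kinetics.k_on == pytest.approx(
            dense.params.kinetics.k_on, rel=0.1
        )
        assert beam.params.kinetics.k_off == pytest.approx(
            dense.params.kinetics.k_off, rel=0.1
        )

    def test_empty_input_rejected(self, emission_k6, global_truth):
        with pytest.raises(InsufficientDataError):
            fit_em([], global_truth, emission_k6)


class TestDecodeAndDwells:
    def test_noiseless_decode_exact(self, emission_k6, truth_params):
        path = simulate_promoter_path(truth_params, 100, DT, seed=13)
        tr = render_trace(path, truth_params.k_ini, emission_k6, noise_sd=0.0)
        sharp = GlobalParams(truth_params, sigma=1e-3)
        decoded = decode_promoter(tr, sharp, emission_k6, M=64)
        assert np.array_equal(decoded.states, path.states)

    def test_all_zero_trace_decodes_off(self, emission_k6, global_truth):
        tr = Trace(0, np.arange(40) * DT, np.zeros(40), None)
        decoded = decode_promoter(tr, global_truth, emission_k6, M=64)
        assert decoded.states.sum() == 0

    def test_decode_error_small_at_snr_10(self, emission_k6, truth_params):
        """Frame disagreement < 5% when plateau/sigma >= 10."""
        plateau = truth_params.k_ini * DT * emission_k6.weights.sum()
        sigma = plateau / 10.0
        traces, paths = make_traces(truth_params, emission_k6, 20, 100, sigma, seed=61)
        model = GlobalParams(truth_params, sigma=sigma)
        _, _, p_on = batch_forward_backward(traces, model, emission_k6)
        err = np.mean([
            np.mean((p > 0.5).astype(np.int8) != path.states)
            for p, path in zip(p_on, paths)
        ])
        assert err < 0.05

    def test_dwell_mean_matches_geometric(self, truth_params):
        """Mean ON dwell ~ 1/p10 = 1/(1-exp(-k_off dt)) frames."""
        paths = [simulate_promoter_path(truth_params, 3000, DT, seed=s) for s in range(30)]
        rep = dwell_time_check(paths)
        expected = 1.0 / (1.0 - math.exp(-1.0 * DT))
        n = rep.on_dwells.size
        se = rep.on_dwells.std() / math.sqrt(n)
        assert abs(rep.on_dwells.mean() - expected) < 3 * se
        assert expected == pytest.approx(3.53, abs=0.01)

    def test_constant_path_insufficient(self):
        path = PromoterPath(np.ones(500, dtype=np.int8), DT)
        with pytest.raises(InsufficientDataError):
            dwell_time_check([path])

    def test_dwells_invariant_to_concatenation_order(self, truth_params):
        paths = [simulate_promoter_path(truth_params, 2000, DT, seed=s) for s in range(10)]
        a = dwell_time_check(paths)
        b = dwell_time_check(paths[::-1])
        assert a.p_hat_on_exit == pytest.approx(b.p_hat_on_exit)
        assert a.p_hat_off_exit == pytest.approx(b.p_hat_off_exit)
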