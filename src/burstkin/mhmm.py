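"""Memory-adjusted hidden Markov model for MS2 fluorescence traces.

A nascent transcript keeps emitting MS2/MCP fluorescence for the whole
time its Pol II travels along the gene, so the observed signal at frame t
depends on the promoter's state over the last K frames (the elongation
window), not just the current one.  The hidden state is therefore the
compound K-bit promoter history, a 2^K state space.  For realistic K this
is too large for the exact forward-backward recursion, so the forward
pass is truncated to the top-M states by (unnormalized) forward weight at
every frame — a beam search over promoter histories.  The backward pass
is restricted to the states the forward beam retained.

State encoding: an integer whose bit i is the promoter state i frames ago
(bit 0 = the current frame).  Appending a new frame shifts the history
left and drops the oldest bit, so every state has exactly two successors
and two predecessors.

EM alternates truncated forward-backward smoothing (E-step) with
closed-form updates (M-step): switching probabilities from expected
transition counts (converted to rates via k = -ln(1-p)/dt), the amplitude
v*k_ini by least squares of the signal against the posterior-expected
loading, and a shared Gaussian noise SD from the residuals.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .types import (
    EmissionModel,
    GlobalParams,
    InvalidParameterError,
    KineticParams,
    PosteriorSummary,
    PromoterPath,
    Trace,
)

__all__ = [
    "build_emission_model",
    "emission_mean",
    "state_emission_means",
    "forward_loglik",
    "exact_forward_oracle",
    "forward_backward",
    "fit_em",
    "EMResult",
    "decode_promoter",
    "dwell_time_check",
    "DwellTimeReport",
]

_LOG2PI = math.log(2.0 * math.pi)


class BeamCollapseError(FloatingPointError):
    """All forward weights underflowed to -inf at some frame."""


class InsufficientDataError(ValueError):
    pass


# -- emission model -----------------------------------------------------------


def build_emission_model(
    gene_length_kb: float,
    ms2_cassette_kb: float,
    elongation_speed_kb_per_min: float,
    dt: float,
    v: float = 1.0,
) -> EmissionModel:
    """Elongation window from gene geometry.

    K = ceil(elongation_time / dt) frames, where elongation_time =
    gene_length / speed.  A Pol II loaded i frames ago has travelled
    (i + 0.5)*dt*speed kb (midpoint rule), so the fraction of the MS2
    cassette it has transcribed — its relative brightness — is
    w_i = min(1, (i + 0.5)*dt*speed / cassette_length).  The cassette is
    assumed to sit at the 5' end, as in the MS2 knock-in lines.
    """
    if min(gene_length_kb, ms2_cassette_kb, elongation_speed_kb_per_min, dt) <= 0:
        raise InvalidParameterError("gene geometry values must all be > 0")
    # tolerance guards ceil against float fuzz (e.g. 10.000000000000002)
    K = int(math.ceil(gene_length_kb / elongation_speed_kb_per_min / dt - 1e-9))
    if K < 1:
        raise InvalidParameterError("elongation window shorter than one frame")
    lags = np.arange(K)
    w = np.minimum(1.0, (lags + 0.5) * dt * elongation_speed_kb_per_min / ms2_cassette_kb)
    return EmissionModel(weights=w, dt=dt, v=v)


def state_emission_means(params: GlobalParams, emission: EmissionModel) -> np.ndarray:
    """Expected fluorescence for every compound state, indexed by state integer."""
    K = emission.K
    states = np.arange(2**K, dtype=np.int64)
    bits = (states[:, None] >> np.arange(K)[None, :]) & 1
    amp = emission.v * params.kinetics.k_ini * emission.dt
    return amp * (bits * emission.weights[None, :]).sum(axis=1)


def emission_mean(state: int, params: GlobalParams, emission: EmissionModel) -> float:
    """mu(z) = v * k_ini * dt * sum_i w_i z_i for one compound state."""
    K = emission.K
    bits = (state >> np.arange(K)) & 1
    amp = emission.v * params.kinetics.k_ini * emission.dt
    return float(amp * (bits * emission.weights).sum())


def _log_transition(params: GlobalParams, dt: float) -> np.ndarray:
    """2x2 log transition matrix [from_bit, to_bit]."""
    p01, p10 = params.kinetics.switch_probabilities(dt)
    with np.errstate(divide="ignore"):
        return np.log(np.array([[1.0 - p01, p01], [p10, 1.0 - p10]]))


def _log_pi(params: GlobalParams) -> np.ndarray:
    occ = params.kinetics.occupancy
    return np.log(np.array([1.0 - occ, occ]))


def _log_emission(fluor: np.ndarray, missing: np.ndarray, mu: np.ndarray, sigma: float) -> np.ndarray:
    """(T, S) log N(F_t; mu_s, sigma); zero (skipped) for missing frames."""
    resid = fluor[:, None] - mu[None, :]
    ll = -0.5 * (resid / sigma) ** 2 - math.log(sigma) - 0.5 * _LOG2PI
    ll[missing, :] = 0.0
    return ll


# -- beam (truncated) forward and forward-backward ---------------------------


def _top_m(states: np.ndarray, logw: np.ndarray, M: int) -> tuple[np.ndarray, np.ndarray]:
    """Retain the top-M entries by weight; ties broken by smaller state integer."""
    if states.size <= M:
        order = np.argsort(states)
        return states[order], logw[order]
    # lexsort: primary key -logw (descending weight), secondary key state value
    order = np.lexsort((states, -logw))[:M]
    keep = np.sort(order)  # keep frame-local state ordering for stable search
    return states[keep], logw[keep]


def _merge_duplicates(states: np.ndarray, logw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inv = np.unique(states, return_inverse=True)
    if uniq.size == states.size:
        return uniq, logw[np.argsort(states)]
    merged = np.full(uniq.size, -np.inf)
    # grouped logsumexp without per-group python loops: max then sum of exps
    np.maximum.at(merged, inv, logw)
    acc = np.zeros(uniq.size)
    np.add.at(acc, inv, np.exp(logw - merged[inv]))
    with np.errstate(divide="ignore"):
        return uniq, merged + np.log(acc)


def _beam_forward(
    trace: Trace, params: GlobalParams, emission: EmissionModel, M: int
) -> tuple[float, list[np.ndarray], list[np.ndarray], np.ndarray, np.ndarray]:
    if M < 1:
        raise InvalidParameterError(f"M must be >= 1, got {M}")
    K = emission.K
    mask = (1 << K) - 1
    mu = state_emission_means(params, emission)
    logT = _log_transition(params, emission.dt)
    logpi = _log_pi(params)
    fluor, missing = trace.fluor, trace.missing
    T = trace.n_frames

    def em_term(t: int, states: np.ndarray) -> np.ndarray:
        if missing[t]:
            return np.zeros(states.size)
        r = fluor[t] - mu[states]
        return -0.5 * (r / params.sigma) ** 2 - math.log(params.sigma) - 0.5 * _LOG2PI

    # frame 0: zero-padded history, promoter bit from the stationary law
    states = np.array([0, 1], dtype=np.int64)
    logw = logpi + em_term(0, states)
    states, logw = _top_m(states, logw, M)
    beam_states = [states]
    beam_logw = [logw]
    for t in range(1, T):
        cur_bit = states & 1
        base = (states << 1) & mask
        cand = np.concatenate([base, base | 1])
        cand_w = np.concatenate([logw + logT[cur_bit, 0], logw + logT[cur_bit, 1]])
        cand, cand_w = _merge_duplicates(cand, cand_w)
        cand_w = cand_w + em_term(t, cand)
        states, logw = _top_m(cand, cand_w, M)
        if not np.isfinite(logw).any():
            raise BeamCollapseError(f"beam collapsed at frame {t}")
        beam_states.append(states)
        beam_logw.append(logw)
    loglik = float(logsumexp(beam_logw[-1]))
    return loglik, beam_states, beam_logw, mu, logT


def forward_loglik(
    trace: Trace, params: GlobalParams, emission: EmissionModel, M: int
) -> tuple[float, list[tuple[np.ndarray, np.ndarray]]]:
    """Truncated forward pass; returns (log-likelihood, beam per frame).

    With M >= 2^K no state is ever pruned and the result equals the exact
    forward recursion.  Missing frames contribute no emission term but
    keep the transition structure.
    """
    loglik, bs, bw, _, _ = _beam_forward(trace, params, emission, M)
    return loglik, list(zip(bs, bw))


def exact_forward_oracle(
    trace: Trace, params: GlobalParams, emission: EmissionModel, max_K: int = 10
) -> float:
    """Untruncated forward log-likelihood by dense scaled recursion.

    Independent of the beam machinery: works in linear space over the full
    2^K state vector with per-frame scaling.  Guarded to small K, where
    the dense sweep is affordable; intended as a reference value for
    truncation tests.
    """
    K = emission.K
    if K > max_K:
        raise InvalidParameterError(f"exact oracle limited to K <= {max_K}, got K={K}")
    S = 2**K
    mask = S - 1
    mu = state_emission_means(params, emission)
    p01, p10 = params.kinetics.switch_probabilities(emission.dt)
    Tmat = np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])
    occ = params.kinetics.occupancy
    fluor, missing = trace.fluor, trace.missing
    sigma = params.sigma

    def em_lin(t: int) -> np.ndarray:
        if missing[t]:
            return np.ones(S)
        return np.exp(-0.5 * ((fluor[t] - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))

    alpha = np.zeros(S)
    alpha[0] = 1.0 - occ
    alpha[1] = occ
    alpha *= em_lin(0)
    log_scale = 0.0
    states = np.arange(S, dtype=np.int64)
    succ0 = (states << 1) & mask
    succ1 = succ0 | 1
    cur_bit = states & 1
    for t in range(1, trace.n_frames):
        new = np.zeros(S)
        np.add.at(new, succ0, alpha * Tmat[cur_bit, 0])
        np.add.at(new, succ1, alpha * Tmat[cur_bit, 1])
        new *= em_lin(t)
        s = new.sum()
        if s <= 0:
            raise FloatingPointError(f"forward underflow at frame {t}")
        log_scale += math.log(s)
        alpha = new / s
    return float(log_scale)


def forward_backward(
    trace: Trace, params: GlobalParams, emission: EmissionModel, M: int
) -> PosteriorSummary:
    """Beam-restricted forward-backward smoothing for one trace.

    The backward recursion only visits states retained by the forward
    beam at each frame; posterior marginals are renormalized within the
    retained set.  P(on)_t is the posterior probability that the newest
    history bit is 1; expected 2x2 transition counts are aggregated from
    the pairwise posteriors and sum to n_frames - 1.
    """
    loglik, bs, bw, mu, logT = _beam_forward(trace, params, emission, M)
    T = trace.n_frames
    K = emission.K
    mask = (1 << K) - 1
    fluor, missing, sigma = trace.fluor, trace.missing, params.sigma

    def em_term(t: int, states: np.ndarray) -> np.ndarray:
        if missing[t]:
            return np.zeros(states.size)
        r = fluor[t] - mu[states]
        return -0.5 * (r / sigma) ** 2 - math.log(sigma) - 0.5 * _LOG2PI

    betas: list[np.ndarray] = [np.zeros(bs[-1].size)]
    counts = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        s_t, w_t = bs[t], bw[t]
        s_n = bs[t + 1]  # sorted by construction
        beta_next = betas[0]
        em_next = em_term(t + 1, s_n)
        cur_bit = s_t & 1
        base = (s_t << 1) & mask
        beta_t = np.full(s_t.size, -np.inf)
        contrib = []  # (to_bit, idx_in_t, idx_in_next, log term)
        for b in (0, 1):
            succ = base | b
            pos = np.searchsorted(s_n, succ)
            ok = (pos < s_n.size) & (s_n[np.minimum(pos, s_n.size - 1)] == succ)
            if ok.any():
                idx = np.where(ok)[0]
                p = pos[idx]
                term = logT[cur_bit[idx], b] + em_next[p] + beta_next[p]
                beta_t[idx] = np.logaddexp(beta_t[idx], term)
                contrib.append((b, idx, p, term))
        # pairwise posteriors for expected transition counts
        for b, idx, p, term in contrib:
            xi = np.exp(w_t[idx] + term - loglik)
            for a in (0, 1):
                sel = cur_bit[idx] == a
                counts[a, b] += xi[sel].sum()
        betas.insert(0, beta_t)
    # per-frame marginals
    p_on = np.empty(T)
    for t in range(T):
        gamma = bw[t] + betas[t]
        gamma -= logsumexp(gamma)
        p_on[t] = float(np.exp(logsumexp(gamma[(bs[t] & 1) == 1]))) if ((bs[t] & 1) == 1).any() else 0.0
    # truncated mass makes counts sum slightly short of T-1; renormalize
    total = counts.sum()
    if total > 0 and T > 1:
        counts *= (T - 1) / total
    return PosteriorSummary(
        nucleus_id=trace.nucleus_id, p_on=p_on, transition_counts=counts, loglik=loglik
    )


# -- batched dense forward-backward (untruncated E-step) ----------------------


def _dense_batch_e_step(
    fluor: np.ndarray,  # (N, T)
    missing: np.ndarray,  # (N, T) bool
    params: GlobalParams,
    emission: EmissionModel,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact E-step over equal-length traces, vectorized across traces.

    Returns (total loglik, pooled expected 2x2 transition counts,
    per-trace-frame P(on) of shape (N, T)).  Used by EM whenever the full
    2^K state space fits the beam width, where it is equivalent to the
    beam E-step but orders of magnitude faster.
    """
    N, T = fluor.shape
    K = emission.K
    S = 2**K
    mask = S - 1
    mu = state_emission_means(params, emission)
    logT = _log_transition(params, emission.dt)
    logpi = _log_pi(params)
    sigma = params.sigma
    states = np.arange(S, dtype=np.int64)
    pred0 = states >> 1
    pred1 = pred0 | (1 << (K - 1))
    in_bit = states & 1
    prev_bit = pred0 & 1  # both predecessors share the current-frame bit
    logT_in = logT[prev_bit, in_bit]  # (S,) log p(step into state s)
    succ0 = (states << 1) & mask
    succ1 = succ0 | 1
    cur_bit = states & 1

    logem = -0.5 * ((fluor[:, :, None] - mu[None, None, :]) / sigma) ** 2 - math.log(
        sigma
    ) - 0.5 * _LOG2PI
    logem[missing, :] = 0.0

    alpha = np.full((N, T, S), -np.inf)
    alpha[:, 0, 0] = logpi[0] + logem[:, 0, 0]
    alpha[:, 0, 1] = logpi[1] + logem[:, 0, 1]
    with np.errstate(invalid="ignore"):
        for t in range(1, T):
            prev = alpha[:, t - 1, :]
            alpha[:, t, :] = (
                np.logaddexp(prev[:, pred0], prev[:, pred1]) + logT_in[None, :] + logem[:, t, :]
            )
    loglik_per = logsumexp(alpha[:, -1, :], axis=1)
    total_loglik = float(loglik_per.sum())

    beta = np.full((N, T, S), -np.inf)
    beta[:, -1, :] = 0.0
    with np.errstate(invalid="ignore"):
        for t in range(T - 2, -1, -1):
            nxt = logem[:, t + 1, :] + beta[:, t + 1, :]
            beta[:, t, :] = np.logaddexp(
                logT[cur_bit, 0][None, :] + nxt[:, succ0],
                logT[cur_bit, 1][None, :] + nxt[:, succ1],
            )

    gamma = alpha + beta - loglik_per[:, None, None]
    post = np.exp(gamma)
    on_mask = (states & 1) == 1
    p_on = post[:, :, on_mask].sum(axis=2)

    counts = np.zeros((2, 2))
    with np.errstate(invalid="ignore"):
        for t in range(T - 1):
            nxt = logem[:, t + 1, :] + beta[:, t + 1, :]
            for b, succ in ((0, succ0), (1, succ1)):
                xi = np.exp(
                    alpha[:, t, :] + logT[cur_bit, b][None, :] + nxt[:, succ]
                    - loglik_per[:, None]
                )
                for a in (0, 1):
                    counts[a, b] += xi[:, cur_bit == a].sum()
    return total_loglik, counts, p_on


def batch_forward_backward(
    traces: list[Trace], params: GlobalParams, emission: EmissionModel
) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact (untruncated) forward-backward over equal-length traces.

    Convenience wrapper around the dense batched sweep: returns
    (total log-likelihood, pooled expected 2x2 transition counts,
    per-trace-frame P(on) of shape (n_traces, n_frames)).  Requires all
    traces to share a length; use :func:`forward_backward` otherwise.
    """
    if len({tr.n_frames for tr in traces}) != 1:
        raise InvalidParameterError("batch sweep requires equal-length traces")
    fluor = np.stack([tr.fluor for tr in traces])
    missing = np.stack([tr.missing for tr in traces])
    return _dense_batch_e_step(fluor, missing, params, emission)


# -- EM -----------------------------------------------------------------------


@dataclass
class EMResult:
    params: GlobalParams
    loglik_history: list[float]
    converged: bool
    n_iter: int
    warnings: list[str]


def _m_step(
    counts: np.ndarray,
    p_on: np.ndarray,  # (N, T)
    fluor: np.ndarray,
    missing: np.ndarray,
    emission: EmissionModel,
    min_rate: float = 1e-4,
    max_p: float = 1 - 1e-10,
) -> tuple[KineticParams, float]:
    dt = emission.dt
    with np.errstate(invalid="ignore"):
        p01 = counts[0, 1] / max(counts[0, 0] + counts[0, 1], 1e-12)
        p10 = counts[1, 0] / max(counts[1, 0] + counts[1, 1], 1e-12)
    p01 = float(np.clip(p01, 1 - math.exp(-min_rate * dt), max_p))
    p10 = float(np.clip(p10, 1 - math.exp(-min_rate * dt), max_p))
    k_on = -math.log(1.0 - p01) / dt
    k_off = -math.log(1.0 - p10) / dt
    # amplitude a = v*k_ini from least squares of F_t on dt * sum_i w_i E[z_{t-i}]
    w = emission.weights
    x = np.apply_along_axis(lambda row: np.convolve(row, w)[: row.size], 1, p_on) * dt
    obs = ~missing
    xv, fv = x[obs], fluor[obs]
    sxx = float((xv * xv).sum())
    amp = float((xv * fv).sum() / sxx) if sxx > 1e-12 else 1e-6
    amp = max(amp, 1e-6)
    resid = fv - amp * xv
    sigma = max(float(np.sqrt((resid**2).mean())), 1e-6)
    k_ini = amp / emission.v
    return KineticParams(k_on=k_on, k_off=k_off, k_ini=k_ini), sigma


def fit_em(
    traces: list[Trace],
    init: GlobalParams,
    emission: EmissionModel,
    M: int = 128,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 5,
    seed: int = 0,
    region: str = "",
) -> EMResult:
    """EM estimation of global kinetic parameters over pooled traces.

    E-step: forward-backward smoothing (dense batched sweep when
    M >= 2^K and all traces share a length; beam-truncated per trace
    otherwise).  M-step: closed-form updates described in the module
    docstring.  Restarts perturb the initial rates multiplicatively
    (seeded lognormal); the restart with the best final log-likelihood
    wins.  The log-likelihood is monotone up to truncation error; any
    decrease beyond 1e-6 relative is recorded as a warning, not an error.
    """
    if not traces:
        raise InsufficientDataError("need at least one retained trace")
    K = emission.K
    lengths = {tr.n_frames for tr in traces}
    use_dense = M >= 2**K and len(lengths) == 1
    if use_dense:
        fluor = np.stack([tr.fluor for tr in traces])
        missing = np.stack([tr.missing for tr in traces])
    rng = np.random.default_rng(seed)
    best: EMResult | None = None
    for restart in range(max(n_restarts, 1)):
        if restart == 0:
            params = init
        else:
            f = rng.lognormal(0.0, 0.3, size=3)
            params = GlobalParams(
                kinetics=KineticParams(
                    init.kinetics.k_on * f[0],
                    init.kinetics.k_off * f[1],
                    init.kinetics.k_ini * f[2],
                ),
                sigma=init.sigma,
                region=region,
            )
        history: list[float] = []
        warn_msgs: list[str] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            if use_dense:
                loglik, counts, p_on = _dense_batch_e_step(fluor, missing, params, emission)
            else:
                loglik = 0.0
                counts = np.zeros((2, 2))
                p_on_list = []
                for tr in traces:
                    post = forward_backward(tr, params, emission, M)
                    loglik += post.loglik
                    counts += post.transition_counts
                    p_on_list.append(post.p_on)
            if history:
                rel = (loglik - history[-1]) / max(abs(history[-1]), 1.0)
                if rel < -1e-6:
                    warn_msgs.append(
                        f"loglik decreased at iter {it} (rel {rel:.2e}); "
                        "possible truncation artifact"
                    )
                if abs(rel) < tol:
                    history.append(loglik)
                    converged = True
                    break
            history.append(loglik)
            if use_dense:
                kin, sigma = _m_step(counts, p_on, fluor, missing, emission)
            else:
                fl = np.stack([tr.fluor for tr in traces]) if len(lengths) == 1 else None
                if fl is not None:
                    kin, sigma = _m_step(
                        counts,
                        np.stack(p_on_list),
                        fl,
                        np.stack([tr.missing for tr in traces]),
                        emission,
                    )
                else:
                    kin, sigma = _m_step_ragged(counts, p_on_list, traces, emission)
            params = GlobalParams(kinetics=kin, sigma=sigma, region=region)
        if not converged:
            warn_msgs.append(f"EM did not converge within {max_iter} iterations")
        res = EMResult(params, history, converged, it, warn_msgs)
        if best is None or res.loglik_history[-1] > best.loglik_history[-1]:
            best = res
    assert best is not None
    for msg in best.warnings:
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return best


def _m_step_ragged(
    counts: np.ndarray,
    p_on_list: list[np.ndarray],
    traces: list[Trace],
    emission: EmissionModel,
) -> tuple[KineticParams, float]:
    w, dt = emission.weights, emission.dt
    sxx = sxy = sse_n = 0.0
    xs, fs = [], []
    for p_on, tr in zip(p_on_list, traces):
        x = np.convolve(p_on, w)[: p_on.size] * dt
        obs = ~tr.missing
        xs.append(x[obs])
        fs.append(tr.fluor[obs])
    xv = np.concatenate(xs)
    fv = np.concatenate(fs)
    sxx = float((xv * xv).sum())
    amp = float((xv * fv).sum() / sxx) if sxx > 1e-12 else 1e-6
    amp = max(amp, 1e-6)
    sigma = max(float(np.sqrt(((fv - amp * xv) ** 2).mean())), 1e-6)
    dtv = dt
    p01 = counts[0, 1] / max(counts[0, 0] + counts[0, 1], 1e-12)
    p10 = counts[1, 0] / max(counts[1, 0] + counts[1, 1], 1e-12)
    p01 = float(np.clip(p01, 1e-8, 1 - 1e-10))
    p10 = float(np.clip(p10, 1e-8, 1 - 1e-10))
    return (
        KineticParams(-math.log(1 - p01) / dtv, -math.log(1 - p10) / dtv, amp / emission.v),
        sigma,
    )


# -- decoding and dwell-time diagnostics --------------------------------------


def decode_promoter(
    trace: Trace, params: GlobalParams, emission: EmissionModel, M: int = 128
) -> PromoterPath:
    """Binary promoter path by thresholding smoothed P(on) at 0.5 (ties -> off)."""
    post = forward_backward(trace, params, emission, M)
    states = (post.p_on > 0.5).astype(np.int8)
    return PromoterPath(states=states, dt=emission.dt)


@dataclass
class DwellTimeReport:
    """Geometric fit of decoded ON/OFF dwell times.

    p_hat_* are the per-frame exit probabilities (MLE 1/mean for a
    geometric law on {1, 2, ...}); chi2/dof/p_value report a goodness of
    fit pooling the distribution tail.
    """

    on_dwells: np.ndarray
    off_dwells: np.ndarray
    p_hat_on_exit: float
    p_hat_off_exit: float
    chi2_on: float
    p_value_on: float
    chi2_off: float
    p_value_off: float


def _dwells(states: np.ndarray) -> tuple[list[int], list[int]]:
    """Run lengths per state, excluding the censored first and last runs."""
    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate([[0], change, [states.size]])
    runs = [(int(states[bounds[i]]), int(bounds[i + 1] - bounds[i])) for i in range(bounds.size - 1)]
    runs = runs[1:-1]  # first and last runs are censored
    on = [r for s, r in runs if s == 1]
    off = [r for s, r in runs if s == 0]
    return on, off


def _geometric_gof(dwells: np.ndarray) -> tuple[float, float, float]:
    """MLE geometric p and a chi-square GOF with tail pooling."""
    from scipy import stats

    n = dwells.size
    p = 1.0 / dwells.mean()
    kmax = int(dwells.max())
    obs = np.bincount(dwells, minlength=kmax + 1)[1:]
    probs = p * (1 - p) ** np.arange(kmax)
    probs[-1] = (1 - p) ** (kmax - 1)  # fold the tail into the last cell
    exp = n * probs
    # pool cells with expected < 5 from the right
    while exp.size > 2 and exp[-1] < 5:
        exp[-2] += exp[-1]
        obs_last = obs[-1]
        obs = obs[:-1].copy()
        obs[-1] += obs_last
        exp = exp[:-1]
    dof = max(exp.size - 2, 1)  # one estimated parameter
    chi2 = float(((obs - exp) ** 2 / np.maximum(exp, 1e-12)).sum())
    pval = float(stats.chi2.sf(chi2, dof))
    return p, chi2, pval


def dwell_time_check(paths: list[PromoterPath], min_dwells: int = 50) -> DwellTimeReport:
    """Check decoded dwell times against the geometric law.

    Under the telegraph model sampled at interval dt, uncensored ON runs
    are geometric with exit probability p10 = 1 - exp(-k_off dt) and OFF
    runs with p01 = 1 - exp(-k_on dt).  First/last runs of each path are
    censored and excluded.
    """
    on_all: list[int] = []
    off_all: list[int] = []
    for path in paths:
        on, off = _dwells(path.states)
        on_all.extend(on)
        off_all.extend(off)
    if len(on_all) < min_dwells or len(off_all) < min_dwells:
        raise InsufficientDataError(
            f"need >= {min_dwells} dwells per state, got on={len(on_all)} off={len(off_all)}"
        )
    on_arr = np.asarray(on_all, dtype=int)
    off_arr = np.asarray(off_all, dtype=int)
    p_on_exit, chi2_on, pval_on = _geometric_gof(on_arr)
    p_off_exit, chi2_off, pval_off = _geometric_gof(off_arr)
    return DwellTimeReport(
        on_dwells=on_arr,
        off_dwells=off_arr,
        p_hat_on_exit=p_on_exit,
        p_hat_off_exit=p_off_exit,
        chi2_on=chi2_on,
        p_value_on=pval_on,
        chi2_off=chi2_off,
        p_value_off=pval_off,
    )
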