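"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from burstkin import build_emission_model, render_trace, simulate_promoter_path
from burstkin.types import EmissionModel, GlobalParams, KineticParams

DT = 1.0 / 3.0  # 20-second frame interval, in minutes


@pytest.fixture(scope="session")
def emission_k6() -> EmissionModel:
    """Standard small elongation window: gene 3 kb, speed 1.5 kb/min -> K=6."""
    return build_emission_model(3.0, 1.3, 1.5, DT)


@pytest.fixture(scope="session")
def truth_params() -> KineticParams:
    return KineticParams(k_on=0.5, k_off=1.0, k_ini=20.0, noise_sd=3.0)


@pytest.fixture(scope="session")
def global_truth(truth_params) -> GlobalParams:
    return GlobalParams(kinetics=truth_params, sigma=truth_params.noise_sd)


def make_traces(params: KineticParams, emission, n, n_frames, noise_sd, seed):
    """Simulate n rendered traces at shared truth, seeded."""
    rng = np.random.default_rng(seed)
    traces, paths = [], []
    for i in range(n):
        path = simulate_promoter_path(params, n_frames, emission.dt, seed=int(rng.integers(2**31 - 1)))
        paths.append(path)
        traces.append(
            render_trace(
                path, params.k_ini, emission, noise_sd=noise_sd,
                seed=int(rng.integers(2**31 - 1)), nucleus_id=i,
            )
        )
    return traces, paths


def enumerate_posterior(trace, params: GlobalParams, emission) -> tuple[float, np.ndarray]:
    """Brute-force sum over all 2^T promoter paths: (loglik, per-frame P(on)).

    Completely independent of the package's forward-backward machinery;
    only usable for very short traces.
    """
    T = trace.n_frames
    w = emission.weights
    K = emission.K
    amp = emission.v * params.kinetics.k_ini * emission.dt
    p01, p10 = params.kinetics.switch_probabilities(emission.dt)
    occ = params.kinetics.occupancy
    sigma = params.sigma
    total = 0.0
    p_on = np.zeros(T)
    for bits in itertools.product((0, 1), repeat=T):
        p = occ if bits[0] else 1.0 - occ
        for a, b in zip(bits, bits[1:]):
            if a == 0:
                p *= p01 if b else 1.0 - p01
            else:
                p *= (1.0 - p10) if b else p10
        for t in range(T):
            if trace.missing[t]:
                continue
            mu = amp * sum(w[i] * bits[t - i] for i in range(min(t + 1, K)))
            p *= math.exp(-0.5 * ((trace.fluor[t] - mu) / sigma) ** 2) / (
                sigma * math.sqrt(2 * math.pi)
            )
        total += p
        p_on += p * np.asarray(bits, dtype=float)
    return math.log(total), p_on / total
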