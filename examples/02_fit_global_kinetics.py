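"""Fit global burst kinetics to a set of traces with the memory-adjusted HMM.

Simulates 80 nuclei at known rates, then runs EM with the truncated
compound-state forward-backward algorithm and prints the recovered
parameters next to the truth.
"""
import warnings

import numpy as np

from burstkin import build_emission_model, fit_em, render_trace, simulate_promoter_path
from burstkin.types import GlobalParams, KineticParams

truth = KineticParams(k_on=0.5, k_off=1.0, k_ini=20.0, noise_sd=3.0)
dt = 1 / 3
emission = build_emission_model(3.0, 1.3, 1.5, dt)

rng = np.random.default_rng(0)
traces = []
for i in range(80):
    path = simulate_promoter_path(truth, 150, dt, seed=int(rng.integers(2**31 - 1)))
    traces.append(render_trace(path, truth.k_ini, emission, noise_sd=truth.noise_sd,
                               seed=int(rng.integers(2**31 - 1)), nucleus_id=i))

init = GlobalParams(KineticParams(0.3, 0.6, 10.0), sigma=5.0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    result = fit_em(traces, init, emission, M=64, tol=1e-5, max_iter=60,
                    n_restarts=1, seed=0)

k = result.params.kinetics
print(f"converged after {result.n_iter} EM iterations "
      f"(loglik {result.loglik_history[-1]:.1f})")
print(f"{'parameter':<12}{'truth':>8}{'fitted':>10}")
for name, t, f in (("k_on", truth.k_on, k.k_on), ("k_off", truth.k_off, k.k_off),
                   ("k_ini", truth.k_ini, k.k_ini),
                   ("occupancy", truth.occupancy, k.occupancy)):
    print(f"{name:<12}{t:>8.3f}{f:>10.3f}")
print("\nRates are in 1/min (k_ini in a.u./min before calibration); the fitted "
      "values should sit within a few percent of the truth at this sample size.")
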