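"""Per-nucleus burst parameters and their correlation with expression.

Runs forward-backward smoothing per trace at the global fit, extracts
pseudo-count-regularised cell rates and occupancy, derives burst
descriptors, and correlates each parameter with mean expression — in a
graded embryo, occupancy (driven by k_on) should dominate.
"""
import numpy as np

from burstkin import (
    build_emission_model,
    cell_occupancy,
    cell_rates,
    correlate_with_expression,
    derive_burst_descriptors,
    forward_backward,
    simulate_embryo,
)
from burstkin.single_cell import CellEstimate
from burstkin.synthetic import GradientConfig
from burstkin.types import GlobalParams, KineticParams

dt = 1 / 3
emission = build_emission_model(3.0, 1.3, 1.5, dt)
gradient = GradientConfig(n_rows=12, n_cols=4, missing_frame_rate=0.0)
base = KineticParams(0.8, 1.0, 20.0, noise_sd=1.5)
traces, truth = simulate_embryo(gradient, base, emission, n_frames=120,
                                background=None, seed=3, apply_onset_delay=False)

model = GlobalParams(KineticParams(0.5, 1.0, 20.0), sigma=1.5)
cells = []
for tr in traces:
    post = forward_backward(tr, model, emission, M=64)
    k_on, k_off = cell_rates(post, pseudo_count=1.0, dt=dt)
    desc = derive_burst_descriptors(k_on, k_off, model.kinetics.k_ini)
    cells.append(CellEstimate(
        nucleus_id=tr.nucleus_id, k_on=k_on, k_off=k_off, k_ini=desc.k_ini,
        occupancy=cell_occupancy(post), frequency=desc.frequency,
        burst_size=desc.burst_size, duration=desc.duration,
        mean_expression=float(tr.fluor.mean()),
        distance_um=truth.distance_um[tr.nucleus_id],
    ))

print(f"{'parameter':<12}{'Pearson r with mean expression':>32}")
for pname in ("occupancy", "k_on", "k_off", "frequency"):
    rep = correlate_with_expression(cells, pname)
    print(f"{pname:<12}{rep.r:>10.3f}   (n={rep.n})")
print("\nExpression varies across the embryo only through the graded k_on, so "
      "occupancy and k_on correlate strongly while k_off does not — the "
      "single-cell signature of burst-frequency regulation.")
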