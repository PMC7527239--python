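"""Spatial quantification of a fixed graded embryo.

Fits the dorsal midline through mRNA spots, assigns spots to nuclei by
nearest long axis, counts actively transcribing alleles, and builds the
mRNA-per-cell profile across 5 μm distance bins.
"""
import numpy as np
from scipy import stats

from burstkin import (
    assign_spots_to_nuclei,
    bin_and_label,
    count_active_alleles,
    fit_midline,
    mrna_per_cell_profile,
    simulate_smfish_embryo,
)
from burstkin.spatial import USH_REGIONS
from burstkin.synthetic import GradientConfig
from burstkin.types import KineticParams

gradient = GradientConfig(n_rows=20, n_cols=10)
base = KineticParams(0.8, 1.0, 8.0)
nuclei, spots, counts = simulate_smfish_embryo(gradient, base, half_life=12.0,
                                               t_fix=50.0, seed=6)
print(f"{len(nuclei)} nuclei, {len(spots)} spots "
      f"({(spots['spot_class'] == 'ts').sum()} transcription sites)")

midline = fit_midline(spots[spots["spot_class"] == "mrna"])
print(f"fitted midline y = {midline.a:.4f}x^2 + {midline.b:.3f}x + {midline.c:.2f} "
      "(simulated flat midline at y = 0)")

assigned, per_nucleus = assign_spots_to_nuclei(spots, nuclei)
agree = (assigned["assigned_nucleus"] == assigned["nucleus_id_true"]).mean()
print(f"spot-to-nucleus assignment agrees with generative truth: {agree:.1%}")

active = count_active_alleles(assigned, ts_threshold=4.0)
merged = active.merge(counts, on="nucleus_id")
labels = bin_and_label(merged["distance_um"].to_numpy(), USH_REGIONS)
for region in ("high", "medium", "low"):
    sel = merged[labels["region"].to_numpy() == region]
    if len(sel):
        print(f"  {region:<7} mean active alleles {sel['n_active_alleles'].mean():.2f} "
              f"over {len(sel)} nuclei")

profile, rho, pval = mrna_per_cell_profile(counts["count"].to_numpy(),
                                           counts["distance_um"].to_numpy(), seed=0)
print("\nmRNA per cell by 5 μm bin (median [95% CI]):")
for _, row in profile.iterrows():
    print(f"  bin {int(row['bin']):2d} ({row['distance_mid_um']:4.1f} μm): "
          f"{row['median']:6.1f} [{row['ci_lo']:.1f}, {row['ci_hi']:.1f}]  n={int(row['n'])}")
print(f"\nSpearman rho(count, |distance|) = {rho:.2f} (p = {pval:.2e}): "
      "output declines away from the signaling peak.")
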