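# burstkin

Transcriptional burst kinetics from MS2/MCP live-imaging traces:
memory-adjusted HMM inference, absolute Pol II calibration, and spatial
quantification of graded expression — with a seeded synthetic-embryo
generator providing ground-truth data for every stage.

## The problem

Developmental genes are transcribed in stochastic bursts.  In the early
*Drosophila* embryo, BMP-responsive genes such as *ush* and *hnt* read a
morphogen gradient centred on the dorsal midline: nuclei receiving more
signal initiate sooner and produce more mRNA.  Live imaging of MS2
stem-loop knock-ins reports the instantaneous transcriptional activity
of each nucleus as a fluorescence time series, and the question is which
kinetic knob the gradient turns — the promoter activation rate, the
inactivation rate, or the Pol II loading rate.

`burstkin` is for quantitative biologists who have (or want to
prototype against) per-nucleus fluorescence traces and fixed-embryo
smFISH tables, and who want telegraph-model burst parameters per region
and per cell, in absolute Pol II units, as tidy tables.

## The model

The promoter is a two-state telegraph process: OFF → ON at rate
k_on, ON → OFF at rate k_off (both 1/min); while ON, Pol II
initiates at k_ini per minute.  Derived descriptors:

- occupancy ⟨n⟩ = k_on / (k_on + k_off)
- burst frequency = k_on·k_off / (k_on + k_off)
- burst size = k_ini / k_off,  burst duration = 1 / k_off

Because each initiated Pol II fluoresces for the whole time it traverses
the gene, the observed signal at frame t depends on the promoter history
over the last K frames (the elongation window):

F_t = v · k_ini · Δt · Σ_{i<K} w_i z_{t−i} + ε_t,  ε_t ~ N(0, σ²),

where z is the binary promoter state, w_i the fraction of the MS2
cassette transcribed by a polymerase loaded i frames ago, and v the
brightness of one Pol II.  The hidden state is the 2^K-valued promoter
history; the forward pass is truncated to the top-M states per frame
(beam search), which makes the exact-for-small-K algorithm scale to
realistic windows.  EM over pooled traces per signaling region estimates
(k_on, k_off, k_ini·v, σ); forward–backward smoothing then gives each
nucleus posterior ON-probabilities, pseudo-count-regularised
cell-specific rates, and decoded promoter paths whose ON/OFF dwell times
are geometric by construction.

Calibration to absolute Pol II numbers uses smFISH anchors: mRNA counts
corrected for decay (half-lives of 12 min for *ush*-like and 3 min for
*hnt*-like transcripts) over the production window fix the per-allele
output, and the ratio of mean integrated trace signal to that output
yields the a.u.-per-Pol II factor.  Spatial machinery fits a quadratic
dorsal midline through spot coordinates, assigns spots to nuclei by
nearest 3-D long axis, counts actively transcribing alleles, and bins
everything in 5 μm (one-cell-wide) distance bands.

## Worked example

Fitting 80 simulated nuclei (150 frames at 20 s) whose true kinetics are
k_on = 0.5/min, k_off = 1.0/min, k_ini = 20/min:

```bash
$ python examples/02_fit_global_kinetics.py
converged after 13 EM iterations (loglik -35303.3)
parameter      truth    fitted
k_on           0.500     0.527
k_off          1.000     1.012
k_ini         20.000    20.211
occupancy      0.333     0.342
```

The fitted switching rates land within a few percent of the truth; the
occupancy estimate is the stationary fraction of time the promoter
spends ON.  The other examples cover trace simulation
(`01_simulate_and_render.py`), single-cell parameters and their
correlation with expression (`03_single_cell_parameters.py`, where
occupancy correlates at r ≈ 0.96 and k_off at r ≈ −0.47 in a graded
embryo), Pol II calibration (`04_calibrate_polII.py`, recovering a
hidden per-Pol II brightness of 2.5 a.u. to 1.9%), spatial profiles
(`05_spatial_profile.py`) and the end-to-end demo
(`06_full_pipeline.py`, also available as `burstkin demo`).

## Layout

- `src/burstkin/` — library: `synthetic` (generators), `preprocess`
  (background/QC/onsets), `mhmm` (the model), `single_cell`,
  `calibration`, `spatial`, `pipeline` + thin `cli`
- `examples/` — one narrative script per capability
- `docs/methods.md` — model details, assumptions, numerical choices
- `tests/` — pytest suite with brute-force enumeration oracles
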