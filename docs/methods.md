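# Methods

## The promoter model and its emission

A nucleus's promoter is a continuous-time two-state (telegraph) chain:
OFF → ON at k_on, ON → OFF at k_off (1/min); while ON, Pol II initiates
at k_ini per minute.  On the imaging grid (frame interval Δt, default
1/3 min = 20 s) the chain is discretised with the exact exponential hold
conversion

    p01 = 1 − exp(−k_on Δt),   p10 = 1 − exp(−k_off Δt),

and rates are recovered from fitted probabilities by k = −ln(1−p)/Δt.
This conversion is well behaved at any Δt (no p > 1 pathologies) and is
used identically by the simulator and the estimator, so inference is
self-consistent.  One consequence worth knowing: the stationary
occupancy of the *discrete* chain is p01/(p01+p10), which approaches the
continuous-time value k_on/(k_on+k_off) as Δt → 0 but differs from it by
O(Δt) at finite sampling (≈ 0.351 vs 1/3 at k_on = 0.5, k_off = 1.0,
Δt = 1/3 min).  Tests assert the exact discrete law and the limit.

Fluorescence is the elongation-window ("memory") convolution

    F_t = v · k_ini · Δt · Σ_{i=0..K−1} w_i · z_{t−i} + b(t) + ε_t,

with K = ceil(elongation time / Δt), elongation time = gene length /
elongation speed, Gaussian noise ε_t, and a linear background b(t).
The lag weights use a midpoint rule for the fraction of the (5′) MS2
cassette a polymerase loaded i frames ago has transcribed:
w_i = min(1, (i+0.5)·Δt·speed / cassette length).  Defaults: gene 3 kb,
24x cassette 1.3 kb, speed 1.5 kb/min, giving K = 6; the speed is a
standard literature value exposed in the config, as is the geometry.

## Truncated compound-state inference

The hidden state at frame t is the K-bit promoter history (2^K states,
bit 0 = current frame).  Each state has exactly two successors (append a
bit, drop the oldest), so the forward recursion per frame is two gathers
and a log-sum.  For tractability at large K the forward pass keeps only
the top-M states per frame by *unnormalized* forward weight (keeping
log-likelihoods comparable across M); ties break on the smaller state
integer.  The backward pass is restricted to the union of states the
forward beam retained, per-frame marginals are renormalized within the
retained set, and expected transition counts are rescaled to sum to
n_frames − 1.  With M ≥ 2^K nothing is pruned and the algorithm is
exact; a dense matrix-product forward (`exact_forward_oracle`) and a
brute-force 2^T path enumeration (tests only) serve as independent
references.  Missing frames contribute no emission term but keep the
transition structure.  The initial state is the zero-padded history
{OFF, ON} weighted by the stationary law.

EM over pooled traces of a region alternates:

- E-step: forward–backward smoothing (a dense sweep vectorised across
  traces when M ≥ 2^K and lengths agree; the beam per trace otherwise);
- M-step: switching probabilities from pooled expected transition
  counts; the amplitude a = v·k_ini by least squares of F_t on
  Δt·Σ w_i·E[z_{t−i}]; shared σ from the residuals of that regression.

The amplitude/σ update is a regression on the posterior *mean* loading
rather than the full quadratic sufficient statistic, so the
log-likelihood can dip by ~1e−4 relative in early iterations; dips are
logged as warnings and convergence uses the relative change criterion
(default tol 1e−6, max 500 iterations, 5 restarts with seeded lognormal
perturbations of the initial rates — the demo and acceptance runs use
1 restart and looser tolerances for speed; problem sizes below).

Decoding thresholds smoothed P(on) at 0.5 (ties → OFF).  Per-cell rates
use pseudo-count-regularised transition probabilities,
p̂01 = (C01+α)/(C0•+2α) with α = 1 per transition type (the magnitude is
a package default; it bounds p̂ away from 0 and 1 for cells whose
posterior shows no transitions).  Per-cell occupancy averages P(on)
from the cell's onset (first frame with P(on) ≥ 0.5) so pre-activation
silence does not dilute it; a flag averages the full trace instead.

## Synthetic embryos: what they emulate, what they do not

The generator reproduces the statistical structure the analysis
assumes: banded k_on falling away from the dorsal midline (defaults
0.8/0.5/0.2 per min with edges at 15 and 30 μm, one 5 μm cell width per
grid row), shared k_off = 1/min and k_ini = 20/min, onset delays growing
linearly with midline distance, a linear background drift, Gaussian
emission noise, ~1% missing frames, and — for fixed embryos — exact
birth–death mRNA snapshots (per-allele telegraph switching in continuous
time, surviving molecules drawn Poisson per ON interval with decay
ln2/half-life; half-lives 12 and 3 min for the two gene archetypes) plus
spot tables with one spot per surviving mRNA and one transcription-site
spot per active allele.  Two alleles are independent.

It does **not** emulate imaging: no pixels, point-spread functions,
segmentation or tracking errors, no photobleaching, no nuclear movement,
and spot intensities are idealized (single-mRNA spots at unit intensity
±10%, site intensity proportional to resident Pol II).  Passing tests
therefore validate the inference and quantification chain, not
robustness to upstream image-analysis failure modes.

## Calibration conventions

The conversion factor is C = (mean over high-region nuclei of Σ F_t Δt)
divided by the per-allele mRNA output; the output is the decay-corrected
count (factor δT/(1−e^{−δT}) for constant production over window T,
validated against the birth–death simulator) divided by 2, matching a
diploid fixed embryo against single-MS2-allele live traces.  C has units
a.u.·min per mRNA; the instantaneous per-Pol II brightness is v = C/τ
where τ is the time one transcript's signal is visible.  The package
uses the elongation-window-weighted residence time τ_eff = Δt·Σ w_i by
default (this is the choice under which the synthetic round trip is
unbiased in expectation); the raw elongation time K·Δt is available via
`use_effective_residence=False`.  The alternative scaling (3-frame mean
signal over the site-derived production rate) is implemented for
comparison but, as with the source data, is noisier.  The steady-state
half-life estimator t½ = ln2·N/P assumes the cytoplasmic pool is at
production–degradation balance.

In the bundled demo the live traces carry onset delays while the smFISH
snapshot assumes production from t = 0, so the demo's recovered v is
biased low by roughly the onset fraction of the window (~10%); the
matched-conditions round trip in the acceptance suite recovers v within
a few percent.  Similarly, per-band k_on fitted on whole traces is
diluted by the forced-OFF pre-onset period; orderings and correlations
are unaffected.

## Spatial conventions

Midline: least-squares quadratic of spot y on x.  Distance: signed
perpendicular (curve-nearest) distance, computed from the closed-form
cubic stationarity condition; the sign is the side of the curve at the
nucleus's own x, and a `vertical` mode gives the plain y-offset.  Spots
attach to the nucleus with the nearest 3-D long-axis segment (ties →
lowest id).  Transcription sites are spots at ≥ 4× the median
single-mRNA intensity (the cutoff separates multi-Pol II sites from
singles in the simulator and is configurable); active-allele counts cap
at 2 with the excess flagged.  Bins are floor(|d|/5 μm); region bands
are 0–15/15–30/>30 μm (*ush*-like), 0–10/>10 μm (*hnt*-like), with a
30–50/>50 μm split for the ectopic-stripe variant.

## Preprocessing conventions

Background is an OLS line through dedicated background samples; the
detection threshold defaults to 3× the SD of residuals around that fit.
Negative post-subtraction values are kept (clamping would skew the
symmetric noise model).  Mitotic-wave correction shifts each trace so
its AP bin's telophase time becomes t = 0, snapping to the nearest frame
(half-frames round away from zero).  nc14 is linearly rescaled to 50
min.  QC removes traces that never exceed the detection threshold, have
more than two missing frames (exactly two is kept), or are transient
(< 5 frames above threshold *and* peak < 2× threshold; both cutoffs are
package defaults, exposed in the rule object).  T_50 is the earliest
time by which at least half of a region's nuclei have initiated, None if
half is never reached.

## Problem sizes and statistical checks

Parameter recovery runs at 200 traces × 150 frames (50 min of nc14 at
20 s), truth k_on = 0.5, k_off = 1.0, k_ini = 20/min, noise σ = 3 a.u.
(plateau/σ ≈ 10.5), K = 6 so the E-step runs as the dense batched sweep;
medians are taken over 5 seeds.  The dwell-time geometry check decodes
800 such traces at σ = 1.5 (plateau/σ ≈ 21), where decoding disagrees
with the true path on ~0.4% of frames: at 10⁴ dwells a chi-square test
is sensitive enough to detect the decoder's suppression of one-frame
dwells at lower SNR, which would measure the decoder rather than the
model's geometric dwell law.  The single-vs-double active allele trend
uses a 1200-nucleus fixed embryo (k_ini = 5/min) so the binary Spearman
test has adequate power (~500 transcribing nuclei).  The demo embryo is
16 × 4 nuclei for speed.

## Known limitations

- Shared σ across compound states (a per-level variance would need a
  nonlinear M-step); amplitude M-step is the posterior-mean regression
  described above.
- The beam scheme (prune by unnormalized weight, no in-beam
  renormalization, backward restricted to retained states) is one
  reasonable truncation; other choices trade accuracy differently.
- Telophase times are an input table; inferring them from nuclear-area
  profiles, like segmentation and tracking, is upstream of this package.
- k_on fitted on whole traces includes pre-onset silence; no explicit
  onset-time parameter is modelled.
- The 3-state (two ON levels) promoter variant, MCMC inference and
  allele-pair correlation analyses are out of scope.
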