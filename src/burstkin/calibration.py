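"""Fluorescence -> absolute Pol II calibration via smFISH counts.

Live MS2 traces are recorded in arbitrary units.  Fixed-embryo smFISH
provides absolute anchors: the intensity ratio of a transcription site to
a single mRNA (after correcting for how much of the probe set a nascent
transcript has transcribed) counts resident Pol II; cytoplasmic mRNA
counts, corrected for decay over the production window, give the mRNA
output per allele.  Dividing the mean time-integrated fluorescence per
nucleus by that single-allele output yields a conversion factor
C (a.u.·min per mRNA), and dividing C by the time one transcript's MS2
signal stays visible converts it to a per-Pol II brightness v.
"""
from __future__ import annotations

import math

import numpy as np

from .types import CalibrationModel, EmissionModel, InvalidParameterError, Trace

__all__ = [
    "probe_position_weight",
    "ts_fluorescence_to_polII",
    "estimate_half_life",
    "degradation_correct",
    "compute_conversion",
    "alternative_scaling",
]


class CalibrationError(ValueError):
    pass


def probe_position_weight(
    probe_positions_kb: np.ndarray | list[float], gene_length_kb: float
) -> float:
    """Expected bound fraction of the probe set on a nascent transcript.

    With the transcribing Pol II uniformly positioned along the gene, a
    probe at position p is present on the nascent RNA with probability
    1 - p/L; the weight is the mean over probes.
    """
    pos = np.asarray(probe_positions_kb, dtype=float)
    if pos.size == 0:
        raise InvalidParameterError("probe set is empty")
    if gene_length_kb <= 0 or (pos < 0).any() or (pos > gene_length_kb).any():
        raise InvalidParameterError("probe positions must lie within [0, gene_length]")
    return float(np.mean(1.0 - pos / gene_length_kb))


def ts_fluorescence_to_polII(
    ts_intensity: float, single_mrna_intensity: float, probe_weight: float
) -> float:
    """Resident Pol II at a transcription site from intensity ratios."""
    if single_mrna_intensity <= 0:
        raise InvalidParameterError("single mRNA intensity must be > 0")
    if probe_weight <= 0:
        raise CalibrationError("probe weight must be > 0")
    return ts_intensity / (single_mrna_intensity * probe_weight)


def estimate_half_life(production_rate: float, cyto_count: float) -> float:
    """Steady-state half-life: delta = production/count, t1/2 = ln2/delta.

    Assumes the cytoplasmic pool is at production-degradation balance.
    A zero production rate returns inf (no turnover detectable).
    """
    if cyto_count <= 0:
        raise InvalidParameterError("cytoplasmic count must be > 0")
    if production_rate < 0:
        raise InvalidParameterError("production rate must be >= 0")
    if production_rate == 0:
        return math.inf
    return math.log(2.0) * cyto_count / production_rate


def degradation_correct(
    observed_count: float, half_life: float, production_window: float
) -> float:
    """mRNAs produced over the window, from the decayed count at its end.

    For constant production P over [0, T] with decay rate delta,
    N(T) = P (1 - e^{-dT}) / d and produced = P T, so
    produced = observed * dT / (1 - e^{-dT}).  As delta -> 0 the factor
    tends to 1.
    """
    if production_window <= 0:
        raise InvalidParameterError("production window must be > 0")
    if not half_life > 0:
        raise InvalidParameterError("half-life must be > 0 (or inf)")
    delta = 0.0 if math.isinf(half_life) else math.log(2.0) / half_life
    x = delta * production_window
    factor = 1.0 if x < 1e-12 else x / -math.expm1(-x)
    return observed_count * factor


def compute_conversion(
    traces_high_region: list[Trace],
    produced_count_per_cell: float,
    emission: EmissionModel,
    half_life: float = 12.0,
    probe_weight: float = 1.0,
    n_alleles: int = 2,
    use_effective_residence: bool = True,
) -> tuple[CalibrationModel, list[Trace]]:
    """Conversion factor from integrated signal vs corrected mRNA output.

    C = mean over high-region nuclei of ∫F dt, divided by the per-allele
    mRNA output (produced/2 for a diploid fixed embryo against a
    single-MS2-allele live embryo).  The per-Pol II brightness is
    v = C / tau, where tau is the time one transcript's signal is visible:
    by default the elongation-window-weighted residence time dt * sum(w)
    (accounting for the cassette position), optionally the raw elongation
    time K * dt.  Returns the model and the traces rescaled to Pol II
    units.
    """
    if produced_count_per_cell <= 0:
        raise CalibrationError("produced count must be > 0")
    if not traces_high_region:
        raise CalibrationError("no traces supplied")
    dt = emission.dt
    integrals = []
    for tr in traces_high_region:
        obs = ~tr.missing
        integrals.append(float(tr.fluor[obs].sum() * dt))
    mean_integral = float(np.mean(integrals))
    if mean_integral <= 0:
        raise CalibrationError("mean integrated signal is not positive")
    per_allele = produced_count_per_cell / n_alleles
    C = mean_integral / per_allele  # a.u.·min per mRNA
    tau = emission.effective_residence_time if use_effective_residence else emission.elongation_time
    v = C / tau  # a.u. per Pol II
    model = CalibrationModel(
        half_life=half_life,
        probe_weight=probe_weight,
        conversion=C,
        v=v,
        elongation_time=tau,
    )
    rescaled = [
        Trace(
            nucleus_id=tr.nucleus_id,
            t=tr.t.copy(),
            fluor=tr.fluor / v,
            missing=tr.missing.copy(),
            x=tr.x,
            y=tr.y,
        )
        for tr in traces_high_region
    ]
    return model, rescaled


def alternative_scaling(
    trace: Trace,
    production_rate_from_ts: float,
    window_center_frame: int,
    window_frames: int = 3,
) -> float:
    """Alternative conversion: signal averaged over a short window at the
    developmental stage matched to the fixed embryos, divided by the
    production rate counted from transcription-site Pol II.  Reported for
    comparison with the integrated-signal conversion; more variable in
    practice because site Pol II numbers are noisy."""
    if production_rate_from_ts <= 0:
        raise CalibrationError("production rate must be > 0")
    half = window_frames // 2
    lo = max(window_center_frame - half, 0)
    hi = min(lo + window_frames, trace.n_frames)
    sel = slice(lo, hi)
    obs = ~trace.missing[sel]
    vals = trace.fluor[sel][obs]
    if vals.size == 0:
        raise CalibrationError("window contains no observed frames")
    return float(vals.mean() / production_rate_from_ts)
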