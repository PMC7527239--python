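"""Per-nucleus burst parameters from smoothed posteriors.

Given a converged global fit, each nucleus's expected transition counts
yield cell-specific switching rates via pseudo-count-regularised
transition probabilities; the per-frame P(on) gives a cell occupancy.
Burst descriptors follow from the telegraph rates in closed form:

    occupancy  = k_on / (k_on + k_off)
    frequency  = k_on * k_off / (k_on + k_off)      (burst cycles per min)
    burst size = k_ini / k_off                      (Pol II per burst)
    duration   = 1 / k_off                          (mean ON dwell, min)
"""
from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .types import InvalidParameterError, PosteriorSummary

__all__ = [
    "BurstDescriptors",
    "CellEstimate",
    "cell_rates",
    "cell_occupancy",
    "derive_burst_descriptors",
    "correlate_with_expression",
    "CorrelationReport",
    "simulate_mean_burst_profile",
    "kmeans_expression",
    "count_decoded_burst_frequency",
    "cell_estimates_table",
]


class UndefinedCorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class BurstDescriptors:
    occupancy: float
    frequency: float  # 1/min
    burst_size: float  # Pol II
    duration: float  # min
    k_ini: float  # Pol II/min


@dataclass
class CellEstimate:
    """One nucleus's estimated kinetics and bookkeeping."""

    nucleus_id: int
    k_on: float
    k_off: float
    k_ini: float
    occupancy: float
    frequency: float
    burst_size: float
    duration: float
    mean_expression: float
    distance_um: float = float("nan")
    region: str = ""


def cell_rates(
    posterior: PosteriorSummary, pseudo_count: float = 1.0, dt: float = 1 / 3
) -> tuple[float, float]:
    """Cell-specific switching rates from expected transition counts.

    p01 = (C01 + a) / (C00 + C01 + 2a), p10 = (C10 + a) / (C10 + C11 + 2a),
    then k = -ln(1 - p) / dt.  The pseudo-count a keeps estimates finite
    for cells whose posterior shows no transitions.  The denominator
    construction guarantees p < 1.
    """
    if pseudo_count < 0:
        raise InvalidParameterError("pseudo_count must be >= 0")
    C = posterior.transition_counts
    denom01 = C[0, 0] + C[0, 1] + 2 * pseudo_count
    denom10 = C[1, 0] + C[1, 1] + 2 * pseudo_count
    if denom01 <= 0 or denom10 <= 0:
        raise InvalidParameterError("no transition mass and no pseudo-count")
    p01 = (C[0, 1] + pseudo_count) / denom01
    p10 = (C[1, 0] + pseudo_count) / denom10
    assert p01 < 1 and p10 < 1
    k_on = -math.log(1.0 - p01) / dt
    k_off = -math.log(1.0 - p10) / dt
    return k_on, k_off


def cell_occupancy(posterior: PosteriorSummary, onset_index: int | None = None) -> float:
    """Mean per-frame P(on), by default from the cell's onset to trace end.

    The onset is the first frame with P(on) >= 0.5 unless given; averaging
    from onset stops pre-activation silence from diluting the occupancy.
    Pass ``onset_index=0`` to average over the full trace.
    """
    p = posterior.p_on
    if onset_index is None:
        idx = np.flatnonzero(p >= 0.5)
        onset_index = int(idx[0]) if idx.size else 0
    return float(p[onset_index:].mean())


def derive_burst_descriptors(k_on: float, k_off: float, k_ini: float) -> BurstDescriptors:
    """Closed-form burst descriptors from telegraph rates."""
    if min(k_on, k_off, k_ini) <= 0:
        raise InvalidParameterError("rates must be > 0")
    ksum = k_on + k_off
    return BurstDescriptors(
        occupancy=k_on / ksum,
        frequency=k_on * k_off / ksum,
        burst_size=k_ini / k_off,
        duration=1.0 / k_off,
        k_ini=k_ini,
    )


@dataclass(frozen=True)
class CorrelationReport:
    param: str
    r: float
    p_value: float
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    n: int


def correlate_with_expression(cells: list[CellEstimate], param_name: str) -> CorrelationReport:
    """Pearson correlation of one burst parameter with mean expression,
    with the least-squares line and a 95% CI on its slope."""
    if len(cells) < 3:
        raise InvalidParameterError("need >= 3 cells")
    x = np.array([getattr(c, param_name) for c in cells], dtype=float)
    y = np.array([c.mean_expression for c in cells], dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidParameterError("non-finite values in correlation inputs")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError(f"zero variance in {param_name} or expression")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, len(x) - 2)
    return CorrelationReport(
        param=param_name,
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci95=(
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        n=len(x),
    )


def simulate_mean_burst_profile(
    descriptors: BurstDescriptors,
    onset: float,
    horizon: float,
    dt: float = 1 / 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Idealized square-wave burst profile from mean parameters.

    Zero before onset; afterwards alternating ON periods of length
    ``duration`` (amplitude k_ini) and OFF periods of length 1/k_on.
    Its time average over whole cycles equals k_ini * stationary
    occupancy.
    """
    if horizon < onset:
        raise InvalidParameterError("horizon must be >= onset")
    t = np.arange(0.0, horizon, dt)
    y = np.zeros_like(t)
    # mean OFF period 1/k_on, recovered from occupancy and duration
    off_len = descriptors.duration * (1.0 - descriptors.occupancy) / max(descriptors.occupancy, 1e-12)
    period = descriptors.duration + off_len
    phase = np.mod(t - onset, period)
    on = (t >= onset) & (phase < descriptors.duration)
    y[on] = descriptors.k_ini
    return t, y


def kmeans_expression(
    mean_expressions: np.ndarray | list[float], k: int, seed: int = 0
) -> np.ndarray:
    """K-means on scalar mean expression; labels renumbered so cluster 0
    has the highest mean (k-means labels are otherwise arbitrary)."""
    x = np.asarray(mean_expressions, dtype=float).reshape(-1, 1)
    if k < 1 or x.shape[0] < k:
        raise InvalidParameterError(f"need n >= k >= 1, got n={x.shape[0]}, k={k}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    order = np.argsort(-km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[km.labels_]


def count_decoded_burst_frequency(states: np.ndarray, dt: float, total_time: float | None = None) -> float:
    """Empirical burst frequency: decoded OFF->ON transitions per minute.

    Alternative to the closed-form k_on*k_off/(k_on+k_off); both are
    reported, the formula being the default elsewhere.
    """
    states = np.asarray(states)
    n_starts = int(((states[1:] == 1) & (states[:-1] == 0)).sum())
    if total_time is None:
        total_time = states.size * dt
    return n_starts / total_time


def cell_estimates_table(cells: list[CellEstimate]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in cells])
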