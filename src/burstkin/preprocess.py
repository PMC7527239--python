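"""Trace conditioning before model fitting.

Mirrors the live-imaging processing chain: a linear background is fitted
to dedicated background samples and subtracted; traces are synchronized
to the mitotic wave (telophase time per anterior-posterior bin defines
t = 0); the nuclear-cycle-14 time axis is normalized to 50 min; traces
failing quality control (empty, more than two missing frames, or only
transient low-level activity) are removed; onset times and T_50 (the
time at which half of a region's nuclei have initiated) are computed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import BackgroundModel, InvalidParameterError, Trace

__all__ = [
    "QCReport",
    "TransientRule",
    "fit_background",
    "subtract_background",
    "detection_threshold",
    "correct_mitotic_wave",
    "rescale_nc14",
    "qc_filter",
    "detect_onset",
    "compute_t50",
]

NC14_DURATION_MIN = 50.0  # normalized nuclear-cycle-14 length
MAX_MISSING_FRAMES = 2  # traces with more missing frames are dropped


class DegenerateFitError(ValueError):
    pass


class BinAssignmentError(KeyError):
    pass


@dataclass(frozen=True)
class TransientRule:
    """A trace is 'transient' if it has fewer than ``min_active_frames``
    frames above the detection threshold AND never exceeds
    ``min_peak_factor`` times that threshold."""

    min_active_frames: int = 5
    min_peak_factor: float = 2.0


@dataclass
class QCReport:
    n_input: int = 0
    n_removed_empty: int = 0
    n_removed_missing: int = 0
    n_removed_transient: int = 0

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.n_removed_empty
            - self.n_removed_missing
            - self.n_removed_transient
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_empty": self.n_removed_empty,
            "n_removed_missing": self.n_removed_missing,
            "n_removed_transient": self.n_removed_transient,
            "n_retained": self.n_retained,
        }


def fit_background(samples: np.ndarray | list[tuple[float, float]]) -> BackgroundModel:
    """Ordinary least-squares line through (t_min, fluor_au) background samples."""
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DegenerateFitError("need >= 2 (t, fluor) samples")
    t, f = arr[:, 0], arr[:, 1]
    if np.unique(t).size < 2:
        raise DegenerateFitError("all background samples share one time point")
    slope, intercept = np.polyfit(t, f, 1)
    return BackgroundModel(intercept=float(intercept), slope=float(slope))


def subtract_background(trace: Trace, model: BackgroundModel) -> Trace:
    """Subtract b(t) from the trace.  Negative values are kept: clamping
    would skew the symmetric Gaussian noise the emission model assumes."""
    return Trace(
        nucleus_id=trace.nucleus_id,
        t=trace.t.copy(),
        fluor=trace.fluor - model(trace.t),
        missing=trace.missing.copy(),
        x=trace.x,
        y=trace.y,
    )


def detection_threshold(
    samples: np.ndarray | list[tuple[float, float]], model: BackgroundModel, n_sd: float = 3.0
) -> float:
    """Default detection threshold: n_sd x SD of residuals around the fitted background."""
    arr = np.asarray(samples, dtype=float)
    resid = arr[:, 1] - model(arr[:, 0])
    return float(n_sd * resid.std(ddof=1))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def correct_mitotic_wave(
    traces: list[Trace],
    telophase_time_by_ap: dict[tuple[float, float], float],
) -> list[Trace]:
    """Shift each trace's clock so its AP bin's telophase time becomes t = 0.

    ``telophase_time_by_ap`` maps half-open AP intervals [lo, hi) (μm) to
    telophase times (min).  Fractional shifts snap to the nearest frame,
    rounding half away from zero, so the uniform grid is preserved.
    """
    out = []
    for tr in traces:
        telo = None
        for (lo, hi), tt in telophase_time_by_ap.items():
            if lo <= tr.x < hi:
                telo = tt
                break
        if telo is None:
            raise BinAssignmentError(f"nucleus {tr.nucleus_id} at x={tr.x} outside all AP bins")
        dt = tr.dt
        shift = _round_half_away(telo / dt) * dt if tr.n_frames >= 2 else telo
        out.append(
            Trace(
                nucleus_id=tr.nucleus_id,
                t=tr.t - shift,
                fluor=tr.fluor.copy(),
                missing=tr.missing.copy(),
                x=tr.x,
                y=tr.y,
            )
        )
    return out


def rescale_nc14(traces: list[Trace], observed_nc14_duration: float) -> list[Trace]:
    """Linearly rescale time so the observed nc14 spans exactly 50 min."""
    if observed_nc14_duration <= 0:
        raise InvalidParameterError("observed nc14 duration must be > 0")
    factor = NC14_DURATION_MIN / observed_nc14_duration
    return [
        Trace(
            nucleus_id=tr.nucleus_id,
            t=tr.t * factor,
            fluor=tr.fluor.copy(),
            missing=tr.missing.copy(),
            x=tr.x,
            y=tr.y,
        )
        for tr in traces
    ]


def qc_filter(
    traces: list[Trace],
    detection_threshold: float,
    transient_rule: TransientRule | None = TransientRule(),
) -> tuple[list[Trace], QCReport]:
    """Remove empty, gappy and transient traces.

    A trace is *empty* if its (background-subtracted) signal never rises
    above the detection threshold; it is *gappy* if more than
    ``MAX_MISSING_FRAMES`` frames are missing (exactly two is retained);
    it is *transient* under the configured rule.  The removal order is
    empty -> gappy -> transient, and the report counts reconcile with the
    input by construction.
    """
    report = QCReport(n_input=len(traces))
    kept: list[Trace] = []
    for tr in traces:
        obs = tr.fluor[~tr.missing]
        if obs.size == 0 or (obs > detection_threshold).sum() == 0:
            report.n_removed_empty += 1
            continue
        if int(tr.missing.sum()) > MAX_MISSING_FRAMES:
            report.n_removed_missing += 1
            continue
        if transient_rule is not None:
            active = int((obs > detection_threshold).sum())
            peak = float(obs.max())
            if (
                active < transient_rule.min_active_frames
                and peak < transient_rule.min_peak_factor * detection_threshold
            ):
                report.n_removed_transient += 1
                continue
        kept.append(tr)
    return kept, report


def detect_onset(trace: Trace, threshold: float) -> float | None:
    """Time of the first observed frame with fluorescence above threshold."""
    above = (trace.fluor > threshold) & ~trace.missing
    idx = np.flatnonzero(above)
    return float(trace.t[idx[0]]) if idx.size else None


def compute_t50(onsets: list[float], n_region_total: int) -> float | None:
    """Earliest time by which at least half the region's nuclei have initiated.

    Returns None (flagged) if fewer than half ever activate.
    """
    if n_region_total < 1:
        raise InvalidParameterError("n_region_total must be >= 1")
    need = n_region_total / 2.0
    srt = sorted(onsets)
    for i, t in enumerate(srt, start=1):
        if i >= need:
            return float(t)
    return None
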