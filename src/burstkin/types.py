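"""Core containers shared across the pipeline.

Units are consistent throughout: time in minutes, rates in 1/min,
positions in micrometres, fluorescence in arbitrary units (a.u.) until
calibration converts it to Pol II molecules.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "KineticParams",
    "PromoterPath",
    "EmissionModel",
    "Trace",
    "GlobalParams",
    "PosteriorSummary",
    "CalibrationModel",
    "BackgroundModel",
    "trace_set_to_frame",
    "trace_set_from_frame",
]


class InvalidParameterError(ValueError):
    """Raised when a physical parameter violates its domain."""


@dataclass(frozen=True)
class KineticParams:
    """Two-state (telegraph) promoter rates.

    Attributes
    ----------
    k_on : float
        OFF -> ON switching rate, 1/min.
    k_off : float
        ON -> OFF switching rate, 1/min.
    k_ini : float
        Pol II initiation (loading) rate while ON, Pol II/min
        (a.u./min before calibration).
    noise_sd : float
        Gaussian emission noise standard deviation, a.u.
    """

    k_on: float
    k_off: float
    k_ini: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_ini"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v}")
        if not (math.isfinite(self.noise_sd) and self.noise_sd >= 0):
            raise InvalidParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def occupancy(self) -> float:
        """Stationary fraction of time the promoter is ON."""
        return self.k_on / (self.k_on + self.k_off)

    def switch_probabilities(self, dt: float) -> tuple[float, float]:
        """Per-frame switch probabilities (p01, p10) at frame interval dt."""
        if dt <= 0:
            raise InvalidParameterError(f"dt must be > 0, got {dt}")
        return 1.0 - math.exp(-self.k_on * dt), 1.0 - math.exp(-self.k_off * dt)


@dataclass(frozen=True)
class PromoterPath:
    """A binary promoter trajectory on a uniform frame grid."""

    states: np.ndarray  # int8, values in {0, 1}
    dt: float  # min

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int8)
        if states.ndim != 1 or states.size < 1:
            raise InvalidParameterError("states must be a non-empty 1-D sequence")
        if not np.isin(states, (0, 1)).all():
            raise InvalidParameterError("promoter states must be 0 or 1")
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        object.__setattr__(self, "states", states)

    @property
    def n_frames(self) -> int:
        return int(self.states.size)

    @property
    def fraction_on(self) -> float:
        return float(self.states.mean())


@dataclass(frozen=True)
class EmissionModel:
    """Elongation "memory" window mapping promoter history to signal.

    A Pol II loaded i frames ago contributes a fraction ``weights[i]`` of
    its full brightness (the MS2 cassette is only partially transcribed
    until the polymerase clears it).  ``weights`` is indexed by lag:
    ``weights[0]`` is the newest frame.
    """

    weights: np.ndarray  # fraction in [0, 1], non-decreasing with lag
    dt: float  # min
    v: float = 1.0  # a.u. per Pol II (1.0 before calibration)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise InvalidParameterError("weights must be a non-empty 1-D array")
        if (w < 0).any() or (w > 1).any():
            raise InvalidParameterError("weights must lie in [0, 1]")
        if self.dt <= 0 or self.v <= 0:
            raise InvalidParameterError("dt and v must be > 0")
        object.__setattr__(self, "weights", w)

    @property
    def K(self) -> int:
        """Window length in frames."""
        return int(self.weights.size)

    @property
    def elongation_time(self) -> float:
        """Nominal residence time of one Pol II on the gene, min."""
        return self.K * self.dt

    @property
    def effective_residence_time(self) -> float:
        """Signal-weighted visible time of one transcript, dt * sum(w), min."""
        return float(self.dt * self.weights.sum())

    def with_v(self, v: float) -> "EmissionModel":
        return replace(self, v=v)


@dataclass
class Trace:
    """One nucleus's uniformly sampled fluorescence time series."""

    nucleus_id: int
    t: np.ndarray  # min, uniform grid
    fluor: np.ndarray  # a.u. (or Pol II after calibration)
    missing: np.ndarray  # bool mask, True = frame not observed
    x: float = 0.0  # μm (AP)
    y: float = 0.0  # μm (DV)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.fluor = np.asarray(self.fluor, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.t.size, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (self.t.size == self.fluor.size == self.missing.size):
            raise InvalidParameterError("t, fluor and missing must have equal length")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise InvalidParameterError("time must strictly increase with a constant step")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size >= 2 else float("nan")

    @property
    def n_frames(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class GlobalParams:
    """Region-level model parameters estimated by EM."""

    kinetics: KineticParams
    sigma: float  # shared Gaussian emission SD, a.u.
    region: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sigma) and self.sigma > 0):
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class PosteriorSummary:
    """Smoothed single-trace posterior from the forward-backward pass."""

    nucleus_id: int
    p_on: np.ndarray  # per-frame P(promoter ON)
    transition_counts: np.ndarray  # expected 2x2 counts, [from, to]
    loglik: float

    def __post_init__(self) -> None:
        self.p_on = np.asarray(self.p_on, dtype=float)
        self.transition_counts = np.asarray(self.transition_counts, dtype=float)
        if self.transition_counts.shape != (2, 2):
            raise InvalidParameterError("transition_counts must be 2x2")
        if ((self.p_on < -1e-9) | (self.p_on > 1 + 1e-9)).any():
            raise InvalidParameterError("p_on must lie in [0, 1]")
        np.clip(self.p_on, 0.0, 1.0, out=self.p_on)


@dataclass(frozen=True)
class CalibrationModel:
    """Fluorescence -> absolute Pol II conversion.

    ``conversion`` is the integrated-signal factor C (a.u.·min per mRNA);
    ``v`` is the instantaneous per-Pol II brightness (a.u. per Pol II).
    """

    half_life: float  # min (inf = no decay)
    probe_weight: float  # fraction of the probe set bound by a nascent transcript
    conversion: float  # a.u.·min per mRNA
    v: float  # a.u. per Pol II
    elongation_time: float  # τ used for the conversion, min

    def __post_init__(self) -> None:
        if not (0 < self.probe_weight <= 1):
            raise InvalidParameterError("probe_weight must lie in (0, 1]")
        if self.conversion <= 0 or self.v <= 0:
            raise InvalidParameterError("conversion factors must be > 0")

    @property
    def degradation_rate(self) -> float:
        """δ = ln2 / half-life, 1/min."""
        return 0.0 if math.isinf(self.half_life) else math.log(2.0) / self.half_life


@dataclass(frozen=True)
class BackgroundModel:
    """Linear background drift b(t) = intercept + slope * t."""

    intercept: float  # a.u.
    slope: float  # a.u./min

    def __post_init__(self) -> None:
        if not (math.isfinite(self.intercept) and math.isfinite(self.slope)):
            raise InvalidParameterError("background coefficients must be finite")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


# -- tidy-table I/O -----------------------------------------------------------

_TRACE_COLUMNS = ["nucleus_id", "t_min", "x_um", "y_um", "fluor_au", "missing"]


def trace_set_to_frame(traces: list[Trace]) -> pd.DataFrame:
    """Serialize traces to a tidy table, one row per nucleus-frame."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "nucleus_id": tr.nucleus_id,
                    "t_min": tr.t,
                    "x_um": tr.x,
                    "y_um": tr.y,
                    "fluor_au": tr.fluor,
                    "missing": tr.missing,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=_TRACE_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def trace_set_from_frame(frame: pd.DataFrame) -> list[Trace]:
    """Inverse of :func:`trace_set_to_frame`."""
    traces = []
    for nid, grp in frame.groupby("nucleus_id", sort=True):
        grp = grp.sort_values("t_min")
        traces.append(
            Trace(
                nucleus_id=int(nid),
                t=grp["t_min"].to_numpy(),
                fluor=grp["fluor_au"].to_numpy(),
                missing=grp["missing"].to_numpy(dtype=bool),
                x=float(grp["x_um"].iloc[0]),
                y=float(grp["y_um"].iloc[0]),
            )
        )
    return traces
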