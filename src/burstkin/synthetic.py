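"""Seeded synthetic embryos with known ground truth.

Emulates the statistical structure of MS2/MCP live-imaging data from the
dorsal ectoderm of early *Drosophila* embryos: a two-state (telegraph)
promoter per nucleus whose activation rate k_on is graded with distance
from the dorsal midline, delayed transcription onsets away from the
midline, fluorescence produced through an elongation "memory" window with
Gaussian noise and a linear background drift, occasional missing frames,
and fixed-embryo (smFISH-style) mRNA count snapshots produced by a
birth-death process with a stated mRNA half-life.

No pixels are rendered; spot tables emulate the post-segmentation stage
(3-D coordinates and intensities) only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    BackgroundModel,
    EmissionModel,
    InvalidParameterError,
    KineticParams,
    PromoterPath,
    Trace,
)

__all__ = [
    "GradientConfig",
    "SyntheticTruth",
    "simulate_promoter_path",
    "render_trace",
    "simulate_embryo",
    "simulate_smfish_counts",
    "simulate_smfish_embryo",
    "make_spot_fixture",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass(frozen=True)
class GradientConfig:
    """Spatial layout of a graded embryo.

    ``bands`` lists (outer_edge_um, k_on) pairs with strictly increasing
    edges; a nucleus at absolute midline distance d takes the k_on of the
    first band whose edge exceeds d (the last edge may be ``inf``).
    Onset delay grows linearly with distance, mirroring the delayed onset
    fronts seen away from the peak-signaling midline.
    """

    bands: tuple[tuple[float, float], ...] = ((15.0, 0.8), (30.0, 0.5), (math.inf, 0.2))
    midline_y_um: float = 0.0
    n_rows: int = 16  # rows across the DV axis (perpendicular to midline)
    n_cols: int = 8  # columns along the AP axis
    spacing_um: float = 5.0  # one cell width
    onset_base_min: float = 5.0
    onset_slope_min_per_um: float = 0.2
    missing_frame_rate: float = 0.01

    def __post_init__(self) -> None:
        if len(self.bands) < 1:
            raise ConfigurationError("at least one band is required")
        edges = [e for e, _ in self.bands]
        if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
            raise ConfigurationError("band edges must strictly increase")
        kons = [k for _, k in self.bands]
        if any(k2 > k1 for k1, k2 in zip(kons, kons[1:])):
            raise ConfigurationError("k_on must be non-increasing with distance")
        if any(k <= 0 for k in kons):
            raise ConfigurationError("band k_on values must be > 0")
        if self.n_rows < 1 or self.n_cols < 1 or self.spacing_um <= 0:
            raise ConfigurationError("grid must be non-empty with positive spacing")

    def k_on_at(self, distance_um: float) -> float:
        d = abs(distance_um)
        for edge, k_on in self.bands:
            if d < edge or math.isinf(edge):
                return k_on
        return self.bands[-1][1]

    def band_index_at(self, distance_um: float) -> int:
        d = abs(distance_um)
        for i, (edge, _) in enumerate(self.bands):
            if d < edge or math.isinf(edge):
                return i
        return len(self.bands) - 1

    def onset_at(self, distance_um: float) -> float:
        return self.onset_base_min + self.onset_slope_min_per_um * abs(distance_um)


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside an emitted trace set."""

    params: dict[int, KineticParams] = field(default_factory=dict)
    paths: dict[int, PromoterPath] = field(default_factory=dict)
    onsets: dict[int, float] = field(default_factory=dict)
    band: dict[int, int] = field(default_factory=dict)
    distance_um: dict[int, float] = field(default_factory=dict)
    background: BackgroundModel | None = None
    mrna_counts: dict[int, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for nid, p in self.params.items():
            rows.append(
                {
                    "nucleus_id": nid,
                    "k_on": p.k_on,
                    "k_off": p.k_off,
                    "k_ini": p.k_ini,
                    "noise_sd": p.noise_sd,
                    "onset_min": self.onsets.get(nid, 0.0),
                    "band": self.band.get(nid, 0),
                    "distance_um": self.distance_um.get(nid, 0.0),
                }
            )
        return pd.DataFrame(rows)


def simulate_promoter_path(
    params: KineticParams,
    n_frames: int,
    dt: float,
    seed: int,
    initial_state: int | None = None,
) -> PromoterPath:
    """Simulate a discrete-time telegraph promoter trajectory.

    Per-frame switch probabilities use the exact exponential hold
    conversion p01 = 1 - exp(-k_on*dt), p10 = 1 - exp(-k_off*dt), so the
    chain is the dt-skeleton of the continuous-time two-state process.
    The initial state is drawn from the stationary distribution unless
    ``initial_state`` pins it.
    """
    if n_frames < 1:
        raise InvalidParameterError(f"n_frames must be >= 1, got {n_frames}")
    p01, p10 = params.switch_probabilities(dt)
    rng = np.random.default_rng(seed)
    u = rng.random(n_frames)
    states = np.empty(n_frames, dtype=np.int8)
    if initial_state is None:
        states[0] = 1 if u[0] < params.occupancy else 0
    else:
        states[0] = 1 if initial_state else 0
        u[0] = 0.0  # consume nothing extra; keep stream length fixed
    for t in range(1, n_frames):
        if states[t - 1] == 0:
            states[t] = 1 if u[t] < p01 else 0
        else:
            states[t] = 0 if u[t] < p10 else 1
    return PromoterPath(states=states, dt=dt)


def render_trace(
    path: PromoterPath,
    k_ini: float,
    emission: EmissionModel,
    background: BackgroundModel | None = None,
    noise_sd: float = 0.0,
    missing_frames: tuple[int, ...] | np.ndarray = (),
    seed: int = 0,
    nucleus_id: int = 0,
    x: float = 0.0,
    y: float = 0.0,
) -> Trace:
    """Render a fluorescence trace from a promoter path.

    F_t = v * k_ini * dt * sum_i w_i * z_{t-i} + b(t) + eps_t, with
    zero-padded promoter history before the trace start and
    eps_t ~ N(0, noise_sd^2).  Frames listed in ``missing_frames`` are
    flagged missing (their fluorescence value is kept for bookkeeping but
    downstream code must ignore it).
    """
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    if k_ini <= 0:
        raise InvalidParameterError(f"k_ini must be > 0, got {k_ini}")
    z = path.states.astype(float)
    # signal_t = amp * sum_i w_i z_{t-i}: causal FIR filter of the path
    signal = np.convolve(z, emission.weights)[: z.size]
    amp = emission.v * k_ini * path.dt
    t = np.arange(z.size) * path.dt
    fluor = amp * signal
    if background is not None:
        fluor = fluor + background(t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fluor = fluor + rng.normal(0.0, noise_sd, size=z.size)
    missing = np.zeros(z.size, dtype=bool)
    mf = np.asarray(missing_frames, dtype=int)
    if mf.size:
        missing[mf] = True
    return Trace(nucleus_id=nucleus_id, t=t, fluor=fluor, missing=missing, x=x, y=y)


def simulate_embryo(
    gradient: GradientConfig,
    params_base: KineticParams,
    emission: EmissionModel,
    n_frames: int = 150,
    background: BackgroundModel | None = BackgroundModel(2.0, 0.02),
    seed: int = 0,
    apply_onset_delay: bool = True,
) -> tuple[list[Trace], SyntheticTruth]:
    """Simulate one embryo: nuclei on a grid with banded k_on.

    Each nucleus takes its band's k_on; k_off, k_ini and noise_sd are
    shared from ``params_base``.  The promoter is held OFF until the
    nucleus's onset time (delay increasing with midline distance), then
    switches freely from the stationary distribution.  Traces share the
    background drift; missing frames are dropped independently at the
    configured rate.
    """
    rng = np.random.default_rng(seed)
    dt = emission.dt
    truth = SyntheticTruth(background=background)
    traces: list[Trace] = []
    nid = 0
    half_extent = (gradient.n_rows - 1) / 2.0
    for row in range(gradient.n_rows):
        yv = gradient.midline_y_um + (row - half_extent) * gradient.spacing_um
        d = yv - gradient.midline_y_um
        for col in range(gradient.n_cols):
            xv = col * gradient.spacing_um
            k_on = gradient.k_on_at(d)
            params = KineticParams(k_on, params_base.k_off, params_base.k_ini, params_base.noise_sd)
            path = simulate_promoter_path(
                params, n_frames, dt, seed=int(rng.integers(2**31 - 1))
            )
            onset = gradient.onset_at(d) if apply_onset_delay else 0.0
            states = path.states.copy()
            onset_frame = min(int(math.ceil(onset / dt)), n_frames)
            states[:onset_frame] = 0
            path = PromoterPath(states=states, dt=dt)
            n_missing = rng.binomial(n_frames, gradient.missing_frame_rate)
            missing = (
                rng.choice(n_frames, size=n_missing, replace=False) if n_missing else ()
            )
            tr = render_trace(
                path,
                params.k_ini,
                emission,
                background=background,
                noise_sd=params.noise_sd,
                missing_frames=missing,
                seed=int(rng.integers(2**31 - 1)),
                nucleus_id=nid,
                x=xv,
                y=yv,
            )
            traces.append(tr)
            truth.params[nid] = params
            truth.paths[nid] = path
            truth.onsets[nid] = onset
            truth.band[nid] = gradient.band_index_at(d)
            truth.distance_um[nid] = d
            nid += 1
    return traces, truth


def _switching_intervals(
    params: KineticParams, t_fix: float, rng: np.random.Generator
) -> tuple[list[tuple[float, float]], int]:
    """Continuous-time telegraph ON intervals over [0, t_fix] and the state at t_fix."""
    state = 1 if rng.random() < params.occupancy else 0
    t = 0.0
    on_intervals: list[tuple[float, float]] = []
    while t < t_fix:
        rate = params.k_off if state == 1 else params.k_on
        hold = rng.exponential(1.0 / rate)
        end = min(t + hold, t_fix)
        if state == 1:
            on_intervals.append((t, end))
        t = end
        if t < t_fix:
            state = 1 - state
    return on_intervals, state


def simulate_smfish_counts(
    params: KineticParams,
    half_life: float,
    t_fix: float,
    n_cells: int,
    n_alleles: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Birth-death mRNA count snapshots at fixation time.

    Each allele carries an independent continuous-time telegraph promoter
    (stationary initial state); while ON, mRNAs are born at rate k_ini and
    each decays independently at rate delta = ln2 / half_life.  Because
    deaths are independent thinning of a Poisson birth stream, the number
    of survivors from an ON interval [s, e] is Poisson with mean
    k_ini * ∫_s^e exp(-delta (t_fix - u)) du, which is sampled exactly.

    Returns one row per cell: ``count`` (surviving mRNAs summed over
    alleles), ``n_active`` (alleles whose promoter is ON at t_fix) and
    per-allele active flags.
    """
    if t_fix <= 0:
        raise InvalidParameterError(f"t_fix must be > 0, got {t_fix}")
    if not (half_life > 0):
        raise InvalidParameterError(f"half_life must be > 0 (or inf), got {half_life}")
    if n_alleles < 1:
        raise InvalidParameterError(f"n_alleles must be >= 1, got {n_alleles}")
    delta = 0.0 if math.isinf(half_life) else math.log(2.0) / half_life
    rng = np.random.default_rng(seed)
    rows = []
    for cell in range(n_cells):
        total = 0
        active = []
        for _ in range(n_alleles):
            on_intervals, state = _switching_intervals(params, t_fix, rng)
            mean = 0.0
            for s, e in on_intervals:
                if delta == 0.0:
                    mean += params.k_ini * (e - s)
                else:
                    mean += (
                        params.k_ini
                        * math.exp(-delta * t_fix)
                        * (math.exp(delta * e) - math.exp(delta * s))
                        / delta
                    )
            total += int(rng.poisson(mean))
            active.append(state)
        row = {"cell_id": cell, "count": total, "n_active": int(sum(active))}
        for a, st in enumerate(active):
            row[f"allele_{a}_active"] = bool(st)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_smfish_embryo(
    gradient: GradientConfig,
    params_base: KineticParams,
    half_life: float,
    t_fix: float,
    seed: int = 0,
    single_mrna_intensity: float = 1.0,
    ts_polII_residence_min: float = 2.0,
    probe_weight: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fixed-embryo snapshot of a graded domain: nuclei, spots and counts.

    Nuclei sit on the gradient's grid; per-cell counts come from
    :func:`simulate_smfish_counts` at the band's k_on.  The spot table
    contains one single-mRNA spot per surviving molecule (intensity
    jittered around ``single_mrna_intensity``) scattered in a cytoplasmic
    neighbourhood, plus one transcription-site spot per active allele with
    intensity = resident Pol II (Poisson with mean
    k_ini * ts_polII_residence_min) * probe_weight * single intensity.
    """
    rng = np.random.default_rng(seed)
    nuc_rows, spot_rows, count_rows = [], [], []
    nid = 0
    spot_id = 0
    half_extent = (gradient.n_rows - 1) / 2.0
    for row in range(gradient.n_rows):
        yv = gradient.midline_y_um + (row - half_extent) * gradient.spacing_um
        d = yv - gradient.midline_y_um
        for col in range(gradient.n_cols):
            xv = col * gradient.spacing_um
            params = KineticParams(
                gradient.k_on_at(d), params_base.k_off, params_base.k_ini, params_base.noise_sd
            )
            cell = simulate_smfish_counts(
                params, half_life, t_fix, n_cells=1, n_alleles=2,
                seed=int(rng.integers(2**31 - 1)),
            ).iloc[0]
            nuc_rows.append(
                {
                    "nucleus_id": nid,
                    "x_um": xv,
                    "y_um": yv,
                    "z_um": 0.0,
                    "axis_x0": xv,
                    "axis_y0": yv - 1.5,
                    "axis_z0": 0.0,
                    "axis_x1": xv,
                    "axis_y1": yv + 1.5,
                    "axis_z1": 0.0,
                }
            )
            count_rows.append(
                {
                    "nucleus_id": nid,
                    "count": int(cell["count"]),
                    "n_active": int(cell["n_active"]),
                    "distance_um": d,
                    "band": gradient.band_index_at(d),
                }
            )
            for _ in range(int(cell["count"])):
                spot_rows.append(
                    {
                        "spot_id": spot_id,
                        "x_um": xv + rng.normal(0, 1.2),
                        "y_um": yv + rng.normal(0, 1.2),
                        "z_um": rng.normal(0, 0.8),
                        "intensity_au": max(
                            single_mrna_intensity * (1 + rng.normal(0, 0.1)), 1e-6
                        ),
                        "spot_class": "mrna",
                        "nucleus_id_true": nid,
                    }
                )
                spot_id += 1
            for _ in range(int(cell["n_active"])):
                n_pol = rng.poisson(params.k_ini * ts_polII_residence_min)
                spot_rows.append(
                    {
                        "spot_id": spot_id,
                        "x_um": xv + rng.normal(0, 0.4),
                        "y_um": yv + rng.normal(0, 0.4),
                        "z_um": rng.normal(0, 0.3),
                        "intensity_au": max(n_pol, 1)
                        * probe_weight
                        * single_mrna_intensity,
                        "spot_class": "ts",
                        "nucleus_id_true": nid,
                    }
                )
                spot_id += 1
            nid += 1
    return pd.DataFrame(nuc_rows), pd.DataFrame(spot_rows), pd.DataFrame(count_rows)


def make_spot_fixture(
    midline_coeffs: tuple[float, float, float],
    n_nuclei: int,
    spots_per_cell: int = 8,
    seed: int = 0,
    span_x_um: float = 100.0,
    offset_sd_um: float = 12.0,
    spot_scatter_um: float = 1.0,
    axis_half_length_um: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Geometric fixture for the spatial pipeline.

    Nuclei are scattered around a quadratic midline y = a x^2 + b x + c
    with vertical long axes; each nucleus receives ``spots_per_cell``
    spots jittered around its centroid.  True assignments and true signed
    offsets are recorded in the tables.
    """
    if n_nuclei < 3:
        raise ConfigurationError("need at least 3 nuclei")
    if axis_half_length_um <= 0:
        raise ConfigurationError("long axis must have positive length")
    a, b, c = midline_coeffs
    rng = np.random.default_rng(seed)
    xs = np.linspace(0.0, span_x_um, n_nuclei)
    offsets = rng.normal(0.0, offset_sd_um, size=n_nuclei)
    nuc_rows, spot_rows = [], []
    spot_id = 0
    for nid, (xv, off) in enumerate(zip(xs, offsets)):
        yv = a * xv**2 + b * xv + c + off
        nuc_rows.append(
            {
                "nucleus_id": nid,
                "x_um": xv,
                "y_um": yv,
                "z_um": 0.0,
                "axis_x0": xv,
                "axis_y0": yv - axis_half_length_um,
                "axis_z0": 0.0,
                "axis_x1": xv,
                "axis_y1": yv + axis_half_length_um,
                "axis_z1": 0.0,
                "true_offset_um": off,
            }
        )
        for _ in range(spots_per_cell):
            spot_rows.append(
                {
                    "spot_id": spot_id,
                    "x_um": xv + rng.normal(0, spot_scatter_um),
                    "y_um": yv + rng.normal(0, spot_scatter_um),
                    "z_um": rng.normal(0, spot_scatter_um),
                    "intensity_au": 1.0,
                    "spot_class": "mrna",
                    "nucleus_id_true": nid,
                }
            )
            spot_id += 1
    return pd.DataFrame(nuc_rows), pd.DataFrame(spot_rows)
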