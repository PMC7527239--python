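"""Fixed-embryo spatial quantification.

The dorsal midline of the expression domain is a quadratic curve fitted
through mRNA spot coordinates; nuclei are characterized by their signed
perpendicular distance to it, binned at one cell width (5 μm), and
assigned to signaling regions by banded distance cutoffs.  Spots are
assigned to the nucleus whose long-axis segment is nearest in 3-D, and
transcription sites (bright foci, intensity a multiple of a single
mRNA's) are counted per nucleus, capped at two for a diploid embryo.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import InvalidParameterError

__all__ = [
    "Midline",
    "RegionConfig",
    "USH_REGIONS",
    "HNT_REGIONS",
    "ST2_DPP_USH_REGIONS",
    "fit_midline",
    "signed_distance_to_midline",
    "assign_spots_to_nuclei",
    "count_active_alleles",
    "bin_and_label",
    "mrna_per_cell_profile",
]

BIN_WIDTH_UM = 5.0  # one cell width


class DegenerateFitError(ValueError):
    pass


@dataclass(frozen=True)
class Midline:
    """y = a x^2 + b x + c, in μm."""

    a: float
    b: float
    c: float

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.square(x) + self.b * x + self.c


@dataclass(frozen=True)
class RegionConfig:
    """Banded signaling regions by absolute midline distance.

    ``bands`` maps labels to outer edges (μm); bands are contiguous from
    0, e.g. high 0-15, medium 15-30, low beyond.
    """

    gene: str
    bands: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        edges = [e for _, e in self.bands]
        if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
            raise InvalidParameterError("band edges must strictly increase")

    def label(self, distance_um: float) -> str:
        d = abs(distance_um)
        for name, edge in self.bands:
            if d < edge or math.isinf(edge):
                return name
        return self.bands[-1][0]


USH_REGIONS = RegionConfig("ush", (("high", 15.0), ("medium", 30.0), ("low", math.inf)))
HNT_REGIONS = RegionConfig("hnt", (("high", 10.0), ("medium", math.inf)))
ST2_DPP_USH_REGIONS = RegionConfig(
    "ush-st2dpp",
    (("high", 15.0), ("medium", 30.0), ("low", 50.0), ("region4", math.inf)),
)


def fit_midline(spots: pd.DataFrame) -> Midline:
    """Least-squares quadratic of spot y on spot x (columns x_um, y_um)."""
    x = np.asarray(spots["x_um"], dtype=float)
    y = np.asarray(spots["y_um"], dtype=float)
    if np.unique(x).size < 3:
        raise DegenerateFitError("need >= 3 spots with distinct x")
    a, b, c = np.polyfit(x, y, 2)
    return Midline(float(a), float(b), float(c))


def signed_distance_to_midline(
    x: float, y: float, midline: Midline, mode: str = "perpendicular"
) -> float:
    """Signed in-plane distance from (x, y) to the midline curve.

    ``perpendicular`` (default) minimizes the Euclidean distance to the
    curve — the stationarity condition is a cubic in the curve parameter,
    solved in closed form; ``vertical`` simply uses y - midline(x).  The
    sign is positive when the point lies above the curve at its own x.
    """
    if mode == "vertical":
        return float(y - midline(x))
    a, b, c = midline.a, midline.b, midline.c
    if a == 0.0:
        # straight line: project onto it
        denom = 1.0 + b * b
        t = (x + b * (y - c)) / denom
        dist = math.hypot(x - t, y - (b * t + c))
    else:
        # d/dt [ (x-t)^2 + (y - (a t^2 + b t + c))^2 ] = 0  ->  cubic in t
        coeffs = [
            2 * a * a,
            3 * a * b,
            1 + b * b + 2 * a * (c - y),
            b * (c - y) - x,
        ]
        roots = np.roots(coeffs)
        real = roots[np.abs(roots.imag) < 1e-8].real
        if real.size == 0:  # numerical fallback
            real = np.array([x])
        ys = a * real**2 + b * real + c
        dists = np.hypot(x - real, y - ys)
        dist = float(dists.min())
    sign = 1.0 if y >= midline(x) else -1.0
    return sign * dist


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from points p (n,3) to segment [a, b] in 3-D."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        raise InvalidParameterError("degenerate (zero-length) nuclear long axis")
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


def assign_spots_to_nuclei(
    spots: pd.DataFrame, nuclei: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each spot to the nucleus with the nearest long-axis segment.

    Ties go to the lowest nucleus id.  Returns the spot table with an
    ``assigned_nucleus`` column and a per-nucleus count table.
    """
    if len(nuclei) < 1:
        raise InvalidParameterError("need at least one nucleus")
    pts = spots[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    nuc_sorted = nuclei.sort_values("nucleus_id")
    ids = nuc_sorted["nucleus_id"].to_numpy()
    # running minimum keeps memory at O(n_spots) regardless of nucleus count;
    # strict < with ids in ascending order makes ties pick the lowest id
    best = np.full(len(spots), np.inf)
    assigned = np.full(len(spots), ids[0])
    for _, nuc in nuc_sorted.iterrows():
        a = np.array([nuc["axis_x0"], nuc["axis_y0"], nuc["axis_z0"]], dtype=float)
        b = np.array([nuc["axis_x1"], nuc["axis_y1"], nuc["axis_z1"]], dtype=float)
        d = _point_segment_distance(pts, a, b)
        closer = d < best - 1e-12
        best[closer] = d[closer]
        assigned[closer] = nuc["nucleus_id"]
    out = spots.copy()
    out["assigned_nucleus"] = assigned
    counts = (
        out.groupby("assigned_nucleus").size().reindex(ids, fill_value=0).rename("n_spots")
    )
    counts = counts.reset_index().rename(columns={"assigned_nucleus": "nucleus_id", "index": "nucleus_id"})
    return out, counts


def count_active_alleles(
    assigned_spots: pd.DataFrame,
    ts_threshold: float = 4.0,
) -> pd.DataFrame:
    """Count transcription sites per nucleus (0, 1 or 2).

    A spot counts as a transcription site if its intensity is at least
    ``ts_threshold`` times the median single-mRNA intensity.  The median
    is taken over spots labelled 'mrna' when a ``spot_class`` column
    exists, otherwise over spots below the provisional threshold.  Counts
    above two (diploid) are capped, with the excess flagged.
    """
    if "spot_class" in assigned_spots.columns:
        singles = assigned_spots.loc[assigned_spots["spot_class"] == "mrna", "intensity_au"]
    else:
        singles = assigned_spots["intensity_au"]
        singles = singles[singles <= np.median(singles) * ts_threshold]
    if singles.empty:
        raise InvalidParameterError("no single-mRNA spots to set the intensity median")
    median_single = float(np.median(singles))
    cutoff = ts_threshold * median_single
    rows = []
    for nid, grp in assigned_spots.groupby("assigned_nucleus"):
        n_ts = int((grp["intensity_au"] >= cutoff).sum())
        rows.append(
            {
                "nucleus_id": nid,
                "n_active_alleles": min(n_ts, 2),
                "excess_sites": max(n_ts - 2, 0),
            }
        )
    return pd.DataFrame(rows)


def bin_and_label(
    distances_um: np.ndarray | list[float], regions: RegionConfig
) -> pd.DataFrame:
    """5 μm bin index (floor(|d|/5)) and signaling-region label per nucleus."""
    d = np.asarray(distances_um, dtype=float)
    bins = np.floor(np.abs(d) / BIN_WIDTH_UM).astype(int)
    labels = [regions.label(v) for v in d]
    return pd.DataFrame({"distance_um": d, "bin": bins, "region": labels})


def mrna_per_cell_profile(
    counts: np.ndarray | list[float],
    distances_um: np.ndarray | list[float],
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Binned median mRNA-per-cell profile with bootstrap 95% intervals.

    Returns (profile table, Spearman rho of count vs |distance|, p-value).
    Empty bins are omitted (they simply do not appear in the table).
    """
    counts = np.asarray(counts, dtype=float)
    d = np.abs(np.asarray(distances_um, dtype=float))
    if counts.size != d.size:
        raise InvalidParameterError("counts and distances must align")
    bins = np.floor(d / BIN_WIDTH_UM).astype(int)
    rng = np.random.default_rng(seed)
    rows = []
    for b in np.unique(bins):
        vals = counts[bins == b]
        boots = np.median(
            rng.choice(vals, size=(n_boot, vals.size), replace=True), axis=1
        )
        rows.append(
            {
                "bin": int(b),
                "distance_mid_um": (b + 0.5) * BIN_WIDTH_UM,
                "n": int(vals.size),
                "median": float(np.median(vals)),
                "ci_lo": float(np.percentile(boots, 2.5)),
                "ci_hi": float(np.percentile(boots, 97.5)),
            }
        )
    if np.unique(counts).size > 1 and np.unique(d).size > 1:
        rho, pval = stats.spearmanr(d, counts)
    else:
        rho, pval = 0.0, 1.0
    return pd.DataFrame(rows), float(rho), float(pval)
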