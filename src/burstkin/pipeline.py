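"""End-to-end orchestration: simulate -> preprocess -> fit -> cells ->
calibrate -> spatial report, from one config mapping.

Every stage is a plain library call; this module only wires them
together, writes tidy outputs and records a manifest (config hash and
seeds) so a run can be reproduced exactly.
"""
from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import mhmm, preprocess, single_cell, spatial, synthetic
from .types import (
    BackgroundModel,
    GlobalParams,
    KineticParams,
    trace_set_to_frame,
)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "load_config"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "output_dir": "burstkin_demo_out",
    "gene": {
        "gene_length_kb": 3.0,
        "ms2_cassette_kb": 1.3,
        "elongation_speed_kb_per_min": 1.5,
        "frame_interval_min": 1.0 / 3.0,
    },
    "model": {"M": 64, "tol": 1e-5, "max_iter": 60, "n_restarts": 1, "pseudo_count": 1.0},
    "calibration": {
        "half_life_min": 12.0,
        "probe_weight": 1.0,
        "production_window_min": 50.0,
    },
    "regions": {"gene": "ush"},
    "simulation": {
        "n_frames": 150,
        "bands": [[15.0, 0.8], [30.0, 0.5], [None, 0.2]],
        "k_off": 1.0,
        "k_ini": 20.0,
        "noise_sd": 1.0,
        "n_rows": 16,
        "n_cols": 4,
        "background": [2.0, 0.02],
        "onset_base_min": 2.0,
        "onset_slope_min_per_um": 0.15,
    },
}

_REGION_CONFIGS = {
    "ush": spatial.USH_REGIONS,
    "hnt": spatial.HNT_REGIONS,
    "ush-st2dpp": spatial.ST2_DPP_USH_REGIONS,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> list[str]:
    """Schema validation; returns a list of failure messages (empty = valid)."""
    failures: list[str] = []
    gene = config.get("gene", {})
    for key in ("gene_length_kb", "ms2_cassette_kb", "elongation_speed_kb_per_min", "frame_interval_min"):
        if key not in gene:
            failures.append(f"gene.{key} is missing")
        elif not (isinstance(gene[key], (int, float)) and gene[key] > 0):
            failures.append(f"gene.{key} must be a positive number")
    model = config.get("model", {})
    if model.get("M", 1) < 1:
        failures.append("model.M must be >= 1")
    sim = config.get("simulation", {})
    bands = sim.get("bands", [])
    if bands:
        edges = [e if e is not None else math.inf for e, _ in bands]
        if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
            failures.append("simulation.bands edges must strictly increase (overlap/ordering)")
        if any(k <= 0 for _, k in bands):
            failures.append("simulation.bands k_on values must be > 0")
    region_gene = config.get("regions", {}).get("gene")
    if region_gene is not None and region_gene not in _REGION_CONFIGS:
        failures.append(f"regions.gene must be one of {sorted(_REGION_CONFIGS)}")
    calib = config.get("calibration", {})
    hl = calib.get("half_life_min")
    if hl is not None and not hl > 0:
        failures.append("calibration.half_life_min must be > 0")
    return failures


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict | None = None, output_dir: str | Path | None = None) -> dict:
    """Run the full synthetic-embryo analysis and write all outputs.

    Returns a results dict (also serialized under the output directory):
    per-region global parameters, the per-nucleus estimate table, the
    calibration model, T_50 per region, the spatial mRNA profile and the
    QC report, plus the run manifest.
    """
    config = {**DEFAULT_CONFIG, **(config or {})}
    failures = validate_config(config)
    if failures:
        raise ValueError("invalid config: " + "; ".join(failures))
    seed = int(config["seed"])
    out = Path(output_dir or config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)

    gene = config["gene"]
    dt = float(gene["frame_interval_min"])
    emission = mhmm.build_emission_model(
        gene["gene_length_kb"], gene["ms2_cassette_kb"], gene["elongation_speed_kb_per_min"], dt
    )
    sim = config["simulation"]
    bands = tuple((math.inf if e is None else float(e), float(k)) for e, k in sim["bands"])
    gradient = synthetic.GradientConfig(
        bands=bands,
        n_rows=int(sim["n_rows"]),
        n_cols=int(sim["n_cols"]),
        onset_base_min=float(sim.get("onset_base_min", 2.0)),
        onset_slope_min_per_um=float(sim.get("onset_slope_min_per_um", 0.15)),
    )
    base = KineticParams(
        k_on=bands[0][1], k_off=float(sim["k_off"]), k_ini=float(sim["k_ini"]),
        noise_sd=float(sim["noise_sd"]),
    )
    bg = BackgroundModel(*sim.get("background", (0.0, 0.0)))
    traces, truth = synthetic.simulate_embryo(
        gradient, base, emission, n_frames=int(sim["n_frames"]), background=bg, seed=seed
    )

    # -- preprocess: fit background on dedicated samples, subtract, QC ------
    rng = np.random.default_rng(seed + 1)
    t_bg = np.arange(0, int(sim["n_frames"]), 3) * dt
    bg_samples = np.column_stack(
        [t_bg, bg(t_bg) + rng.normal(0, base.noise_sd, t_bg.size)]
    )
    bg_fit = preprocess.fit_background(bg_samples)
    thresh = preprocess.detection_threshold(bg_samples, bg_fit)
    subtracted = [preprocess.subtract_background(tr, bg_fit) for tr in traces]
    kept, qc = preprocess.qc_filter(subtracted, thresh)

    region_cfg = _REGION_CONFIGS[config["regions"]["gene"]]
    dist = {tr.nucleus_id: truth.distance_um[tr.nucleus_id] for tr in kept}
    labels = {nid: region_cfg.label(d) for nid, d in dist.items()}

    # -- onsets and T_50 per region ----------------------------------------
    onsets_by_region: dict[str, list[float]] = {}
    totals: dict[str, int] = {}
    for tr in kept:
        lab = labels[tr.nucleus_id]
        totals[lab] = totals.get(lab, 0) + 1
        onset = preprocess.detect_onset(tr, thresh)
        if onset is not None:
            onsets_by_region.setdefault(lab, []).append(onset)
    t50 = {
        lab: preprocess.compute_t50(onsets_by_region.get(lab, []), totals[lab])
        for lab in totals
    }

    # -- global EM fit per region -------------------------------------------
    mdl = config["model"]
    init = GlobalParams(
        kinetics=KineticParams(k_on=0.4, k_off=0.8, k_ini=base.k_ini * 0.5),
        sigma=max(base.noise_sd, 1e-3),
    )
    region_params: dict[str, GlobalParams] = {}
    region_fit_info: dict[str, dict] = {}
    for lab in sorted(totals):
        sub = [tr for tr in kept if labels[tr.nucleus_id] == lab]
        res = mhmm.fit_em(
            sub, init, emission, M=int(mdl["M"]), tol=float(mdl["tol"]),
            max_iter=int(mdl["max_iter"]), n_restarts=int(mdl["n_restarts"]),
            seed=seed + 10, region=lab,
        )
        region_params[lab] = res.params
        region_fit_info[lab] = {
            "k_on": res.params.kinetics.k_on,
            "k_off": res.params.kinetics.k_off,
            "k_ini_au": res.params.kinetics.k_ini,
            "sigma": res.params.sigma,
            "occupancy": res.params.kinetics.occupancy,
            "loglik": res.loglik_history[-1],
            "n_iter": res.n_iter,
            "converged": res.converged,
            "n_traces": len(sub),
        }

    # -- single-cell estimates ----------------------------------------------
    cells: list[single_cell.CellEstimate] = []
    for tr in kept:
        lab = labels[tr.nucleus_id]
        params = region_params[lab]
        post = mhmm.forward_backward(tr, params, emission, M=int(mdl["M"]))
        k_on, k_off = single_cell.cell_rates(post, float(mdl.get("pseudo_count", 1.0)), dt)
        occ = single_cell.cell_occupancy(post)
        desc = single_cell.derive_burst_descriptors(k_on, k_off, params.kinetics.k_ini)
        cells.append(
            single_cell.CellEstimate(
                nucleus_id=tr.nucleus_id,
                k_on=k_on,
                k_off=k_off,
                k_ini=params.kinetics.k_ini,
                occupancy=occ,
                frequency=desc.frequency,
                burst_size=desc.burst_size,
                duration=desc.duration,
                mean_expression=float(tr.fluor[~tr.missing].mean()),
                distance_um=dist[tr.nucleus_id],
                region=lab,
            )
        )
    cell_table = single_cell.cell_estimates_table(cells)
    correlations = {}
    for pname in ("occupancy", "k_on", "k_off"):
        try:
            rep = single_cell.correlate_with_expression(cells, pname)
            correlations[pname] = {"r": rep.r, "p": rep.p_value, "n": rep.n}
        except single_cell.UndefinedCorrelationError:
            correlations[pname] = None

    # -- calibration: smFISH counts at matched kinetics ---------------------
    calib_cfg = config["calibration"]
    half_life = float(calib_cfg["half_life_min"])
    window = float(calib_cfg["production_window_min"])
    high_params = KineticParams(bands[0][1], base.k_off, base.k_ini)
    fish = synthetic.simulate_smfish_counts(
        high_params, half_life, t_fix=window, n_cells=300, n_alleles=2, seed=seed + 20
    )
    produced = cal.degradation_correct(float(fish["count"].mean()), half_life, window)
    high_traces = [tr for tr in kept if labels[tr.nucleus_id] == "high"]
    calib_model, _ = cal.compute_conversion(
        high_traces, produced, emission, half_life=half_life,
        probe_weight=float(calib_cfg.get("probe_weight", 1.0)),
    )

    # -- spatial: fixed-embryo snapshot -------------------------------------
    nuc_df, spot_df, count_df = synthetic.simulate_smfish_embryo(
        gradient, base, half_life, t_fix=window, seed=seed + 30
    )
    midline = spatial.fit_midline(spot_df[spot_df["spot_class"] == "mrna"])
    assigned, _ = spatial.assign_spots_to_nuclei(spot_df, nuc_df)
    profile, rho, rho_p = spatial.mrna_per_cell_profile(
        count_df["count"].to_numpy(), count_df["distance_um"].to_numpy(), seed=seed + 31
    )

    # -- outputs -------------------------------------------------------------
    trace_set_to_frame(kept).to_csv(out / "traces.csv", index=False)
    truth.to_frame().to_csv(out / "truth.csv", index=False)
    cell_table.to_csv(out / "cell_estimates.csv", index=False)
    profile.to_csv(out / "mrna_profile.csv", index=False)
    results = {
        "qc": qc.to_dict(),
        "t50_min": t50,
        "global_params": region_fit_info,
        "correlations": correlations,
        "calibration": {
            "half_life_min": calib_model.half_life,
            "conversion_au_min_per_mrna": calib_model.conversion,
            "v_au_per_polII": calib_model.v,
            "produced_per_cell": produced,
        },
        "spatial": {
            "midline": [midline.a, midline.b, midline.c],
            "spearman_rho_count_vs_distance": rho,
            "spearman_p": rho_p,
            "n_spots_assigned": int(len(assigned)),
        },
        "manifest": {
            "config_hash": _config_hash(config),
            "seed": seed,
            "n_traces_input": qc.n_input,
            "n_traces_retained": qc.n_retained,
        },
    }
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    return results
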