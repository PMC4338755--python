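"""End-to-end experiment templates.

Four shipped templates mirror the standard whole-brain study designs:

* ``rest-noise-scan`` — resting-state runs across noise amplitudes
  (0.01, 0.05, 0.07, 0.1), totals of last-2 s mean firing per sigma;
* ``focal-lesion`` — disconnect whole named regions (default rCUN, rLOCC,
  rPCUN) and compare against the healthy network per sigma;
* ``diffuse-lesion`` — disconnect randomly scattered nodes (default 50) and
  compare against the healthy network per sigma;
* ``tms-efferents`` — inhibitory current on a region set during the first
  5 s, post-vs-pre ΔFR map and return-to-baseline latency.

Each run writes summary CSVs and a JSON manifest (all parameters, seeds,
software version) sufficient to reproduce the outputs byte-identically.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import delta_fr, mean_firing, noise_scan, return_to_baseline
from .atlas import load_builtin_atlas, nodes_of_regions
from .connectome import Connectome, read_graphml
from .dynamics import MeanFieldParams, SimulationConfig, calibrate_g, simulate_meanfield
from .perturbation import (
    apply_lesion,
    diffuse_lesion,
    focal_lesion,
    lesion_connection_fraction,
    make_stimulation,
)
from .synthetic import SynthSpec, generate

__all__ = ["TEMPLATES", "template_config", "run_experiment"]

log = logging.getLogger("connectosim")

_BASE = {
    "connectome": None,          # path to GraphML; None -> synthetic
    "synthetic": {"seed": 0},    # SynthSpec overrides
    "model": "meanfield",
    "params": {},                # MeanFieldParams overrides
    "calibrate": {"enabled": True, "tol": 0.02},
    "sim": {"dt_ms": 0.1, "duration_s": 10.0, "sample_ms": 1.0,
            "seed": 0, "initial_S": 0.001},
    "sigmas": [0.01, 0.05, 0.07, 0.1],
    "seeds": [0],
    "lesion": None,
    "stimulation": None,
    "analysis": {"window_s": 2.0},
}

TEMPLATES = {
    "rest-noise-scan": {},
    "focal-lesion": {"lesion": {"focal": ["rCUN", "rLOCC", "rPCUN"]}},
    "diffuse-lesion": {"lesion": {"diffuse": {"n": 50, "seed": 7}}},
    "tms-efferents": {
        "sigmas": [0.01],
        "sim": {"dt_ms": 0.1, "duration_s": 10.0, "sample_ms": 1.0,
                "seed": 0, "initial_S": 0.001},
        "stimulation": {"regions": ["rCUN", "rLOCC", "rPCUN"],
                        "amplitude_nA": -0.1, "t_on_s": 0.0, "t_off_s": 5.0},
    },
}


def template_config(name: str, **overrides) -> dict:
    """The full config dict for a shipped template, with overrides applied."""
    if name not in TEMPLATES:
        raise KeyError(f"unknown template {name!r}; available: {sorted(TEMPLATES)}")
    cfg = copy.deepcopy(_BASE)
    _deep_update(cfg, copy.deepcopy(TEMPLATES[name]))
    _deep_update(cfg, overrides)
    cfg["template"] = name
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _load_connectome(cfg: dict) -> Connectome:
    atlas = load_builtin_atlas()
    if cfg.get("connectome"):
        return read_graphml(cfg["connectome"], atlas=atlas)
    synth = dict(cfg.get("synthetic") or {})
    spec = SynthSpec(**synth)
    return generate(spec)


def _sim_config(cfg: dict, seed: int) -> SimulationConfig:
    sim = cfg["sim"]
    return SimulationConfig(
        dt=sim["dt_ms"] / 1000.0,
        duration=sim["duration_s"],
        sample_interval=sim["sample_ms"] / 1000.0,
        seed=seed,
        initial_s=sim.get("initial_S", 0.001),
    )


def _build_protocol(cfg: dict, conn: Connectome):
    atlas = conn.atlas or load_builtin_atlas()
    protocol = []
    lesion = None
    les_cfg = cfg.get("lesion")
    if les_cfg:
        if "focal" in les_cfg:
            lesion = focal_lesion(atlas, les_cfg["focal"])
        elif "diffuse" in les_cfg:
            d = les_cfg["diffuse"]
            lesion = diffuse_lesion(conn, d["n"], seed=d.get("seed", 0))
        else:
            raise ValueError("lesion config must contain 'focal' or 'diffuse'")
        protocol.append(lesion)
    stim = None
    stim_cfg = cfg.get("stimulation")
    if stim_cfg:
        if "regions" in stim_cfg:
            nodes = nodes_of_regions(atlas, stim_cfg["regions"]).tolist()
        else:
            nodes = list(stim_cfg["nodes"])
        stim = make_stimulation(
            nodes, stim_cfg["amplitude_nA"], stim_cfg["t_on_s"], stim_cfg["t_off_s"]
        )
        protocol.append(stim)
    return protocol, lesion, stim


def run_experiment(config: dict, out_dir) -> dict:
    """Run one experiment config end-to-end and write its result bundle.

    Writes per-sigma summary tables (CSV), ΔFR tables where a comparison
    condition exists, and ``manifest.json``.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = copy.deepcopy(_BASE)
    _deep_update(cfg, config)

    conn = _load_connectome(cfg)
    params = MeanFieldParams(**cfg.get("params", {}))
    if cfg["calibrate"]["enabled"] and params.g == 0.0:
        g = calibrate_g(conn, params, tol=cfg["calibrate"].get("tol", 0.02))
        params = replace(params, g=g)
        log.info("calibrated global coupling G = %.4f", g)

    protocol, lesion, stim = _build_protocol(cfg, conn)
    window = cfg["analysis"].get("window_s", 2.0)
    sigmas = list(cfg["sigmas"])
    seeds = list(cfg["seeds"])

    manifest = {
        "version": __version__,
        "template": cfg.get("template", "custom"),
        "model": cfg["model"],
        "params": asdict(params),
        "sim": cfg["sim"],
        "sigmas": sigmas,
        "seeds": seeds,
        "n_nodes": conn.n_nodes,
        "n_edge_pairs": conn.n_edge_pairs,
        "synthetic": cfg.get("synthetic"),
        "connectome": cfg.get("connectome"),
    }
    if lesion is not None:
        manifest["lesion"] = {
            "kind": lesion.kind,
            "provenance": lesion.provenance,
            "n_nodes": lesion.n_nodes,
            "nodes": list(lesion.node_set),
            "connection_fraction_count": lesion_connection_fraction(conn, lesion, "count"),
            "connection_fraction_weight": lesion_connection_fraction(conn, lesion, "weight"),
        }
    if stim is not None:
        manifest["stimulation"] = {
            "nodes": list(stim.node_set),
            "amplitude_nA": stim.amplitude,
            "window_s": [stim.t_on, stim.t_off],
        }

    rows = []
    for sigma in sigmas:
        for seed in seeds:
            p = replace(params, sigma=float(sigma))
            sim_cfg = _sim_config(cfg, int(seed))
            log.info("simulating sigma=%.3g seed=%d (%.0f s)", sigma, seed,
                     sim_cfg.duration)
            series = simulate_meanfield(conn, p, sim_cfg, protocol=protocol or None)
            t_end = series.times[-1]
            t_lo = max(series.times[0], t_end - window)
            summary = mean_firing(series, window=(t_lo, t_end))
            tag = f"sigma{sigma:g}_seed{seed}"
            summary.to_frame(conn).to_csv(out / f"summary_{tag}.csv", index=False)
            row = {"sigma": float(sigma), "seed": int(seed),
                   "total_rate_hz": summary.total}

            if protocol:
                baseline = simulate_meanfield(conn, p, sim_cfg)
                base_summary = mean_firing(baseline, window=(t_lo, t_end))
                d = delta_fr(base_summary, summary)
                pd.DataFrame({
                    "node_id": conn.node_ids,
                    "region": conn.region_labels,
                    "delta_fr_hz": d,
                }).to_csv(out / f"delta_fr_{tag}.csv", index=False)
                row["total_delta_hz"] = base_summary.total - summary.total
                if stim is not None:
                    pre = mean_firing(series, window=(max(series.times[0], stim.t_off - window), stim.t_off))
                    post = mean_firing(series, window=(stim.t_off, min(t_end, stim.t_off + window)))
                    pd.DataFrame({
                        "node_id": conn.node_ids,
                        "region": conn.region_labels,
                        "delta_fr_hz": delta_fr(post, pre),
                    }).to_csv(out / f"stim_delta_fr_{tag}.csv", index=False)
                    row["return_to_baseline_ms"] = return_to_baseline(
                        series, stim.t_off, base_summary
                    )
            rows.append(row)

    scan = pd.DataFrame(rows)
    scan.to_csv(out / "scan.csv", index=False)
    manifest["totals"] = rows
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
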