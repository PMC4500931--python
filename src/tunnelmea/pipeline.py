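"""End-to-end orchestration: simulate -> detect -> bursts -> propagation -> connectivity.

A pipeline run is driven by a YAML configuration and writes a result bundle
(CSV tables, JSON summaries, graph exports) plus a manifest recording the
seed, a configuration hash, package versions, and the content hash of every
output, so identical configurations produce hash-identical bundles.  Stage
timings and exclusions go to a separate log file to keep the manifest
deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bursts import detect_network_bursts
from .connectivity import cgc_matrix, connection_summaries, export_graph, smooth_trains

from .io import (
    read_spikes_h5, write_bursts_csv, write_spikes_h5, write_trials_csv,
)
from .layout import REGION_A, REGION_B
from .preprocessing import detect_spikes, remove_stimulus_artifact
from .propagation import analyze_trials, summarize_propagation
from .synthetic import SimConfig, simulate_session

__all__ = ["run_pipeline", "build_sim_config"]

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)
               if f.name not in ("success_curve", "delay_calibration")}


def build_sim_config(section: dict) -> SimConfig:
    unknown = set(section) - _SIM_FIELDS
    if unknown:
        raise ValueError(f"unknown simulate options: {sorted(unknown)}")
    if "axonal_delay_range" in section:
        section = dict(section)
        section["axonal_delay_range"] = tuple(section["axonal_delay_range"])
    return SimConfig(**section)


def _validate(cfg: dict) -> dict:
    known = {"seed", "simulate", "detection", "bursts", "propagation",
             "connectivity", "out_dir", "input_spikes"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown configuration sections: {sorted(unknown)}")
    if "simulate" not in cfg and "input_spikes" not in cfg:
        raise ValueError("configuration needs either 'simulate' or 'input_spikes'")
    for sec in ("simulate", "detection", "bursts", "propagation", "connectivity"):
        if sec in cfg and not isinstance(cfg[sec], dict):
            raise ValueError(f"section {sec!r} must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o).__name__)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; return the manifest dictionary.

    Any stage failure aborts with the stage name attached; outputs of
    completed stages are retained.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _validate(dict(config))
    out = Path(out_dir or cfg.get("out_dir", "tunnelmea_results"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    log: list[str] = []
    outputs: dict[str, list[str]] = {}
    stage = "setup"

    def run_stage(name, fn):
        nonlocal stage
        stage = name
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            log.append(f"{name}: FAILED: {exc}")
            (out / "pipeline.log").write_text("\n".join(log) + "\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.append(f"{name}: ok in {time.perf_counter() - t0:.2f} s")
        return result

    # --- simulate / load -------------------------------------------------
    if "simulate" in cfg:
        sim_cfg = build_sim_config({**cfg["simulate"], "seed": seed})

        def _simulate():
            spikes, stim, truth = simulate_session(sim_cfg)
            write_spikes_h5(spikes, out / "spikes.h5", stim)
            (out / "ground_truth.json").write_text(json.dumps({
                "n_axons": truth.n_axons,
                "source_well": truth.source_well,
                "n_transmitted": truth.n_transmitted,
                "stimuli": [dataclasses.asdict(s) for s in truth.stimuli],
            }, default=_json_default))
            outputs["simulate"] = ["spikes.h5", "ground_truth.json"]
            return spikes, stim

        spikes, stim = run_stage("simulate", _simulate)
    else:
        spikes, stim = run_stage(
            "load", lambda: read_spikes_h5(cfg["input_spikes"]))
        if stim is None:
            raise ValueError("input spike file carries no stimulus log")

    # --- optional raw-trace detection -----------------------------------
    if "detection" in cfg and cfg["detection"].get("raw_file"):
        det = cfg["detection"]

        def _detect():
            from .io import read_raw_h5
            rec = read_raw_h5(det["raw_file"])
            rec = remove_stimulus_artifact(rec, stim,
                                           blank_ms=det.get("blank_ms", 5.0),
                                           fit_window_ms=det.get("fit_window_ms", 20.0),
                                           max_degree=det.get("max_degree", 3))
            sd = detect_spikes(rec, k=det.get("k", 5.0),
                               dead_time_ms=det.get("dead_time_ms", 1.0))
            write_spikes_h5(sd, out / "detected_spikes.h5", stim)
            outputs["detect"] = ["detected_spikes.h5"]
            return sd

        spikes = run_stage("detect", _detect)

    # --- bursts ----------------------------------------------------------
    bcfg = cfg.get("bursts", {})

    def _bursts():
        events = {
            region: detect_network_bursts(
                spikes, region,
                frac=bcfg.get("isi_fraction", 0.25),
                min_spikes=bcfg.get("min_spikes", 4),
                min_duration=bcfg.get("min_duration_ms", 10.0) / 1e3)
            for region in (REGION_A, REGION_B)
        }
        write_bursts_csv(events, out / "bursts.csv")
        outputs["bursts"] = ["bursts.csv"]
        return events

    bursts = run_stage("bursts", _bursts)

    # --- propagation -----------------------------------------------------
    pcfg = cfg.get("propagation", {})

    def _propagation():
        trials = analyze_trials(
            spikes, stim,
            window=pcfg.get("window_ms", 500.0) / 1e3,
            bin_s=pcfg.get("bin_ms", 5.0) / 1e3,
            blank=pcfg.get("blank_ms", 5.0) / 1e3,
            thresholds=tuple(pcfg.get("thresholds", (0.1, 0.2, 0.5))),
            min_electrodes=pcfg.get("min_electrodes", 4),
            bursts_a=bursts[REGION_A], bursts_b=bursts[REGION_B])
        summary = summarize_propagation(trials)
        write_trials_csv(trials, out / "trials.csv")
        (out / "propagation.json").write_text(json.dumps(
            dataclasses.asdict(summary), default=_json_default, indent=1))
        outputs["propagation"] = ["trials.csv", "propagation.json"]
        return summary

    run_stage("propagation", _propagation)

    # --- connectivity ----------------------------------------------------
    ccfg = cfg.get("connectivity", {})
    if ccfg.get("enabled", True):
        def _connectivity():
            X = smooth_trains(
                spikes, stim,
                window=ccfg.get("window_ms", 500.0) / 1e3,
                bin_s=ccfg.get("bin_ms", 1.0) / 1e3,
                tau=ccfg.get("tau_ms", 4.0) / 1e3,
                min_rate_hz=ccfg.get("min_rate_hz", 0.5))
            res = cgc_matrix(X, p=ccfg.get("order", 10))
            res.significant(ccfg.get("fdr_q", 0.001))
            import pandas as pd
            pd.DataFrame(res.gc, index=res.channels,
                         columns=res.channels).to_csv(out / "cgc_matrix.csv")
            pd.DataFrame(res.pvals, index=res.channels,
                         columns=res.channels).to_csv(out / "cgc_pvals.csv")
            summ = connection_summaries(res, spikes.layout,
                                        denominator=ccfg.get("denominator", "well_a"))
            (out / "connectivity.json").write_text(json.dumps(
                summ, default=_json_default, indent=1))
            export_graph(res, spikes.layout, str(out / "connectivity"))
            outputs["connectivity"] = [
                "cgc_matrix.csv", "cgc_pvals.csv", "connectivity.json",
                "connectivity.gexf", "connectivity.graphml"]
            return summ

        run_stage("connectivity", _connectivity)

    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()
    manifest = {
        "package": "tunnelmea",
        "version": __version__,
        "numpy": np.__version__,
        "seed": seed,
        "config_sha256": cfg_hash,
        "stages": {name: {f: _sha256(out / f) for f in files}
                   for name, files in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
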