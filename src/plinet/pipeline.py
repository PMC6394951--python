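"""End-to-end pipeline driver over plain-text artifacts.

Stages (in dependency order): ``simulate`` -> ``preprocess`` ->
``inverse`` -> ``connectivity`` -> ``nbs``; ``behavior`` (from the
simulated event logs) and ``correlate`` (network strength vs. behavioral
variables) close the chain.  Every stage reads its inputs from the output
directory and writes text artifacts back to it, so stages can be toggled
individually; a missing upstream artifact raises
:class:`PipelineDependencyError` naming the stage that should have
produced it.  Re-running with an identical config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeding import derive_rng
from . import behavior as bh
from .connectivity import connectivity_matrices
from .corr import CorrFamily, network_strength, perm_corr_fwe
from .epochs import EpochSet
from .inverse import LeadField, minimum_norm_operator, roi_timeseries
from .io import (read_connmatrix, read_epochset, roi_table, write_connmatrix,
                 write_epochset, write_network_files, write_network_result)
from .netstats import (ContrastSpec, nbs_contrast, network_effect_size,
                       node_degrees, split_by_direction)
from .preprocess import (FilterSpec, apply_fir, design_bandpass,
                         exclude_event_epochs, reject_artifacts,
                         segment_epochs)
from .synthdata import (SimConfig, mix_to_sensors, random_leadfield,
                        simulate_behavior, simulate_event_log,
                        simulate_sources)

__all__ = ["PipelineConfig", "PipelineDependencyError", "run_pipeline",
           "run_stage", "STAGES", "demo_config"]

STAGES = ("simulate", "preprocess", "inverse", "connectivity", "nbs",
          "behavior", "correlate")


class PipelineDependencyError(RuntimeError):
    """A stage's required upstream artifact is missing."""


@dataclass
class PipelineConfig:
    """Everything the seven stages need, with one global seed."""

    sim: SimConfig = field(default_factory=SimConfig)
    stages: Mapping[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    n_sensors: int = 16
    inverse_lambda: float = 0.1
    filter_low: float = 0.5
    filter_high: float = 45.0
    filter_taps: int = 4530
    filter_beta: float = 5.65
    reject_threshold_uv: float = 100.0
    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"alpha": (8.0, 12.0)})
    contrast: tuple[str, str] = ("focused", "divided")
    contrast_spec: ContrastSpec = field(default_factory=ContrastSpec)
    corr_n_perm: int = 1000
    events_per_block: tuple[int, int, int] = (3, 3, 2)  # targets, distractors, irrelevant
    seed: int = 0
    log_level: str = "INFO"

    def subjects(self) -> list[str]:
        return [f"S{k:02d}" for k in range(self.sim.n_subjects)]


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small two-condition configuration with a planted 3-edge chain.

    Sized so the full seven-stage run finishes in seconds while still
    producing a recoverable attention-contrast network: 8 subjects, 8
    ROIs, 16 epochs of 2048 ms at 500 Hz, alpha-band coupling planted in
    the 'focused' condition only.
    """
    sim = SimConfig(
        n_subjects=8, n_rois=8, conditions=("focused", "divided"),
        epochs_per_condition=16, epoch_ms=2048.0, fs=500.0,
        bands=((8.0, 12.0),),
        planted_edges={"focused": {0: [(0, 1, np.pi / 4, 8.0),
                                       (1, 2, np.pi / 4, 8.0),
                                       (2, 3, np.pi / 4, 8.0)]}},
        noise_sd=0.3, behavior_r=0.6, seed=seed,
    )
    return PipelineConfig(
        sim=sim,
        contrast_spec=ContrastSpec(n_perm=256, permutations="exact", seed=seed),
        corr_n_perm=1000,
        seed=seed,
    )


# -- helpers ---------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _need(path: Path, stage: str, upstream: str) -> Path:
    if not path.exists():
        raise PipelineDependencyError(
            f"stage {stage!r} requires {path.name!r} produced by stage "
            f"{upstream!r}; enable it or provide the artifact")
    return path


def _write_leadfield(lf: LeadField, stem: Path) -> None:
    np.savetxt(stem.with_suffix(".tsv"), lf.gain, fmt="%.15g", delimiter="\t")
    stem.with_suffix(".json").write_text(json.dumps(
        {"voxel_roi_map": list(lf.voxel_roi_map),
         "roi_labels": list(lf.roi_labels)}, indent=1, sort_keys=True))


def _read_leadfield(stem: Path) -> LeadField:
    meta = json.loads(stem.with_suffix(".json").read_text())
    gain = np.loadtxt(stem.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    return LeadField(gain=gain, voxel_roi_map=meta["voxel_roi_map"],
                     roi_labels=meta["roi_labels"])


# -- stages ----------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    d = out / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    lf = random_leadfield(cfg.n_sensors, cfg.sim.n_rois, seed=cfg.seed)
    _write_leadfield(lf, d / "leadfield")
    written = [d / "leadfield.tsv", d / "leadfield.json"]
    duration_ms = cfg.sim.epochs_per_condition * cfg.sim.epoch_ms
    nt, nd, ni = cfg.events_per_block
    for subj in cfg.subjects():
        for cond in cfg.sim.conditions:
            src = simulate_sources(cfg.sim, subj, cond)
            sens = mix_to_sensors(src, lf)
            cont = np.concatenate(list(sens.data), axis=1)  # channels x total
            p = d / f"sensor_{subj}_{cond}.tsv"
            np.savetxt(p, cont, fmt="%.15g", delimiter="\t")
            p.with_suffix(".tsv.json").write_text(json.dumps(
                {"fs": sens.fs, "labels": sens.labels, "subject": subj,
                 "condition": cond}, indent=1, sort_keys=True))
            log = simulate_event_log(
                duration_ms, seed=cfg.seed, n_targets=nt, n_distractors=nd,
                n_irrelevant=ni, subject=subj, condition=cond)
            lp = d / f"events_{subj}_{cond}.tsv"
            bh.write_event_log(log, lp)
            written += [p, Path(str(p) + ".json"), lp]
    return written


def _stage_preprocess(cfg: PipelineConfig, out: Path) -> list[Path]:
    d = out / "preprocess"
    d.mkdir(parents=True, exist_ok=True)
    spec = FilterSpec(low=cfg.filter_low, high=cfg.filter_high,
                      taps=cfg.filter_taps, kaiser_beta=cfg.filter_beta,
                      fs=cfg.sim.fs)
    coeffs = design_bandpass(spec)
    written = []
    for subj in cfg.subjects():
        for cond in cfg.sim.conditions:
            p = _need(out / "simulate" / f"sensor_{subj}_{cond}.tsv",
                      "preprocess", "simulate")
            meta = json.loads(Path(str(p) + ".json").read_text())
            cont = np.loadtxt(p, delimiter="\t", ndmin=2)
            filtered = apply_fir(cont, coeffs)
            epochs = segment_epochs(filtered, meta["fs"], cfg.sim.epoch_ms,
                                    labels=meta["labels"], subject=subj,
                                    condition=cond)
            log = bh.read_event_log(
                _need(out / "simulate" / f"events_{subj}_{cond}.tsv",
                      "preprocess", "simulate"))
            # drop epochs containing detection targets or button presses
            epochs, _ = exclude_event_epochs(
                epochs, log.onsets("target"), log.responses)
            epochs, _ = reject_artifacts(epochs, cfg.reject_threshold_uv)
            ep = d / f"epochs_{subj}_{cond}.tsv"
            write_epochset(epochs, ep)
            written += [ep, Path(str(ep) + ".json")]
    return written


def _stage_inverse(cfg: PipelineConfig, out: Path) -> list[Path]:
    d = out / "inverse"
    d.mkdir(parents=True, exist_ok=True)
    lf = _read_leadfield(_need(out / "simulate" / "leadfield.tsv",
                               "inverse", "simulate").with_suffix(""))
    op = minimum_norm_operator(lf, cfg.inverse_lambda)
    written = []
    for subj in cfg.subjects():
        for cond in cfg.sim.conditions:
            ep = read_epochset(_need(
                out / "preprocess" / f"epochs_{subj}_{cond}.tsv",
                "inverse", "preprocess"))
            roi = roi_timeseries(ep, op, lf.voxel_roi_map, lf.roi_labels)
            rp = d / f"roi_{subj}_{cond}.tsv"
            write_epochset(roi, rp)
            written += [rp, Path(str(rp) + ".json")]
    return written


def _stage_connectivity(cfg: PipelineConfig, out: Path) -> list[Path]:
    d = out / "connectivity"
    d.mkdir(parents=True, exist_ok=True)
    written = []
    for subj in cfg.subjects():
        for cond in cfg.sim.conditions:
            roi = read_epochset(_need(
                out / "inverse" / f"roi_{subj}_{cond}.tsv",
                "connectivity", "inverse"))
            for m in connectivity_matrices(roi, cfg.bands):
                mp = d / f"pli_{subj}_{cond}_{m.band}.tsv"
                write_connmatrix(m, mp)
                written += [mp, Path(str(mp) + ".json")]
    return written


def _load_band(cfg: PipelineConfig, out: Path, cond: str, band: str,
               stage: str) -> list:
    return [read_connmatrix(_need(
        out / "connectivity" / f"pli_{s}_{cond}_{band}.tsv", stage,
        "connectivity")) for s in cfg.subjects()]


def _stage_nbs(cfg: PipelineConfig, out: Path) -> list[Path]:
    d = out / "nbs"
    d.mkdir(parents=True, exist_ok=True)
    cond_a, cond_b = cfg.contrast
    rows = []
    written = []
    for band in cfg.bands:
        A = _load_band(cfg, out, cond_a, band, "nbs")
        B = _load_band(cfg, out, cond_b, band, "nbs")
        result = nbs_contrast(A, B, cfg.contrast_spec)
        rp = d / f"network_{band}.json"
        write_network_result(result, rp)
        written.append(rp)
        row = {"band": band, "threshold": result.threshold,
               "n_edges": result.n_edges, "n_nodes": result.n_nodes,
               "p_fwe": result.p_fwe}
        if result.edges:
            table = roi_table(cfg.sim.n_rois)
            table = table.assign(label=A[0].labels[: len(table)])
            node_p, edge_p = write_network_files(result, table,
                                                 d / f"network_{band}")
            written += [node_p, edge_p]
            up, down = split_by_direction(result)
            for name, sub in (("A>B", up), ("B>A", down)):
                if sub:
                    row[f"cohens_d[{name}]"] = network_effect_size(A, B, sub)
                    row[f"n_edges[{name}]"] = len(sub)
        rows.append(row)
    sp = d / "summary.tsv"
    pd.DataFrame(rows).to_csv(sp, sep="\t", index=False, float_format="%.6g")
    written.append(sp)
    return written


def _stage_behavior(cfg: PipelineConfig, out: Path) -> list[Path]:
    d = out / "behavior"
    d.mkdir(parents=True, exist_ok=True)
    logs = {}
    pooled_rts: list[float] = []
    for subj in cfg.subjects():
        for cond in cfg.sim.conditions:
            log = bh.read_event_log(_need(
                out / "simulate" / f"events_{subj}_{cond}.tsv",
                "behavior", "simulate"))
            logs[(subj, cond)] = log
            labeled = bh.match_responses(log)
            pooled_rts += list(labeled.loc[labeled["label"] == "hit", "rt_ms"])
    cutoffs = bh.trim_rts(pooled_rts)[1] if pooled_rts else None
    rows = []
    for (subj, cond), log in logs.items():
        idx = bh.detection_indices(log, rt_cutoffs=cutoffs)
        rows.append({"subject": subj, "condition": cond,
                     "d_prime": idx.d_prime, "mean_rt_ms": idx.mean_rt_ms,
                     "distractor_ratio": idx.distractor_ratio,
                     **idx.counts})
    p = d / "indices.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    return [p]


def _stage_correlate(cfg: PipelineConfig, out: Path) -> list[Path]:
    from .io import read_network_result  # local import keeps io surface tidy

    d = out / "correlate"
    d.mkdir(parents=True, exist_ok=True)
    cond_a = cfg.contrast[0]
    band = next(iter(cfg.bands))
    result = read_network_result(_need(out / "nbs" / f"network_{band}.json",
                                       "correlate", "nbs"))
    if result.edges:
        edges = [(e.i, e.j) for e in result.edges]
    else:
        planted = cfg.sim.edges_for(cond_a, 0)
        if not planted:
            raise PipelineDependencyError(
                "stage 'correlate' found neither a significant network nor "
                "planted edges to define a network strength")
        edges = [(e.roi_i, e.roi_j) for e in planted]
    strengths = np.array([
        network_strength(read_connmatrix(_need(
            out / "connectivity" / f"pli_{s}_{cond_a}_{band}.tsv",
            "correlate", "connectivity")), edges)
        for s in cfg.subjects()
    ])
    memory = simulate_behavior(strengths, cfg.sim.behavior_r,
                               seed=cfg.seed)
    beh = pd.read_csv(_need(out / "behavior" / "indices.tsv",
                            "correlate", "behavior"), sep="\t")
    beh = beh[beh["condition"] == cond_a].set_index("subject")
    beh = beh.loc[cfg.subjects()]
    variables = {"memory_score": memory,
                 "d_prime": beh["d_prime"].to_numpy(),
                 "mean_rt_ms": beh["mean_rt_ms"].to_numpy(),
                 "distractor_ratio": beh["distractor_ratio"].to_numpy()}
    variables = {k: v for k, v in variables.items()
                 if np.all(np.isfinite(v)) and np.std(v) > 0}
    family = CorrFamily(strengths=strengths, variables=variables,
                        n_perm=cfg.corr_n_perm, seed=cfg.seed)
    res = perm_corr_fwe(family)
    rows = [{"network": f"{band}:{cfg.contrast[0]}>{cfg.contrast[1]}",
             "variable": k, "r": r, "p_fwe": p, "n_perm": cfg.corr_n_perm,
             "seed": cfg.seed} for k, (r, p) in res.items()]
    p = d / "correlations.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    return [p]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "inverse": _stage_inverse,
    "connectivity": _stage_connectivity,
    "nbs": _stage_nbs,
    "behavior": _stage_behavior,
    "correlate": _stage_correlate,
}


def run_stage(config: PipelineConfig, stage: str, out_dir) -> list[Path]:
    """Execute a single named stage against an output directory.

    Upstream artifacts must already exist there (see
    :class:`PipelineDependencyError`).  Returns the files written.
    """
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return _STAGE_FUNCS[stage](config, out)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the run manifest (also written to ``manifest.json``):
    per-stage parameters, the global seed, and SHA-256 hashes of every
    written artifact.  Identical configs produce byte-identical artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}
    params = {
        "simulate": {"sim": _cfg_dict(config.sim),
                     "n_sensors": config.n_sensors,
                     "events_per_block": list(config.events_per_block)},
        "preprocess": {"low": config.filter_low, "high": config.filter_high,
                       "taps": config.filter_taps, "beta": config.filter_beta,
                       "reject_threshold_uv": config.reject_threshold_uv},
        "inverse": {"lambda": config.inverse_lambda},
        "connectivity": {"bands": {k: list(v) for k, v in config.bands.items()}},
        "nbs": {"contrast": list(config.contrast),
                **_cfg_dict(config.contrast_spec)},
        "behavior": {},
        "correlate": {"n_perm": config.corr_n_perm,
                      "behavior_r": config.sim.behavior_r},
    }
    for stage in STAGES:
        if not config.stages.get(stage, True):
            continue
        outputs = _STAGE_FUNCS[stage](config, out)
        manifest["stages"].append({
            "name": stage,
            "params": params[stage],
            "seed": config.seed,
            "outputs": {str(p.relative_to(out)): _sha256(p)
                        for p in sorted(set(outputs))},
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def _cfg_dict(obj) -> dict:
    d = asdict(obj) if hasattr(obj, "__dataclass_fields__") else dict(obj)

    def conv(v):
        if isinstance(v, dict):
            return {str(k): conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if isinstance(v, (np.integer, np.floating)):
            return float(v)
        return v

    return conv(d)
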