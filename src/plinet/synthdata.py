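"""Synthetic phase-coupled oscillator data with planted connectivity.

The generator emulates the statistical structure the analysis pipeline
assumes: per-band narrowband ROI oscillations, condition-specific
phase-coupled edge sets with a constant nonzero lag, zero-lag linear
sensor mixing (a volume-conduction surrogate), and per-subject behavioral
scores linearly related to network strength.

Coupling model
--------------
Within a band, every non-follower ROI oscillates at a frequency drawn
uniformly inside the band (fresh per epoch) with a uniform initial phase.
A planted edge ``(i, j, lag_rad, kappa)`` makes ROI ``j`` follow ROI ``i``:
``phi_j(t) = phi_i(t) + lag_rad + eps(t)`` where ``eps`` is a
zero-order-hold process of i.i.d. von Mises(0, kappa) draws refreshed every
``jitter_ms`` milliseconds.  The hold preserves the von Mises marginal
exactly, so the expected phase lag index of a planted edge has the closed
form ``|E sign(sin(lag + eps))|``, while keeping the jitter slow relative
to the carrier so the signal stays narrowband.  ``kappa -> inf`` gives a
constant phase difference (PLI -> 1); ``kappa = 0`` gives a uniform phase
difference (PLI -> 0 up to sampling error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from ._seeding import derive_rng
from .epochs import EpochSet
from .inverse import LeadField

__all__ = [
    "PlantedEdge",
    "SimConfig",
    "simulate_sources",
    "mix_to_sensors",
    "simulate_behavior",
    "random_leadfield",
    "simulate_event_log",
    "load_sim_config",
    "save_sim_config",
]


@dataclass(frozen=True)
class PlantedEdge:
    """Directed phase-coupling: ``roi_j`` follows ``roi_i`` at a fixed lag."""

    roi_i: int
    roi_j: int
    lag_rad: float
    kappa: float


@dataclass
class SimConfig:
    """Study-condition parameters for the oscillator simulation.

    Defaults mirror the recording setup the pipeline targets: 25 subjects,
    95 artifact-free epochs of 2048 ms per condition at 1 kHz.
    """

    n_subjects: int = 25
    n_rois: int = 44
    conditions: Sequence[str] = ("focused", "divided")
    epochs_per_condition: int = 95
    epoch_ms: float = 2048.0
    fs: float = 1000.0
    bands: Sequence[tuple[float, float]] = ((8.0, 12.0),)
    # planted_edges[condition][band_index] -> list of (i, j, lag_rad, kappa)
    planted_edges: Mapping[str, Mapping[int, Sequence[tuple]]] = field(
        default_factory=dict
    )
    noise_sd: float = 0.3
    behavior_r: float = 0.5
    jitter_ms: float = 64.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError("need at least 2 ROIs")
        if self.epochs_per_condition < 1 or self.n_subjects < 1:
            raise ValueError("counts must be positive")
        nyq = self.fs / 2.0
        for lo, hi in self.bands:
            if not (0.0 < lo < hi < nyq):
                raise ValueError(f"band ({lo}, {hi}) must satisfy 0 < low < high < fs/2")
        if abs(self.behavior_r) > 1.0:
            raise ValueError("|behavior_r| must be <= 1")
        if self.noise_sd < 0 or self.jitter_ms <= 0:
            raise ValueError("noise_sd >= 0 and jitter_ms > 0 required")
        for cond, per_band in self.planted_edges.items():
            if cond not in self.conditions:
                raise ValueError(f"planted edges reference unknown condition {cond!r}")
            for b, edges in per_band.items():
                if not 0 <= int(b) < len(self.bands):
                    raise ValueError(f"planted edges reference unknown band index {b}")
                for e in edges:
                    e = PlantedEdge(*e) if not isinstance(e, PlantedEdge) else e
                    if e.kappa < 0:
                        raise ValueError("kappa must be >= 0")
                    ok = (0 <= e.roi_i < self.n_rois and 0 <= e.roi_j < self.n_rois
                          and e.roi_i != e.roi_j)
                    if not ok:
                        raise ValueError(f"invalid planted edge ROI indices {e}")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_ms * self.fs / 1000.0))

    def edges_for(self, condition: str, band_index: int) -> list[PlantedEdge]:
        per_band = self.planted_edges.get(condition, {})
        return [PlantedEdge(*e) if not isinstance(e, PlantedEdge) else e
                for e in per_band.get(band_index, [])]


def _zoh_jitter(rng: np.random.Generator, kappa: float, n_samples: int,
                hold: int) -> np.ndarray:
    """Piecewise-constant von Mises jitter, one draw per ``hold`` samples."""
    n_draws = -(-n_samples // hold)  # ceil
    draws = rng.vonmises(0.0, kappa, size=n_draws)
    return np.repeat(draws, hold)[:n_samples]


def simulate_sources(config: SimConfig, subject: object, condition: str) -> EpochSet:
    """Simulate ROI-level oscillatory epochs for one subject/condition.

    Deterministic given ``(config.seed, subject, condition)``; streams are
    derived per (subject, condition, band) so extending the subject list
    does not reshuffle existing subjects.
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    n_samp = config.n_samples
    t = np.arange(n_samp) / config.fs
    hold = max(1, int(round(config.jitter_ms * config.fs / 1000.0)))
    data = np.zeros((config.epochs_per_condition, config.n_rois, n_samp))

    for b, (lo, hi) in enumerate(config.bands):
        rng = derive_rng(config.seed, "sources", subject, condition, b)
        edges = config.edges_for(condition, b)
        followers = {e.roi_j: e for e in edges}  # last edge targeting a ROI wins
        margin = 0.125 * (hi - lo)
        for e_idx in range(config.epochs_per_condition):
            phases = np.empty((config.n_rois, n_samp))
            # independent carriers first (drivers may themselves be followers
            # of earlier ROIs only in acyclic configs; evaluate followers in
            # index-sorted passes until stable for simple chains)
            for r in range(config.n_rois):
                if r in followers:
                    continue
                f_r = rng.uniform(lo + margin, hi - margin)
                phi0 = rng.uniform(-np.pi, np.pi)
                phases[r] = 2.0 * np.pi * f_r * t + phi0
            # follower phases; iterate so chains (a->b->c) resolve
            pending = dict(followers)
            for _ in range(config.n_rois):
                if not pending:
                    break
                progressed = False
                for j in sorted(pending):
                    e = pending[j]
                    if e.roi_i in pending:
                        continue  # driver itself not yet resolved
                    jit = _zoh_jitter(rng, e.kappa, n_samp, hold)
                    phases[j] = phases[e.roi_i] + e.lag_rad + jit
                    del pending[j]
                    progressed = True
                if not progressed:  # cycle: break it at the smallest index
                    j = min(pending)
                    e = pending.pop(j)
                    f_r = rng.uniform(lo + margin, hi - margin)
                    phi0 = rng.uniform(-np.pi, np.pi)
                    phases[j] = 2.0 * np.pi * f_r * t + phi0
            data[e_idx] += np.cos(phases)

    if config.noise_sd > 0:
        noise_rng = derive_rng(config.seed, "noise", subject, condition)
        data += noise_rng.normal(0.0, config.noise_sd, size=data.shape)

    labels = [f"ROI{r:02d}" for r in range(config.n_rois)]
    return EpochSet(data=data, fs=config.fs, labels=labels,
                    subject=str(subject), condition=condition,
                    meta={"space": "source"})


def mix_to_sensors(sources: EpochSet, leadfield: LeadField) -> EpochSet:
    """Instantaneous (zero-lag) linear mixture of source epochs.

    With one voxel per source ROI this is ``gain @ sources`` sample by
    sample; no time shifts are introduced, so any coupling it creates
    between sensors is strictly zero-lag and invisible to the PLI.
    """
    if leadfield.n_voxels != sources.n_channels:
        raise ValueError(
            f"lead field has {leadfield.n_voxels} voxel columns, "
            f"sources have {sources.n_channels} channels"
        )
    mixed = np.tensordot(sources.data, leadfield.gain, axes=([1], [1]))
    mixed = np.moveaxis(mixed, -1, 1)
    labels = [f"S{k:02d}" for k in range(leadfield.n_sensors)]
    return EpochSet(data=mixed, fs=sources.fs, labels=labels,
                    subject=sources.subject, condition=sources.condition,
                    meta={**sources.meta, "space": "sensor"})


def simulate_behavior(strengths: np.ndarray, r_target: float, sd: float = 1.0,
                      seed: int = 0) -> np.ndarray:
    """Per-subject behavioral scores with population correlation ``r_target``.

    scores = r * z(strengths) + sqrt(1 - r^2) * noise, with unit-variance
    Gaussian noise scaled by ``sd`` applied to both terms jointly so the
    population Pearson correlation with the strengths equals ``r_target``.
    """
    strengths = np.asarray(strengths, dtype=float)
    if strengths.size < 3:
        raise ValueError("need at least 3 subjects")
    if not -1.0 <= r_target <= 1.0:
        raise ValueError("|r_target| must be <= 1")
    s = strengths.std()
    if s == 0:
        raise ValueError("constant network strengths: correlation undefined")
    z = (strengths - strengths.mean()) / s
    rng = derive_rng(seed, "behavior")
    noise = rng.standard_normal(strengths.size)
    return sd * (r_target * z + np.sqrt(1.0 - r_target**2) * noise)


def random_leadfield(n_sensors: int, n_rois: int, seed: int = 0,
                     voxels_per_roi: int = 1) -> LeadField:
    """Random dense gain matrix; voxels assigned round-robin to ROI labels."""
    rng = derive_rng(seed, "leadfield")
    n_vox = n_rois * voxels_per_roi
    gain = rng.normal(0.0, 1.0, size=(n_sensors, n_vox))
    roi_labels = [f"ROI{r:02d}" for r in range(n_rois)]
    vmap = [roi_labels[v // voxels_per_roi] for v in range(n_vox)]
    return LeadField(gain=gain, voxel_roi_map=vmap, roi_labels=roi_labels)


def simulate_event_log(duration_ms: float, seed: int = 0, *,
                       n_targets: int = 20, n_distractors: int = 20,
                       n_irrelevant: int = 10, hit_rate: float = 0.85,
                       fa_rate: float = 0.1, rt_mean_ms: float = 900.0,
                       rt_sd_ms: float = 250.0, subject: str = "",
                       condition: str = ""):
    """Simple simulated detection-task log (events + button presses).

    Targets are responded to with probability ``hit_rate`` and distractors
    with ``fa_rate``; response times are Gaussian, truncated at 50 ms.
    Returns an :class:`plinet.behavior.EventLog`.
    """
    from .behavior import EventLog  # deferred to avoid a cycle

    rng = derive_rng(seed, "events", subject, condition)
    n_ev = n_targets + n_distractors + n_irrelevant
    onsets = np.sort(rng.uniform(0.0, duration_ms, size=n_ev))
    types = np.array(["target"] * n_targets + ["distractor"] * n_distractors
                     + ["irrelevant"] * n_irrelevant)
    rng.shuffle(types)
    streams = np.where(types == "target", "attended", "concurrent")
    responses = []
    for onset, ev in zip(onsets, types):
        p = hit_rate if ev == "target" else (fa_rate if ev == "distractor" else 0.0)
        if rng.uniform() < p:
            rt = max(50.0, rng.normal(rt_mean_ms, rt_sd_ms))
            responses.append(onset + rt)
    return EventLog(
        events=[(ev, st, float(on)) for ev, st, on in zip(types, streams, onsets)],
        responses=sorted(float(r) for r in responses),
        subject=subject, condition=condition,
    )


# -- flat YAML config round-trip ------------------------------------------

def save_sim_config(config: SimConfig, path) -> None:
    d = {
        "n_subjects": config.n_subjects,
        "n_rois": config.n_rois,
        "conditions": list(config.conditions),
        "epochs_per_condition": config.epochs_per_condition,
        "epoch_ms": config.epoch_ms,
        "fs": config.fs,
        "bands": [list(b) for b in config.bands],
        "planted_edges": {
            cond: {int(b): [list(PlantedEdge(*e).__dict__.values())
                            if not isinstance(e, PlantedEdge)
                            else [e.roi_i, e.roi_j, e.lag_rad, e.kappa]
                            for e in edges]
                   for b, edges in per_band.items()}
            for cond, per_band in config.planted_edges.items()
        },
        "noise_sd": config.noise_sd,
        "behavior_r": config.behavior_r,
        "jitter_ms": config.jitter_ms,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["conditions"] = tuple(d.get("conditions", ()))
    d["bands"] = tuple(tuple(b) for b in d.get("bands", ()))
    d["planted_edges"] = {
        cond: {int(b): [tuple(e) for e in edges] for b, edges in per_band.items()}
        for cond, per_band in d.get("planted_edges", {}).items()
    }
    return SimConfig(**d)
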