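"""Simulate the study's recordings: coupled oscillator sources, zero-lag
sensor mixtures, and detection-task event logs for every subject and
condition."""

from common import OUT, config
from plinet.pipeline import run_stage

cfg = config()
files = run_stage(cfg, "simulate", OUT)
print(f"simulated {cfg.sim.n_subjects} subjects x "
      f"{len(cfg.sim.conditions)} conditions "
      f"({cfg.sim.epochs_per_condition} epochs of {cfg.sim.epoch_ms:.0f} ms, "
      f"{cfg.n_sensors} sensors, fs = {cfg.sim.fs:.0f} Hz)")
print(f"planted alpha-band edges (focused only): "
      f"{[(e[0], e[1]) for e in cfg.sim.planted_edges['focused'][0]]}")
print(f"wrote {len(files)} files under {OUT/'simulate'}")
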