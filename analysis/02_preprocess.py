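"""Band-pass the continuous sensor recordings (0.5-45 Hz Kaiser FIR),
tile them into 2048 ms epochs, and drop epochs containing detection
targets, button presses, or >100 uV amplitude changes."""

import json

from common import OUT, config
from plinet.pipeline import run_stage

cfg = config()
files = run_stage(cfg, "preprocess", OUT)
kept = []
for p in sorted((OUT / "preprocess").glob("epochs_*.tsv.json")):
    kept.append(json.loads(p.read_text())["shape"][0])
print(f"filtered {cfg.filter_low}-{cfg.filter_high} Hz "
      f"(Kaiser beta {cfg.filter_beta}, {cfg.filter_taps} taps)")
print(f"epochs retained per subject/condition: min {min(kept)}, "
      f"max {max(kept)} of {cfg.sim.epochs_per_condition}")
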