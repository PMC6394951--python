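"""Compute band-limited phase lag index adjacency matrices per subject,
condition, and band."""

import numpy as np

from common import OUT, config
from plinet.io import read_connmatrix
from plinet.pipeline import run_stage

cfg = config()
run_stage(cfg, "connectivity", OUT)
band = next(iter(cfg.bands))
planted = [(e[0], e[1]) for e in cfg.sim.planted_edges["focused"][0]]
for cond in cfg.sim.conditions:
    vals = []
    for s in cfg.subjects():
        m = read_connmatrix(OUT / "connectivity" / f"pli_{s}_{cond}_{band}.tsv")
        vals.append(np.mean([m.values[i, j] for i, j in planted]))
    print(f"{cond}: mean PLI over planted edges = {np.mean(vals):.3f}")
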