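"""NBS contrast of focused vs. divided attention: edge-wise paired F
tests, supra-threshold components, and the permutation FWE p value."""

from common import OUT, config
from plinet.io import read_network_result
from plinet.pipeline import run_stage

cfg = config()
run_stage(cfg, "nbs", OUT)
for band in cfg.bands:
    res = read_network_result(OUT / "nbs" / f"network_{band}.json")
    if res.edges:
        print(f"{band}: network of {res.n_edges} edges / {res.n_nodes} nodes "
              f"at F >= {res.threshold:.1f}, p_fwe = {res.p_fwe:.4f}")
        print(f"  edges: {[(e.i, e.j) for e in res.edges]}")
    else:
        print(f"{band}: no significant network (p_fwe = {res.p_fwe:.3f})")
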