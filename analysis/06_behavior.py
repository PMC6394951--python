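"""Score the simulated detection-task logs: hits within the 0-5000 ms
windows, pooled 5/95% RT trimming, d', and the distractor ratio."""

import pandas as pd

from common import OUT, config
from plinet.pipeline import run_stage

cfg = config()
run_stage(cfg, "behavior", OUT)
df = pd.read_csv(OUT / "behavior" / "indices.tsv", sep="\t")
print(df.groupby("condition")[["d_prime", "mean_rt_ms"]]
        .mean().round(3).to_string())
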