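"""Project the sensor epochs back to source space with the standardized
minimum-norm operator and average voxels into ROI time series."""

from common import OUT, config
from plinet.pipeline import run_stage

cfg = config()
files = run_stage(cfg, "inverse", OUT)
print(f"sLORETA-style inverse (relative lambda = {cfg.inverse_lambda}) "
      f"applied; wrote {len(files)} ROI epoch files under {OUT/'inverse'}")
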