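"""Shared configuration for the numbered analysis drivers.

All drivers operate on the same seeded study configuration and write
into ``results/pipeline``; run them in order (01 -> 07).  The setup is a
scaled-down version of the full recording design: 8 subjects, 8 cortical
ROIs, 16 epochs of 2048 ms per condition at 500 Hz, with a 3-edge
alpha-band coupling chain planted in the focused-attention condition.
"""

from pathlib import Path

from plinet.pipeline import demo_config

SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def config():
    return demo_config(seed=SEED)
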