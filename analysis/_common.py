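"""Shared location and seed for the numbered analysis drivers."""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run"
SEED = 2026
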