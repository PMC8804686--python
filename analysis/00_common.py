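"""Shared run configuration for the numbered analysis drivers.

Every driver operates on the same run directory (``results/run``) so the
steps can be executed in order; the seed is fixed here so the whole
analysis is reproducible end to end.
"""

from pathlib import Path

from iraeab.config import AnalysisConfig, CohortConfig

SEED = 1
RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"

def configs():
    return CohortConfig(seed=SEED), AnalysisConfig()
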