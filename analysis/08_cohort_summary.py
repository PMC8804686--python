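"""Produce the cohort-characteristics summary table."""

import runpy
import warnings
from pathlib import Path

common = runpy.run_path(Path(__file__).parent / "00_common.py")

from iraeab.pipeline import stage_summary

_, analysis_cfg = common["configs"]()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table = stage_summary(common["RUN_DIR"], analysis_cfg)

print(table.to_string(index=False))
print(f"\nwritten to {common['RUN_DIR'] / 'cohort_summary.tsv'}")
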