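"""Differential autoantibody abundance between clinical groups.

Per-antigen Mann-Whitney tests with BH adjustment for each organ-specific,
timing and severity grouping at baseline, both isotypes; writes the DE
table and volcano tables with per-side significant counts.
"""

import runpy
import warnings
from pathlib import Path

common = runpy.run_path(Path(__file__).parent / "00_common.py")

from iraeab.pipeline import stage_de

_, analysis_cfg = common["configs"]()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    de = stage_de(common["RUN_DIR"], analysis_cfg)

sig = de[de["significant"]]
print(f"{len(de)} antigen x grouping tests; {len(sig)} significant at adjusted p < {analysis_cfg.alpha}")
if not sig.empty:
    by = sig.groupby(["isotype", "grouping"]).size()
    print(by.to_string())
    lower_in_event = (sig["log2fc"] < 0).mean()
    print(f"fraction of significant antigens LOWER in the event group: {lower_in_event:.2f}")
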