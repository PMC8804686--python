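"""Baseline-to-week-6 fold changes vs irAE burden.

Computes per-patient fold-change matrices over the DE antigens, tests the
association between mean |FC| and the number of distinct organ systems
with irAE, and writes the supervised heatmap ordering.
"""

import json
import runpy
import warnings
from pathlib import Path

common = runpy.run_path(Path(__file__).parent / "00_common.py")

from iraeab.pipeline import stage_longitudinal

_, analysis_cfg = common["configs"]()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    out = stage_longitudinal(common["RUN_DIR"], analysis_cfg)

for isotype, stats in out.items():
    print(
        f"{isotype}: n={stats['n_patients']} (dropped {stats['dropped_patients']} "
        f"without week-6 draws); Spearman rho={stats['spearman_rho']:.3f} "
        f"(p={stats['spearman_p']:.2e}), Kruskal-Wallis p={stats['kruskal_p']:.2e}"
    )
print("higher fold changes accompany more distinct irAE when rho > 0")
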