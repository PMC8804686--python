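"""Serostatus, seroconversion and time-to-event analyses.

Classifies ANA/RF/anti-CCP positivity, accounts for seroconversion between
baseline and week 6, compares seropositive vs seronegative patients, and
runs Kaplan-Meier / log-rank for time to (severe) irAE and PFS/OS.
"""

import runpy
import warnings
from pathlib import Path

common = runpy.run_path(Path(__file__).parent / "00_common.py")

from iraeab.pipeline import stage_survival

_, analysis_cfg = common["configs"]()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    out = stage_survival(common["RUN_DIR"], analysis_cfg)

flow = out["seroconversion"]
print(
    f"baseline seropositive {flow['baseline_positive']}; "
    f"gained {flow['gained']}, lost {flow['lost']} -> week-6 positive "
    f"{flow['week6_positive']} of {flow['n_with_week6']}; ever positive "
    f"{flow['any_timepoint_positive']}"
)
for endpoint, res in out["logrank"].items():
    p = res["p"]
    p_txt = "undefined" if p is None else f"{p:.3f}"
    print(f"{endpoint}: log-rank p={p_txt}; medians per stratum {res['medians']}")
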