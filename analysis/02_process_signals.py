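"""Score, filter and normalize the array signals.

Computes ABS = log2(NFI*SNR + 1) per spot, drops antigens below SNR 3 in
more than 90% of samples, and removes per-slide affine distortions with
the control-based robust fit.
"""

import runpy
from pathlib import Path

import pandas as pd

common = runpy.run_path(Path(__file__).parent / "00_common.py")

from iraeab.pipeline import stage_process

retained = stage_process(common["RUN_DIR"])
report = pd.read_csv(common["RUN_DIR"] / "normalization_report.tsv", sep="\t")

for isotype, kept in retained.items():
    print(f"{isotype}: {kept} antigens retained of 120")
print(f"normalization slopes: mean {report['slope'].mean():.3f}, "
      f"sd {report['slope'].std():.3f} over {len(report)} slides")
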