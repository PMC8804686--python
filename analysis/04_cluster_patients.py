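"""Cluster patients into four baseline-intensity subgroups.

Hierarchical clustering (Euclidean, complete linkage) on the DE antigen
set, labeled high/moderate/slightly_low/low by mean score, with
Fisher-exact irAE enrichment per cluster and organ.
"""

import runpy
import warnings
from pathlib import Path

import pandas as pd

common = runpy.run_path(Path(__file__).parent / "00_common.py")

from iraeab.pipeline import stage_cluster

_, analysis_cfg = common["configs"]()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    enrichment = stage_cluster(common["RUN_DIR"], analysis_cfg)

clusters = pd.read_csv(common["RUN_DIR"] / "clusters.tsv", sep="\t", index_col=0)["cluster"]
print("cluster sizes:", clusters.value_counts().to_dict())
flagged = enrichment[enrichment["highlight"]]
if flagged.empty:
    print("no (cluster, organ) cell deviates from the cohort rate at p < 0.05")
else:
    print("enriched/depleted cells:")
    print(flagged[["cluster", "organ", "fraction", "p", "direction"]].to_string(index=False))
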