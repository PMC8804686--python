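"""Hierarchical patient clustering on differentially expressed antigens.

Patients are clustered on their baseline scores over the DE antigen set
(Euclidean distance, complete linkage, tree cut at k=4) and the four
clusters are labeled high / moderate / slightly_low / low by descending
mean score. Per (cluster, organ), a two-sided Fisher exact test compares
the in-cluster event rate against the rest of the cohort; cells with
p < 0.05 are highlighted with a direction (more_common / less_common) from
the odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .synthetic import qualifying_events

INTENSITY_LABELS = ("high", "moderate", "slightly_low", "low")


@dataclass
class ClusterResult:
    assignments: pd.Series  # patient_id -> intensity label
    cluster_means: pd.Series  # label -> mean score over the clustering antigens
    linkage: np.ndarray
    method: str
    antigens: list[str]


def cluster_patients(
    matrix: pd.DataFrame, k: int = 4, method: str = "complete"
) -> ClusterResult:
    """Cut a hierarchical tree of patients into ``k`` intensity subgroups.

    ``matrix`` is patients x antigens (already restricted to the DE set).
    scipy's linkage on Euclidean distances is deterministic for a fixed
    input order (ties merge lowest-index first).
    """
    if matrix.shape[0] < k:
        raise ValueError(f"need >= {k} patients, got {matrix.shape[0]}")
    if matrix.shape[1] < 1:
        raise ValueError("need >= 1 antigen")
    X = matrix.to_numpy(dtype=float)
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=method)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    means = pd.Series(X.mean(axis=1), index=matrix.index).groupby(raw).mean()
    order = means.sort_values(ascending=False).index  # cluster ids by descending mean
    if k == 4:
        label_of = {cid: INTENSITY_LABELS[rank] for rank, cid in enumerate(order)}
    else:
        label_of = {cid: f"c{rank + 1}" for rank, cid in enumerate(order)}
    assignments = pd.Series([label_of[c] for c in raw], index=matrix.index, name="cluster")
    cluster_means = pd.Series({label_of[c]: means[c] for c in means.index})
    return ClusterResult(
        assignments=assignments,
        cluster_means=cluster_means,
        linkage=Z,
        method=method,
        antigens=list(matrix.columns),
    )


def cluster_enrichment(result: ClusterResult, events: pd.DataFrame) -> pd.DataFrame:
    """Fisher-exact irAE enrichment per (cluster, organ).

    For each cell: 2x2 table of event-vs-no-event inside vs outside the
    cluster, two-sided Fisher p, observed in-cluster event fraction, and a
    direction flag (more_common / less_common when p < 0.05, else none).
    """
    qual = qualifying_events(events)
    patients = result.assignments.index
    rows = []
    organs = sorted(qual["organ"].unique()) if not qual.empty else []
    for organ in organs:
        hit = set(qual.loc[qual["organ"] == organ, "patient_id"]) & set(patients)
        for label in result.cluster_means.index:
            members = set(patients[result.assignments == label])
            n_in = len(members)
            a = len(members & hit)
            c = len(hit) - a
            d = len(patients) - n_in - c
            if n_in == 0:
                rows.append(
                    {"cluster": label, "organ": organ, "n_cluster": 0,
                     "n_events": 0, "fraction": np.nan, "odds_ratio": np.nan,
                     "p": np.nan, "direction": "undefined", "highlight": False}
                )
                continue
            table = [[a, n_in - a], [c, d]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            in_rate = a / n_in
            out_rate = c / (c + d) if (c + d) else np.nan
            if p < 0.05 and in_rate > out_rate:
                direction = "more_common"
            elif p < 0.05 and in_rate < out_rate:
                direction = "less_common"
            else:
                direction = "none"
            rows.append(
                {"cluster": label, "organ": organ, "n_cluster": n_in,
                 "n_events": a, "fraction": in_rate, "odds_ratio": odds,
                 "p": p, "direction": direction, "highlight": bool(p < 0.05)}
            )
    return pd.DataFrame(rows)
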