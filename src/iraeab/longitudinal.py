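"""Baseline-to-week-6 fold changes and their relation to irAE burden.

The fold change per patient and antigen is the week-6 score minus the
baseline score (both log2), so positive values mean rising antibody
levels. Patients without a week-6 draw drop out and are listed in a
report. The per-patient summary (mean |FC| over the DE antigen set) is
related to the number of distinct organ systems with qualifying irAE via
Spearman correlation, with a Kruskal-Wallis test across count strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import distinct_organ_counts


@dataclass
class FCMatrix:
    values: pd.DataFrame  # patients (with both draws) x antigens
    dropped_patients: list[str]

    @property
    def mean_abs_fc(self) -> pd.Series:
        return self.values.abs().mean(axis=1).rename("mean_abs_fc")

    @property
    def mean_fc(self) -> pd.Series:
        return self.values.mean(axis=1).rename("mean_fc")


def fold_changes(baseline: pd.DataFrame, week6: pd.DataFrame) -> FCMatrix:
    """Cellwise ``week6 - baseline`` over the shared patients and antigens."""
    if not baseline.columns.equals(week6.columns):
        common = baseline.columns.intersection(week6.columns)
        if len(common) == 0:
            raise ValueError("matrices share no antigens")
        baseline, week6 = baseline[common], week6[common]
    shared = baseline.index.intersection(week6.index)
    if len(shared) == 0:
        raise ValueError("no patient has both timepoints")
    dropped = [p for p in baseline.index if p not in set(shared)]
    values = week6.loc[shared] - baseline.loc[shared]
    return FCMatrix(values=values, dropped_patients=dropped)


def fc_vs_irae_count(fc: FCMatrix, events: pd.DataFrame) -> dict:
    """Association between fold-change magnitude and distinct-organ irAE count.

    Returns Spearman rho/p between per-patient mean |FC| and the count,
    plus a Kruskal-Wallis test across count strata. With a constant
    summary or constant counts the correlation is undefined and flagged.
    """
    if fc.values.shape[0] < 3:
        raise ValueError("need >= 3 patients")
    summary = fc.mean_abs_fc
    counts = distinct_organ_counts(events, list(summary.index))
    out: dict = {"n": len(summary), "counts": counts}
    if summary.nunique() <= 1 or counts.nunique() <= 1:
        out.update(spearman_rho=np.nan, spearman_p=np.nan,
                   kruskal_stat=np.nan, kruskal_p=np.nan, defined=False)
        return out
    rho, p = stats.spearmanr(summary.to_numpy(), counts.to_numpy())
    groups = [summary[counts == c].to_numpy() for c in sorted(counts.unique())]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) >= 2:
        k_stat, k_p = stats.kruskal(*groups)
    else:
        k_stat, k_p = np.nan, np.nan
    out.update(spearman_rho=float(rho), spearman_p=float(p),
               kruskal_stat=float(k_stat), kruskal_p=float(k_p), defined=True)
    return out


def supervised_order(fc: FCMatrix, events: pd.DataFrame) -> tuple[list[str], pd.DataFrame]:
    """Event-profile patient ordering plus the organ x patient indicator block.

    Sort key: any qualifying irAE (event patients first), then
    distinct-organ count descending, then mean |FC| descending; no-event
    patients keep their input order at the end (stable sort).
    """
    patients = list(fc.values.index)
    counts = distinct_organ_counts(events, patients)
    summary = fc.mean_abs_fc
    key = pd.DataFrame(
        {"count": counts, "mean_abs_fc": summary},
        index=pd.Index(patients, name="patient_id"),
    )
    event_block = key[counts > 0].sort_values(
        ["count", "mean_abs_fc"], ascending=False, kind="stable"
    )
    ordered = event_block.index.tolist() + [p for p in patients if counts[p] == 0]
    from .synthetic import qualifying_events

    qual = qualifying_events(events)
    organs = sorted(qual["organ"].unique()) if not qual.empty else []
    indicator = pd.DataFrame(0, index=pd.Index(organs, name="organ"), columns=ordered)
    for organ in organs:
        hit = set(qual.loc[qual["organ"] == organ, "patient_id"])
        indicator.loc[organ, [p for p in ordered if p in hit]] = 1
    return ordered, indicator
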