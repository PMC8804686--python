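"""Per-antigen group comparisons of antibody scores.

Groups are clinically defined from qualifying (definite/probable) adverse
events: organ-specific event vs not, first-event timing (< 6 vs >= 6
weeks), and maximum severity (CTCAE grade >= 3 vs 1-2). Each antigen is
compared with a two-sided Mann-Whitney U test; fold change is the
difference of group mean scores (the score is already log2, so the linear
fold change is ``2**log2fc``); Benjamini-Hochberg adjustment runs across
the retained antigens of one (isotype, timepoint, grouping) family.

Sign convention: positive log2fc means higher antibody levels in the event
group (group A), negative means higher in the comparison group.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signal import AbsMatrix
from .synthetic import qualifying_events

TIMING_CUTOFF_WEEKS = 6.0
SEVERE_GRADE = 3


@dataclass(frozen=True)
class GroupAssignment:
    """A two-group patient partition (possibly with exclusions)."""

    name: str
    assignment: pd.Series  # patient_id -> "A" | "B" | "excluded"

    @property
    def group_a(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "A"])

    @property
    def group_b(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "B"])

    @property
    def degenerate(self) -> bool:
        return len(self.group_a) == 0 or len(self.group_b) == 0


def assign_groups(
    events: pd.DataFrame, clinical: pd.DataFrame, grouping: tuple[str, ...]
) -> GroupAssignment:
    """Build a patient partition from a grouping spec.

    Specs: ``("organ", <organ>)`` — patients with >= 1 qualifying event of
    that organ vs all others; ``("timing",)`` — first qualifying event
    before vs at/after week 6 (no-event patients excluded); ``("severity",)``
    — max qualifying grade >= 3 vs 1-2 (no-event patients excluded);
    ``("any_irae",)`` — any qualifying event vs none; ``("first_half",)`` —
    deterministic half split for calibration runs.
    """
    patients = pd.Index(clinical["patient_id"], name="patient_id")
    qual = qualifying_events(events)
    kind = grouping[0]
    labels = pd.Series("B", index=patients)
    if kind == "organ":
        organ = grouping[1]
        hit = set(qual.loc[qual["organ"] == organ, "patient_id"])
        labels[labels.index.isin(hit)] = "A"
    elif kind == "timing":
        if qual.empty:
            labels[:] = "excluded"
        else:
            first = qual.groupby("patient_id")["onset_week"].min()
            labels[:] = "excluded"
            early = first.index[first < TIMING_CUTOFF_WEEKS]
            late = first.index[first >= TIMING_CUTOFF_WEEKS]
            labels[labels.index.isin(early)] = "A"
            labels[labels.index.isin(late)] = "B"
    elif kind == "severity":
        if qual.empty:
            labels[:] = "excluded"
        else:
            max_grade = qual.groupby("patient_id")["grade"].max()
            labels[:] = "excluded"
            severe = max_grade.index[max_grade >= SEVERE_GRADE]
            mild = max_grade.index[max_grade < SEVERE_GRADE]
            labels[labels.index.isin(severe)] = "A"
            labels[labels.index.isin(mild)] = "B"
    elif kind == "any_irae":
        hit = set(qual["patient_id"]) if not qual.empty else set()
        labels[labels.index.isin(hit)] = "A"
    elif kind == "first_half":
        half = (len(patients) + 1) // 2
        labels.iloc[:half] = "A"
    else:
        raise ValueError(f"unknown grouping spec {grouping!r}")
    name = "_".join(str(g) for g in grouping)
    ga = GroupAssignment(name=name, assignment=labels)
    if ga.degenerate:
        warnings.warn(f"grouping {name!r} is degenerate (an empty group)", stacklevel=2)
    return ga


def compare_antigen(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U and mean-difference fold change.

    Exact null distribution when the pooled size is <= 20 with no ties,
    tie-corrected normal approximation otherwise. Returns
    ``(log2fc, p_raw)`` with ``log2fc = mean(a) - mean(b)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need >= 1 value")
    log2fc = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    small = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
    method = "exact" if small else "asymptotic"
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return log2fc, float(p)


def run_de(
    matrix: AbsMatrix,
    grouping: GroupAssignment,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-antigen Mann-Whitney with BH adjustment across the panel.

    Returns one row per antigen: group sizes, log2 fold change (positive =
    higher in group A), raw and BH-adjusted p, and the significance flag
    ``p_adj < alpha``.
    """
    a_ids = [p for p in grouping.group_a if p in matrix.values.index]
    b_ids = [p for p in grouping.group_b if p in matrix.values.index]
    if len(a_ids) == 0 or len(b_ids) == 0:
        warnings.warn(f"grouping {grouping.name!r} degenerate on this matrix; empty DE result")
        return pd.DataFrame(
            columns=["antigen", "isotype", "timepoint", "grouping", "n_a", "n_b",
                     "log2fc", "p_raw", "p_adj", "significant"]
        )
    A = matrix.values.loc[a_ids].to_numpy(dtype=float)
    B = matrix.values.loc[b_ids].to_numpy(dtype=float)
    log2fc = A.mean(axis=0) - B.mean(axis=0)
    n_total = len(a_ids) + len(b_ids)
    if n_total > 20:
        with np.errstate(invalid="ignore"):
            _, p_raw = stats.mannwhitneyu(A, B, alternative="two-sided", method="asymptotic", axis=0)
        # all-tied columns yield nan from the normal approximation
        flat = np.ptp(np.vstack([A, B]), axis=0) == 0
        p_raw = np.where(flat, 1.0, p_raw)
        log2fc = np.where(flat, 0.0, log2fc)
    else:
        p_raw = np.empty(A.shape[1])
        for j in range(A.shape[1]):
            log2fc[j], p_raw[j] = compare_antigen(A[:, j], B[:, j])
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    return pd.DataFrame(
        {
            "antigen": matrix.antigens,
            "isotype": matrix.isotype,
            "timepoint": matrix.timepoint,
            "grouping": grouping.name,
            "n_a": len(a_ids),
            "n_b": len(b_ids),
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        }
    )


def volcano_table(de_results: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Volcano-plot table and the per-side significant-antigen counts.

    Side ``event`` = positive log2fc (higher in the event group), ``non_event``
    = negative. The corner counts tally significant antigens per side; a
    raw-p count at the 0.05 plot line is reported alongside.
    """
    if de_results.empty:
        raise ValueError("empty DE results")
    table = de_results.copy()
    with np.errstate(divide="ignore"):
        table["neg_log10_p"] = -np.log10(table["p_raw"])
    table["side"] = np.where(table["log2fc"] > 0, "event",
                             np.where(table["log2fc"] < 0, "non_event", "zero"))
    sig = table[table["significant"]]
    counts = {
        "non_event": int((sig["side"] == "non_event").sum()),
        "event": int((sig["side"] == "event").sum()),
        "raw_line_non_event": int(((table["p_raw"] < 0.05) & (table["side"] == "non_event")).sum()),
        "raw_line_event": int(((table["p_raw"] < 0.05) & (table["side"] == "event")).sum()),
    }
    return table, counts
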