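"""Total immunoglobulin quartile analyses and the Ig-normalization
sensitivity check on the microarray results.

Patients are split into quartiles of total IgG (or IgM) with the
linear-interpolation sample-quantile definition; clinical traits are
compared across quartiles with an exact conditional test (Fisher-
Freeman-Halton by enumeration for R x 2 tables, chi-square for wider
tables), sex vs Ig level with the Wilcoxon rank-sum test, and PFS/OS
between the highest and lowest quartile with KM + log-rank. The
sensitivity check rescales every patient's linear antigen signal by their
relative total Ig of the matching isotype, re-runs the differential
analysis, and reports how much the fold-change ranking moves.
"""

from __future__ import annotations

from functools import lru_cache
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .differential import GroupAssignment, run_de
from .signal import AbsMatrix
from .survival import build_time_to_event, logrank

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def assign_quartiles(levels: pd.Series) -> tuple[pd.Series, bool]:
    """Quartile labels from linear-interpolation sample quantiles.

    Values at or below the k-th cut point get Qk (deterministic tie
    handling: equal values always share a label). Returns the labels and a
    degeneracy flag (true when cut points collide, e.g. all levels equal).
    """
    if len(levels) < 4:
        raise ValueError("need >= 4 patients for quartiles")
    values = levels.to_numpy(dtype=float)
    cuts = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    degenerate = len(np.unique(cuts)) < 3
    idx = np.searchsorted(cuts, values, side="left")
    labels = pd.Series(
        [QUARTILE_LABELS[i] for i in idx], index=levels.index, name="quartile"
    )
    if degenerate:
        warnings.warn("degenerate quartiles: cut points collide", stacklevel=2)
    return labels, degenerate


@lru_cache(maxsize=None)
def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_freeman_halton_rx2(table: np.ndarray) -> float:
    """Exact conditional p for an R x 2 contingency table by enumeration.

    Sums the multivariate-hypergeometric probability of every table with
    the observed margins whose probability does not exceed the observed
    table's (two-sided by the point-probability criterion, matching the
    2 x 2 Fisher test).
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("expected an R x 2 table")
    rows = table.sum(axis=1)
    col1 = int(table[:, 0].sum())
    n = int(table.sum())
    if col1 == 0 or col1 == n:
        return 1.0

    norm = _log_binom(n, col1)
    observed = (
        sum(_log_binom(int(r), int(c)) for r, c in zip(rows, table[:, 0])) - norm
    )
    total = 0.0

    def recurse(i: int, remaining: int, acc: float) -> None:
        nonlocal total
        if i == len(rows) - 1:
            if remaining <= rows[i]:
                lp = acc + _log_binom(int(rows[i]), remaining) - norm
                if lp <= observed + 1e-9:
                    total += math.exp(lp)
            return
        lo = max(0, remaining - int(rows[i + 1 :].sum()))
        hi = min(int(rows[i]), remaining)
        for c in range(lo, hi + 1):
            recurse(i + 1, remaining - c, acc + _log_binom(int(rows[i]), c))

    recurse(0, col1, 0.0)
    return min(1.0, float(total))


def _across_quartile_test(quartiles: pd.Series, flags: pd.Series) -> tuple[str, float]:
    present = [q for q in QUARTILE_LABELS if (quartiles == q).any()]
    table = np.array(
        [
            [int(flags[quartiles == q].sum()), int((~flags[quartiles == q]).sum())]
            for q in present
        ]
    )
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return "undefined", np.nan
    if len(present) < 2:
        return "undefined", np.nan
    return "fisher_freeman_halton", fisher_freeman_halton_rx2(table)


def quartile_associations(
    quartiles: pd.Series,
    clinical: pd.DataFrame,
    events: pd.DataFrame,
    survival: pd.DataFrame,
    levels: pd.Series | None = None,
) -> pd.DataFrame:
    """Associations of Ig quartiles with clinical traits and survival.

    Binary traits: exact test across quartiles. Sex vs Ig level (when
    ``levels`` given): Wilcoxon rank-sum. PFS and OS: log-rank of Q4 vs Q1
    among stage IV patients. Quartiles empty of patients are skipped with
    a warning.
    """
    from .synthetic import qualifying_events

    clin = clinical.set_index("patient_id")
    quartiles = quartiles.reindex(clin.index)
    empty = [q for q in QUARTILE_LABELS if not (quartiles == q).any()]
    if empty:
        warnings.warn(f"empty quartile(s) skipped: {empty}", stacklevel=2)
    rows = []
    qual = qualifying_events(events)

    def add_binary(name: str, flags: pd.Series) -> None:
        test, p = _across_quartile_test(quartiles, flags.astype(bool))
        rows.append({"characteristic": name, "test": test, "p": p})

    add_binary("sex_male", clin["sex"] == "male")
    add_binary("stage_iv", clin["stage"] == "IV")
    add_binary("cutaneous_histology", clin["melanoma_type"] == "cutaneous")
    if not qual.empty:
        max_grade = qual.groupby("patient_id")["grade"].max().reindex(clin.index).fillna(0)
        add_binary("severe_max_grade", max_grade >= 3)
        first = qual.groupby("patient_id")["onset_week"].min().reindex(clin.index)
        add_binary("first_irae_lt6w", first.fillna(np.inf) < 6.0)
    if levels is not None:
        men = levels[clin.index[clin["sex"] == "male"]]
        women = levels[clin.index[clin["sex"] == "female"]]
        if len(men) and len(women):
            _, p = stats.ranksums(women, men)
            rows.append({"characteristic": "ig_level_by_sex", "test": "ranksum", "p": float(p)})
    for endpoint in ("pfs", "os"):
        tte = build_time_to_event(events, clinical, survival, endpoint,
                                  strata=quartiles)
        hi = tte[tte["stratum"] == "Q4"]
        lo = tte[tte["stratum"] == "Q1"]
        if len(hi) and len(lo):
            _, p = logrank(hi["time"], lo["time"], hi["event"], lo["event"])
            rows.append({"characteristic": f"{endpoint}_q4_vs_q1", "test": "logrank", "p": p})
    return pd.DataFrame(rows)


def ig_normalized_sensitivity(
    matrix: AbsMatrix,
    ig_levels: pd.Series,
    grouping: GroupAssignment,
    alpha: float = 0.05,
) -> dict:
    """Re-run the differential analysis after rescaling by total Ig.

    Each patient's linear-scale signal (``NFI x SNR = 2**ABS - 1``) is
    divided by their total Ig of the matching isotype relative to the
    cohort median, then re-scored and re-tested. Reports the sign
    concordance and Spearman rank correlation of the per-antigen fold
    changes, and the overlap of significant sets.
    """
    ig = ig_levels.reindex(matrix.values.index)
    if ig.isna().any():
        raise ValueError("ig_levels missing for some patients in the matrix")
    if (ig <= 0).any():
        raise ValueError("zero or negative total Ig level")
    rel = ig / ig.median()
    linear = np.exp2(matrix.values.to_numpy(dtype=float)) - 1.0
    rescored = np.log2(linear / rel.to_numpy()[:, None] + 1.0)
    adj_matrix = AbsMatrix(
        values=pd.DataFrame(rescored, index=matrix.values.index, columns=matrix.values.columns),
        mask=matrix.mask,
        isotype=matrix.isotype,
        timepoint=matrix.timepoint,
        normalization=matrix.normalization,
        controls=matrix.controls,
    )
    de_raw = run_de(matrix, grouping, alpha=alpha)
    de_adj = run_de(adj_matrix, grouping, alpha=alpha)
    merged = de_raw.merge(de_adj, on="antigen", suffixes=("_raw", "_adj"))
    nonzero = merged[(merged["log2fc_raw"] != 0) | (merged["log2fc_adj"] != 0)]
    concordance = float(
        (np.sign(nonzero["log2fc_raw"]) == np.sign(nonzero["log2fc_adj"])).mean()
    ) if len(nonzero) else 1.0
    if merged["log2fc_raw"].nunique() > 1 and merged["log2fc_adj"].nunique() > 1:
        rho, _ = stats.spearmanr(merged["log2fc_raw"], merged["log2fc_adj"])
        rho = float(rho)
    else:
        rho = 1.0 if merged["log2fc_raw"].equals(merged["log2fc_adj"]) else np.nan
    sig_raw = set(merged.loc[merged["significant_raw"], "antigen"])
    sig_adj = set(merged.loc[merged["significant_adj"], "antigen"])
    union = sig_raw | sig_adj
    jaccard = len(sig_raw & sig_adj) / len(union) if union else 1.0
    return {
        "sign_concordance": concordance,
        "log2fc_rank_correlation": rho,
        "significant_jaccard": float(jaccard),
        "n_significant_raw": len(sig_raw),
        "n_significant_adj": len(sig_adj),
        "identical": bool(np.allclose(merged["log2fc_raw"], merged["log2fc_adj"])),
    }
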