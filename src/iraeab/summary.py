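"""Cohort characteristics table and the centralized n (%) arithmetic."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .synthetic import qualifying_events


def proportion(numerator: int, denominator: int, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def _median_iqr(values: pd.Series) -> dict:
    v = values.to_numpy(dtype=float)
    return {
        "median": float(np.median(v)),
        "q1": float(np.percentile(v, 25)),
        "q3": float(np.percentile(v, 75)),
    }


def summarize(
    clinical: pd.DataFrame,
    events: pd.DataFrame,
    serostatus: pd.DataFrame | None = None,
) -> dict:
    """Cohort summary: medians with IQR for continuous characteristics and
    n (%) rows for categories, on the denominators a trial report would
    print (timing percentages over the whole cohort; week-6 serology over
    patients with a week-6 draw)."""
    if clinical.empty:
        raise ValueError("empty cohort")
    n = len(clinical)
    out: dict = {"n_patients": n}
    out["age"] = _median_iqr(clinical["age"])
    out["ici_cycles"] = _median_iqr(clinical["ici_cycles"])
    out["sex_male"] = {"n": int((clinical["sex"] == "male").sum())}
    out["sex_male"]["pct"] = proportion(out["sex_male"]["n"], n, 0)
    for stage in ("III", "IV"):
        cnt = int((clinical["stage"] == stage).sum())
        out[f"stage_{stage}"] = {"n": cnt, "pct": proportion(cnt, n, 0)}
    for mtype in sorted(clinical["melanoma_type"].unique()):
        cnt = int((clinical["melanoma_type"] == mtype).sum())
        out[f"melanoma_{mtype}"] = {"n": cnt, "pct": proportion(cnt, n, 1)}

    qual = qualifying_events(events)
    per_patient = qual.groupby("patient_id").size().reindex(clinical["patient_id"]).fillna(0)
    out["total_irae"] = _median_iqr(per_patient)
    max_grade = (
        qual.groupby("patient_id")["grade"].max().reindex(clinical["patient_id"]).fillna(0)
    )
    none_n = int((max_grade == 0).sum())
    mild_n = int(((max_grade >= 1) & (max_grade <= 2)).sum())
    severe_n = int((max_grade >= 3).sum())
    out["max_grade_none"] = {"n": none_n, "pct": proportion(none_n, n, 1)}
    out["max_grade_mild"] = {"n": mild_n, "pct": proportion(mild_n, n, 1)}
    out["max_grade_severe"] = {"n": severe_n, "pct": proportion(severe_n, n, 1)}

    first = qual.groupby("patient_id")["onset_week"].min()
    early = int((first < 6.0).sum())
    late = int((first >= 6.0).sum())
    out["first_irae_lt6w"] = {"n": early, "pct": proportion(early, n, 0)}
    out["first_irae_ge6w"] = {"n": late, "pct": proportion(late, n, 0)}
    severe_first = qual[qual["grade"] >= 3].groupby("patient_id")["onset_week"].min()
    if len(severe_first):
        se = int((severe_first < 6.0).sum())
        sl = int((severe_first >= 6.0).sum())
        denom = len(severe_first)
        out["first_severe_lt6w"] = {"n": se, "pct": proportion(se, denom, 0)}
        out["first_severe_ge6w"] = {"n": sl, "pct": proportion(sl, denom, 0)}

    if serostatus is not None:
        n_week6 = int(serostatus["has_week6"].sum())
        for assay in ("ana", "rf", "ccp", "any"):
            base = int(serostatus[f"{assay}_positive_baseline"].sum())
            out[f"{assay}_positive_baseline"] = {"n": base, "pct": proportion(base, n, 1)}
            wk = int(serostatus.loc[serostatus["has_week6"], f"{assay}_positive_week6"].sum())
            out[f"{assay}_positive_week6"] = {
                "n": wk,
                "pct": proportion(wk, n_week6, 1) if n_week6 else np.nan,
            }
            if assay == "any":
                anyn = int(serostatus["any_positive_any"].sum())
            else:
                base_f = serostatus[f"{assay}_positive_baseline"].fillna(0).astype(bool)
                wk_f = serostatus[f"{assay}_positive_week6"].fillna(0).astype(bool)
                anyn = int((base_f | wk_f).sum())
            out[f"{assay}_positive_any_timepoint"] = {"n": anyn, "pct": proportion(anyn, n, 1)}
    return out


def summary_frame(summary: dict) -> pd.DataFrame:
    """Flatten :func:`summarize` output into a printable two-column table."""
    rows = []
    for key, val in summary.items():
        if isinstance(val, dict):
            if "median" in val:
                text = f"{val['median']:g} ({val['q1']:g}, {val['q3']:g})"
            else:
                text = f"{val['n']} ({val['pct']:g})"
        else:
            text = f"{val}"
        rows.append({"characteristic": key, "value": text})
    return pd.DataFrame(rows)
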