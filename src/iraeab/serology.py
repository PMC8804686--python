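"""ANA/RF/anti-CCP serostatus classification and seroconversion accounting.

Positivity is strict: RF > 14 IU/mL, anti-CCP > 20 U/mL; ANA is a binary
immunofluorescence call. A patient is seropositive at a timepoint when any
of the three is positive; "any timepoint" positivity is baseline OR week 6
(missing week-6 draws contribute nothing and are excluded from week-6
denominators). Seroconversion accounting restricts to patients with both
draws and checks the flow identities
``week6 = baseline + gained - lost`` and ``any = baseline + gained``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import distinct_organ_counts, qualifying_events

RF_THRESHOLD = 14.0  # IU/mL, positive strictly above
CCP_THRESHOLD = 20.0  # U/mL, positive strictly above


def classify_serostatus(
    panel: pd.DataFrame,
    rf_threshold: float = RF_THRESHOLD,
    ccp_threshold: float = CCP_THRESHOLD,
) -> pd.DataFrame:
    """Per-patient positivity flags per timepoint and overall.

    ``panel`` is the long serology table (patient_id, timepoint,
    ana_positive, rf_iu_ml, ccp_u_ml). Returns one row per patient with
    baseline/week6 flags (week6 columns NaN when the draw is missing) and
    ``any_timepoint`` positivity.
    """
    if (panel[["rf_iu_ml", "ccp_u_ml"]] < 0).any().any():
        bad = panel[(panel[["rf_iu_ml", "ccp_u_ml"]] < 0).any(axis=1)]
        raise ValueError(f"negative titer for patient {bad['patient_id'].iloc[0]}")
    panel = panel.assign(
        rf_positive=panel["rf_iu_ml"] > rf_threshold,
        ccp_positive=panel["ccp_u_ml"] > ccp_threshold,
    )
    panel = panel.assign(
        any_positive=panel["ana_positive"].astype(bool)
        | panel["rf_positive"]
        | panel["ccp_positive"]
    )
    wide = panel.pivot(index="patient_id", columns="timepoint")
    out = pd.DataFrame(index=wide.index)
    for flag in ("ana_positive", "rf_positive", "ccp_positive", "any_positive"):
        for tp in ("baseline", "week6"):
            col = (flag, tp)
            out[f"{flag}_{tp}"] = wide[col].astype(float) if col in wide.columns else np.nan
    out["has_week6"] = out["any_positive_week6"].notna()
    # missing week 6 -> overall falls back to baseline
    out["any_positive_any"] = (
        out["any_positive_baseline"].fillna(0).astype(bool)
        | out["any_positive_week6"].fillna(0).astype(bool)
    )
    return out


def seroconversion_accounting(status: pd.DataFrame) -> dict[str, int]:
    """Seroconversion flow counts from a :func:`classify_serostatus` table.

    Counts baseline positives (whole cohort), conversions among patients
    with both draws, week-6 positives, and any-timepoint positives, and
    asserts the flow identities. Raises if a patient's flags violate them.
    """
    base_all = int(status["any_positive_baseline"].sum())
    both = status[status["has_week6"]]
    base_both = int(both["any_positive_baseline"].sum())
    gained = int(((both["any_positive_baseline"] == 0) & (both["any_positive_week6"] == 1)).sum())
    lost = int(((both["any_positive_baseline"] == 1) & (both["any_positive_week6"] == 0)).sum())
    week6 = int(both["any_positive_week6"].sum())
    any_pos = int(status["any_positive_any"].sum())
    if week6 != base_both + gained - lost:
        raise AssertionError(
            f"seroconversion identity violated: week6 {week6} != "
            f"{base_both} + {gained} - {lost}"
        )
    if any_pos != base_all + gained:
        raise AssertionError(
            f"any-timepoint identity violated: {any_pos} != {base_all} + {gained}"
        )
    return {
        "baseline_positive": base_all,
        "baseline_positive_with_week6": base_both,
        "gained": gained,
        "lost": lost,
        "week6_positive": week6,
        "any_timepoint_positive": any_pos,
        "n_with_week6": int(status["has_week6"].sum()),
    }


def _cat_test(table: np.ndarray) -> tuple[str, float]:
    """Fisher for 2x2 (or chi-square when all expected counts >= 5)."""
    table = np.asarray(table)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return "undefined", np.nan
    expected = stats.contingency.expected_freq(table)
    if table.shape == (2, 2) and (expected < 5).any():
        _, p = stats.fisher_exact(table)
        return "fisher", float(p)
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi2", float(p)


def compare_serogroups(
    clinical: pd.DataFrame,
    events: pd.DataFrame,
    status: pd.DataFrame,
) -> pd.DataFrame:
    """Baseline seropositive-vs-seronegative comparison table.

    Continuous characteristics (age, distinct irAE count) use the Wilcoxon
    rank-sum test; categorical ones (sex, severe max grade, early timing,
    each organ) use Fisher's exact test, switching to chi-square when all
    expected counts are >= 5. Empty strata skip the tests.
    """
    clin = clinical.set_index("patient_id")
    pos_ids = status.index[status["any_positive_baseline"] == 1]
    neg_ids = status.index[status["any_positive_baseline"] == 0]
    pos_ids = [p for p in pos_ids if p in clin.index]
    neg_ids = [p for p in neg_ids if p in clin.index]
    rows = []
    if len(pos_ids) == 0 or len(neg_ids) == 0:
        return pd.DataFrame(
            [{"characteristic": "all", "test": "skipped_empty_stratum", "p": np.nan}]
        )
    qual = qualifying_events(events)
    counts = distinct_organ_counts(events, list(clin.index))

    def ranksum(name: str, series: pd.Series) -> None:
        a, b = series.loc[pos_ids], series.loc[neg_ids]
        if a.nunique() <= 1 and b.nunique() <= 1 and a.iloc[0] == b.iloc[0]:
            rows.append({"characteristic": name, "test": "ranksum", "p": 1.0})
            return
        _, p = stats.ranksums(a, b)
        rows.append({"characteristic": name, "test": "ranksum", "p": float(p)})

    def categorical(name: str, flags: pd.Series) -> None:
        a = int(flags.loc[pos_ids].sum())
        b = int(flags.loc[neg_ids].sum())
        table = np.array([[a, len(pos_ids) - a], [b, len(neg_ids) - b]])
        test, p = _cat_test(table)
        rows.append({"characteristic": name, "test": test, "p": p,
                     "positive_n": a, "negative_n": b})

    ranksum("age", clin["age"].astype(float))
    ranksum("distinct_irae_count", counts)
    categorical("sex_male", clin["sex"] == "male")
    if not qual.empty:
        max_grade = qual.groupby("patient_id")["grade"].max().reindex(clin.index).fillna(0)
        categorical("severe_max_grade", max_grade >= 3)
        first = qual.groupby("patient_id")["onset_week"].min()
        early = first.reindex(clin.index) < 6.0
        categorical("first_irae_lt6w", early.fillna(False))
        for organ in sorted(qual["organ"].unique()):
            hit = clin.index.isin(set(qual.loc[qual["organ"] == organ, "patient_id"]))
            categorical(f"organ_{organ}", pd.Series(hit, index=clin.index))
    return pd.DataFrame(rows)
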