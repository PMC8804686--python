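"""Serostatus thresholds, seroconversion flow, serogroup comparisons."""

import numpy as np
import pandas as pd
import pytest

from iraeab.serology import (
    classify_serostatus,
    compare_serogroups,
    seroconversion_accounting,
)
from tests.conftest import make_clinical, make_events


def panel_row(pid, tp, ana=0, rf=0.0, ccp=0.0):
    return {"patient_id": pid, "timepoint": tp, "ana_positive": ana,
            "rf_iu_ml": rf, "ccp_u_ml": ccp}


def build_panel(rows):
    return pd.DataFrame(rows)


class TestClassify:
    def test_thresholds_are_strict(self):
        panel = build_panel(
            [panel_row("P1", "baseline", rf=14.0), panel_row("P2", "baseline", rf=14.01),
             panel_row("P3", "baseline", ccp=20.0), panel_row("P4", "baseline", ccp=20.5)]
        )
        status = classify_serostatus(panel)
        assert status.loc["P1", "rf_positive_baseline"] == 0
        assert status.loc["P2", "rf_positive_baseline"] == 1
        assert status.loc["P3", "ccp_positive_baseline"] == 0
        assert status.loc["P4", "any_positive_baseline"] == 1

    def test_week6_only_positive_is_overall_positive(self):
        panel = build_panel(
            [panel_row("P1", "baseline"), panel_row("P1", "week6", ana=1)]
        )
        status = classify_serostatus(panel)
        assert status.loc["P1", "any_positive_baseline"] == 0
        assert status.loc["P1", "any_positive_any"]

    def test_missing_week6_is_unknown(self):
        panel = build_panel([panel_row("P1", "baseline", ana=1)])
        status = classify_serostatus(panel)
        assert not status.loc["P1", "has_week6"]
        assert np.isnan(status.loc["P1", "any_positive_week6"])
        assert status.loc["P1", "any_positive_any"]

    def test_negative_titer_rejected(self):
        with pytest.raises(ValueError, match="P1"):
            classify_serostatus(build_panel([panel_row("P1", "baseline", rf=-1.0)]))

    def test_monotone_in_titers(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            rf, ccp = rng.uniform(0, 40), rng.uniform(0, 40)
            lo = classify_serostatus(build_panel([panel_row("P1", "baseline", rf=rf, ccp=ccp)]))
            hi = classify_serostatus(
                build_panel([panel_row("P1", "baseline", rf=rf + 5, ccp=ccp + 5)])
            )
            assert hi.loc["P1", "any_positive_baseline"] >= lo.loc["P1", "any_positive_baseline"]


def _flow_panel(n=60, n_missing=9, base_pos=17, gained=7, lost=5):
    """Panel engineered to a given seroconversion flow; conversions happen
    among the patients with both draws."""
    ids = [f"P{i:02d}" for i in range(n)]
    with_week6 = ids[: n - n_missing]
    rows = []
    pos_base = ids[:base_pos]  # all have week-6 draws when base_pos <= n - n_missing
    lost_set = pos_base[:lost]
    gain_set = [p for p in with_week6 if p not in pos_base][:gained]
    for pid in ids:
        rows.append(panel_row(pid, "baseline", ana=int(pid in pos_base)))
        if pid in with_week6:
            week6_pos = (pid in pos_base and pid not in lost_set) or pid in gain_set
            rows.append(panel_row(pid, "week6", ana=int(week6_pos)))
    return build_panel(rows)


class TestSeroconversion:
    def test_printed_flow_arithmetic(self):
        # 17 baseline positive, 7 gained, 5 lost -> 19 at week 6, 24 ever
        flow = seroconversion_accounting(classify_serostatus(_flow_panel()))
        assert flow["baseline_positive"] == 17
        assert flow["gained"] == 7
        assert flow["lost"] == 5
        assert flow["week6_positive"] == 19
        assert flow["any_timepoint_positive"] == 24

    def test_no_conversions(self):
        flow = seroconversion_accounting(
            classify_serostatus(_flow_panel(gained=0, lost=0))
        )
        assert flow["week6_positive"] == flow["baseline_positive_with_week6"]
        assert flow["any_timepoint_positive"] == flow["baseline_positive"]

    def test_inconsistent_flags_raise(self):
        status = classify_serostatus(_flow_panel())
        tampered = status.copy()
        tampered["any_positive_any"] = 0  # contradicts baseline positivity
        with pytest.raises(AssertionError, match="identity"):
            seroconversion_accounting(tampered)


class TestCompareSerogroups:
    def _status(self, ids, positive):
        rows = [panel_row(p, "baseline", ana=int(p in positive)) for p in ids]
        rows += [panel_row(p, "week6", ana=int(p in positive)) for p in ids]
        return classify_serostatus(build_panel(rows))

    def test_identical_strata_all_p1(self):
        ids = [f"P{i:02d}" for i in range(40)]
        clin = make_clinical(ids)
        # same event profile in both strata
        events = make_events(
            [(p, "hepatic", 2, 3.0, "definite") for i, p in enumerate(ids) if i % 2 == 0]
        )
        status = self._status(ids, set(ids[:20]))
        # strata: P00..P19 positive; events on even indices -> 10 in each
        table = compare_serogroups(clin, events, status).set_index("characteristic")
        assert table.loc["age", "p"] == 1.0
        assert table.loc["organ_hepatic", "p"] == pytest.approx(1.0)

    def test_thyroid_confined_to_seronegative_exact_p(self):
        # 0/17 positive vs 10/43 negative patients with thyroid events:
        # Fisher on [[0, 17], [10, 33]]
        ids = [f"P{i:02d}" for i in range(60)]
        status = self._status(ids, set(ids[:17]))
        events = make_events([(p, "thyroid", 1, 8.0, "definite") for p in ids[17:27]])
        table = compare_serogroups(make_clinical(ids), events, status).set_index(
            "characteristic"
        )
        from scipy import stats

        expected = stats.fisher_exact([[0, 17], [10, 33]])[1]
        assert table.loc["organ_thyroid", "p"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0492, abs=2e-4)

    def test_empty_stratum_skips(self):
        ids = ["P1", "P2"]
        status = self._status(ids, set(ids))  # nobody seronegative
        table = compare_serogroups(make_clinical(ids), make_events([]), status)
        assert table["test"].iloc[0] == "skipped_empty_stratum"
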