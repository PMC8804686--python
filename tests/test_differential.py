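"""Group assignment, Mann-Whitney comparisons, BH adjustment, volcano."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from iraeab.differential import (
    assign_groups,
    compare_antigen,
    run_de,
    volcano_table,
)
from tests.conftest import make_clinical, make_events


class TestAssignGroups:
    def test_organ_grouping_and_attribution_filter(self):
        clin = make_clinical(["P1", "P2", "P3"])
        events = make_events(
            [
                ("P1", "gastrointestinal", 2, 3.0, "probable"),
                ("P2", "gastrointestinal", 2, 3.0, "unlikely"),  # excluded
                ("P3", "hepatic", 1, 4.0, "definite"),
            ]
        )
        ga = assign_groups(events, clin, ("organ", "gastrointestinal"))
        assert ga.group_a == ["P1"]
        assert sorted(ga.group_b) == ["P2", "P3"]

    def test_timing_partition_table1_sizes(self):
        # 38 first events < 6 weeks, 17 >= 6 weeks, 5 with no qualifying event
        ids = [f"P{i:02d}" for i in range(60)]
        rows = [(p, "dermatologic", 1, 2.0, "definite") for p in ids[:38]]
        rows += [(p, "hepatic", 2, 9.0, "probable") for p in ids[38:55]]
        rows += [(p, "sicca", 1, 1.0, "unrelated") for p in ids[55:]]
        ga = assign_groups(make_events(rows), make_clinical(ids), ("timing",))
        assert (len(ga.group_a), len(ga.group_b)) == (38, 17)
        assert (ga.assignment == "excluded").sum() == 5

    def test_severity_matches_recount(self):
        rng = np.random.default_rng(0)
        ids = [f"P{i}" for i in range(40)]
        rows = [
            (p, "hepatic", int(g), 5.0, "definite")
            for p in ids
            for g in rng.integers(1, 6, rng.integers(1, 4))
        ]
        events = make_events(rows)
        ga = assign_groups(events, make_clinical(ids), ("severity",))
        max_grade = events.groupby("patient_id")["grade"].max()
        assert set(ga.group_a) == set(max_grade.index[max_grade >= 3])
        assert set(ga.group_b) == set(max_grade.index[max_grade < 3])

    def test_degenerate_grouping_warns(self):
        ids = ["P1", "P2"]
        events = make_events([(p, "gastrointestinal", 2, 3.0, "definite") for p in ids])
        with pytest.warns(UserWarning, match="degenerate"):
            ga = assign_groups(events, make_clinical(ids), ("organ", "gastrointestinal"))
        assert ga.degenerate

    def test_unknown_spec_rejected(self):
        with pytest.raises(ValueError, match="grouping"):
            assign_groups(make_events([]), make_clinical(["P1", "P2"]), ("bogus",))


class TestCompareAntigen:
    def test_identical_samples(self):
        assert compare_antigen([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])[1] == 1.0
        assert compare_antigen([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_complete_separation_exact_p(self):
        # all 20 rank configurations enumerable; the two extremes give 2/20
        log2fc, p = compare_antigen([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)
        assert log2fc == pytest.approx(-3.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_label_swap_negates_fc_preserves_p(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        fc_ab, p_ab = compare_antigen(a, b)
        fc_ba, p_ba = compare_antigen(b, a)
        assert fc_ab == pytest.approx(-fc_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_p_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 25), rng.normal(0.7, 1, 25)
        _, p1 = compare_antigen(a, b)
        _, p2 = compare_antigen(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestRunDe:
    def test_bh_properties_and_sign_convention(self, default_study, processed_baseline_igg):
        ga = assign_groups(default_study.events, default_study.clinical, ("timing",))
        de = run_de(processed_baseline_igg, ga)
        assert ((de["p_adj"] >= de["p_raw"] - 1e-12) & (de["p_adj"] <= 1.0)).all()
        order = de.sort_values("p_raw")
        assert order["p_adj"].is_monotonic_increasing
        # sign convention spot check against group means
        a = processed_baseline_igg.values.loc[
            [p for p in ga.group_a if p in processed_baseline_igg.values.index]
        ]
        b = processed_baseline_igg.values.loc[
            [p for p in ga.group_b if p in processed_baseline_igg.values.index]
        ]
        antigen = de["antigen"].iloc[0]
        assert de["log2fc"].iloc[0] == pytest.approx(
            a[antigen].mean() - b[antigen].mean()
        )

    def test_degenerate_grouping_empty_result(self, processed_baseline_igg):
        ids = list(processed_baseline_igg.values.index)
        events = make_events([(p, "hepatic", 2, 3.0, "definite") for p in ids])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ga = assign_groups(events, make_clinical(ids), ("organ", "hepatic"))
        with pytest.warns(UserWarning, match="degenerate"):
            de = run_de(processed_baseline_igg, ga)
        assert de.empty


class TestVolcano:
    def _de(self, rows):
        return pd.DataFrame(
            rows,
            columns=["antigen", "log2fc", "p_raw", "p_adj", "significant"],
        ).assign(isotype="IgG", timepoint="baseline", grouping="g", n_a=10, n_b=10)

    def test_all_null_counts_zero(self):
        de = self._de([(f"A{i}", 0.1 * (-1) ** i, 0.8, 0.9, False) for i in range(10)])
        _, counts = volcano_table(de)
        assert counts["event"] == 0 and counts["non_event"] == 0

    def test_sign_convention_left_side(self):
        de = self._de([("A1", -2.0, 0.001, 0.01, True), ("A2", 1.0, 0.5, 0.8, False)])
        table, counts = volcano_table(de)
        assert counts == {
            "non_event": 1, "event": 0, "raw_line_non_event": 1, "raw_line_event": 0,
        }
        assert table.set_index("antigen").loc["A1", "side"] == "non_event"

    def test_planted_negative_shifts_land_left(self):
        from iraeab.config import CohortConfig, PlantedEffect
        from iraeab.synthetic import generate_cohort
        from tests.conftest import process_isotype

        antigens = tuple(f"AG{i + 1:03d}" for i in range(8))
        cfg = CohortConfig(
            seed=9,
            planted_effects=(PlantedEffect(antigens, ("first_half",), "baseline", -1.5),),
            dim_antigen_fraction=0.0,
        )
        study = generate_cohort(cfg)
        matrix, _ = process_isotype(study)
        ga = assign_groups(study.events, study.clinical, ("first_half",))
        de = run_de(matrix, ga)
        _, counts = volcano_table(de)
        assert counts["non_event"] >= 6
        assert counts["event"] == 0
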