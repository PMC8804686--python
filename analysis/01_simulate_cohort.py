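"""Simulate the trial cohort and report its marginal structure.

Generates the default 60-patient study (120 antigens x IgG/IgM at baseline
and week 6, ~15% missing week-6 draws) and writes the fixture tables the
later steps consume.
"""

import runpy
from pathlib import Path

common = runpy.run_path(Path(__file__).parent / "00_common.py")

from iraeab.summary import proportion
from iraeab.synthetic import generate_cohort, qualifying_events, write_fixtures

cohort_cfg, _ = common["configs"]()
study = generate_cohort(cohort_cfg)
write_fixtures(study, common["RUN_DIR"])

n = cohort_cfg.n_patients
week6 = len(study.week6_patients)
qual = qualifying_events(study.events)
max_grade = qual.groupby("patient_id")["grade"].max()
severe = int((max_grade >= 3).sum())
no_event = n - max_grade.index.nunique()

print(f"cohort written to {common['RUN_DIR']}")
print(f"patients: {n}; week-6 plasma: {week6} ({proportion(week6, n, 0)}%)")
print(f"qualifying events: {len(qual)} across {qual['organ'].nunique()} organ systems")
print(f"max grade severe: {severe} ({proportion(severe, n, 1)}%); "
      f"no qualifying irAE: {no_event} ({proportion(no_event, n, 1)}%)")
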