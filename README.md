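# iraeab

Autoantibody profiling of immune-related adverse events (irAE) under
checkpoint-inhibitor therapy.

Combination immune checkpoint inhibition (ipilimumab + nivolumab) for
advanced melanoma causes autoimmune-like toxicities — hepatitis, colitis,
dermatitis, arthritis, thyroiditis and others — in most patients. A natural
question for rheumatologists and oncologists is whether circulating
autoantibodies, measured *before* treatment, mark the patients who will
develop these events. `iraeab` implements the full analysis pipeline for
that question as it applies to autoantigen-microarray data from a
60-patient trial design: plasma drawn at baseline and week 6, a
120-autoantigen array read out in IgG and IgM, commercial ANA/RF/anti-CCP
serology, total immunoglobulins, and prospectively adjudicated adverse
events in nine organ systems.

Because patient-level trial data of this kind are not publicly deposited,
the package ships a first-class synthetic-cohort generator that emulates
the study design (including its marginal structure) with controllable
planted effects, so every stage of the pipeline is testable end to end:
parameter recovery, type-I error and power are validated on simulated
cohorts, and the design's worked-example counts are reproduced exactly by
the bookkeeping code.

## The method

Per array spot, the quantitative readout is the **antibody score**

```
ABS = log2(NFI × SNR + 1)
```

where NFI is the net fluorescence intensity and SNR the signal-to-noise
ratio. Spots with SNR ≥ 3 count as true signals; an antigen is dropped
when SNR < 3 in more than 90% of all samples. Slides are normalized by a
robust linear model on the internal positive-control spots: each sample's
control scores are regressed (Huber M-estimation, c = 1.345) on the
across-sample median control profile and the fitted affine map is
inverted.

Downstream, the pipeline runs:

- **Differential abundance** — per-antigen two-sided Mann-Whitney U tests
  between event and non-event patients (organ-specific, timing < 6 vs ≥ 6
  weeks, severity grade 3–5 vs 1–2), fold change as the difference of mean
  scores (log2 scale), Benjamini–Hochberg adjustment per family, volcano
  tables with per-side significant counts.
- **Patient clustering** — hierarchical clustering (Euclidean, complete
  linkage) of patients on the differentially expressed baseline antigens
  into four intensity subgroups (high/moderate/slightly-low/low), with
  Fisher-exact irAE enrichment per cluster and organ.
- **Longitudinal fold changes** — per-patient week-6 minus baseline score
  changes, Spearman/Kruskal–Wallis association with the number of distinct
  organ systems affected, and the supervised event-profile ordering for
  heatmaps.
- **Serology & survival** — strict-threshold seropositivity (RF > 14
  IU/mL, anti-CCP > 20 U/mL, ANA binary), seroconversion accounting with
  flow identities, seropositive-vs-seronegative comparisons, and
  Kaplan–Meier / log-rank analyses of time to (severe) irAE and of PFS/OS
  in stage IV patients (via lifelines).
- **Immunoglobulins** — IgG/IgM quartile analyses (exact conditional tests
  across quartiles) and a sensitivity check that rescales signals by total
  Ig and re-runs the differential analysis.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic cohort (seed 1), writing tables under `results/run/`:

```
$ python analysis/01_simulate_cohort.py
cohort written to .../results/run
patients: 60; week-6 plasma: 51 (85.0%)
qualifying events: 145 across 9 organ systems
max grade severe: 25 (41.7%); no qualifying irAE: 3 (5.0%)

$ python analysis/02_process_signals.py
IgG: 109 antigens retained of 120
IgM: 110 antigens retained of 120
normalization slopes: mean 0.995, sd 0.062 over 222 slides

$ python analysis/05_longitudinal_fold_change.py
IgG: n=51 (dropped 9 without week-6 draws); Spearman rho=0.806 (p=1.01e-12), ...
IgM: n=51 (dropped 9 without week-6 draws); Spearman rho=0.865 (p=2.55e-16), ...
```

Reading: 51 of 60 patients (85%) have week-6 plasma, matching the design's
15% missingness; about a tenth of the panel sits below the SNR filter;
per-slide normalization slopes scatter tightly around 1; and because the
generator couples week-6 antibody drift to irAE burden, patients with more
distinct irAE show larger fold changes (rho ≈ 0.8), with the no-event
patients showing the least change. Steps 03–08 cover differential
abundance, clustering with enrichment, serology/survival, immunoglobulins
and the cohort summary table.

The same pipeline is scriptable through the `iraeab` CLI
(`simulate`, `process`, `de`, `cluster`, `longitudinal`, `survival`, `ig`,
`summary`, `all`), with `--config` (YAML), `--seed` and `--outdir`.

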