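# Methods

## Study design being emulated

The pipeline targets the design of a prospective single-tumor-type trial
cohort: 60 patients with unresectable stage III/IV melanoma on combination
ipilimumab + nivolumab, plasma at baseline and week 6 (about 15% of week-6
draws missing), a 120-autoantigen fluorescence array read out in IgG and
IgM with internal positive-control spots, ANA/RF/anti-CCP serology, total
immunoglobulins by nephelometry, and adverse events in nine organ systems
(hepatic, gastrointestinal, dermatologic, arthritis/arthralgia,
myocarditis, myositis/myalgia, sicca, thyroid, non-thyroid endocrine) with
CTCAE grades 1–5 and attribution calls; only events attributed
*definitely* or *probably* to treatment enter any analysis, and grade 3–5
counts as severe. Median follow-up is 25 months; PFS/OS analyses are
restricted to stage IV patients.

## Signal model and processing

**Score.** ABS = log2(NFI × SNR + 1) per spot. Negative NFI (possible
after upstream background subtraction) clamps to 0 with a warning, keeping
the log defined while flagging quality; non-finite inputs are errors.

**True-signal rule and panel filter.** SNR ≥ 3 flags a true signal. An
antigen is removed when the fraction of samples with SNR < 3 strictly
exceeds 0.90, pooling both timepoints within an isotype ("all samples").
Scores of sub-threshold cells on retained antigens are still used by the
statistics — the filter removes antigens, not cells — with the mask
carried for reporting.

**Normalization.** Each sample (slide = patient × timepoint × isotype) is
regressed on the across-sample median control profile: Huber M-estimation
with tuning constant 1.345, MAD scale, ≤ 50 iterations, tolerance 1e-8,
intercept included; sample scores are passed through the inverse fitted
affine map. The fit is a small in-package IRLS validated against
statsmodels' RLM to ~1e-5 in the tests; degenerate controls (zero
variance) fall back to median-ratio scaling and are logged. Normalization
brings every sample into the median-profile frame: planted affine
distortions are removed exactly (samples with common underlying biology
collapse onto one row to 1e-6 on noiseless controls), and the procedure is
idempotent — renormalizing returns slopes of 1 within 1e-6. The exact
robust formulation used by array core facilities is not standardized; this
affine control-profile regression is one defensible choice and is isolated
behind a single function for substitution.

## Statistics

**Differential abundance.** Two-sided Mann-Whitney U per antigen; exact
null distribution when the pooled size is ≤ 20 without ties, tie-corrected
normal approximation otherwise. The fold change is the difference of group
mean scores (the score is already log2, so linear FC = 2^log2fc), positive
when higher in the event group. Benjamini–Hochberg runs across the
retained antigens of one (isotype, timepoint, grouping) family; the DE
sets fed to clustering use adjusted p < alpha (default 0.05), while
volcano tables also report raw-p counts at the conventional 0.05 plot
line, since both conventions appear in practice. The timing dichotomy is
first qualifying event < 6 vs ≥ 6 weeks.

**Clustering.** Euclidean distance on patient score rows over the DE
antigen set, complete linkage (the classic hclust default), tree cut at
k = 4; clusters are labeled high/moderate/slightly-low/low by descending
mean score. The DE set is the union of significant antigens over the nine
organ-specific baseline comparisons of the configured isotype (IgG by
default); when that union is empty — common on null cohorts — it falls
back to raw-p hits and then to the whole retained panel, with a log
message. Enrichment per (cluster, organ) is a two-sided Fisher exact test
of in-cluster vs out-of-cluster event counts, highlighted at p < 0.05 with
the direction read off the event-rate comparison.

**Longitudinal.** FC = week-6 score − baseline score per patient and
antigen, only for patients with both draws (the rest are listed in a
report). "Higher FCs" is operationalized as the per-patient mean |FC| over
the DE antigen set — direction-agnostic, since both signs represent change
— with the signed mean reported alongside. Association with the
distinct-organ irAE count uses Spearman correlation plus Kruskal–Wallis
across count strata, consistent with the rest of the nonparametric
toolkit. The supervised heatmap ordering puts event patients first (by
count, then mean |FC|, both descending) and preserves input order within
the no-event block.

**Serology and survival.** RF > 14 IU/mL and anti-CCP > 20 U/mL are
positive (strict inequalities); ANA is ingested as the binary
immunofluorescence call, without titer modeling. Missing week-6 draws are
unknown at week 6 (excluded from week-6 denominators) and contribute
nothing to "any timepoint" positivity. Seroconversion accounting asserts
week6 = baseline + gained − lost (among both-draw patients) and
ever = baseline + gained on every cohort. Group comparisons use Wilcoxon
rank-sum for continuous traits and Fisher's exact test for categorical
ones, switching to chi-square when all expected counts are ≥ 5.
Kaplan–Meier estimation and log-rank testing go through lifelines; the
median is the earliest time with S ≤ 0.5, undefined when never reached.
irAE endpoints run in weeks from the first dose with event-free patients
censored at last follow-up (supplied per patient in the clinical table,
25 months by default); PFS/OS run in months, stage IV only.

**Immunoglobulins.** Quartiles use the linear-interpolation sample
quantile definition; equal values always share a label, and colliding cut
points are flagged degenerate. Across-quartile tests of binary traits use
an exact conditional R×2 test (Fisher–Freeman–Halton) computed by
enumeration over tables with the observed margins — no installed Python
package exposes an r×c exact test — cross-checked against R's
`fisher.test` and against the 2×2 Fisher test. The Ig-normalization
sensitivity check divides each patient's linear signal (NFI × SNR) by
their total Ig of the matching isotype relative to the cohort median,
re-scores, re-runs the DE stage, and reports fold-change sign concordance,
rank correlation, and the Jaccard overlap of significant sets.

**Summary arithmetic.** All n (%) values go through one function: 100·n/d
rounded half-up at the requested precision — note half-up, not
truncation, so e.g. 2/43 reports as 4.7%, not 4.6%.

## The synthetic generator

The generator draws scores, not intensities: each antigen has a cohort
mean score (uniform on 3.5–8.5; lognormal in intensity), a configurable
10% of the panel is "dim" (mean 0.5–2.0) so the SNR filter has real work,
patients carry a global-reactivity offset (SD 0.3), and spots add
independent noise (SD 1.0). SNR tracks the score
(log2 SNR = ABS − 2 + noise, SD 0.8) so dim spots fall below 3. Each slide
applies an affine distortion (scale SD 0.06, offset SD 0.25) to scores and
control spots alike; NFI is back-computed as (2^ABS − 1)/SNR so re-scoring
recovers the planted quantities exactly. Week-6 scores drift from baseline
with a per-patient SD of 0.3 × (1 + 0.3 × distinct-organ irAE count),
which builds in the observed coupling between fold change and irAE burden
and makes no-event patients the least-changed. Planted effects add a
stated shift on the score scale to one patient group (organ, timing,
severity, or a deterministic half-split used for calibration) at one
timepoint.

Events arrive independently per organ with rates chosen once to reproduce
the emulated cohort's marginal structure (≈8% with no qualifying event,
≈47% with a severe one, median 2–3 distinct organs); onset weeks are
lognormal around per-organ medians (dermatologic and myocarditis 2.4,
hepatic 5.3, gastrointestinal 6.3, arthritis 11.5, non-thyroid endocrine
11.7; organs without a reported median get mid-range values: thyroid 8,
myositis 7, sicca 10). Severe events onset later (×2), with the organ's
overall median analytically preserved. Attribution is sampled mostly
definite/probable (55/30/8/4/3%), since downstream filters keep only the
first two. Serology rates (ANA 23.3% baseline, RF titers lognormal with
~7% above threshold, CCP essentially negative at baseline, small titer
drift to week 6) reproduce the design's ~28% baseline any-positivity.
Week-6 missingness is completely at random, exactly round(0.15 × n)
patients, and removes the plasma draw as a whole (signals and serology).
One global seed fans out to per-component substreams, so cohorts are
byte-for-byte reproducible and components can be regenerated
independently.

What the generator does *not* emulate: spatial slide artifacts, batch
effects beyond per-slide affine distortion, antigen–antigen correlation
(each antigen is independent), informative missingness, competing risks
between events, or any tumor-response process. Passing tests therefore
show the pipeline's statistics are correct and calibrated under a clean
version of the design — not that the biological findings would replicate
on real arrays.

## Calibration and problem sizes

The validation suite runs: a 500-seed null study (no planted effects,
120 antigens, 30-vs-30 split) confirming BH keeps the empirical FDR at
0.05; a 200-seed power study (1.5-score shifts on 10 antigens, 30 vs 30)
confirming median fold-change recovery within ±0.1 and ≥80% adjusted-significance
on planted antigens; 100-seed exact recovery (ARI = 1) of four intensity
groups at 5-SD separation; KM median within 2% of the exponential closed
form at n = 10⁴ and a 1000-seed log-rank null rejection rate of 5% ± 1.5%;
and seroconversion identities fuzzed over 100 cohorts. Calibration cohorts
use a fully-bright panel (dim fraction 0) so planted antigens are never
dropped by the SNR filter, and the half-split grouping so group sizes are
exactly 30/30. These sizes were chosen as the smallest that pin each
property down to its stated tolerance.

## Known limitations

- The robust-normalization formulation, the DE-set choice for clustering,
  and the "higher FC" summary are all defensible readings of
  under-specified conventions; each is isolated behind one function and
  configurable where alternatives are plausible.
- The organ-specific event groupings overlap (a patient can be in several
  event groups), so organ comparisons are not independent — as in the
  emulated design, where no clean control group exists.
- Exact R×2 enumeration is exponential in the number of rows; it is
  intended for quartile-sized tables (4×2 at n ≤ a few hundred). Wider
  categorical tables fall back to chi-square.
- GPR-like ingestion covers the header-block + column-table dialect with
  standard column names only; it is a convenience path, not a full parser
  for every scanner export.
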