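"""End-to-end pipeline: simulate -> score/filter/normalize -> differential
abundance -> clustering -> longitudinal fold changes -> serology & survival
-> immunoglobulins -> cohort summary.

Each stage is a function over a run directory so the CLI subcommands and
the numbered analysis drivers stay thin. ``run_pipeline`` chains them and
writes a provenance manifest (seed, config hash, package version).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, CohortConfig, ORGAN_CATEGORIES
from .clustering import cluster_enrichment, cluster_patients
from .differential import assign_groups, run_de, volcano_table
from .immunoglobulin import (
    assign_quartiles,
    ig_normalized_sensitivity,
    quartile_associations,
)
from .longitudinal import fc_vs_irae_count, fold_changes, supervised_order
from .serology import classify_serostatus, compare_serogroups, seroconversion_accounting
from .signal import build_abs_matrices, filter_antigens, load_signals, normalize_rlm
from .summary import summarize, summary_frame
from .survival import build_time_to_event, km_by_stratum
from .synthetic import generate_cohort, load_fixtures, write_fixtures

logger = logging.getLogger(__name__)

#: Baseline groupings examined for differential abundance.
def default_groupings() -> list[tuple[str, ...]]:
    return [("organ", organ) for organ in ORGAN_CATEGORIES] + [("timing",), ("severity",)]


def stage_simulate(config: CohortConfig, outdir: Path) -> dict:
    study = generate_cohort(config)
    write_fixtures(study, outdir)
    logger.info("simulated %d patients, %d signal rows", config.n_patients, len(study.signals))
    return {"n_patients": config.n_patients, "n_signal_rows": len(study.signals)}


def stage_process(outdir: Path) -> dict:
    """Score, filter and normalize; writes per-(isotype, timepoint) matrices."""
    signals = load_signals(outdir / "signals.tsv")
    retained: dict[str, list[str]] = {}
    reports = []
    for isotype in sorted(signals.loc[~signals["is_control"].astype(bool), "isotype"].unique()):
        kept, report = filter_antigens(signals, isotype=isotype)
        retained[isotype] = kept
        reports.append(report.assign(isotype=isotype))
    pd.concat(reports, ignore_index=True).to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    matrices = build_abs_matrices(signals, retained=retained)
    norm_reports = []
    for (isotype, timepoint), matrix in matrices.items():
        normalized, report = normalize_rlm(matrix)
        matrices[(isotype, timepoint)] = normalized
        norm_reports.append(report.assign(isotype=isotype, timepoint=timepoint))
        normalized.values.to_csv(outdir / f"abs_matrix_{isotype}_{timepoint}.tsv", sep="\t")
        normalized.mask.astype(int).to_csv(outdir / f"abs_mask_{isotype}_{timepoint}.tsv", sep="\t")
    pd.concat(norm_reports, ignore_index=True).to_csv(
        outdir / "normalization_report.tsv", sep="\t", index=False
    )
    return {iso: len(kept) for iso, kept in retained.items()}


def _read_matrix(outdir: Path, isotype: str, timepoint: str):
    from .signal import AbsMatrix

    path = outdir / f"abs_matrix_{isotype}_{timepoint}.tsv"
    if not path.exists():
        raise FileNotFoundError(f"run the process stage first: missing {path}")
    values = pd.read_csv(path, sep="\t", index_col=0)
    mask = pd.read_csv(outdir / f"abs_mask_{isotype}_{timepoint}.tsv", sep="\t", index_col=0).astype(bool)
    return AbsMatrix(values=values, mask=mask, isotype=isotype, timepoint=timepoint,
                     normalization="normalized")


def stage_de(outdir: Path, analysis: AnalysisConfig) -> pd.DataFrame:
    study = load_fixtures(outdir)
    results = []
    isotypes = sorted(study.signals.loc[~study.signals["is_control"].astype(bool), "isotype"].unique())
    for isotype in isotypes:
        matrix = _read_matrix(outdir, isotype, "baseline")
        for spec in default_groupings():
            grouping = assign_groups(study.events, study.clinical, spec)
            if grouping.degenerate:
                continue
            de = run_de(matrix, grouping, alpha=analysis.alpha)
            results.append(de)
            if not de.empty:
                table, counts = volcano_table(de)
                table.to_csv(outdir / f"volcano_{isotype}_{grouping.name}.tsv", sep="\t", index=False)
    de_all = pd.concat(results, ignore_index=True) if results else pd.DataFrame()
    de_all.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    return de_all


def de_antigen_set(de_all: pd.DataFrame, isotype: str, alpha: float) -> list[str]:
    """Union of significant antigens over the organ-specific baseline
    comparisons of one isotype, falling back to raw-p hits, then to the
    whole retained panel."""
    de = de_all[
        (de_all["isotype"] == isotype) & (de_all["grouping"].str.startswith("organ_"))
    ]
    chosen = sorted(de.loc[de["significant"], "antigen"].unique())
    if not chosen:
        chosen = sorted(de.loc[de["p_raw"] < alpha, "antigen"].unique())
    if not chosen:
        logger.warning("no DE antigens for %s; using the full retained panel", isotype)
        chosen = sorted(de["antigen"].unique())
    return chosen


def clustering_antigen_set(de_all: pd.DataFrame, analysis: AnalysisConfig) -> list[str]:
    return de_antigen_set(de_all, analysis.clustering_isotype, analysis.alpha)


def stage_cluster(outdir: Path, analysis: AnalysisConfig) -> pd.DataFrame:
    study = load_fixtures(outdir)
    de_all = pd.read_csv(outdir / "de_results.tsv", sep="\t")
    antigens = clustering_antigen_set(de_all, analysis)
    matrix = _read_matrix(outdir, analysis.clustering_isotype, "baseline")
    result = cluster_patients(matrix.values[antigens], k=analysis.n_clusters,
                              method=analysis.linkage)
    result.assignments.rename("cluster").to_csv(outdir / "clusters.tsv", sep="\t")
    enrichment = cluster_enrichment(result, study.events)
    enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return enrichment


def stage_longitudinal(outdir: Path, analysis: AnalysisConfig) -> dict:
    study = load_fixtures(outdir)
    de_all = pd.read_csv(outdir / "de_results.tsv", sep="\t")
    out = {}
    for isotype in de_all["isotype"].unique():
        base = _read_matrix(outdir, isotype, "baseline")
        week6 = _read_matrix(outdir, isotype, "week6")
        antigens = de_antigen_set(de_all, isotype, analysis.alpha)
        antigens = [a for a in antigens if a in base.values.columns]
        fc = fold_changes(base.values[antigens], week6.values[antigens])
        fc.values.to_csv(outdir / f"fc_matrix_{isotype}.tsv", sep="\t")
        assoc = fc_vs_irae_count(fc, study.events)
        ordered, indicator = supervised_order(fc, study.events)
        indicator.to_csv(outdir / f"event_indicator_{isotype}.tsv", sep="\t")
        out[isotype] = {
            "n_patients": assoc["n"],
            "spearman_rho": assoc["spearman_rho"],
            "spearman_p": assoc["spearman_p"],
            "kruskal_p": assoc["kruskal_p"],
            "dropped_patients": len(fc.dropped_patients),
        }
    with open(outdir / "fc_association.json", "w") as fh:
        json.dump(out, fh, indent=2, default=float)
    return out


def stage_survival(outdir: Path, analysis: AnalysisConfig) -> dict:
    study = load_fixtures(outdir)
    status = classify_serostatus(study.serology, rf_threshold=analysis.rf_threshold,
                                 ccp_threshold=analysis.ccp_threshold)
    status.to_csv(outdir / "serostatus.tsv", sep="\t")
    flow = seroconversion_accounting(status)
    comparison = compare_serogroups(study.clinical, study.events, status)
    comparison.to_csv(outdir / "serogroup_comparison.tsv", sep="\t", index=False)
    strata = pd.Series(
        np.where(status["any_positive_baseline"] == 1, "seropositive", "seronegative"),
        index=status.index,
    )
    out: dict = {"seroconversion": flow, "logrank": {}}
    for endpoint in ("first_irae", "first_severe_irae", "pfs", "os"):
        tte = build_time_to_event(study.events, study.clinical, study.survival,
                                  endpoint, strata=strata)
        curves, (stat, p) = km_by_stratum(tte)
        frames = []
        for label, est in curves.items():
            frames.append(est.curve.assign(stratum=label))
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / f"km_{endpoint}.tsv", sep="\t", index=False
        )
        out["logrank"][endpoint] = {
            "statistic": None if np.isnan(stat) else stat,
            "p": None if np.isnan(p) else p,
            "medians": {k: (None if np.isnan(v.median) else v.median) for k, v in curves.items()},
        }
    with open(outdir / "survival_summary.json", "w") as fh:
        json.dump(out, fh, indent=2, default=float)
    return out


def stage_ig(outdir: Path, analysis: AnalysisConfig) -> dict:
    study = load_fixtures(outdir)
    ig = study.ig_levels.set_index("patient_id")
    out: dict = {}
    for isotype, column in (("IgG", "igg_mg_dl"), ("IgM", "igm_mg_dl")):
        quartiles, degenerate = assign_quartiles(ig[column])
        assoc = quartile_associations(quartiles, study.clinical, study.events,
                                      study.survival, levels=ig[column])
        assoc.to_csv(outdir / f"ig_quartile_{isotype}.tsv", sep="\t", index=False)
        matrix = _read_matrix(outdir, isotype, "baseline")
        grouping = assign_groups(study.events, study.clinical, ("any_irae",))
        if grouping.degenerate:
            sens = {"skipped": "degenerate any-irae grouping"}
        else:
            sens = ig_normalized_sensitivity(matrix, ig[column], grouping, alpha=analysis.alpha)
        out[isotype] = {"degenerate_quartiles": degenerate, "sensitivity": sens}
    with open(outdir / "ig_sensitivity.json", "w") as fh:
        json.dump(out, fh, indent=2, default=float)
    return out


def stage_summary(outdir: Path, analysis: AnalysisConfig) -> pd.DataFrame:
    study = load_fixtures(outdir)
    status = classify_serostatus(study.serology, rf_threshold=analysis.rf_threshold,
                                 ccp_threshold=analysis.ccp_threshold)
    table = summary_frame(summarize(study.clinical, study.events, status))
    table.to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False)
    return table


STAGES = ("simulate", "process", "de", "cluster", "longitudinal", "survival", "ig", "summary")


def run_pipeline(
    config: CohortConfig,
    analysis: AnalysisConfig,
    outdir: str | Path,
) -> Path:
    """Run every stage into ``outdir`` and write a provenance manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_simulate(config, outdir)
    stage_process(outdir)
    stage_de(outdir, analysis)
    stage_cluster(outdir, analysis)
    stage_longitudinal(outdir, analysis)
    stage_survival(outdir, analysis)
    stage_ig(outdir, analysis)
    stage_summary(outdir, analysis)
    manifest = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "alpha": analysis.alpha,
        "linkage": analysis.linkage,
        "version": __version__,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
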