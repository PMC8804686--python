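"""Synthetic study generator.

Emulates the structure of a 60-patient combination-ICI melanoma trial with
autoantigen-microarray profiling at baseline and week 6: spot-level array
signals (NFI/SNR) for 120 antigens x 2 isotypes with internal
positive-control spots, a clinical table, organ-categorized adverse events
with CTCAE grades and attribution calls, ANA/RF/anti-CCP serology, total
immunoglobulin levels and PFS/OS follow-up.

The signal model works on the antibody-score scale (ABS = log2(NFI*SNR+1)):
scores are drawn normally per antigen (lognormal in intensity), planted
group effects are added on that scale, a per-slide affine distortion is
applied, and NFI is back-computed from the distorted score and the drawn
SNR so that downstream re-scoring recovers the planted quantities exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    ATTRIBUTIONS,
    CohortConfig,
    ConfigurationError,
    QUALIFYING_ATTRIBUTIONS,
)

SIGNAL_COLUMNS = ["patient_id", "timepoint", "isotype", "antigen", "is_control", "nfi", "snr"]

_FIXTURE_FILES = {
    "signals": "signals.tsv",
    "clinical": "clinical.tsv",
    "events": "events.tsv",
    "serology": "serology.tsv",
    "ig_levels": "ig.tsv",
    "survival": "survival.tsv",
}


@dataclass
class SyntheticStudy:
    """One generated study: all tables a real trial export would provide."""

    config: CohortConfig
    signals: pd.DataFrame
    clinical: pd.DataFrame
    events: pd.DataFrame
    serology: pd.DataFrame
    ig_levels: pd.DataFrame
    survival: pd.DataFrame

    @property
    def week6_patients(self) -> list[str]:
        """Patients with a week-6 plasma draw."""
        mask = self.clinical["has_week6"].astype(bool)
        return self.clinical.loc[mask, "patient_id"].tolist()


def qualifying_events(events: pd.DataFrame) -> pd.DataFrame:
    """Events attributed definitely or probably to the ICI."""
    if events.empty:
        return events
    return events[events["attribution"].isin(QUALIFYING_ATTRIBUTIONS)]


def distinct_organ_counts(events: pd.DataFrame, patient_ids: list[str]) -> pd.Series:
    """Number of distinct organ systems with a qualifying event, per patient."""
    counts = pd.Series(0, index=pd.Index(patient_ids, name="patient_id"))
    qual = qualifying_events(events)
    if not qual.empty:
        observed = qual.groupby("patient_id")["organ"].nunique()
        counts.loc[observed.index.intersection(counts.index)] = observed
    return counts


def _mixture_median_shift(severe_p: float, mult: float, log_sd: float) -> float:
    """Median inflation of a lognormal onset mixture where a ``severe_p``
    fraction is multiplied by ``mult`` (relative to the unmixed median)."""
    if severe_p <= 0 or mult == 1.0 or log_sd <= 0:
        return 1.0
    from scipy.optimize import brentq
    from scipy.stats import norm

    def cdf_at(x: float) -> float:
        return (1 - severe_p) * norm.cdf(x / log_sd) + severe_p * norm.cdf(
            (x - np.log(mult)) / log_sd
        )

    x = brentq(lambda v: cdf_at(v) - 0.5, -10, 10)
    return float(np.exp(x))


def _rngs(seed: int, n: int = 8) -> list[np.random.Generator]:
    # One root seed fans out to independent substreams so each component
    # (clinical, events, serology, ...) is reproducible on its own.
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _generate_clinical(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    patients = config.patient_ids()
    age = np.clip(np.round(rng.normal(61, 12, n)), 25, 92).astype(int)
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    stage = np.where(rng.random(n) < config.stage_iv_fraction, "IV", "III")
    types = list(config.melanoma_type_probs)
    probs = np.array([config.melanoma_type_probs[t] for t in types], dtype=float)
    melanoma_type = rng.choice(types, size=n, p=probs / probs.sum())
    cycles = np.maximum(1, np.round(rng.lognormal(np.log(5.5), 1.0, n))).astype(int)
    n_missing = int(round(config.week6_missing_fraction * n))
    missing_idx = rng.choice(n, size=n_missing, replace=False)
    has_week6 = np.ones(n, dtype=bool)
    has_week6[missing_idx] = False
    return pd.DataFrame(
        {
            "patient_id": patients,
            "age": age,
            "sex": sex,
            "stage": stage,
            "melanoma_type": melanoma_type,
            "ici_cycles": cycles,
            "has_week6": has_week6,
        }
    )


def generate_events(
    config: CohortConfig,
    patient_ids: list[str],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw adverse events per patient with organ-specific onset distributions.

    Each organ occurs independently with its configured rate; an affected
    organ contributes 1 + Poisson extra events.  Onset weeks are lognormal
    around the organ's median; grades split mild (1-2) vs severe (3-5) with
    an organ-specific severe probability; attribution is sampled over the
    five trial categories.
    """
    if rng is None:
        rng = _rngs(config.seed)[1]
    n = len(patient_ids)
    organs = [o for o in config.organ_categories if config.organ_rates.get(o, 0) > 0]
    rows: dict[str, list] = {k: [] for k in ("patient_id", "organ", "grade", "onset_week", "attribution")}
    attr_probs = np.array([config.attribution_probs.get(a, 0.0) for a in ATTRIBUTIONS])
    attr_probs = attr_probs / attr_probs.sum()
    for organ in organs:
        rate = min(1.0, config.organ_rates[organ] * config.event_rate_scale)
        if rate <= 0:
            continue
        affected = rng.random(n) < rate
        counts = np.where(affected, 1 + rng.poisson(config.extra_event_rate, n), 0)
        total = int(counts.sum())
        if total == 0:
            continue
        pid = np.repeat(np.asarray(patient_ids, dtype=object), counts)
        severe_p = config.severe_probs.get(organ, 0.2)
        onset = rng.lognormal(np.log(config.onset_medians[organ]), config.onset_log_sd, total)
        severe = rng.random(total) < severe_p
        # Severe events onset later; rescale so the organ's overall median
        # stays at its configured value.
        mult = config.severe_onset_multiplier
        onset = np.where(severe, onset * mult, onset)
        onset = onset / _mixture_median_shift(severe_p, mult, config.onset_log_sd)
        mild_grade = rng.choice([1, 2], size=total, p=[0.6, 0.4])
        severe_grade = rng.choice([3, 4, 5], size=total, p=[0.92, 0.06, 0.02])
        grade = np.where(severe, severe_grade, mild_grade)
        attribution = rng.choice(ATTRIBUTIONS, size=total, p=attr_probs)
        rows["patient_id"].extend(pid)
        rows["organ"].extend([organ] * total)
        rows["grade"].extend(grade.tolist())
        rows["onset_week"].extend(np.round(onset, 2).tolist())
        rows["attribution"].extend(attribution.tolist())
    events = pd.DataFrame(rows, columns=["patient_id", "organ", "grade", "onset_week", "attribution"])
    events = events.sort_values(["patient_id", "onset_week", "organ"], kind="stable").reset_index(drop=True)
    events["grade"] = events["grade"].astype(int)
    return events


def _generate_serology(
    config: CohortConfig, clinical: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n = config.n_patients
    ana0 = rng.random(n) < config.ana_baseline_rate
    stay = rng.random(n) < config.ana_persist_prob
    gain = rng.random(n) < config.ana_gain_prob
    ana6 = np.where(ana0, stay, gain)
    rf0 = rng.lognormal(config.rf_log_mean, config.rf_log_sd, n)
    ccp0 = rng.lognormal(config.ccp_log_mean, config.ccp_log_sd, n)
    rf6 = rf0 * np.exp(rng.normal(0, config.titer_drift_sd, n))
    ccp6 = ccp0 * np.exp(rng.normal(0, config.titer_drift_sd, n))
    base = pd.DataFrame(
        {
            "patient_id": clinical["patient_id"],
            "timepoint": "baseline",
            "ana_positive": ana0.astype(int),
            "rf_iu_ml": np.round(rf0, 2),
            "ccp_u_ml": np.round(ccp0, 2),
        }
    )
    week6 = pd.DataFrame(
        {
            "patient_id": clinical["patient_id"],
            "timepoint": "week6",
            "ana_positive": ana6.astype(int),
            "rf_iu_ml": np.round(rf6, 2),
            "ccp_u_ml": np.round(ccp6, 2),
        }
    )
    week6 = week6[clinical["has_week6"].to_numpy()]
    return pd.concat([base, week6], ignore_index=True)


def _generate_ig(config: CohortConfig, clinical: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    shift = np.where(clinical["sex"].to_numpy() == "female", config.igg_female_shift, 0.0)
    igg = np.clip(rng.normal(config.igg_mean, config.igg_sd, n) + shift, 250, None)
    igm = rng.lognormal(config.igm_log_mean, config.igm_log_sd, n)
    return pd.DataFrame(
        {
            "patient_id": clinical["patient_id"],
            "igg_mg_dl": np.round(igg, 1),
            "igm_mg_dl": np.round(igm, 1),
        }
    )


def _generate_survival(
    config: CohortConfig, clinical: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    n = config.n_patients
    ln2 = np.log(2)
    pfs_raw = rng.exponential(config.pfs_median_months / ln2, n)
    os_extra = rng.exponential(config.os_median_months / ln2, n)
    os_raw = np.maximum(pfs_raw, os_extra)
    followup = np.minimum(config.followup_months, os_raw)
    pfs_event = pfs_raw <= followup + 1e-9
    os_event = os_raw <= config.followup_months
    survival = pd.DataFrame(
        {
            "patient_id": clinical["patient_id"],
            "stage": clinical["stage"],
            "pfs_months": np.round(np.minimum(pfs_raw, followup), 2),
            "pfs_event": pfs_event.astype(int),
            "os_months": np.round(np.minimum(os_raw, config.followup_months), 2),
            "os_event": os_event.astype(int),
        }
    )
    return survival, np.round(followup, 2)


def _planted_group(
    effect_grouping: tuple[str, ...],
    events: pd.DataFrame,
    clinical: pd.DataFrame,
) -> set[str]:
    # Local import: differential owns the grouping semantics.
    from .differential import assign_groups

    assignment = assign_groups(events, clinical, effect_grouping)
    return set(assignment.group_a)


def _generate_signals(
    config: CohortConfig,
    clinical: pd.DataFrame,
    events: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n, m = config.n_patients, config.n_antigens
    patients = config.patient_ids()
    antigens = np.array(config.antigen_labels(), dtype=object)
    controls = np.array(config.control_labels(), dtype=object)
    n_iso = len(config.isotypes)

    # Antigen-specific mean scores; a configured fraction of the panel is
    # "dim" (near background) so the >90%-below-SNR-3 filter has work to do.
    n_dim = int(round(config.dim_antigen_fraction * m))
    dim_idx = rng.choice(m, size=n_dim, replace=False)
    mu = rng.uniform(*config.bright_abs_mean_range, size=(n_iso, m))
    mu[:, dim_idx] = rng.uniform(*config.dim_abs_mean_range, size=(n_iso, n_dim))
    patient_offset = rng.normal(0, config.patient_offset_sd, n)

    # True baseline scores: (iso, patient, antigen)
    abs_base = mu[:, None, :] + patient_offset[None, :, None]
    abs_base = abs_base + rng.normal(0, config.spot_noise_sd, (n_iso, n, m))

    # Week-6 drift scales with the patient's distinct-organ irAE burden.
    organ_counts = distinct_organ_counts(events, patients).to_numpy()
    drift_sd = config.fc_base_sd * (1 + config.fc_event_coupling * organ_counts)
    abs_week6 = abs_base + rng.normal(0, 1.0, (n_iso, n, m)) * drift_sd[None, :, None]

    abs_by_tp = {"baseline": abs_base, "week6": abs_week6}
    antigen_pos = {a: i for i, a in enumerate(antigens)}
    for effect in config.planted_effects:
        group = _planted_group(effect.grouping, events, clinical)
        p_mask = np.array([p in group for p in patients])
        a_idx = [antigen_pos[a] for a in effect.antigens]
        target = abs_by_tp[effect.timepoint]
        target[np.ix_(range(n_iso), np.where(p_mask)[0], a_idx)] += effect.effect_abs

    # SNR tracks the (true) score, so dim spots fall under the threshold.
    profile = np.linspace(*config.control_profile_range, config.n_control_spots)
    has_week6 = clinical["has_week6"].to_numpy()
    frames = []
    for tp in config.timepoints:
        abs_true = np.clip(abs_by_tp[tp], 0, None)
        log2_snr = abs_true - config.snr_pivot + rng.normal(0, config.snr_noise_sd, abs_true.shape)
        snr = np.clip(np.exp2(log2_snr), 0.05, 500.0)
        # Per-slide affine distortion (patient x isotype), removed later by
        # control-based normalization.
        scale = np.clip(rng.normal(1.0, config.sample_scale_sd, (n_iso, n)), 0.5, None)
        offset = rng.normal(0.0, config.sample_offset_sd, (n_iso, n))
        abs_obs = np.clip(scale[:, :, None] * abs_true + offset[:, :, None], 0, None)
        nfi = (np.exp2(abs_obs) - 1.0) / snr
        ctrl_obs = (
            scale[:, :, None] * profile[None, None, :]
            + offset[:, :, None]
            + rng.normal(0, config.control_noise_sd, (n_iso, n, config.n_control_spots))
        )
        ctrl_obs = np.clip(ctrl_obs, 0, None)
        ctrl_nfi = (np.exp2(ctrl_obs) - 1.0) / config.control_snr
        keep = np.ones(n, dtype=bool) if tp == "baseline" else has_week6
        kept = np.where(keep)[0]
        n_kept = len(kept)
        for i, iso in enumerate(config.isotypes):
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": np.repeat(np.asarray(patients, dtype=object)[kept], m),
                        "timepoint": tp,
                        "isotype": iso,
                        "antigen": np.tile(antigens, n_kept),
                        "is_control": 0,
                        "nfi": np.round(nfi[i, kept, :].ravel(), 4),
                        "snr": np.round(snr[i, kept, :].ravel(), 4),
                    }
                )
            )
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": np.repeat(np.asarray(patients, dtype=object)[kept], config.n_control_spots),
                        "timepoint": tp,
                        "isotype": iso,
                        "antigen": np.tile(controls, n_kept),
                        "is_control": 1,
                        "nfi": np.round(ctrl_nfi[i, kept, :].ravel(), 4),
                        "snr": config.control_snr,
                    }
                )
            )
    signals = pd.concat(frames, ignore_index=True)[SIGNAL_COLUMNS]
    return signals


def generate_cohort(config: CohortConfig) -> SyntheticStudy:
    """Generate a complete synthetic study, deterministically for a fixed seed."""
    if not isinstance(config, CohortConfig):
        raise ConfigurationError("config must be a CohortConfig")
    r_clin, r_events, r_sero, r_ig, r_surv, r_sig, *_ = _rngs(config.seed)
    clinical = _generate_clinical(config, r_clin)
    events = generate_events(config, clinical["patient_id"].tolist(), r_events)
    serology = _generate_serology(config, clinical, r_sero)
    ig_levels = _generate_ig(config, clinical, r_ig)
    survival, followup = _generate_survival(config, clinical, r_surv)
    clinical = clinical.assign(followup_months=followup)
    signals = _generate_signals(config, clinical, events, r_sig)
    return SyntheticStudy(
        config=config,
        signals=signals,
        clinical=clinical,
        events=events,
        serology=serology,
        ig_levels=ig_levels,
        survival=survival,
    )


def write_fixtures(study: SyntheticStudy, directory: str | os.PathLike) -> dict[str, Path]:
    """Write the study as TSV files plus a manifest; returns written paths."""
    out = Path(directory)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc
    paths: dict[str, Path] = {}
    for attr, filename in _FIXTURE_FILES.items():
        path = out / filename
        table: pd.DataFrame = getattr(study, attr)
        try:
            table.to_csv(path, sep="\t", index=False)
        except OSError as exc:
            raise OSError(f"cannot write fixture {path}: {exc}") from exc
        paths[attr] = path
    manifest = {
        "seed": study.config.seed,
        "config_hash": study.config.content_hash(),
        "n_patients": study.config.n_patients,
        "n_antigens": study.config.n_antigens,
        "files": {k: p.name for k, p in paths.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths


def load_fixtures(directory: str | os.PathLike) -> SyntheticStudy:
    """Read a fixture directory written by :func:`write_fixtures`."""
    out = Path(directory)
    tables = {}
    for attr, filename in _FIXTURE_FILES.items():
        path = out / filename
        if not path.exists():
            raise FileNotFoundError(f"missing fixture file {path}")
        tables[attr] = pd.read_csv(path, sep="\t")
    manifest = json.loads((out / "manifest.json").read_text())
    config = CohortConfig(seed=int(manifest["seed"]))
    return SyntheticStudy(config=config, **tables)
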