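"""Study-design configuration for the simulated ICI-melanoma cohort.

The defaults encode the design of the trial the pipeline emulates: 60
patients with unresectable stage III/IV melanoma on combination
ipilimumab+nivolumab, plasma drawn at baseline and week 6 (~15% of week-6
draws missing), a 120-autoantigen array read out in IgG and IgM channels
with internal positive-control spots, nine organ-system categories of
immune-related adverse events (irAE), and commercial ANA/RF/anti-CCP
serology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
from typing import Any, Mapping, Sequence

import yaml

ISOTYPES = ("IgG", "IgM")
TIMEPOINTS = ("baseline", "week6")

#: The nine irAE organ categories of interest.
ORGAN_CATEGORIES = (
    "hepatic",
    "gastrointestinal",
    "dermatologic",
    "arthritis_arthralgia",
    "myocarditis",
    "myositis_myalgia",
    "sicca",
    "thyroid",
    "nonthyroid_endocrine",
)

ATTRIBUTIONS = ("definite", "probable", "possible", "unlikely", "unrelated")
#: Attribution levels that qualify an adverse event as treatment-related.
QUALIFYING_ATTRIBUTIONS = frozenset({"definite", "probable"})

#: Probability that a patient develops >=1 event in each organ category.
DEFAULT_ORGAN_RATES: Mapping[str, float] = {
    "dermatologic": 0.55,
    "gastrointestinal": 0.45,
    "hepatic": 0.40,
    "thyroid": 0.28,
    "arthritis_arthralgia": 0.22,
    "myositis_myalgia": 0.15,
    "nonthyroid_endocrine": 0.12,
    "sicca": 0.10,
    "myocarditis": 0.05,
}

#: Median onset week per organ.  Dermatologic/myocarditis events cluster
#: early, arthritis and non-thyroid endocrinopathies late; organs without a
#: reported median get mid-range values.
DEFAULT_ONSET_MEDIANS: Mapping[str, float] = {
    "dermatologic": 2.4,
    "myocarditis": 2.4,
    "hepatic": 5.3,
    "gastrointestinal": 6.3,
    "arthritis_arthralgia": 11.5,
    "nonthyroid_endocrine": 11.7,
    "thyroid": 8.0,
    "myositis_myalgia": 7.0,
    "sicca": 10.0,
}

#: P(CTCAE grade >= 3 | event) per organ; myocarditis is frequently severe.
DEFAULT_SEVERE_PROBS: Mapping[str, float] = {
    "dermatologic": 0.15,
    "gastrointestinal": 0.36,
    "hepatic": 0.40,
    "thyroid": 0.08,
    "arthritis_arthralgia": 0.15,
    "myositis_myalgia": 0.30,
    "nonthyroid_endocrine": 0.30,
    "sicca": 0.05,
    "myocarditis": 0.70,
}

DEFAULT_ATTRIBUTION_PROBS: Mapping[str, float] = {
    "definite": 0.55,
    "probable": 0.30,
    "possible": 0.08,
    "unlikely": 0.04,
    "unrelated": 0.03,
}


class ConfigurationError(ValueError):
    """Raised when a cohort configuration field is invalid."""


@dataclass(frozen=True)
class PlantedEffect:
    """An additive antibody-score shift planted into one patient group.

    Parameters
    ----------
    antigens:
        Antigen labels receiving the shift (must be in the panel).
    grouping:
        Which patient group gets the shift. One of ``("organ", <organ>)``,
        ``("timing",)`` (first qualifying event before week 6),
        ``("severity",)`` (max grade >= 3), or ``("first_half",)`` — a
        deterministic half-split used for calibration runs.
    timepoint:
        ``"baseline"`` or ``"week6"``.
    effect_abs:
        Signed shift in antibody-score (log2) units applied to the group.
    """

    antigens: tuple[str, ...]
    grouping: tuple[str, ...]
    timepoint: str = "baseline"
    effect_abs: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "antigens", tuple(self.antigens))
        object.__setattr__(self, "grouping", tuple(self.grouping))
        import math

        if not math.isfinite(self.effect_abs):
            raise ConfigurationError("effect_abs must be finite")
        if self.timepoint not in TIMEPOINTS:
            raise ConfigurationError(f"unknown timepoint {self.timepoint!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic study generator.

    Signal-model parameters are on the antibody-score (ABS, log2) scale:
    each antigen has a cohort mean, patients add a global-reactivity
    offset, spots add independent noise, and each slide (patient x
    timepoint x isotype) applies an affine distortion that the
    control-based normalization is meant to remove.
    """

    n_patients: int = 60
    n_antigens: int = 120
    n_control_spots: int = 8
    isotypes: tuple[str, ...] = ISOTYPES
    timepoints: tuple[str, ...] = TIMEPOINTS
    week6_missing_fraction: float = 0.15
    organ_categories: tuple[str, ...] = ORGAN_CATEGORIES
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    # --- signal model (ABS scale) ---
    bright_abs_mean_range: tuple[float, float] = (3.5, 8.5)
    dim_abs_mean_range: tuple[float, float] = (0.5, 2.0)
    dim_antigen_fraction: float = 0.10
    patient_offset_sd: float = 0.3
    spot_noise_sd: float = 1.0
    #: log2(SNR) = ABS - snr_pivot + N(0, snr_noise_sd); raising the pivot
    #: pushes more spots under the SNR>=3 true-signal threshold.
    snr_pivot: float = 2.0
    snr_noise_sd: float = 0.8
    sample_scale_sd: float = 0.06
    sample_offset_sd: float = 0.25
    control_profile_range: tuple[float, float] = (5.0, 11.0)
    control_noise_sd: float = 0.05
    control_snr: float = 50.0

    # --- longitudinal model ---
    #: Per-patient week-6 drift SD = fc_base_sd * (1 + fc_event_coupling * k)
    #: where k is the patient's distinct-organ irAE count.
    fc_base_sd: float = 0.3
    fc_event_coupling: float = 0.3

    # --- clinical / events ---
    organ_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_RATES)
    )
    onset_medians: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ONSET_MEDIANS)
    )
    onset_log_sd: float = 0.6
    severe_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEVERE_PROBS)
    )
    attribution_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTRIBUTION_PROBS)
    )
    extra_event_rate: float = 0.3
    event_rate_scale: float = 1.0
    #: Severe (grade >= 3) events onset later than mild ones by this factor.
    severe_onset_multiplier: float = 2.0

    # --- serology ---
    ana_baseline_rate: float = 0.2333
    ana_persist_prob: float = 0.80
    ana_gain_prob: float = 0.08
    rf_log_mean: float = 1.386  # ln 4 IU/mL
    rf_log_sd: float = 0.85
    ccp_log_mean: float = 0.693  # ln 2 U/mL
    ccp_log_sd: float = 0.9
    titer_drift_sd: float = 0.3

    # --- immunoglobulins & survival ---
    igg_mean: float = 1050.0
    igg_sd: float = 230.0
    igg_female_shift: float = 120.0
    igm_log_mean: float = 4.554  # ln 95 mg/dL
    igm_log_sd: float = 0.45
    followup_months: float = 25.0
    pfs_median_months: float = 10.0
    os_median_months: float = 28.0

    # --- demographics ---
    male_fraction: float = 38 / 60
    stage_iv_fraction: float = 51 / 60
    melanoma_type_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "cutaneous": 37 / 60,
            "uveal": 1 / 60,
            "acral": 1 / 60,
            "mucosal": 16 / 60,
            "unknown": 5 / 60,
        }
    )

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if self.n_antigens < 1:
            raise ConfigurationError("n_antigens must be >= 1")
        if self.n_control_spots < 2:
            raise ConfigurationError("n_control_spots must be >= 2")
        for name in (
            "week6_missing_fraction",
            "dim_antigen_fraction",
            "ana_baseline_rate",
            "ana_persist_prob",
            "ana_gain_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for name in ("spot_noise_sd", "snr_noise_sd", "fc_base_sd", "onset_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.event_rate_scale < 0:
            raise ConfigurationError("event_rate_scale must be >= 0")
        unknown = set(self.organ_rates) - set(self.organ_categories)
        if unknown:
            raise ConfigurationError(f"organ_rates has unknown organs: {sorted(unknown)}")
        object.__setattr__(self, "planted_effects", tuple(self.planted_effects))
        panel = set(self.antigen_labels())
        for effect in self.planted_effects:
            missing = set(effect.antigens) - panel
            if missing:
                raise ConfigurationError(
                    f"planted_effects antigens outside the panel: {sorted(missing)}"
                )

    def antigen_labels(self) -> list[str]:
        width = max(3, len(str(self.n_antigens)))
        return [f"AG{i + 1:0{width}d}" for i in range(self.n_antigens)]

    def control_labels(self) -> list[str]:
        return [f"CTRL{i + 1}" for i in range(self.n_control_spots)]

    def patient_ids(self) -> list[str]:
        width = max(3, len(str(self.n_patients)))
        return [f"P{i + 1:0{width}d}" for i in range(self.n_patients)]

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["planted_effects"] = [asdict(e) for e in self.planted_effects]
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the statistical stages."""

    alpha: float = 0.05
    linkage: str = "complete"
    n_clusters: int = 4
    #: DE set fed to clustering: union of organ-specific baseline
    #: comparisons for this isotype.
    clustering_isotype: str = "IgG"
    rf_threshold: float = 14.0
    ccp_threshold: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.linkage not in ("complete", "average", "ward", "single"):
            raise ConfigurationError(f"unsupported linkage {self.linkage!r}")


def load_config(path: str) -> tuple[CohortConfig, AnalysisConfig]:
    """Load a YAML run configuration with ``cohort:`` and ``analysis:`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = dict(raw.get("cohort", {}))
    effects = [
        PlantedEffect(
            antigens=tuple(e["antigens"]),
            grouping=tuple(e["grouping"]),
            timepoint=e.get("timepoint", "baseline"),
            effect_abs=float(e.get("effect_abs", 1.0)),
        )
        for e in cohort_raw.pop("planted_effects", [])
    ]
    for key in ("isotypes", "timepoints", "organ_categories"):
        if key in cohort_raw:
            cohort_raw[key] = tuple(cohort_raw[key])
    try:
        cohort = CohortConfig(planted_effects=tuple(effects), **cohort_raw)
        analysis = AnalysisConfig(**dict(raw.get("analysis", {})))
    except TypeError as exc:  # unknown field name
        raise ConfigurationError(str(exc)) from exc
    return cohort, analysis
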