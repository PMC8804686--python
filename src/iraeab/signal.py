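"""Spot-signal processing: antibody scores, true-signal filtering, and
control-based robust normalization.

The quantitative readout per spot is the antibody score
``ABS = log2(NFI * SNR + 1)`` where NFI is net fluorescence intensity and
SNR the signal-to-noise ratio. Spots with SNR >= 3 count as true signals;
antigens below that in more than 90% of all samples are dropped from the
panel. Slides are then brought onto a common scale by regressing each
sample's internal positive-control scores on the across-sample median
control profile with a Huber robust linear fit and inverting the fitted
affine map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

SNR_TRUE_SIGNAL = 3.0
#: An antigen is dropped when the fraction of samples with SNR < 3
#: strictly exceeds this.
FILTER_FRACTION = 0.90

HUBER_C = 1.345
HUBER_MAX_ITER = 50
HUBER_TOL = 1e-8

logger = logging.getLogger(__name__)


@dataclass
class AbsMatrix:
    """Patients x antigens antibody-score matrix for one isotype/timepoint.

    ``values`` holds the score for every cell; ``mask`` flags cells whose
    underlying spot met the SNR >= 3 true-signal rule. Statistics downstream
    operate on all retained-antigen values (the panel filter removes
    antigens, not cells), the mask is carried for reporting.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    isotype: str
    timepoint: str
    normalization: str = "raw"
    controls: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise ValueError("values and mask must share axes")

    @property
    def patients(self) -> list[str]:
        return list(self.values.index)

    @property
    def antigens(self) -> list[str]:
        return list(self.values.columns)


def compute_abs(nfi, snr):
    """Antibody score ``log2(nfi * snr + 1)``.

    Accepts scalars or arrays. Negative NFI (possible after upstream
    background subtraction) is clamped to 0 with a warning; non-finite
    inputs are rejected.
    """
    nfi = np.asarray(nfi, dtype=float)
    snr = np.asarray(snr, dtype=float)
    if not (np.all(np.isfinite(nfi)) and np.all(np.isfinite(snr))):
        bad = np.flatnonzero(~(np.isfinite(nfi) & np.isfinite(snr)))
        raise ValueError(f"non-finite NFI/SNR at flat index {bad[:5].tolist()}")
    if np.any(nfi < 0):
        warnings.warn(
            f"{int(np.sum(nfi < 0))} negative NFI value(s) clamped to 0", stacklevel=2
        )
        nfi = np.clip(nfi, 0, None)
    if np.any(snr < 0):
        raise ValueError("SNR must be >= 0")
    out = np.log2(nfi * snr + 1.0)
    return float(out) if out.ndim == 0 else out


def true_signal_mask(signals: pd.DataFrame) -> pd.Series:
    """True where a spot's SNR meets the >= 3 true-signal threshold."""
    return signals["snr"] >= SNR_TRUE_SIGNAL


def filter_antigens(signals: pd.DataFrame, isotype: str | None = None) -> tuple[list[str], pd.DataFrame]:
    """Drop antigens with SNR < 3 in more than 90% of all samples.

    "All samples" pools both timepoints within an isotype. Returns the
    retained antigen list (panel order) and a per-antigen report with the
    low-SNR fraction and the removal decision.
    """
    if signals.empty:
        raise ValueError("no antigen spots to filter")
    spots = signals[~signals["is_control"].astype(bool)]
    if isotype is not None:
        spots = spots[spots["isotype"] == isotype]
    if spots.empty:
        raise ValueError("no antigen spots to filter")
    low = (spots["snr"] < SNR_TRUE_SIGNAL).groupby(spots["antigen"], sort=False).mean()
    report = pd.DataFrame(
        {
            "antigen": low.index,
            "low_snr_fraction": low.to_numpy(),
            "removed": (low > FILTER_FRACTION).to_numpy(),
        }
    ).reset_index(drop=True)
    retained = report.loc[~report["removed"], "antigen"].tolist()
    return retained, report


def _huber_affine(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Huber M-estimate of ``y ~ intercept + slope * x`` (c=1.345, MAD scale)."""
    w = np.ones_like(x)
    slope, intercept = np.polyfit(x, y, 1)
    for _ in range(HUBER_MAX_ITER):
        resid = y - (intercept + slope * x)
        scale = np.median(np.abs(resid)) / 0.6745  # MAD about zero, as in RLM
        if scale < 1e-12:
            break
        u = np.abs(resid) / (HUBER_C * scale)
        w = np.where(u <= 1.0, 1.0, 1.0 / u)
        sw = w.sum()
        xw = (w * x).sum() / sw
        yw = (w * y).sum() / sw
        denom = (w * (x - xw) ** 2).sum()
        if denom < 1e-12:
            break
        new_slope = (w * (x - xw) * (y - yw)).sum() / denom
        new_intercept = yw - new_slope * xw
        if abs(new_slope - slope) < HUBER_TOL and abs(new_intercept - intercept) < HUBER_TOL:
            slope, intercept = new_slope, new_intercept
            break
        slope, intercept = new_slope, new_intercept
    return float(slope), float(intercept)


def normalize_rlm(matrix: AbsMatrix) -> tuple[AbsMatrix, pd.DataFrame]:
    """Remove per-sample affine distortions using internal positive controls.

    For each sample (row), the control-spot scores are regressed on the
    across-sample median control profile with a Huber fit; the sample's
    antigen scores are then passed through the inverse affine map. Samples
    with degenerate controls fall back to median-ratio scaling (logged).
    Returns the normalized matrix and a per-sample slope/intercept report.
    """
    if matrix.controls is None or matrix.controls.shape[1] < 2:
        raise ValueError("normalization needs >= 2 control spots per sample")
    controls = matrix.controls.loc[matrix.values.index]
    profile = controls.median(axis=0).to_numpy()
    rows = []
    norm_values = matrix.values.copy()
    norm_controls = controls.copy()
    for sample in matrix.values.index:
        y = controls.loc[sample].to_numpy(dtype=float)
        if np.ptp(profile) < 1e-12 or np.ptp(y) < 1e-12:
            med = np.median(profile)
            ratio = np.median(y) / med if med > 1e-12 else 1.0
            slope, intercept, method = (ratio if ratio > 1e-12 else 1.0), 0.0, "median_ratio"
            logger.warning("degenerate controls for sample %s; median-ratio fallback", sample)
        else:
            slope, intercept = _huber_affine(profile, y)
            method = "huber"
            if abs(slope) < 1e-6:
                med = np.median(profile)
                ratio = np.median(y) / med if med > 1e-12 else 1.0
                slope, intercept, method = (ratio if ratio > 1e-12 else 1.0), 0.0, "median_ratio"
                logger.warning("near-zero control slope for sample %s; fallback", sample)
        norm_values.loc[sample] = (matrix.values.loc[sample] - intercept) / slope
        norm_controls.loc[sample] = (controls.loc[sample] - intercept) / slope
        rows.append({"sample": sample, "slope": slope, "intercept": intercept, "method": method})
    report = pd.DataFrame(rows)
    normalized = replace(
        matrix, values=norm_values, controls=norm_controls, normalization="normalized"
    )
    return normalized, report


def build_abs_matrices(
    signals: pd.DataFrame,
    retained: dict[str, list[str]] | None = None,
) -> dict[tuple[str, str], AbsMatrix]:
    """Score all spots and pivot into per-(isotype, timepoint) matrices.

    ``retained`` optionally maps isotype -> antigen list from
    :func:`filter_antigens`; antigens outside it are dropped.
    """
    signals = signals.copy()
    signals["abs"] = compute_abs(signals["nfi"].to_numpy(), signals["snr"].to_numpy())
    signals["true_signal"] = true_signal_mask(signals)
    matrices: dict[tuple[str, str], AbsMatrix] = {}
    is_ctrl = signals["is_control"].astype(bool)
    for (isotype, timepoint), chunk in signals.groupby(["isotype", "timepoint"], sort=False):
        spots = chunk[~is_ctrl.loc[chunk.index]]
        ctrls = chunk[is_ctrl.loc[chunk.index]]
        values = spots.pivot(index="patient_id", columns="antigen", values="abs")
        mask = spots.pivot(index="patient_id", columns="antigen", values="true_signal")
        if retained is not None:
            keep = [a for a in values.columns if a in set(retained.get(isotype, values.columns))]
            values, mask = values[keep], mask[keep]
        controls = None
        if not ctrls.empty:
            controls = ctrls.pivot(index="patient_id", columns="antigen", values="abs")
            controls = controls.loc[values.index]
        matrices[(isotype, timepoint)] = AbsMatrix(
            values=values,
            mask=mask.astype(bool),
            isotype=isotype,
            timepoint=timepoint,
            controls=controls,
        )
    return matrices


REQUIRED_SIGNAL_COLUMNS = ("patient_id", "timepoint", "isotype", "antigen", "is_control", "nfi", "snr")


def load_signals(path: str | Path, known_antigens: list[str] | None = None, on_unknown: str = "keep") -> pd.DataFrame:
    """Load a spot-signal table (TSV, or a GenePix-results-style export).

    Negative NFI values are clamped to 0 with a warning. ``on_unknown``
    controls antigens outside ``known_antigens``: ``"keep"`` passes them
    through, ``"reject"`` raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    if first.lstrip().startswith(('"', "ATF")):
        signals = _load_gpr_like(path)
    else:
        try:
            signals = pd.read_csv(path, sep="\t")
        except Exception as exc:
            raise ValueError(f"cannot parse signal table {path}: {exc}") from exc
        missing = set(REQUIRED_SIGNAL_COLUMNS) - set(signals.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    numeric = signals[["nfi", "snr"]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | ~np.isfinite(numeric.to_numpy()).all(axis=1)
    if bad.any():
        line = int(signals.index[bad][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: malformed NFI/SNR near line {line}")
    signals[["nfi", "snr"]] = numeric
    if (signals["nfi"] < 0).any():
        warnings.warn(
            f"{int((signals['nfi'] < 0).sum())} negative NFI value(s) clamped to 0",
            stacklevel=2,
        )
        signals["nfi"] = signals["nfi"].clip(lower=0)
    if (signals["snr"] < 0).any():
        raise ValueError(f"{path}: negative SNR")
    dup = signals.duplicated(["patient_id", "timepoint", "isotype", "antigen"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (patient, timepoint, isotype, antigen) rows")
    if known_antigens is not None:
        unknown = set(signals.loc[~signals["is_control"].astype(bool), "antigen"]) - set(known_antigens)
        if unknown and on_unknown == "reject":
            raise ValueError(f"{path}: unknown antigens {sorted(unknown)[:5]}")
    return signals


def _load_gpr_like(path: Path) -> pd.DataFrame:
    """Parse a GenePix-results-style file: quoted key=value header block
    followed by a column-titled table. Header keys supply patient/timepoint/
    isotype; control rows are flagged by the Name column."""
    meta: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            header_lines += 1
            stripped = line.strip().strip('"')
            if "=" in stripped and "\t" not in line.rstrip("\n"):
                key, _, value = stripped.partition("=")
                meta[key.strip().lower()] = value.strip()
            elif stripped and not stripped[0].isdigit():
                break  # column title row
    table = pd.read_csv(path, sep="\t", skiprows=header_lines - 1)
    table.columns = [c.strip().strip('"').lower() for c in table.columns]
    colmap = {"name": "antigen", "f532 median - b532": "nfi", "snr 532": "snr"}
    for src, dst in colmap.items():
        if src in table.columns:
            table = table.rename(columns={src: dst})
    missing = {"antigen", "nfi", "snr"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: GPR-like table lacks columns {sorted(missing)}")
    out = pd.DataFrame(
        {
            "patient_id": meta.get("patient", "unknown"),
            "timepoint": meta.get("timepoint", "baseline"),
            "isotype": meta.get("isotype", "IgG"),
            "antigen": table["antigen"].astype(str).str.strip().str.strip('"'),
            "nfi": table["nfi"].astype(float),
            "snr": table["snr"].astype(float),
        }
    )
    out.insert(4, "is_control", out["antigen"].str.lower().str.startswith(("ctrl", "control")).astype(int))
    return out[list(REQUIRED_SIGNAL_COLUMNS)]
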