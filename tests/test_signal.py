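"""Antibody scoring, the SNR filter, and control-based normalization."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from iraeab.signal import (
    AbsMatrix,
    _huber_affine,
    build_abs_matrices,
    compute_abs,
    filter_antigens,
    load_signals,
    normalize_rlm,
    true_signal_mask,
)


class TestComputeAbs:
    @pytest.mark.parametrize(
        "nfi,snr,expected",
        [
            (0.0, 5.0, 0.0),
            (31.0, 33.0, 10.0),  # 31*33+1 = 1024
            (1000.0, 4.0, np.log2(4001.0)),
            (7.0, 0.0, 0.0),
        ],
    )
    def test_values(self, nfi, snr, expected):
        assert compute_abs(nfi, snr) == pytest.approx(expected, abs=1e-12)

    def test_negative_nfi_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert compute_abs(-5.0, 10.0) == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            compute_abs(np.nan, 1.0)
        with pytest.raises(ValueError, match="non-finite"):
            compute_abs([1.0, np.inf], [1.0, 1.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n1=st.floats(0, 1e6), n2=st.floats(0, 1e6),
        s1=st.floats(0, 1e3), s2=st.floats(0, 1e3),
    )
    def test_monotone_in_each_argument(self, n1, n2, s1, s2):
        lo_n, hi_n = sorted([n1, n2])
        lo_s, hi_s = sorted([s1, s2])
        assert compute_abs(lo_n, lo_s) <= compute_abs(hi_n, lo_s)
        assert compute_abs(lo_n, lo_s) <= compute_abs(lo_n, hi_s)


class TestTrueSignalMask:
    def test_threshold_is_inclusive(self):
        frame = pd.DataFrame({"snr": [3.0, 2.999, 0.0, 10.0]})
        assert true_signal_mask(frame).tolist() == [True, False, False, True]


def _signal_frame(snr_by_antigen: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for antigen, snrs in snr_by_antigen.items():
        for i, snr in enumerate(snrs):
            rows.append(
                {"patient_id": f"S{i}", "timepoint": "baseline", "isotype": "IgG",
                 "antigen": antigen, "is_control": 0, "nfi": 10.0, "snr": snr}
            )
    return pd.DataFrame(rows)


class TestFilterAntigens:
    def test_exact_boundary(self):
        signals = _signal_frame(
            {
                "removed91": [1.0] * 91 + [5.0] * 9,
                "kept90": [1.0] * 90 + [5.0] * 10,
                "bright": [5.0] * 100,
            }
        )
        retained, report = filter_antigens(signals)
        assert retained == ["kept90", "bright"]
        assert report.set_index("antigen").loc["removed91", "removed"]

    def test_invariant_to_order_and_duplication(self):
        signals = _signal_frame({"a": [1.0] * 95 + [5.0] * 5, "b": [5.0] * 100})
        shuffled = signals.sample(frac=1, random_state=0)
        doubled = pd.concat([signals, signals.assign(timepoint="week6")])
        assert filter_antigens(signals)[0] == filter_antigens(shuffled)[0]
        assert filter_antigens(signals)[0] == filter_antigens(doubled)[0]

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError):
            filter_antigens(_signal_frame({}))


def _matrix_with_controls(values, controls):
    patients = [f"S{i}" for i in range(values.shape[0])]
    antigens = [f"A{j}" for j in range(values.shape[1])]
    ctrl_names = [f"C{j}" for j in range(controls.shape[1])]
    return AbsMatrix(
        values=pd.DataFrame(values, index=patients, columns=antigens),
        mask=pd.DataFrame(True, index=patients, columns=antigens),
        isotype="IgG",
        timepoint="baseline",
        controls=pd.DataFrame(controls, index=patients, columns=ctrl_names),
    )


class TestNormalizeRlm:
    def test_identity_sample(self):
        profile = np.linspace(5, 11, 8)
        controls = np.tile(profile, (4, 1))
        values = np.tile(np.linspace(2, 9, 10), (4, 1))
        matrix = _matrix_with_controls(values, controls)
        normalized, report = normalize_rlm(matrix)
        assert np.allclose(report["slope"], 1.0, atol=1e-9)
        assert np.allclose(report["intercept"], 0.0, atol=1e-9)
        assert np.allclose(normalized.values, values)

    def test_known_affine_map_inverted(self):
        profile = np.linspace(5, 11, 8)
        truth = np.tile(np.linspace(2, 9, 10), (5, 1))
        controls = np.tile(profile, (5, 1))
        # sample 0 distorted by x1.5 + 0.3 on every spot
        controls[0] = profile * 1.5 + 0.3
        values = truth.copy()
        values[0] = truth[0] * 1.5 + 0.3
        normalized, report = normalize_rlm(_matrix_with_controls(values, controls))
        assert report.loc[0, "slope"] == pytest.approx(1.5, abs=1e-6)
        assert report.loc[0, "intercept"] == pytest.approx(0.3, abs=1e-6)
        assert np.allclose(normalized.values.iloc[0], truth[0], atol=1e-6)

    def test_planted_distortions_reduce_control_variance(self):
        rng = np.random.default_rng(0)
        profile = np.linspace(5, 11, 8)
        scales = rng.normal(1, 0.1, 30)
        offsets = rng.normal(0, 0.4, 30)
        controls = scales[:, None] * profile[None, :] + offsets[:, None]
        controls += rng.normal(0, 0.05, controls.shape)
        values = scales[:, None] * rng.uniform(2, 9, (30, 40)) + offsets[:, None]
        matrix = _matrix_with_controls(values, controls)
        normalized, _ = normalize_rlm(matrix)
        before = matrix.controls.var(axis=0).mean()
        after = normalized.controls.var(axis=0).mean()
        assert after < before

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(1)
        profile = np.linspace(5, 11, 8)
        controls = rng.normal(1, 0.08, 20)[:, None] * profile[None, :] + rng.normal(
            0, 0.3, 20
        )[:, None]
        values = rng.uniform(2, 9, (20, 15))
        once, _ = normalize_rlm(_matrix_with_controls(values, controls))
        _, report = normalize_rlm(once)
        assert np.allclose(report["slope"], 1.0, atol=1e-6)
        assert np.allclose(report["intercept"], 0.0, atol=1e-6)

    def test_degenerate_controls_fall_back(self):
        controls = np.full((3, 8), 7.0)  # zero-variance profile
        values = np.tile(np.linspace(2, 9, 5), (3, 1))
        normalized, report = normalize_rlm(_matrix_with_controls(values, controls))
        assert (report["method"] == "median_ratio").all()
        assert np.isfinite(normalized.values.to_numpy()).all()

    def test_huber_matches_statsmodels_rlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = np.linspace(5, 11, 8)
        for _ in range(20):
            y = 0.3 + 1.4 * x + rng.normal(0, 0.1, 8)
            y[rng.integers(0, 8)] += rng.normal(0, 2)  # one outlier
            slope, intercept = _huber_affine(x, y)
            ref = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.HuberT(1.345)).fit(
                maxiter=50, tol=1e-8
            )
            assert slope == pytest.approx(ref.params[1], abs=1e-3)
            assert intercept == pytest.approx(ref.params[0], abs=1e-3)


class TestLoadSignals:
    def test_round_trip(self, tmp_path, default_study):
        path = tmp_path / "signals.tsv"
        default_study.signals.to_csv(path, sep="\t", index=False)
        loaded = load_signals(path)
        assert len(loaded) == len(default_study.signals)
        pd.testing.assert_frame_equal(loaded, default_study.signals, check_dtype=False)

    def test_negative_nfi_clamped(self, tmp_path):
        frame = pd.DataFrame(
            {"patient_id": ["P1"], "timepoint": ["baseline"], "isotype": ["IgG"],
             "antigen": ["A1"], "is_control": [0], "nfi": [-4.0], "snr": [5.0]}
        )
        path = tmp_path / "neg.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.warns(UserWarning, match="clamped"):
            loaded = load_signals(path)
        assert loaded["nfi"].iloc[0] == 0.0

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "patient_id\ttimepoint\tisotype\tantigen\tis_control\tnfi\tsnr\n"
            "P1\tbaseline\tIgG\tA1\t0\t5.0\t4.0\n"
            "P1\tbaseline\tIgG\tA2\t0\toops\t4.0\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            load_signals(path)

    def test_gpr_like_dialect(self, tmp_path):
        path = tmp_path / "slide.gpr"
        path.write_text(
            '"Patient=P9"\n"Timepoint=week6"\n"Isotype=IgM"\n'
            '"Name"\t"F532 Median - B532"\t"SNR 532"\n'
            '"AG001"\t100\t5.0\n'
            '"CTRL1"\t200\t50.0\n'
        )
        loaded = load_signals(path)
        assert loaded["patient_id"].unique().tolist() == ["P9"]
        assert loaded["isotype"].unique().tolist() == ["IgM"]
        assert loaded["is_control"].tolist() == [0, 1]


def test_build_abs_matrices_masks_low_snr(default_study):
    matrices = build_abs_matrices(default_study.signals)
    matrix = matrices[("IgG", "baseline")]
    assert matrix.values.shape == (60, 120)
    spots = default_study.signals
    one = spots[
        (spots["patient_id"] == matrix.patients[0])
        & (spots["timepoint"] == "baseline")
        & (spots["isotype"] == "IgG")
        & (spots["antigen"] == matrix.antigens[0])
    ]
    expected = np.log2(one["nfi"].iloc[0] * one["snr"].iloc[0] + 1)
    assert matrix.values.iloc[0, 0] == pytest.approx(expected)
    assert matrix.mask.iloc[0, 0] == (one["snr"].iloc[0] >= 3)
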