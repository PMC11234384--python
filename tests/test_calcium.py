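"""F/F_max normalization and peak dF/F_max recovery."""

import numpy as np
import pandas as pd
import pytest

from mcsquant.calcium import (
    Trace,
    extract_trace,
    normalize_fmax,
    peak_delta,
    quantify_trace_frame,
)
from mcsquant.core import Image, Mask
from mcsquant.simulate import CalciumTraceSpec, simulate_trace


def _trace_from_spec(spec):
    df = simulate_trace(spec)
    return Trace(df["time_s"].to_numpy(), df["F"].to_numpy())


class TestExtractTrace:
    def test_constant_stack_minus_background(self):
        stack = Image(np.full((5, 8, 8), 10.0), pixel_size_nm=1)
        roi = np.zeros((8, 8), bool)
        roi[2:4, 2:4] = True
        bg = np.zeros((8, 8), bool)
        bg[0, :] = True
        stack.data[:, 0, :] = 4.0
        tr = extract_trace(stack, Mask(roi), Mask(bg))
        assert np.allclose(tr.F, 6.0)

    def test_equal_roi_and_bg_statistics_give_zero(self):
        stack = Image(np.full((3, 6, 6), 5.0), pixel_size_nm=1)
        roi = np.zeros((6, 6), bool)
        roi[:3] = True
        bg = ~roi
        tr = extract_trace(stack, Mask(roi), Mask(bg))
        assert np.allclose(tr.F, 0.0)

    def test_single_frame_stack(self):
        stack = Image(np.ones((1, 4, 4)), pixel_size_nm=1)
        m = Mask(np.ones((4, 4), bool))
        b = Mask(np.zeros((4, 4), bool))
        b.data[0, 0] = True
        assert len(extract_trace(stack, m, b)) == 1

    def test_empty_roi_rejected(self):
        stack = Image(np.ones((2, 4, 4)), pixel_size_nm=1)
        with pytest.raises(ValueError, match="ROI"):
            extract_trace(stack, Mask(np.zeros((4, 4), bool)), Mask(np.ones((4, 4), bool)))


class TestNormalizeFmax:
    def test_noise_free_plateau_normalizes_to_one(self):
        spec = CalciumTraceSpec(noise_sd_frac=0.0)
        tr = _trace_from_spec(spec)
        norm = normalize_fmax(tr, (spec.fmax_frame, spec.n_frames))
        assert norm.f_max == pytest.approx(spec.f_max)
        assert norm.f_over_fmax[spec.fmax_frame :].mean() == pytest.approx(1.0)

    def test_fmax_recovered_within_two_percent_at_one_percent_noise(self):
        spec = CalciumTraceSpec(baseline_frac=0.2, peak_frac=0.55, noise_sd_frac=0.01, seed=5)
        tr = _trace_from_spec(spec)
        norm = normalize_fmax(tr, (spec.fmax_frame, spec.n_frames))
        assert abs(norm.f_max - spec.f_max) / spec.f_max < 0.02

    def test_window_on_baseline_rejected(self):
        spec = CalciumTraceSpec(noise_sd_frac=0.0)
        tr = _trace_from_spec(spec)
        # window placed mid-decay: the claimed plateau sits below the
        # earlier transient peak
        with pytest.raises(ValueError, match="invalid F_max window"):
            normalize_fmax(tr, (spec.stim_frame + 100, spec.stim_frame + 200))
        # a window fully on the pre-stimulus baseline also fails: the
        # stimulus peak exceeds the claimed plateau
        with pytest.raises(ValueError, match="invalid F_max window"):
            tr2 = Trace(tr.time_s[: spec.fmax_frame], tr.F[: spec.fmax_frame])
            normalize_fmax(tr2, (0, spec.stim_frame))

    def test_short_window_rejected(self):
        tr = Trace(np.arange(10.0), np.ones(10))
        with pytest.raises(ValueError, match="3 frames"):
            normalize_fmax(tr, (8, 10))


class TestPeakDelta:
    def test_flat_trace_gives_zero(self):
        tr = Trace(np.arange(100.0), np.full(100, 500.0))
        norm = normalize_fmax(tr, (90, 100))
        norm = peak_delta(norm, (0, 30), (30, 80))
        assert norm.delta_peak == pytest.approx(0.0)

    def test_recovers_generated_delta(self):
        spec = CalciumTraceSpec(baseline_frac=0.2, peak_frac=0.55, noise_sd_frac=0.01, seed=6)
        tr = _trace_from_spec(spec)
        norm = normalize_fmax(tr, (spec.fmax_frame, spec.n_frames))
        norm = peak_delta(norm, (0, spec.stim_frame), (spec.stim_frame, spec.fmax_frame))
        assert norm.delta_peak == pytest.approx(0.35, abs=0.02)

    def test_linearity_flag_raised_above_half_fmax(self):
        spec = CalciumTraceSpec(baseline_frac=0.2, peak_frac=0.8, noise_sd_frac=0.0)
        tr = _trace_from_spec(spec)
        norm = normalize_fmax(tr, (spec.fmax_frame, spec.n_frames))
        norm = peak_delta(norm, (0, spec.stim_frame), (spec.stim_frame, spec.fmax_frame),
                          smooth_frames=1)
        assert norm.delta_peak == pytest.approx(0.6, abs=1e-6)
        assert norm.linearity_flag

    def test_overlapping_windows_rejected(self):
        tr = Trace(np.arange(100.0), np.full(100, 10.0))
        norm = normalize_fmax(tr, (90, 100))
        with pytest.raises(ValueError, match="disjoint"):
            peak_delta(norm, (0, 50), (40, 80))

    def test_scale_invariance(self):
        spec = CalciumTraceSpec(noise_sd_frac=0.02, seed=7)
        tr = _trace_from_spec(spec)
        scaled = Trace(tr.time_s, tr.F * 37.5)
        win = (spec.fmax_frame, spec.n_frames)
        bw, rw = (0, spec.stim_frame), (spec.stim_frame, spec.fmax_frame)
        d1 = peak_delta(normalize_fmax(tr, win), bw, rw).delta_peak
        d2 = peak_delta(normalize_fmax(scaled, win), bw, rw).delta_peak
        assert d1 == pytest.approx(d2, rel=1e-12)


class TestTwoChannelQuantification:
    @staticmethod
    def _pair_frame(cyto, mito):
        a, b = simulate_trace(cyto), simulate_trace(mito)
        return pd.DataFrame({"frame": a["frame"], "time_s": a["time_s"],
                             "F_cyto": a["F"], "F_mito": b["F"]})

    def test_channels_quantified_independently(self):
        cyto = CalciumTraceSpec(peak_frac=0.45, noise_sd_frac=0.01, seed=1)
        mito = CalciumTraceSpec(peak_frac=0.5, noise_sd_frac=0.01, seed=2)
        mito_edited = CalciumTraceSpec(peak_frac=0.3, noise_sd_frac=0.01, seed=9)
        df1 = self._pair_frame(cyto, mito)
        df2 = self._pair_frame(cyto, mito_edited)
        q1 = quantify_trace_frame(df1, cyto.stim_frame, cyto.fmax_frame)
        q2 = quantify_trace_frame(df2, cyto.stim_frame, cyto.fmax_frame)
        c1 = q1[q1["channel"] == "cytosolic"]["delta_f_over_fmax"].iloc[0]
        c2 = q2[q2["channel"] == "cytosolic"]["delta_f_over_fmax"].iloc[0]
        assert c1 == c2

    def test_tidy_output_schema(self):
        cyto = CalciumTraceSpec(seed=1)
        df = self._pair_frame(cyto, CalciumTraceSpec(seed=2))
        q = quantify_trace_frame(df, cyto.stim_frame, cyto.fmax_frame, cell_id="c1")
        assert set(q.columns) >= {"cell", "channel", "delta_f_over_fmax", "f_max",
                                  "linearity_flag", "drift_flag"}
        assert len(q) == 2


class TestParameterRecovery:
    @pytest.mark.parametrize("delta", [0.1, 0.3, 0.5])
    def test_bias_and_rmse_across_noise_levels(self, delta):
        errs = []
        for i in range(34):
            noise = 0.01 + 0.04 * (i % 5) / 4  # 1-5% of F_max
            spec = CalciumTraceSpec(
                baseline_frac=0.2, peak_frac=0.2 + delta, noise_sd_frac=noise,
                seed=1000 + i,
            )
            tr = _trace_from_spec(spec)
            norm = normalize_fmax(tr, (spec.fmax_frame, spec.n_frames))
            norm = peak_delta(norm, (0, spec.stim_frame),
                              (spec.stim_frame, spec.fmax_frame))
            errs.append(norm.delta_peak - delta)
        errs = np.array(errs)
        # per-delta bias is looser than the pooled-recovery criterion: the
        # smoothed-max estimator trades a small +bias at small responses
        # against a small -bias at sharp large ones
        assert abs(errs.mean()) < 0.02
        assert np.sqrt((errs**2).mean()) < 0.03
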