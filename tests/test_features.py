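"""Feature-extraction tests: brute-force oracles, invariances, table shape."""

import numpy as np
import pytest

from teppipe import features as ft
from teppipe.containers import EpochSet, RoiTrace, TepTrace
from teppipe.montage import (ROI_ORDER, ROIS, TIME_WINDOWS, RoiSpec,
                             make_default_layout)

LAYOUT = make_default_layout()
TIMES = -1.0 + np.arange(2001) / 1000.0
N100 = TIME_WINDOWS["N100"]
P200 = TIME_WINDOWS["P200"]


def trace_from(data, smoothed=True):
    return TepTrace(data=data, times=TIMES, sfreq=1000.0, layout=LAYOUT,
                    smoothed=smoothed)


def roi_trace_from(x, roi="Fr", smoothed=True):
    return RoiTrace(x=x, times=TIMES, sfreq=1000.0, roi=ROIS[roi],
                    smoothed=smoothed)


def epochs_from(data):
    return EpochSet(data=data, times=TIMES, sfreq=1000.0, layout=LAYOUT)


# ---------------------------------------------------------------- oracles

def brute_gmfp(data):
    n_ch, n_s = data.shape
    out = np.empty(n_s)
    for i in range(n_s):
        vmean = sum(data[j, i] for j in range(n_ch)) / n_ch
        out[i] = np.sqrt(sum((data[j, i] - vmean) ** 2
                             for j in range(n_ch)) / n_ch)
    return out


def brute_lmfp(data, layout, roi, window, times):
    idx = [layout.index(c) for c in roi.channels]
    cols = np.flatnonzero(window.mask(times))
    acc = 0.0
    for i in cols:
        vals = [data[j, i] for j in idx]
        vmean = sum(vals) / len(vals)
        acc += np.sqrt(sum((v - vmean) ** 2 for v in vals) / len(vals))
    return acc / len(cols)


def brute_std(x, window, times):
    vals = x[window.mask(times)]
    m = sum(vals) / len(vals)
    return np.sqrt(sum((v - m) ** 2 for v in vals) / len(vals))


def brute_auc(x, window, times, f):
    vals = x[window.mask(times)]
    return sum(vals[i] + vals[i + 1] for i in range(len(vals) - 1)) / (2 * f)


class TestSegmentation:
    @pytest.mark.parametrize("n,expected", [
        (100, (30, 30, 40)),
        (90, (30, 30, 30)),
        (61, (30, 30, 1)),
        (5, (3, 1, 1)),
        (3, (1, 1, 1)),
    ])
    def test_segment_sizes(self, n, expected):
        ep = epochs_from(np.arange(n)[:, None, None]
                         * np.ones((n, 62, TIMES.size)))
        segs = ft.segment_trials(ep)
        assert tuple(s.n_trials for s in segs) == expected
        # disjoint union preserving order
        stacked = np.concatenate([s.data for s in segs], axis=0)
        assert np.array_equal(stacked, ep.data)

    def test_too_few_trials_rejected(self):
        ep = epochs_from(np.zeros((2, 62, TIMES.size)))
        with pytest.raises(ValueError):
            ft.segment_trials(ep)


class TestAveraging:
    def test_identical_trials_average_to_one_trial(self):
        trial = np.random.default_rng(0).standard_normal((62, TIMES.size))
        ep = epochs_from(np.tile(trial, (5, 1, 1)))
        assert np.allclose(ft.average_trials(ep).data, trial)

    def test_opposite_trials_cancel(self):
        trial = np.ones((62, TIMES.size))
        ep = epochs_from(np.stack([trial, -trial]))
        assert np.allclose(ft.average_trials(ep).data, 0.0)

    def test_variance_shrinks_as_one_over_n(self):
        # averaging n iid unit-variance trials leaves variance ~ 1/n
        rng = np.random.default_rng(42)
        n = 30
        ep = epochs_from(rng.standard_normal((n, 62, TIMES.size)))
        avg = ft.average_trials(ep)
        assert avg.data.var() == pytest.approx(1.0 / n, rel=0.1)


class TestSmoothing:
    def test_constant_signal_unchanged(self):
        tr = trace_from(np.full((62, TIMES.size), 3.0), smoothed=False)
        out = ft.gaussian_smooth(tr)
        assert np.allclose(out.data, 3.0)
        assert out.smoothed

    def test_impulse_response_is_unit_sum_kernel(self):
        data = np.zeros((62, TIMES.size))
        data[0, 1000] = 1.0
        out = ft.gaussian_smooth(trace_from(data, smoothed=False))
        assert out.data[0].sum() == pytest.approx(1.0, abs=1e-12)
        assert out.data[0].max() < 1.0

    def test_noise_variance_strictly_decreases(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((62, TIMES.size))
        out = ft.gaussian_smooth(trace_from(data, smoothed=False))
        assert out.data.var() < data.var()

    def test_window_longer_than_trace_rejected(self):
        short = TepTrace(np.zeros((2, 10)), TIMES[:10], 1000.0,
                         LAYOUT.subset(["F1", "F2"]))
        with pytest.raises(ValueError):
            ft.gaussian_smooth(short, 20)


class TestFieldPower:
    def test_gmfp_two_channel_hand_case(self):
        data = np.zeros((62, TIMES.size))
        layout2 = LAYOUT.subset(["F1", "F2"])
        tr = TepTrace(np.stack([np.ones(5), -np.ones(5)]),
                      TIMES[:5], 1000.0, layout2)
        assert np.allclose(ft.gmfp(tr), 1.0)

    def test_gmfp_zero_for_identical_channels(self):
        tr = trace_from(np.tile(np.sin(TIMES), (62, 1)))
        assert np.allclose(ft.gmfp(tr), 0.0, atol=1e-12)

    def test_gmfp_matches_brute_force(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((62, 200))
        tr = TepTrace(data, TIMES[:200], 1000.0, LAYOUT)
        assert np.allclose(ft.gmfp(tr), brute_gmfp(data), atol=1e-12)

    def test_gmfp_single_channel_rejected(self):
        tr = TepTrace(np.zeros((1, 10)), TIMES[:10], 1000.0,
                      LAYOUT.subset(["F1"]))
        with pytest.raises(ValueError):
            ft.gmfp(tr)

    def test_lmfp_two_channel_hand_case(self):
        data = np.zeros((62, TIMES.size))
        idx = LAYOUT.indices(ROIS["Fr"].channels)
        data[idx[0]] = 1.0
        data[idx[1]] = -1.0
        # remaining two ROI channels at 0: population SD of {1,-1,0,0}
        expect = np.sqrt((1 + 1) / 4.0)
        got = ft.feat_lmfp(trace_from(data), ROIS["Fr"], N100)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_lmfp_zero_for_identical_roi_channels(self):
        data = np.tile(np.sin(TIMES), (62, 1))
        assert ft.feat_lmfp(trace_from(data), ROIS["Fr"], N100) == \
            pytest.approx(0.0, abs=1e-12)

    def test_lmfp_matches_brute_force(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((62, TIMES.size))
        got = ft.feat_lmfp(trace_from(data), ROIS["Cp"], P200)
        assert got == pytest.approx(
            brute_lmfp(data, LAYOUT, ROIS["Cp"], P200, TIMES), abs=1e-12)

    def test_field_powers_invariant_to_common_shift(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((62, TIMES.size))
        shifted = data + 17.3  # same constant on every channel
        assert np.allclose(ft.gmfp(trace_from(data)),
                           ft.gmfp(trace_from(shifted)), atol=1e-10)
        assert ft.feat_lmfp(trace_from(data), ROIS["Fr"], N100) == \
            pytest.approx(ft.feat_lmfp(trace_from(shifted), ROIS["Fr"], N100),
                          abs=1e-10)


class TestRoiAverage:
    def test_constant_channels_average(self):
        data = np.zeros((62, TIMES.size))
        idx = LAYOUT.indices(ROIS["Fr"].channels)
        data[idx] = np.array([1.0, 1.0, 3.0, 3.0])[:, None]
        rt = ft.roi_average(trace_from(data), ROIS["Fr"])
        assert np.allclose(rt.x, 2.0)

    def test_single_channel_roi_identity(self):
        data = np.random.default_rng(4).standard_normal((62, TIMES.size))
        roi = RoiSpec("solo", ("Cz",))
        rt = ft.roi_average(trace_from(data), roi)
        assert np.array_equal(rt.x, data[LAYOUT.index("Cz")])

    def test_matches_brute_force(self):
        data = np.random.default_rng(5).standard_normal((62, TIMES.size))
        rt = ft.roi_average(trace_from(data), ROIS["Pl"])
        idx = LAYOUT.indices(ROIS["Pl"].channels)
        brute = sum(data[j] for j in idx) / len(idx)
        assert np.allclose(rt.x, brute, atol=1e-12)

    def test_missing_channel_rejected(self):
        small = TepTrace(np.zeros((2, 10)), TIMES[:10], 1000.0,
                         LAYOUT.subset(["F1", "F2"]))
        with pytest.raises(KeyError):
            ft.roi_average(small, ROIS["Fr"])


class TestPeak:
    def test_constructed_negative_peak(self):
        x = np.zeros(TIMES.size)
        bump = np.exp(-((TIMES - 0.13) ** 2) / (2 * 0.01**2))
        res = ft.feat_latency_amplitude(roi_trace_from(-bump), N100)
        assert res.latency == pytest.approx(0.13, abs=1e-9)
        assert res.amplitude == pytest.approx(-1.0, abs=1e-9)
        assert not res.edge_peak

    def test_p200_takes_maximum(self):
        bump = np.exp(-((TIMES - 0.22) ** 2) / (2 * 0.02**2))
        res = ft.feat_latency_amplitude(roi_trace_from(bump), P200)
        assert res.latency == pytest.approx(0.22, abs=1e-9)
        assert res.amplitude == pytest.approx(1.0, abs=1e-9)

    def test_monotone_ramp_flags_edge_peak(self):
        res = ft.feat_latency_amplitude(roi_trace_from(-TIMES.copy()), N100)
        assert res.edge_peak
        assert res.latency == pytest.approx(0.160, abs=1e-9)


class TestScalarFeatures:
    def test_std_alternating_unit_signal(self):
        x = np.zeros(TIMES.size)
        mask = N100.mask(TIMES)
        vals = np.where(np.arange(mask.sum()) % 2 == 0, 1.0, -1.0)
        # 61 samples: means is 1/61, not 0; use an exact +-1 pattern instead
        x[mask] = vals
        got = ft.feat_std(roi_trace_from(x), N100)
        assert got == pytest.approx(brute_std(x, N100, TIMES), abs=1e-12)

    def test_std_constant_is_zero(self):
        assert ft.feat_std(roi_trace_from(np.full(TIMES.size, 2.0)), N100) == 0

    def test_std_matches_brute_force(self):
        x = np.random.default_rng(6).standard_normal(TIMES.size)
        assert ft.feat_std(roi_trace_from(x), P200) == \
            pytest.approx(brute_std(x, P200, TIMES), abs=1e-12)

    def test_auc_constant_closed_form(self):
        # constant 1 uV over the 61-sample N100 window at 1 kHz: (N-1)/f
        got = ft.feat_auc(roi_trace_from(np.ones(TIMES.size)), N100)
        assert got == pytest.approx(0.060, abs=1e-12)

    def test_auc_antisymmetric_cancels(self):
        x = np.zeros(TIMES.size)
        mask = N100.mask(TIMES)
        n = mask.sum()
        x[mask] = np.linspace(-1, 1, n)
        assert ft.feat_auc(roi_trace_from(x), N100) == pytest.approx(0, abs=1e-12)

    def test_auc_matches_trapezoid_oracle(self):
        x = np.random.default_rng(7).standard_normal(TIMES.size)
        assert ft.feat_auc(roi_trace_from(x), P200) == \
            pytest.approx(brute_auc(x, P200, TIMES, 1000.0), abs=1e-12)

    def test_avg_and_range_hand_cases(self):
        const = roi_trace_from(np.full(TIMES.size, 2.0))
        assert ft.feat_avg(const, N100) == pytest.approx(2.0)
        assert ft.feat_range(const, N100) == 0.0
        x = np.zeros(TIMES.size)
        mask = np.flatnonzero(N100.mask(TIMES))
        x[mask[0]] = -3.0
        x[mask[1]] = 5.0
        assert ft.feat_range(roi_trace_from(x), N100) == pytest.approx(8.0)


class TestHomogeneityAndShift:
    @pytest.mark.parametrize("c", [2.0, -0.5, 10.0])
    def test_scaling_the_trace_scales_features(self, c):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((62, TIMES.size))
        base, scaled = trace_from(data), trace_from(c * data)
        for roi in (ROIS["Fr"], ROIS["O"]):
            assert ft.feat_lmfp(scaled, roi, N100) == \
                pytest.approx(abs(c) * ft.feat_lmfp(base, roi, N100), rel=1e-10)
        rb = ft.roi_average(base, ROIS["Fr"])
        rs = ft.roi_average(scaled, ROIS["Fr"])
        assert ft.feat_std(rs, N100) == pytest.approx(
            abs(c) * ft.feat_std(rb, N100), rel=1e-10)
        assert ft.feat_avg(rs, N100) == pytest.approx(
            c * ft.feat_avg(rb, N100), rel=1e-10)
        assert ft.feat_auc(rs, N100) == pytest.approx(
            c * ft.feat_auc(rb, N100), rel=1e-10)
        assert ft.feat_range(rs, N100) == pytest.approx(
            abs(c) * ft.feat_range(rb, N100), rel=1e-10)
        if c > 0:
            pb = ft.feat_latency_amplitude(rb, N100)
            ps = ft.feat_latency_amplitude(rs, N100)
            assert ps.latency == pb.latency
            assert ps.amplitude == pytest.approx(c * pb.amplitude, rel=1e-10)


class TestFeatureTable:
    def test_column_order_is_window_major(self):
        cols = ft.feature_columns()
        assert len(cols) == 98
        assert cols[0] == "N100.Fl.LMFP"
        assert cols[6] == "N100.Fl.Range"
        assert cols[7] == "N100.Fr.LMFP"
        assert cols[49] == "P200.Fl.LMFP"

    def test_micro_cohort_table_shape_and_determinism(self, micro_cohort):
        cohort, rois = micro_cohort
        a = ft.build_feature_table(cohort, rois=rois)
        b = ft.build_feature_table(cohort, rois=rois)
        assert a.shape == (len(cohort) * 3, 3 + 98)
        assert a.equals(b)
        assert not a.filter(regex=r"\.").isna().any().any()

    def test_each_roi_contributes_14_columns(self, micro_table):
        for roi in ROI_ORDER:
            roi_cols = [c for c in micro_table.columns
                        if c.split(".")[1:2] == [roi]]
            assert len(roi_cols) == 14

    def test_three_rows_per_subject_with_segment_index(self, micro_table):
        counts = micro_table.groupby("subject_id")["segment"].apply(list)
        assert all(v == [1, 2, 3] for v in counts)
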