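"""Expansion analysis: step detection, opening angle, summary statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fpsense
from fpsense import (
    ExpanderGeometry,
    InvalidInputError,
    InvalidWindowError,
    ReconciliationError,
    SensorTimeSeries,
)

GEOM = ExpanderGeometry()  # s = 900 um, pitch 0.8 mm, 1/6 turn


def make_series(plateaus, plateau_len=60, noise_sd=0.0, seed=0, channel="S1"):
    """Staircase series: `plateaus` cavity lengths, `plateau_len` samples each."""
    rng = np.random.default_rng(seed)
    d = np.concatenate([np.full(plateau_len, v) for v in plateaus])
    if noise_sd > 0:
        d = d + rng.normal(0, noise_sd, d.size)
    t = np.arange(d.size, dtype=float)
    return SensorTimeSeries(t, d, np.full(d.size, 400), [""] * d.size, channel=channel)


class TestExpectedExpansion:
    def test_one_sixth_turn_is_about_130um(self):
        per_load = fpsense.expected_expansion(1.0 / 6.0, GEOM)
        assert round(per_load, 2) == 0.13
        assert per_load == pytest.approx(0.8 / 6)

    def test_half_turn_total(self):
        assert fpsense.expected_expansion(0.5, GEOM) == pytest.approx(0.4)

    def test_zero_and_negative(self):
        assert fpsense.expected_expansion(0.0, GEOM) == 0.0
        with pytest.raises(InvalidInputError):
            fpsense.expected_expansion(-1.0, GEOM)


class TestExpansionAngle:
    def test_first_load_v_type_value(self):
        theta = fpsense.expansion_angle(27.0, 0.0, 900.0)
        assert theta == pytest.approx(0.03)
        assert round(fpsense.rad_to_deg(theta), 2) == 1.72

    def test_third_load_angle_in_degrees(self):
        assert round(fpsense.rad_to_deg(0.031), 2) == 1.78

    def test_parallel_expansion_is_zero(self):
        assert fpsense.expansion_angle(130.0, 130.0, 900.0) == 0.0

    @given(
        st.floats(-500, 500),
        st.floats(-500, 500),
        st.floats(100, 5000),
        st.floats(0.1, 10),
    )
    def test_antisymmetric_and_inverse_in_separation(self, da, dp, s, scale):
        theta = fpsense.expansion_angle(da, dp, s)
        assert fpsense.expansion_angle(dp, da, s) == pytest.approx(-theta, abs=1e-12)
        assert fpsense.expansion_angle(da, dp, s * scale) == pytest.approx(
            theta / scale, abs=1e-9
        )

    def test_rejects_nonpositive_separation(self):
        with pytest.raises(InvalidInputError):
            fpsense.expansion_angle(27.0, 0.0, 0.0)


class TestDetectSteps:
    def test_clean_staircase_recovered(self):
        series = make_series([300, 430, 560, 690], noise_sd=0.5, seed=3)
        records = fpsense.detect_steps(series)
        assert len(records) == 3
        for rec, expected_onset in zip(records, (60.0, 120.0, 180.0)):
            assert rec.delta_um == pytest.approx(130.0, abs=0.5)
            assert rec.onset_s == expected_onset
        assert records[-1].cumulative_um == pytest.approx(390.0, abs=0.5)

    def test_flat_noisy_series_has_no_steps(self):
        series = make_series([300], plateau_len=200, noise_sd=0.5, seed=4)
        assert fpsense.detect_steps(series) == []

    def test_unequal_first_steps_per_channel(self):
        s1 = make_series([285, 401.5, 531.5, 661.5], noise_sd=0.5, seed=5, channel="S1")
        s2 = make_series([300, 443.5, 573.5, 703.5], noise_sd=0.5, seed=6, channel="S2")
        r1 = fpsense.detect_steps(s1)
        r2 = fpsense.detect_steps(s2)
        assert r1[0].delta_um == pytest.approx(116.5, abs=0.5)
        assert r2[0].delta_um == pytest.approx(143.5, abs=0.5)

    def test_step_sizes_within_3x_noise_for_10x_steps(self):
        # steps of 10x the noise SD are the smallest the contract covers
        sd = 2.0
        series = make_series([300, 320, 340], noise_sd=sd, seed=7)
        records = fpsense.detect_steps(series, min_step_um=10.0)
        assert len(records) == 2
        for rec in records:
            assert rec.delta_um == pytest.approx(20.0, abs=3 * sd)

    def test_lone_outlier_is_not_a_step(self):
        series = make_series([300, 430], noise_sd=0.1, seed=8)
        series.d_um[30] = 520.0  # single corrupted sample inside plateau 1
        records = fpsense.detect_steps(series)
        assert len(records) == 1
        assert records[0].delta_um == pytest.approx(130.0, abs=0.5)


class TestBaselineNoise:
    def test_constant_plateau_is_zero(self):
        series = make_series([300.0])
        assert fpsense.baseline_noise(series, (0.0, 59.0)) == 0.0

    def test_recovers_configured_sd_within_30pct(self):
        sigma = 2.5
        series = make_series([300.0], plateau_len=60, noise_sd=sigma, seed=11)
        est = fpsense.baseline_noise(series, (0.0, 59.0))
        assert abs(est - sigma) / sigma < 0.30

    def test_window_crossing_activation_rejected(self):
        series = make_series([300, 430], noise_sd=0.2, seed=12)
        with pytest.raises(InvalidWindowError):
            fpsense.baseline_noise(series, (40.0, 80.0))

    def test_too_few_samples_rejected(self):
        series = make_series([300.0])
        with pytest.raises(InvalidWindowError):
            fpsense.baseline_noise(series, (0.0, 5.0))


class TestSummarize:
    def _pair(self, first_split=(143.5, 116.5), noise_sd=0.3):
        ant = make_series(
            [300, 300 + first_split[0], 300 + first_split[0] + 130,
             300 + first_split[0] + 260],
            noise_sd=noise_sd, seed=21, channel="S2",
        )
        post = make_series(
            [285, 285 + first_split[1], 285 + first_split[1] + 130,
             285 + first_split[1] + 260],
            noise_sd=noise_sd, seed=22, channel="S1",
        )
        return ant, post

    def test_v_type_first_load_then_parallel(self):
        ant, post = self._pair()
        summary = fpsense.summarize(ant, post, GEOM, [1 / 6] * 3)
        assert summary.n_activations == 3
        assert summary.angle_rad[0] == pytest.approx(0.03, abs=0.002)
        # later loads keep the same difference: angle stays at load-1 value
        assert summary.angle_rad[2] == pytest.approx(summary.angle_rad[0], abs=0.002)
        assert summary.average_cum_um[0] == pytest.approx(130.0, abs=1.0)
        assert summary.expected_um[-1] == pytest.approx(400.0, abs=1e-9)

    def test_parallel_expansion_zero_angle_zero_error(self):
        step = 0.8e3 / 6  # exactly the screw-driven expectation, in um
        ant = make_series([300, 300 + step, 300 + 2 * step], channel="S2")
        post = make_series([285, 285 + step, 285 + 2 * step], channel="S1")
        summary = fpsense.summarize(ant, post, GEOM, [1 / 6] * 2)
        assert np.allclose(summary.angle_rad, 0.0)
        assert summary.error_mean_um == pytest.approx(0.0, abs=1e-9)
        assert summary.error_sd_um == pytest.approx(0.0, abs=1e-9)

    def test_displacement_conservation(self):
        ant, post = self._pair()
        for series in (ant, post):
            records = fpsense.detect_steps(series)
            total = sum(r.delta_um for r in records)
            assert total == pytest.approx(records[-1].cumulative_um, abs=0.5)

    def test_schedule_mismatch_raises(self):
        ant, post = self._pair()
        with pytest.raises(ReconciliationError):
            fpsense.summarize(ant, post, GEOM, [1 / 6] * 2)

    def test_report_table_shape(self):
        ant, post = self._pair()
        summary = fpsense.summarize(ant, post, GEOM, [1 / 6] * 3)
        frame = summary.to_frame()
        assert list(frame["activation"]) == [1, 2, 3]
        assert {"average_um", "expected_um", "angle_rad", "angle_deg"} <= set(frame.columns)
        doc = summary.to_dict()
        assert doc["anterior_channel"] == "S2"
        assert len(doc["per_activation"]) == 3
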