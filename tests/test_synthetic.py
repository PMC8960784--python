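"""Synthetic cohort generator: pen/accel synthesis, calibration, cohorts."""

import filecmp

import numpy as np
import pytest

import spiraltremor as st
from spiraltremor.errors import AliasingError, InvalidParameterError
from spiraltremor.features import MagnitudeSignal
from spiraltremor.synthetic import MIN_TASK_TIME

FS = 148.1


# ---------------------------------------------------------------------------
# pen synthesis
# ---------------------------------------------------------------------------


def test_pen_sample_counts():
    pen = st.synth_spiral_pen(10.0, fs_pen=100.0, lead_pen_up=1.0, seed=0)
    assert int(pen.pen_down.sum()) == 1000
    assert not pen.pen_down[:100].any()


@pytest.mark.parametrize("duration", [5.0, 12.64, 26.92])
def test_pen_task_time_equals_duration(duration):
    pen = st.synth_spiral_pen(duration, seed=1)
    w = st.segment_task(pen)
    assert abs(w.pen_down_duration - duration) <= 1.0 / pen.fs + 1e-9


def test_pen_spiral_angle_span():
    """Arctangent-unwrapping oracle: 3 turns span 6*pi within 1%."""
    pen = st.synth_spiral_pen(15.0, n_turns=3, seed=2)
    down = pen.pen_down
    theta = np.unwrap(np.arctan2(pen.y[down], pen.x[down]))
    assert (theta[-1] - theta[0]) == pytest.approx(6 * np.pi, rel=0.01)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"duration_drawing": 0.0},
        {"duration_drawing": -3.0},
        {"duration_drawing": 10.0, "n_turns": 0},
        {"duration_drawing": 10.0, "fs_pen": 0.0},
        {"duration_drawing": 10.0, "lead_pen_up": -1.0},
    ],
)
def test_pen_invalid_parameters(kwargs):
    with pytest.raises(InvalidParameterError):
        st.synth_spiral_pen(**kwargs)


# ---------------------------------------------------------------------------
# accelerometer synthesis
# ---------------------------------------------------------------------------


def _spec(amp, freq=6.5, noise=0.0):
    return st.TremorSpec(tremor_freq=freq, tremor_amplitude=amp, noise_sd=noise)


def test_synth_accel_seeded_determinism():
    pen = st.synth_spiral_pen(10.0, seed=3)
    a = st.synth_accel(pen, _spec(0.1, noise=0.01), seed=4)
    b = st.synth_accel(pen, _spec(0.1, noise=0.01), seed=4)
    for col in ("t", "ax", "ay", "az"):
        np.testing.assert_array_equal(getattr(a, col), getattr(b, col))


def test_synth_accel_no_tremor_has_low_band_ratio():
    pen = st.synth_spiral_pen(12.0, seed=3)
    acc = st.synth_accel(pen, _spec(0.0), seed=4)
    assert st.extract_features(acc, pen, "x").psd_ratio < 0.2


def test_synth_accel_ratio_quadratic_in_amplitude():
    """Band-power arithmetic: power scales with amplitude^2, so doubling the
    tremor amplitude quadruples the ratio (once tremor dominates leakage)."""
    pen = st.synth_spiral_pen(12.0, seed=3)
    r1 = st.extract_features(st.synth_accel(pen, _spec(0.2), seed=4), pen, "x").psd_ratio
    r2 = st.extract_features(st.synth_accel(pen, _spec(0.4), seed=4), pen, "x").psd_ratio
    assert r2 / r1 == pytest.approx(4.0, rel=0.05)


def test_synth_accel_aliasing_guard():
    pen = st.synth_spiral_pen(10.0, seed=3)
    with pytest.raises(AliasingError):
        st.synth_accel(pen, _spec(0.1, freq=11.0), fs=20.0, seed=4)


def test_tremor_spec_validation():
    with pytest.raises(InvalidParameterError):
        st.TremorSpec(tremor_freq=4.0, tremor_amplitude=0.1)  # band edge excluded
    with pytest.raises(InvalidParameterError):
        st.TremorSpec(tremor_freq=6.0, tremor_amplitude=-1.0)


# ---------------------------------------------------------------------------
# amplitude calibration
# ---------------------------------------------------------------------------


def test_calibrate_amplitude_zero_target():
    t = np.arange(int(30 * FS)) / FS
    vol = MagnitudeSignal(t, np.sin(2 * np.pi * 2 * t) + 2.0, FS)
    assert st.calibrate_amplitude(0.0, vol, 6.0) == 0.0


def test_calibrate_amplitude_pure_tone_inversion():
    """(A^2/2)/(1^2/2) = 4 -> A = 2 for a unit 2 Hz voluntary tone."""
    t = np.arange(int(30 * FS)) / FS
    vol = MagnitudeSignal(t, np.sin(2 * np.pi * 2 * t) + 2.0, FS)
    A = st.calibrate_amplitude(4.0, vol, 6.0)
    assert A == pytest.approx(2.0, rel=0.1)


def test_calibrate_amplitude_round_trip():
    """Adding the calibrated tone reproduces the target ratio within 10%."""
    t = np.arange(int(30 * FS)) / FS
    base = np.sin(2 * np.pi * 2 * t) + 0.4 * np.sin(2 * np.pi * 1.1 * t)
    vol = MagnitudeSignal(t, base + 8.0, FS)
    for target in (0.5, 2.84, 6.96):
        A = st.calibrate_amplitude(target, vol, 7.0)
        mixed = MagnitudeSignal(t, base + 8.0 + A * np.sin(2 * np.pi * 7.0 * t), FS)
        r = st.psd_ratio(st.highpass(mixed)).ratio
        assert r == pytest.approx(target, rel=0.10)


# ---------------------------------------------------------------------------
# moment-matched truncated normal
# ---------------------------------------------------------------------------


def test_truncated_normal_mean_matches_target(rng):
    """Monte-Carlo oracle: the truncated draw is centred on the configured
    mean even when the SD exceeds it (the Table-style 0.79 +/- 1.12 cell)."""
    draws = st.truncated_normal(rng, 0.79, 1.12, lower=0.0, size=40000)
    assert np.all(draws >= 0)
    se = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - 0.79) < 3 * se


def test_truncated_normal_degenerate_sd():
    rng = np.random.default_rng(0)
    assert st.truncated_normal(rng, 5.0, 0.0) == 5.0


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def test_default_cohort_group_sizes(default_cohort):
    sizes = {}
    for s in default_cohort:
        sizes[s.group_label] = sizes.get(s.group_label, 0) + 1
    assert sizes == {"control": 18, "ET0": 6, "ET1plus": 5, "ET2plus": 6}


def test_cohort_written_bytes_are_deterministic(tmp_path):
    small = [
        st.GroupParams("control", 2, (0.55, 0.79, 0.81), (0.37, 1.12, 0.60), 10.0, 2.0),
        st.GroupParams("ET0", 2, (2.15, 2.84, 0.88), (1.66, 2.42, 1.14), 12.0, 3.0),
    ]
    d1, d2 = tmp_path / "a", tmp_path / "b"
    st.write_cohort(st.make_cohort(small, seed=7), d1)
    st.write_cohort(st.make_cohort(small, seed=7), d2)
    files = sorted(p.name for p in d1.iterdir())
    assert files == sorted(p.name for p in d2.iterdir())
    match, mismatch, errors = filecmp.cmpfiles(d1, d2, files, shallow=False)
    assert mismatch == [] and errors == []


def test_cohort_degenerate_sds_give_identical_features():
    """With zero SDs and zero noise every subject in a group collapses onto
    the same feature point (up to calibration tolerance)."""
    params = [
        st.GroupParams("ET0", 4, (2.0, 3.0, 1.0), (0.0, 0.0, 0.0), 15.0, 0.0, 16.0)
    ]
    cohort = st.make_cohort(params, seed=9, noise_sd=0.0)
    feats = [
        st.extract_features(s.accel_by_site["S2"], s.pen, s.subject_id)
        for s in cohort
    ]
    ratios = np.array([f.psd_ratio for f in feats])
    times = np.array([f.task_time for f in feats])
    np.testing.assert_allclose(ratios, ratios[0], rtol=0.05)
    np.testing.assert_allclose(times, times[0], rtol=1e-9)


def test_cohort_mean_ratio_is_monotone_in_configured_mean():
    base = [st.GroupParams("ET0", 6, (2.0, 3.0, 1.0), (0.5, 0.5, 0.3), 15.0, 2.0, 16.0)]
    raised = [st.GroupParams("ET0", 6, (2.0, 5.0, 1.0), (0.5, 0.5, 0.3), 15.0, 2.0, 16.0)]

    def mean_ratio(params):
        cohort = st.make_cohort(params, seed=11)
        return np.mean(
            [
                st.extract_features(s.accel_by_site["S2"], s.pen, s.subject_id).psd_ratio
                for s in cohort
            ]
        )

    assert mean_ratio(raised) > mean_ratio(base)


def test_cohort_task_times_respect_minimum():
    cohort = st.make_cohort(seed=13)
    for s in cohort:
        assert s.targets["task_time"] >= MIN_TASK_TIME


def test_cohort_controls_lack_ftm(default_cohort):
    for s in default_cohort:
        if s.group_label == "control":
            assert s.clinical.ftm_mean is None
        else:
            assert s.clinical.ftm_mean is not None and s.clinical.ftm_mean >= 0


def test_make_cohort_requires_groups():
    with pytest.raises(InvalidParameterError):
        st.make_cohort([], seed=1)
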