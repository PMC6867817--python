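"""Pupil cleaning, eye selection, trial exclusion, convolution GLM."""

import numpy as np
import pytest
from scipy import signal

from threatphys.containers import ChannelRecording
from threatphys.design import CS, Phase, TrialSequence, TrialSpec, assign_timing
from threatphys.kernels import psrf_kernel
from threatphys.pupil import (PupilPipelineConfig, clean_pupil,
                              exclude_pupil_trials, fit_pupil_glm,
                              gaze_to_degrees, select_eye)

RATE = 500.0


def _channels(n, gaze_deg=0.0):
    area = ChannelRecording(np.full(n, 1000.0), RATE, name="pupil")
    gaze = ChannelRecording(np.full((n, 2), gaze_deg), RATE, name="gaze")
    return area, gaze


def test_gaze_conversion_matches_trigonometric_oracle():
    offsets_cm = np.array([-10.0, -1.0, 0.0, 2.5, 12.0])
    got = gaze_to_degrees(offsets_cm, 70.0)
    want = np.degrees(np.arctan2(offsets_cm, 70.0))
    assert np.allclose(got, want)


def test_offscreen_gaze_masked():
    n = int(10 * RATE)
    area, gaze = _channels(n)
    gaze.data[int(3 * RATE):int(4 * RATE), 0] = 6.0   # 1 s excursion to 6 deg
    out = clean_pupil(area, gaze, [])
    t = out.times()
    assert not out.valid[(t >= 3.0) & (t < 4.0)].any()
    assert out.valid[(t < 3.0) | (t >= 4.0)].all()


def test_clean_gaze_and_no_blinks_keeps_all_samples():
    area, gaze = _channels(int(5 * RATE))
    out = clean_pupil(area, gaze, [])
    assert out.valid.all()


def test_misaligned_channels_rejected():
    area, _ = _channels(1000)
    _, gaze = _channels(999)
    with pytest.raises(ValueError, match="misaligned"):
        clean_pupil(area, gaze, [])


def test_select_eye_prefers_fewer_missing_and_ties_go_left():
    n = 1000
    left = ChannelRecording(np.ones(n), RATE,
                            valid=np.r_[np.zeros(100, bool), np.ones(900, bool)])
    right = ChannelRecording(np.ones(n), RATE,
                             valid=np.r_[np.zeros(50, bool), np.ones(950, bool)])
    assert select_eye(left, right) is right
    even = ChannelRecording(np.ones(n), RATE,
                            valid=np.r_[np.zeros(50, bool), np.ones(950, bool)])
    assert select_eye(even, right) is even       # tie -> left argument


def test_exclusion_boundary_exactly_half_is_included():
    seq = TrialSequence(Phase.ACQUISITION, [
        TrialSpec(index=1, cs=CS.CS_MINUS, iti_s=9.0, cs_onset_s=0.0),
        TrialSpec(index=2, cs=CS.CS_MINUS, iti_s=9.0, cs_onset_s=20.0),
        TrialSpec(index=3, cs=CS.CS_MINUS, iti_s=9.0, cs_onset_s=40.0),
    ])
    n = int(60 * RATE)
    valid = np.ones(n, bool)
    w = int(10 * RATE)
    # trial 1: exactly 50% valid -> included; trial 2: 49.9% -> excluded
    valid[:w // 2] = False
    i2 = int(20 * RATE)
    valid[i2:i2 + w - int(0.499 * w)] = False
    rec = ChannelRecording(np.ones(n), RATE, valid=valid)
    flags = exclude_pupil_trials(rec, seq)
    assert flags.loc[0, "included"]
    assert not flags.loc[1, "included"]
    assert flags.loc[2, "included"]


def test_excess_missing_trials_warns():
    seq = TrialSequence(Phase.ACQUISITION, [
        TrialSpec(index=i + 1, cs=CS.CS_MINUS, iti_s=9.0, cs_onset_s=20.0 * i)
        for i in range(3)
    ])
    n = int(60 * RATE)
    valid = np.ones(n, bool)
    valid[:int(12 * RATE)] = False
    valid[int(20 * RATE):int(32 * RATE)] = False
    rec = ChannelRecording(np.ones(n), RATE, valid=valid)
    with pytest.warns(RuntimeWarning, match="excluded"):
        exclude_pupil_trials(rec, seq)


def _noiseless_session(amps, seed=3):
    trials = [TrialSpec(index=i + 1, cs=CS.CS_MINUS) for i in range(len(amps))]
    seq = assign_timing(TrialSequence(Phase.ACQUISITION, trials), seed=seed)
    n = int(seq.duration_s * RATE)
    k = psrf_kernel().sample(RATE)
    x = np.full(n, 1000.0)
    for t, a in zip(seq, amps):
        j = int(t.cs_onset_s * RATE)
        imp = np.zeros(n)
        imp[j] = a
        x += signal.fftconvolve(imp, k)[:n]
    return seq, ChannelRecording(x, RATE, name="pupil")


def test_noiseless_glm_recovers_amplitudes_to_numerical_precision():
    amps = np.array([3.0, 1.0, 2.0, 0.5, 4.0])
    seq, rec = _noiseless_session(amps)
    tab = fit_pupil_glm(rec, seq)
    # tolerance reflects the block-mean downsampling discretization
    assert np.allclose(tab["amplitude"], amps, rtol=1e-3)


def test_glm_equals_normal_equation_oracle_on_toy_session():
    amps = np.array([2.0, 1.0, 3.0])
    seq, rec = _noiseless_session(amps, seed=9)
    config = PupilPipelineConfig()
    tab = fit_pupil_glm(rec, seq, config)

    # explicit normal equations at the GLM's working rate
    step = int(RATE / config.target_rate_hz)
    n = (rec.n_samples // step) * step
    y = rec.data[:n].reshape(-1, step).mean(axis=1)
    m = len(y)
    k = config.kernel.sample(config.target_rate_hz)
    cols = []
    for t in seq:
        x = np.zeros(m)
        x[int(t.cs_onset_s * config.target_rate_hz)] = 1.0
        cols.append(signal.fftconvolve(x, k)[:m])
    tt = np.linspace(-1, 1, m)
    X = np.column_stack(cols + [np.ones(m), tt])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(tab["amplitude"], beta[:3], rtol=1e-8)


def test_masked_samples_do_not_influence_glm():
    amps = np.array([3.0, 1.0, 2.0])
    seq, rec = _noiseless_session(amps)
    rec.valid[int(5 * RATE):int(7 * RATE)] = False
    a = fit_pupil_glm(rec, seq)
    tampered = rec.copy()
    tampered.data[~tampered.valid] = 1e6
    b = fit_pupil_glm(tampered, seq)
    assert np.allclose(a["amplitude"].dropna(), b["amplitude"].dropna())


def test_excluded_trials_get_missing_amplitudes():
    amps = np.array([3.0, 1.0, 2.0])
    seq, rec = _noiseless_session(amps)
    i = int(seq.trials[1].cs_onset_s * RATE)
    rec.valid[i:i + int(6 * RATE)] = False   # 60% missing in the 10 s window
    tab = fit_pupil_glm(rec, seq)
    assert not tab.loc[1, "included"]
    assert np.isnan(tab.loc[1, "amplitude"])
    assert np.isfinite(tab.loc[0, "amplitude"])
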