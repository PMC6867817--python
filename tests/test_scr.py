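"""SCR artifact handling, preprocessing, and model inversion."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from threatphys.containers import ChannelRecording
from threatphys.design import CS, Phase, TrialSequence, TrialSpec, assign_timing
from threatphys.scr import (ScrPipelineConfig, exclude_scr_trials, invert_scr,
                            preprocess_scr, select_scr_trials)
from threatphys.synthgen import SimConfig, simulate_scr, true_amplitudes

RATE = 1000.0


def _single_trial_seq(onset=10.0, reinforced=False):
    t = TrialSpec(index=1, cs=CS.CSR_PLUS if reinforced else CS.CS_MINUS,
                  reinforced=reinforced, iti_s=9.0, cs_onset_s=onset)
    if reinforced:
        t.us_onset_s = onset + 3.5
    return TrialSequence(Phase.ACQUISITION, [t])


def _forward(amp, lat, n_s=40.0, evoked=0.0, config=None, onset=10.0):
    """Independent forward model: dispersed input ⊛ SCRF at full rate."""
    config = config or ScrPipelineConfig()
    n = int(n_s * RATE)
    k = config.kernel.sample(RATE)
    idx = np.arange(n)
    sd = config.dispersion_s * RATE
    center = (onset + lat) * RATE
    bump = np.exp(-0.5 * ((idx - center) / sd) ** 2)
    x = signal.fftconvolve(amp * bump / bump.sum(), k)[:n]
    if evoked:
        d = np.zeros(n)
        d[int((onset + 3.5) * RATE)] = evoked
        x += signal.fftconvolve(d, k)[:n]
    return ChannelRecording(x, RATE, units="uS")


def test_constant_input_filtered_to_zero():
    pre = preprocess_scr(ChannelRecording(np.full(60000, 5.0), RATE), [])
    assert np.max(np.abs(pre.data)) < 1e-6


def test_downsampled_to_target_rate_with_mask():
    pre = preprocess_scr(ChannelRecording(np.zeros(60000), RATE),
                         [(10.0, 11.0)])
    assert pre.rate_hz == 10.0
    t = pre.times()
    inside = (t >= 10.0) & (t < 11.0)
    assert not pre.valid[inside].any()
    assert pre.valid[~inside].all()


def test_overlapping_artifact_intervals_rejected():
    with pytest.raises(ValueError, match="overlap"):
        preprocess_scr(ChannelRecording(np.zeros(60000), RATE),
                       [(1.0, 3.0), (2.0, 4.0)])


def test_short_artifact_keeps_trial_long_artifact_excludes():
    seq = assign_timing(TrialSequence(Phase.ACQUISITION, [
        TrialSpec(index=1, cs=CS.CS_MINUS),
        TrialSpec(index=2, cs=CS.CS_MINUS),
    ]), seed=0)
    t2 = seq.trials[1]
    short = [(seq.trials[0].cs_onset_s + 1.0, seq.trials[0].cs_onset_s + 2.5)]
    long = [(t2.cs_onset_s + 1.0, t2.cs_onset_s + 4.0)]
    assert exclude_scr_trials(seq, short) == {}
    assert exclude_scr_trials(seq, long) == {2: "artifact"}


def test_single_response_recovered():
    """Zero noise: 1 μS at 0.5 s -> (1.00 ± 0.05, 0.5 ± 0.1)."""
    pre = preprocess_scr(_forward(1.0, 0.5), [])
    est = invert_scr(pre, _single_trial_seq())[0]
    assert est.anticipatory_amplitude == pytest.approx(1.0, abs=0.05)
    assert est.anticipatory_latency_s == pytest.approx(0.5, abs=0.1)


def test_anticipatory_and_evoked_disentangled():
    """Overlapping 0.5 μS anticipatory + 1.5 μS evoked, both within 10%."""
    pre = preprocess_scr(_forward(0.5, 1.0, evoked=1.5), [])
    est = invert_scr(pre, _single_trial_seq(reinforced=True))[0]
    assert est.anticipatory_amplitude == pytest.approx(0.5, rel=0.10)
    assert est.evoked_amplitude == pytest.approx(1.5, rel=0.10)


def test_matches_brute_force_two_parameter_grid():
    """Independent oracle: dense latency grid with per-point NNLS on
    independently constructed regressors."""
    config = ScrPipelineConfig()
    pre = preprocess_scr(_forward(0.8, 0.7, evoked=1.2), [])
    est = invert_scr(pre, _single_trial_seq(reinforced=True), config)[0]

    y = pre.data
    t = pre.times()
    sos = signal.butter(1, config.bandpass_hz, btype="bandpass",
                        fs=RATE, output="sos")
    k = config.kernel.sample(RATE)

    def col(center_s, dispersed):
        x = np.zeros(int(len(y) / 10 * RATE))
        if dispersed:
            sd = config.dispersion_s * RATE
            b = np.exp(-0.5 * ((np.arange(len(x)) - center_s * RATE) / sd) ** 2)
            x = b / b.sum()
        else:
            x[int(center_s * RATE)] = 1.0
        c = signal.fftconvolve(x, k)[:len(x)]
        return signal.sosfiltfilt(sos, c)[::100]

    from scipy.optimize import nnls
    best = None
    ev = col(13.5, False)
    for lat in np.arange(0.0, 2.0001, 0.05):
        X = np.column_stack([col(10.0 + lat, True), ev])
        amps, r = nnls(X, y)
        if best is None or r < best[0] - 1e-12:
            best = (r, lat, amps)
    assert est.anticipatory_latency_s == pytest.approx(best[1], abs=0.051)
    assert est.anticipatory_amplitude == pytest.approx(best[2][0], rel=0.05)
    assert est.evoked_amplitude == pytest.approx(best[2][1], rel=0.05)


def test_evoked_estimated_on_unreinforced_trials_blind_to_us():
    """The inversion models a potential US response on every trial."""
    pre = preprocess_scr(_forward(1.0, 0.5), [])
    est = invert_scr(pre, _single_trial_seq(reinforced=False))[0]
    assert est.evoked_amplitude is not None
    assert est.evoked_amplitude == pytest.approx(0.0, abs=0.1)


def test_masked_samples_have_zero_influence():
    pre = preprocess_scr(_forward(1.0, 0.5), [(20.0, 21.5)])
    est1 = invert_scr(pre, _single_trial_seq())[0]
    tampered = pre.copy()
    tampered.data[~tampered.valid] = 99.0
    est2 = invert_scr(tampered, _single_trial_seq())[0]
    assert est1.anticipatory_amplitude == est2.anticipatory_amplitude
    assert est1.anticipatory_latency_s == est2.anticipatory_latency_s


def test_latency_stays_in_bounds(acquisition_seq, quiet_config, rng):
    amps = true_amplitudes(acquisition_seq, "scr", "placebo", quiet_config)
    rec, truth, ivs = simulate_scr(acquisition_seq, amps, quiet_config, rng)
    ests = invert_scr(preprocess_scr(rec, ivs), acquisition_seq)
    lats = [e.anticipatory_latency_s for e in ests if not e.excluded]
    assert all(0.0 <= l <= 2.0 for l in lats)


def test_select_keeps_only_nonreinforced_trials(acquisition_seq):
    from threatphys.scr import ScrTrialEstimate
    ests = [ScrTrialEstimate(t.index, 1.0, 0.5, 0.0)
            for t in acquisition_seq]
    out = select_scr_trials(ests, acquisition_seq)
    n_nonreinf = sum(not t.reinforced for t in acquisition_seq)
    assert len(out) == n_nonreinf
    assert not out["reinforced"].any()


def test_select_all_reinforced_warns_and_returns_empty():
    from threatphys.scr import ScrTrialEstimate
    seq = _single_trial_seq(reinforced=True)
    ests = [ScrTrialEstimate(1, 1.0, 0.5, 0.0)]
    with pytest.warns(RuntimeWarning, match="no nonreinforced"):
        out = select_scr_trials(ests, seq)
    assert out.empty


def test_session_recovery_zero_noise(acquisition_seq, quiet_config, rng):
    amps = true_amplitudes(acquisition_seq, "scr", "placebo", quiet_config)
    rec, truth, ivs = simulate_scr(acquisition_seq, amps, quiet_config, rng)
    tab = select_scr_trials(invert_scr(preprocess_scr(rec, ivs),
                                       acquisition_seq), acquisition_seq)
    m = tab.merge(truth, on="trial", suffixes=("_est", "_true"))
    r = np.corrcoef(m["amplitude_est"], m["amplitude_true"])[0, 1]
    assert r > 0.98
    assert m["amplitude_est"].mean() == pytest.approx(
        m["amplitude_true"].mean(), rel=0.10)
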