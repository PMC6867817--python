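"""Startle eye-blink response (SEBR) quantification from orbicularis EMG.

Processing chain: 4th-order Butterworth band-pass (50–470 Hz), notch filters
at 50 Hz and harmonics, rectification, 4th-order low-pass smoothing at
53.05 Hz (3 ms time constant), then per-trial amplitude estimation by linear
regression of the envelope onto a canonical blink kernel whose onset is
searched on a grid after the startle probe.  Electrode impedance and muscle
anatomy scale the recorded EMG multiplicatively per participant, so raw
amplitudes are normalized by each participant's mean CS⁻ amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import ChannelRecording
from .kernels import CanonicalKernel, sebr_kernel


@dataclass
class EmgPipelineConfig:
    bandpass_hz: tuple[float, float] = (50.0, 470.0)
    bandpass_order: int = 4
    notch_base_hz: float = 50.0
    notch_q: float = 35.0
    smooth_cutoff_hz: float = 53.05
    smooth_order: int = 4
    onset_window_s: tuple[float, float] = (0.0, 0.15)  # search grid post probe
    onset_step_s: float = 0.001
    kernel: CanonicalKernel = field(default_factory=sebr_kernel)

    def __post_init__(self) -> None:
        low, high = self.bandpass_hz
        if not 0 < low < high:
            raise ValueError("bandpass cutoffs must satisfy 0 < low < high")
        if not (0 <= self.onset_window_s[0] < self.onset_window_s[1] <= 0.2):
            raise ValueError("onset window must lie within [0, 0.2] s")

    def notch_harmonics(self) -> list[float]:
        """Mains harmonics below the band-pass high cutoff."""
        base, high = self.notch_base_hz, self.bandpass_hz[1]
        return [base * k for k in range(1, int(high / base) + 1)
                if base * k < high]


@dataclass
class SebrEstimate:
    trial: int
    amplitude: float
    onset_s: float | None
    fit_r2: float
    flat: bool = False  # all-zero segment; onset undefined


def preprocess_emg(raw: ChannelRecording,
                   config: EmgPipelineConfig | None = None) -> ChannelRecording:
    """Band-pass + mains-notch filter, rectify, and smooth raw EMG.

    All filters are applied bidirectionally (zero phase).  Returns the
    nonnegative rectified-smoothed envelope at the input rate.
    """
    config = config or EmgPipelineConfig()
    low, high = config.bandpass_hz
    if raw.rate_hz < 2 * high:
        raise ValueError(
            f"sampling rate {raw.rate_hz} Hz below 2x high cutoff {high} Hz")
    x = raw.data
    if not np.all(np.isfinite(x)):
        raise ValueError("EMG contains non-finite samples")

    sos = signal.butter(config.bandpass_order, [low, high], btype="bandpass",
                        fs=raw.rate_hz, output="sos")
    y = signal.sosfiltfilt(sos, x)
    for f0 in config.notch_harmonics():
        b, a = signal.iirnotch(f0, config.notch_q, fs=raw.rate_hz)
        y = signal.filtfilt(b, a, y)
    y = np.abs(y)
    sos_lp = signal.butter(config.smooth_order, config.smooth_cutoff_hz,
                           btype="lowpass", fs=raw.rate_hz, output="sos")
    y = signal.sosfiltfilt(sos_lp, y)
    np.clip(y, 0.0, None, out=y)
    return raw.copy(data=y, name="emg_envelope")


def fit_sebr_trial(envelope: ChannelRecording, probe_onset_s: float,
                   config: EmgPipelineConfig | None = None,
                   trial: int = 0) -> SebrEstimate:
    """Estimate one trial's blink amplitude by variable-onset kernel regression.

    The canonical kernel is slid over a 1 ms onset grid after the probe; the
    amplitude is the nonnegative least-squares coefficient at the onset with
    minimal residual sum of squares (ties broken toward the earliest onset).
    """
    config = config or EmgPipelineConfig()
    rate = envelope.rate_hz
    # regressor passes through the same smoothing as the data envelope
    k = config.kernel.sample(rate)
    sos_lp = signal.butter(config.smooth_order, config.smooth_cutoff_hz,
                           btype="lowpass", fs=rate, output="sos")
    pad = int(round(0.05 * rate))
    k = signal.sosfiltfilt(sos_lp, np.concatenate([k, np.zeros(pad)]))
    lo, hi = config.onset_window_s
    step = max(1, int(round(config.onset_step_s * rate)))
    i0 = envelope.index_of(probe_onset_s)
    offsets = np.arange(int(round(lo * rate)), int(round(hi * rate)) + 1, step)
    seg_len = offsets[-1] + len(k)
    if i0 < 0 or i0 + seg_len > envelope.n_samples:
        raise ValueError("probe window exceeds recording")
    y = envelope.data[i0:i0 + seg_len]

    if not np.any(y):
        return SebrEstimate(trial, 0.0, None, 0.0, flat=True)

    kk = float(k @ k)
    yy = float(y @ y)
    # cross-correlation of the segment with the kernel at each grid onset
    corr = signal.correlate(y, k, mode="valid")  # length seg_len - len(k) + 1
    c = corr[offsets]
    a = np.maximum(c / kk, 0.0)
    rss = yy - (2.0 * a * c - a * a * kk)
    best = int(np.argmin(rss))  # argmin returns first minimum: earliest onset
    amp = float(a[best])
    r2 = float(1.0 - rss[best] / yy) if yy > 0 else 0.0
    return SebrEstimate(trial, amp, float(offsets[best] / rate), r2)


def fit_sebr_session(envelope: ChannelRecording, seq,
                     config: EmgPipelineConfig | None = None) -> pd.DataFrame:
    """Fit every probed trial of a session; one row per trial, none missing."""
    rows = []
    for t in seq:
        if t.probe_onset_s is None:
            continue
        est = fit_sebr_trial(envelope, t.probe_onset_s, config, trial=t.index)
        rows.append(
            dict(trial=t.index, cs=t.cs.value, reinforced=t.reinforced,
                 amplitude=est.amplitude, onset_s=est.onset_s,
                 fit_r2=est.fit_r2, flat=est.flat)
        )
    return pd.DataFrame(rows)


def normalize_sebr(estimates: pd.DataFrame,
                   participant_col: str | None = None,
                   amplitude_col: str = "amplitude") -> pd.DataFrame:
    """Divide amplitudes by the participant's mean CS⁻ amplitude.

    After normalization the CS⁻ mean equals 1 exactly for every participant,
    removing the multiplicative per-participant gain.  Raises if a CS⁻ mean
    is zero (normalization undefined).
    """
    out = estimates.copy()

    def _norm(group: pd.DataFrame) -> pd.Series:
        cs_minus = group.loc[group["cs"] == "CS-", amplitude_col]
        if cs_minus.empty:
            raise ValueError("no CS- trials: normalization undefined")
        m = float(cs_minus.mean())
        if m == 0:
            raise ValueError("CS- mean amplitude is zero: normalization undefined")
        return group[amplitude_col] / m

    if participant_col is None:
        out["normalized_amplitude"] = _norm(out)
    else:
        out["normalized_amplitude"] = (
            out.groupby(participant_col, group_keys=False)[[amplitude_col, "cs"]]
            .apply(_norm)
        )
    return out
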