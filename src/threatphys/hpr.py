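"""Heart-period response (HPR, conditioned bradycardia) quantification.

R spikes are detected with a Pan–Tompkins-style chain (5–15 Hz band-pass,
derivative, squaring, 150 ms moving-window integration, adaptive dual
thresholds, 200 ms refractory period).  Each inter-beat interval is mapped
onto the time of the following R spike; values outside 400–1200 ms (heart
rate outside 50–150 bpm) are dropped; the series is linearly interpolated
to 10 Hz and band-pass filtered at 0.015–0.5 Hz.  Condition-wise response
amplitudes come from a general linear convolution model: one regressor per
CS type (onset train convolved with the canonical heart-period kernel),
fitted by OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import ChannelRecording
from .design import CS, TrialSequence
from .kernels import CanonicalKernel, hprf_kernel


@dataclass
class HprPipelineConfig:
    ibi_bounds_ms: tuple[float, float] = (400.0, 1200.0)
    bounds_exclusive: bool = False      # boundary IBIs kept valid by default
    interp_rate_hz: float = 10.0
    bandpass_hz: tuple[float, float] = (0.015, 0.5)
    bandpass_order: int = 4
    refractory_s: float = 0.2
    kernel: CanonicalKernel = field(default_factory=hprf_kernel)

    def __post_init__(self) -> None:
        lo, hi = self.bandpass_hz
        if not 0 < lo < hi:
            raise ValueError("bandpass cutoffs must satisfy 0 < low < high")


# ---------------------------------------------------------------------------
# R-spike detection

def detect_r_spikes(ecg: ChannelRecording,
                    config: HprPipelineConfig | None = None) -> np.ndarray:
    """Pan–Tompkins-style QRS detection; returns spike times in seconds.

    Our variant of the classic chain: band-pass 5–15 Hz, derivative,
    squaring, 150 ms moving-window integration, adaptive signal/noise
    thresholds, and a hard refractory period.  Deterministic.  A flatline
    input yields an empty list with a warning.
    """
    config = config or HprPipelineConfig()
    fs = ecg.rate_hz
    if fs < 250:
        raise ValueError("ECG sampling rate must be >= 250 Hz")
    x = ecg.data
    if np.ptp(x) == 0:
        warnings.warn("flatline ECG: no R spikes detected", RuntimeWarning,
                      stacklevel=2)
        return np.array([])

    sos = signal.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    sq = deriv ** 2
    w = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(w) / w, mode="same")

    refr = int(round(config.refractory_s * fs))
    # candidate peaks of the integrated signal
    peaks, _ = signal.find_peaks(mwi, distance=refr)
    if len(peaks) == 0:
        return np.array([])

    spki = float(np.max(mwi[:int(2 * fs)])) / 2 if len(mwi) > 2 * fs else float(mwi[peaks[0]])
    npki = float(np.mean(mwi[:int(2 * fs)])) / 2 if len(mwi) > 2 * fs else 0.0
    accepted = []
    for p in peaks:
        thr = npki + 0.25 * (spki - npki)
        if mwi[p] > thr:
            if accepted and p - accepted[-1] < refr:
                # refractory rule: keep the larger peak
                if mwi[p] > mwi[accepted[-1]]:
                    accepted[-1] = p
            else:
                accepted.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki

    # refine each detection to the local band-passed maximum (R apex)
    half = int(round(0.075 * fs))
    out = []
    for p in accepted:
        a, b = max(0, p - half), min(len(bp), p + half + 1)
        out.append(a + int(np.argmax(np.abs(bp[a:b]))))
    out = np.unique(out)
    # enforce refractory on refined positions
    final = []
    for p in out:
        if final and (p - final[-1]) < refr:
            if np.abs(bp[p]) > np.abs(bp[final[-1]]):
                final[-1] = p
        else:
            final.append(p)
    return ecg.t0_s + np.asarray(final, dtype=float) / fs


# ---------------------------------------------------------------------------
# heart-period trace

def build_hp_trace(spikes: np.ndarray,
                   config: HprPipelineConfig | None = None,
                   duration_s: float | None = None,
                   t0_s: float = 0.0,
                   filter_trace: bool = True) -> ChannelRecording:
    """Interpolated, filtered heart-period (ms) trace at 10 Hz.

    Each inter-beat interval is assigned to the time of its *following*
    spike (the first spike carries no value).  Out-of-bounds IBIs are
    dropped before interpolation, which then bridges their neighbors.
    Un-bracketed edges are extended with the nearest value before filtering.
    """
    config = config or HprPipelineConfig()
    spikes = np.asarray(spikes, dtype=float)
    if len(spikes) < 2:
        raise ValueError("need at least two spikes to form an IBI")
    ibi_ms = np.diff(spikes) * 1000.0
    at = spikes[1:]
    lo, hi = config.ibi_bounds_ms
    keep = (ibi_ms > lo) & (ibi_ms < hi) if config.bounds_exclusive else \
        (ibi_ms >= lo) & (ibi_ms <= hi)
    ibi_ms, at = ibi_ms[keep], at[keep]
    if len(ibi_ms) == 0:
        raise ValueError("no in-bounds IBIs")

    rate = config.interp_rate_hz
    end = duration_s if duration_s is not None else spikes[-1] - t0_s
    t = t0_s + np.arange(int(round(end * rate))) / rate
    hp = np.interp(t, at, ibi_ms)  # np.interp extends edges by nearest value
    if filter_trace:
        sos = signal.butter(config.bandpass_order, config.bandpass_hz,
                            btype="bandpass", fs=rate, output="sos")
        hp = signal.sosfiltfilt(sos, hp)
    return ChannelRecording(hp, rate, units="ms", name="heart_period", t0_s=t0_s)


# ---------------------------------------------------------------------------
# conditionwise convolution GLM

def fit_hpr_glm(hp: ChannelRecording, seq: TrialSequence,
                config: HprPipelineConfig | None = None,
                mean_ibi_s: float | None = None) -> pd.DataFrame:
    """One heart-period response amplitude per CS condition.

    Regressors are CS-onset impulse trains convolved with the canonical
    heart-period kernel and passed through the same band-pass as the data,
    plus intercept; OLS on valid samples.  When ``mean_ibi_s`` is given the
    kernel is additionally convolved with a right-aligned boxcar of that
    width, modeling how each inter-beat interval averages the instantaneous
    heart period over the beat and is stamped at the following R spike.
    """
    config = config or HprPipelineConfig()
    rate = hp.rate_hz
    n = hp.n_samples
    k = config.kernel.sample(rate)
    if mean_ibi_s is not None and mean_ibi_s > 0:
        w = max(1, int(round(mean_ibi_s * rate)))
        k = np.convolve(k, np.ones(w) / w)   # right-aligned: delay + average
    sos = signal.butter(config.bandpass_order, config.bandpass_hz,
                        btype="bandpass", fs=rate, output="sos")
    conditions = [CS.CS_MINUS, CS.CSR_PLUS, CS.CSN_PLUS]
    cols = []
    for c in conditions:
        x = np.zeros(n)
        for t in seq:
            if t.cs is c:
                j = hp.index_of(t.cs_onset_s)
                if 0 <= j < n:
                    x[j] = 1.0
        cols.append(signal.sosfiltfilt(sos, signal.fftconvolve(x, k)[:n]))
    X = np.column_stack(cols + [np.ones(n)])
    ok = hp.valid
    beta, *_ = np.linalg.lstsq(X[ok], hp.data[ok], rcond=None)
    return pd.DataFrame(
        dict(cs=[c.value for c in conditions], amplitude=beta[:3])
    )
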