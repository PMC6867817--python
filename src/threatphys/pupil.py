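"""Pupil-size response (PSR) quantification.

Pupil area is cleaned (blink/saccade samples and samples with gaze outside a
5° box around screen center are treated as missing), the eye with fewer
missing samples is selected, trials with less than 50% valid data in the
10 s after CS onset are excluded, and trialwise anticipatory dilation
amplitudes are estimated with a single-trial general linear convolution
model at 250 Hz: one impulse regressor per trial at CS onset convolved with
a canonical pupil response function, plus intercept and linear drift,
fitted by ordinary least squares on valid samples only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import ChannelRecording, interpolate_invalid, mask_intervals
from .design import TrialSequence
from .kernels import CanonicalKernel, psrf_kernel


@dataclass
class PupilPipelineConfig:
    gaze_box_deg: float = 5.0           # half-angle around screen center
    screen_distance_cm: float = 70.0
    min_valid_fraction: float = 0.5     # over the 10 s following CS onset
    valid_window_s: float = 10.0
    target_rate_hz: float = 250.0
    max_missing_trials_fraction: float = 0.35
    drift_order: int = 1                # per-session polynomial drift terms
    kernel: CanonicalKernel = field(default_factory=psrf_kernel)

    def __post_init__(self) -> None:
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must lie in (0, 1]")
        if self.screen_distance_cm <= 0:
            raise ValueError("screen distance must be positive")


def gaze_to_degrees(offset_cm: np.ndarray,
                    screen_distance_cm: float = 70.0) -> np.ndarray:
    """Convert on-screen offsets (cm from center) to visual angle (degrees)."""
    return np.degrees(np.arctan2(np.asarray(offset_cm, dtype=float),
                                 screen_distance_cm))


def clean_pupil(area: ChannelRecording, gaze: ChannelRecording,
                blink_saccade_intervals,
                config: PupilPipelineConfig | None = None) -> ChannelRecording:
    """Mask blinks/saccades and off-screen gaze; interpolate for filtering.

    ``gaze`` holds gaze direction in degrees from screen center, shape
    ``(n, 2)``.  Masked samples are linearly interpolated (so later filters
    see a continuous signal) but remain invalid for model inversion.
    """
    config = config or PupilPipelineConfig()
    if (gaze.n_samples != area.n_samples) or (gaze.rate_hz != area.rate_hz):
        raise ValueError("pupil area and gaze channels are misaligned")
    bad = mask_intervals(area, blink_saccade_intervals)
    gaze_xy = gaze.data.reshape(area.n_samples, -1)
    off_screen = np.any(np.abs(gaze_xy) > config.gaze_box_deg, axis=1)
    valid = area.valid & gaze.valid & ~bad & ~off_screen
    # NaN samples (tracker dropouts) are missing regardless of annotations
    valid &= np.isfinite(area.data)
    data = interpolate_invalid(area.data, valid)
    return area.copy(data=data, valid=valid, name="pupil_clean")


def select_eye(left: ChannelRecording, right: ChannelRecording) -> ChannelRecording:
    """Return the eye with fewer missing samples; ties go to the left eye."""
    n_left = int((~left.valid).sum() + (~np.isfinite(left.data)).sum())
    n_right = int((~right.valid).sum() + (~np.isfinite(right.data)).sum())
    return right if n_right < n_left else left


def exclude_pupil_trials(rec: ChannelRecording, seq: TrialSequence,
                         config: PupilPipelineConfig | None = None) -> pd.DataFrame:
    """Per-trial validity: excluded if <50% valid samples in CS onset +10 s.

    The boundary case (exactly 50% valid) is included.  Emits a warning if
    more than 35% of a session's trials are excluded — in the kind of data
    this pipeline targets that is a data-quality red flag, not an error.
    """
    config = config or PupilPipelineConfig()
    rows = []
    for t in seq:
        i0 = max(0, rec.index_of(t.cs_onset_s))
        i1 = min(rec.n_samples, rec.index_of(t.cs_onset_s + config.valid_window_s))
        frac = float(rec.valid[i0:i1].mean()) if i1 > i0 else 0.0
        rows.append(dict(trial=t.index, valid_fraction=frac,
                         included=frac >= config.min_valid_fraction))
    df = pd.DataFrame(rows)
    excl_frac = 1.0 - df["included"].mean()
    if excl_frac > config.max_missing_trials_fraction:
        warnings.warn(
            f"{excl_frac:.0%} of trials excluded (> "
            f"{config.max_missing_trials_fraction:.0%} threshold)",
            RuntimeWarning, stacklevel=2)
    return df


def _downsample(rec: ChannelRecording, target_hz: float) -> ChannelRecording:
    step = int(round(rec.rate_hz / target_hz))
    if step == 1:
        return rec
    n = (rec.n_samples // step) * step
    data = rec.data[:n].reshape(-1, step).mean(axis=1)
    valid = rec.valid[:n].reshape(-1, step).all(axis=1)
    return rec.copy(data=data, valid=valid, rate_hz=rec.rate_hz / step)


def fit_pupil_glm(trace: ChannelRecording, seq: TrialSequence,
                  config: PupilPipelineConfig | None = None,
                  trial_flags: pd.DataFrame | None = None) -> pd.DataFrame:
    """Single-trial convolution GLM for anticipatory pupil dilation.

    Design matrix: one impulse per included trial at CS onset convolved with
    the canonical pupil kernel, plus intercept and polynomial drift; OLS on
    valid samples only.  Excluded trials get missing amplitudes.
    """
    config = config or PupilPipelineConfig()
    if trial_flags is None:
        trial_flags = exclude_pupil_trials(trace, seq, config)
    included = set(trial_flags.loc[trial_flags["included"], "trial"])

    rec = _downsample(trace, config.target_rate_hz)
    rate = rec.rate_hz
    n = rec.n_samples
    k = config.kernel.sample(rate)
    trials = [t for t in seq if t.index in included]
    cols = []
    for t in trials:
        x = np.zeros(n)
        j = rec.index_of(t.cs_onset_s)
        if 0 <= j < n:
            x[j] = 1.0
        cols.append(signal.fftconvolve(x, k)[:n])
    tt = np.linspace(-1, 1, n)
    drift = [tt ** p for p in range(config.drift_order + 1)]
    X = np.column_stack(cols + drift)
    ok = rec.valid
    Xv, yv = X[ok], rec.data[ok]
    rank = np.linalg.matrix_rank(Xv)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient pupil design (overlap beyond repair)",
                      RuntimeWarning, stacklevel=2)
    beta, *_ = np.linalg.lstsq(Xv, yv, rcond=None)

    amp = dict(zip((t.index for t in trials), beta[:len(trials)]))
    rows = []
    for t in seq:
        rows.append(dict(trial=t.index, cs=t.cs.value, reinforced=t.reinforced,
                         amplitude=amp.get(t.index, np.nan),
                         included=t.index in included))
    return pd.DataFrame(rows)
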