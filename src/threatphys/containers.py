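"""Shared in-memory containers for sampled physiological channels.

A :class:`ChannelRecording` is one uniformly sampled signal with a sampling
rate, physical units, and a per-sample validity mask.  Masks carry artifact
and missing-data information through filtering and down-sampling so that
model inversion can ignore invalid samples without losing their positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class ChannelRecording:
    """One uniformly sampled physiological signal.

    Parameters
    ----------
    data:
        Sample values, shape ``(n,)`` (or ``(n, k)`` for multi-column
        channels such as gaze x/y).
    rate_hz:
        Sampling rate in Hz.
    units:
        Physical units of ``data`` (e.g. ``"uS"``, ``"au"``, ``"ms"``).
    valid:
        Boolean per-sample validity mask; invalid samples are ignored by
        model inversion.  Defaults to all-valid.
    name:
        Channel name (``"emg"``, ``"sc"``, ``"pupil"``, ``"gaze"``, ``"ecg"``).
    t0_s:
        Time of the first sample relative to session start, in seconds.
    """

    data: np.ndarray
    rate_hz: float
    units: str = "au"
    valid: np.ndarray | None = None
    name: str = ""
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape[0] != self.data.shape[0]:
                raise ValueError("valid mask length does not match data length")

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to session start."""
        return self.t0_s + np.arange(self.n_samples) / self.rate_hz

    def index_of(self, t_s: float) -> int:
        """Index of the sample at (or just before) time ``t_s``."""
        return int(np.floor((t_s - self.t0_s) * self.rate_hz + 1e-9))

    def copy(self, **changes) -> "ChannelRecording":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        if "valid" not in changes:
            out.valid = self.valid.copy()
        return out


def mask_intervals(rec: ChannelRecording, intervals) -> np.ndarray:
    """Boolean mask with True inside the given ``(start_s, end_s)`` intervals.

    Intervals are interpreted in session time (seconds); half-open
    ``[start, end)``.  Raises on inverted or overlapping intervals.
    """
    t = rec.times()
    mask = np.zeros(rec.n_samples, dtype=bool)
    prev_end = -np.inf
    for iv in sorted(intervals, key=lambda iv: float(iv[0])):
        start, end = float(iv[0]), float(iv[1])
        if end < start:
            raise ValueError(f"inverted interval ({start}, {end})")
        if start < prev_end:
            raise ValueError(f"overlapping interval starting at {start}")
        prev_end = end
        mask |= (t >= start) & (t < end)
    return mask


def interpolate_invalid(data: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly interpolate invalid samples (nearest-value at edges)."""
    data = np.asarray(data, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if valid.all():
        return data.copy()
    if not valid.any():
        raise ValueError("cannot interpolate: no valid samples")
    idx = np.arange(data.shape[0])
    out = data.copy()
    out[~valid] = np.interp(idx[~valid], idx[valid], data[valid])
    return out
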