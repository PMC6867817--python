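"""Skin-conductance response (SCR) quantification.

The measurement model: each trial elicits an anticipatory sudomotor input at
CS onset — a fixed-dispersion bump whose latency is free within [0, 2] s —
and a (potential) US-evoked input at US time, both convolved with a canonical
skin-conductance response function.  Inversion estimates both amplitudes and
the anticipatory latency per trial by windowed nonlinear least squares, blind
to trial type and to whether a US actually occurred.  Responses overlapping
from neighboring trials are summed in the forward model.

Artifact periods shorter than 2 s are linearly interpolated for filtering
and ignored for inversion; trials containing a longer artifact are excluded.
Only nonreinforced trials enter statistical analysis, to avoid contamination
by US responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .containers import ChannelRecording, interpolate_invalid, mask_intervals
from .design import PROBE_DELAY_S, TrialSequence
from .kernels import CanonicalKernel, scrf_kernel


@dataclass
class ScrPipelineConfig:
    bandpass_hz: tuple[float, float] = (0.0159, 5.0)
    bandpass_order: int = 1
    target_rate_hz: float = 10.0
    artifact_interp_max_s: float = 2.0
    anticipatory_latency_bounds_s: tuple[float, float] = (0.0, 2.0)
    dispersion_s: float = 0.3         # SD of the fixed-dispersion input bump
    evoked_delay_s: float = 0.0       # evoked input relative to US onset
    kernel: CanonicalKernel = field(default_factory=scrf_kernel)
    latency_grid_step_s: float = 0.05
    max_sweeps: int = 6
    window_before: int = 2            # modeled trials preceding the target
    window_after: int = 1             # and following it (causal tails leak in)
    window_margin_s: float = 12.0     # data kept after a window's last CS onset


@dataclass
class ScrTrialEstimate:
    trial: int
    anticipatory_amplitude: float | None
    anticipatory_latency_s: float | None
    evoked_amplitude: float | None
    excluded: bool = False
    reason: str = ""
    converged: bool = True


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_scr(raw: ChannelRecording, artifacts,
                   config: ScrPipelineConfig | None = None) -> ChannelRecording:
    """Interpolate/mask artifacts, band-pass filter, resample to 10 Hz.

    Every artifact sample is interpolated for filtering and masked invalid
    for inversion; the distinction between short (< 2 s, trial retained) and
    long artifacts (trial excluded) is applied by :func:`exclude_scr_trials`.
    """
    config = config or ScrPipelineConfig()
    bad = mask_intervals(raw, artifacts)
    valid = raw.valid & ~bad
    x = interpolate_invalid(raw.data, valid)

    sos = signal.butter(config.bandpass_order, config.bandpass_hz,
                        btype="bandpass", fs=raw.rate_hz, output="sos")
    y = signal.sosfiltfilt(sos, x)

    step = int(round(raw.rate_hz / config.target_rate_hz))
    y_ds = y[::step]
    # a low-rate sample is invalid if any source sample in its block was
    n = len(y_ds) * step
    blocks = valid[:n].reshape(-1, step)
    valid_ds = blocks.all(axis=1)
    return raw.copy(data=y_ds, valid=valid_ds, rate_hz=config.target_rate_hz,
                    name="scr")


def exclude_scr_trials(seq: TrialSequence, artifacts,
                       config: ScrPipelineConfig | None = None) -> dict[int, str]:
    """Map trial index -> reason for trials hit by an artifact >= 2 s.

    A trial's extent runs from its CS onset to the next trial's CS onset
    (or CS offset + ITI for the last trial).
    """
    config = config or ScrPipelineConfig()
    out: dict[int, str] = {}
    for t in seq:
        t_end = t.cs_onset_s + t.cs_duration_s + t.iti_s
        for start, end in artifacts:
            if end - start < config.artifact_interp_max_s:
                continue
            if start < t_end and end > t.cs_onset_s:
                out[t.index] = "artifact"
                break
    return out


# ---------------------------------------------------------------------------
# inversion

_OVERSAMPLE = 10
_TEMPLATE_PAD_BEFORE_S = 40.0    # zero-phase filtering undershoots acausally
_TEMPLATE_PAD_AFTER_S = 80.0     # covers the high-pass undershoot tail


def _filtered_templates(config: ScrPipelineConfig, rate: float):
    """Filtered response templates for anticipatory and evoked inputs.

    Built once at an oversampled rate so the full band-pass the data went
    through (including the 5 Hz low-pass leg, above the 10 Hz Nyquist) can
    be applied; model columns are then time shifts of these templates
    (the filtering chain is LTI).  Returns ``(t_rel_s, T_ant, T_ev)`` where
    ``t_rel_s`` is time relative to the input center.
    """
    hi_rate = rate * _OVERSAMPLE
    k = config.kernel.sample(hi_rate)
    n_pad_b = int(_TEMPLATE_PAD_BEFORE_S * hi_rate)
    n_pad_a = int(_TEMPLATE_PAD_AFTER_S * hi_rate)
    n = n_pad_b + n_pad_a
    sos = signal.butter(config.bandpass_order, config.bandpass_hz,
                        btype="bandpass", fs=hi_rate, output="sos")
    t_rel = (np.arange(n) - n_pad_b) / hi_rate

    sd = config.dispersion_s * hi_rate
    bump = np.zeros(n)
    lo, hi = int(n_pad_b - 6 * sd), int(n_pad_b + 6 * sd)
    b = np.exp(-0.5 * ((np.arange(lo, hi) - n_pad_b) / sd) ** 2)
    bump[lo:hi] = b / b.sum()
    t_ant = signal.sosfiltfilt(sos, signal.fftconvolve(bump, k)[:n])

    delta = np.zeros(n)
    delta[n_pad_b] = 1.0
    t_ev = signal.sosfiltfilt(sos, signal.fftconvolve(delta, k)[:n])
    return t_rel, t_ant, t_ev


def _shifted_column(times_s, center_s, t_rel, template):
    """Template evaluated at ``times_s`` for an input centered at ``center_s``."""
    return np.interp(times_s - center_s, t_rel, template, left=0.0, right=0.0)


def invert_scr(trace: ChannelRecording, seq: TrialSequence,
               config: ScrPipelineConfig | None = None,
               excluded: dict[int, str] | None = None) -> list[ScrTrialEstimate]:
    """Jointly estimate anticipatory (amplitude, latency) and evoked amplitude.

    Every trial gets an evoked regressor at its *potential* US time (CS
    onset + 3.5 s + configurable delay) whether or not a US occurred — the
    inversion is blind to reinforcement.  Each trial is estimated from a
    3-trial sliding window so neighboring responses are modeled jointly;
    amplitudes are nonnegative (inner NNLS), latencies are optimized on a
    bounded grid by coordinate descent, which is deterministic and, per
    coordinate, global over [0, 2] s.
    """
    config = config or ScrPipelineConfig()
    excluded = excluded or {}
    rate = trace.rate_hz
    t_rel, T_ant, T_ev = _filtered_templates(config, rate)
    lo, hi = config.anticipatory_latency_bounds_s
    trials = list(seq)
    results: list[ScrTrialEstimate] = []

    for pos, t in enumerate(trials):
        if t.index in excluded:
            results.append(ScrTrialEstimate(t.index, None, None, None,
                                            excluded=True,
                                            reason=excluded[t.index]))
            continue
        window = trials[max(0, pos - config.window_before):
                        pos + 1 + config.window_after]
        w_start = trials[max(0, pos - 1)].cs_onset_s - 1.0
        w_end = window[-1].cs_onset_s + config.window_margin_s
        i0 = max(0, trace.index_of(w_start))
        i1 = min(trace.n_samples, trace.index_of(w_end))
        y = trace.data[i0:i1]
        ok = trace.valid[i0:i1]
        if not ok.any():
            results.append(ScrTrialEstimate(t.index, None, None, None,
                                            excluded=True, reason="no-valid-data"))
            continue

        times = (trace.t0_s + np.arange(i0, i1) / rate)[ok]
        ev_cols = np.column_stack([
            _shifted_column(times,
                            w.cs_onset_s + w.cs_duration_s - 0.5
                            + config.evoked_delay_s, t_rel, T_ev)
            for w in window
        ])
        grid = np.arange(lo, hi + 1e-9, config.latency_grid_step_s)
        # anticipatory columns precomputed for every (trial, latency)
        ant_bank = [
            np.column_stack([
                _shifted_column(times, w.cs_onset_s + la, t_rel, T_ant)
                for la in grid
            ])
            for w in window
        ]
        yv = y[ok]
        m = len(window)

        def rss_at(lat_idx):
            X = np.hstack(
                [np.column_stack([ant_bank[i][:, lat_idx[i]] for i in range(m)]),
                 ev_cols])
            amps, r = optimize.nnls(X, yv)
            return r ** 2, amps

        lat_idx = [len(grid) // 2] * m
        cur, amps = rss_at(lat_idx)
        converged = False
        for _ in range(config.max_sweeps):
            changed = False
            for i in range(m):
                vals = []
                for g in range(len(grid)):
                    trial_lats = list(lat_idx)
                    trial_lats[i] = g
                    vals.append(rss_at(trial_lats)[0])
                g_best = int(np.argmin(vals))
                if g_best != lat_idx[i]:
                    lat_idx[i] = g_best
                    changed = True
            if not changed:
                converged = True
                break
        cur, amps = rss_at(lat_idx)
        j = window.index(t)
        results.append(ScrTrialEstimate(
            t.index,
            anticipatory_amplitude=float(amps[j]),
            anticipatory_latency_s=float(grid[lat_idx[j]]),
            evoked_amplitude=float(amps[m + j]),
            converged=converged,
        ))
        if not converged:
            warnings.warn(f"SCR inversion did not converge on trial {t.index}",
                          RuntimeWarning, stacklevel=2)
    return results


def select_scr_trials(estimates: list[ScrTrialEstimate],
                      seq: TrialSequence) -> pd.DataFrame:
    """Keep nonreinforced, non-excluded trials; the analyzed measure is the
    anticipatory amplitude."""
    by_index = {t.index: t for t in seq}
    rows = []
    for e in estimates:
        t = by_index[e.trial]
        if t.reinforced or e.excluded:
            continue
        rows.append(dict(trial=e.trial, cs=t.cs.value, reinforced=t.reinforced,
                         amplitude=e.anticipatory_amplitude,
                         latency_s=e.anticipatory_latency_s,
                         evoked_amplitude=e.evoked_amplitude))
    if not rows:
        warnings.warn("no nonreinforced trials to analyze", RuntimeWarning,
                      stacklevel=2)
        return pd.DataFrame(columns=["trial", "cs", "reinforced", "amplitude",
                                     "latency_s", "evoked_amplitude"])
    return pd.DataFrame(rows)
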