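"""Canonical response functions (fixed-shape kernels).

Each physiological measure is modeled as amplitude x kernel, so trialwise
quantification reduces to (possibly latency-shifted) regression.  The kernel
shapes here are standard phenomenological forms:

* SEBR — gamma density, mode ~40 ms, support ~150 ms (startle eye-blink
  envelope).
* SCRF — bi-exponential (Bateman) skin-conductance response, rise ~0.75 s,
  decay ~3 s.
* PSRF — gamma density pupil dilation response peaking ~2 s.
* HPRF — difference of gammas spanning ~10 s, peak ~4 s (conditioned
  bradycardia).

All kernels are peak-normalized so a fitted coefficient is the response
peak amplitude in channel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CanonicalKernel:
    """A parameterized canonical response basis function.

    ``params`` are passed to the registered shape function; ``duration_s``
    is the kernel support.  ``sample(rate_hz)`` returns the peak-normalized
    kernel at the requested rate.
    """

    shape: str
    duration_s: float
    params: dict = field(default_factory=dict)

    def sample(self, rate_hz: float) -> np.ndarray:
        n = int(round(self.duration_s * rate_hz))
        t = np.arange(n) / rate_hz
        y = _SHAPES[self.shape](t, **self.params)
        peak = np.max(np.abs(y))
        if peak == 0:
            raise ValueError(f"kernel {self.shape!r} is identically zero")
        return y / peak

    def peak_latency_s(self, rate_hz: float = 1000.0) -> float:
        y = self.sample(rate_hz)
        return float(np.argmax(np.abs(y)) / rate_hz)


def _gamma_density(t, shape_k, scale_s):
    return stats.gamma.pdf(t, a=shape_k, scale=scale_s)


def _bateman(t, rise_s, decay_s):
    # classic two-compartment impulse response
    return np.exp(-t / decay_s) - np.exp(-t / rise_s)


def _diff_of_gammas(t, shape1, scale1, shape2, scale2, ratio):
    return stats.gamma.pdf(t, a=shape1, scale=scale1) - ratio * stats.gamma.pdf(
        t, a=shape2, scale=scale2
    )


_SHAPES = {
    "gamma": _gamma_density,
    "bateman": _bateman,
    "diff_of_gammas": _diff_of_gammas,
}


def sebr_kernel(mode_s: float = 0.040, shape_k: float = 4.0,
                duration_s: float = 0.15) -> CanonicalKernel:
    """Startle eye-blink envelope kernel; gamma with mode at ``mode_s``."""
    scale = mode_s / (shape_k - 1.0)
    return CanonicalKernel("gamma", duration_s,
                           {"shape_k": shape_k, "scale_s": scale})


def scrf_kernel(rise_s: float = 0.75, decay_s: float = 3.0,
                duration_s: float = 20.0) -> CanonicalKernel:
    """Skin-conductance response function; bi-exponential."""
    return CanonicalKernel("bateman", duration_s,
                           {"rise_s": rise_s, "decay_s": decay_s})


def psrf_kernel(peak_s: float = 2.0, shape_k: float = 3.0,
                duration_s: float = 10.0) -> CanonicalKernel:
    """Pupil dilation response function; gamma with mode at ``peak_s``."""
    scale = peak_s / (shape_k - 1.0)
    return CanonicalKernel("gamma", duration_s,
                           {"shape_k": shape_k, "scale_s": scale})


def hprf_kernel(duration_s: float = 12.0) -> CanonicalKernel:
    """Heart-period response function; difference of gammas, peak ~4 s."""
    return CanonicalKernel(
        "diff_of_gammas",
        duration_s,
        {"shape1": 3.0, "scale1": 2.0, "shape2": 6.0, "scale2": 1.4,
         "ratio": 0.35},
    )
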