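"""Forward simulation of multichannel conditioning recordings.

The generator produces session bundles (EMG, skin conductance, pupil + gaze
for both eyes, ECG) for a two-group cohort with known ground-truth per-trial
response amplitudes, so that every downstream quantification stage can be
verified by parameter recovery.  The emulated statistical structure:

* conditioned discrimination — CS⁺ amplitudes exceed CS⁻ by a per-measure
  multiplier;
* drug modulation — the retention-phase CS⁺ effect is multiplied by a group
  factor (the drug group retains more);
* habituation — overall amplitudes decay exponentially over trials;
* extinction — the CS⁺/CS⁻ differential decays over unreinforced trials;
* multiplicative per-participant gain on EMG (electrode impedance/anatomy),
  which is what CS⁻ normalization is designed to remove;
* blink gaps in pupil, step artifacts in skin conductance, gaze wander.

By default each channel is generated with the same canonical kernel family
its fitter assumes; ``misspecify_kernels=True`` shifts peaks and dispersions
to probe robustness, so that recovery tests are not a tautology only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import ChannelRecording
from .design import CS, Phase, TrialSequence, generate_trial_sequence, sequence_to_table
from .io import SessionBundle
from .kernels import hprf_kernel, psrf_kernel, scrf_kernel, sebr_kernel

MEASURES = ("sebr", "scr", "psr", "hpr")


@dataclass
class SimConfig:
    """Cohort simulation settings; the defaults are the study conditions.

    Amplitude units: SEBR in arbitrary envelope units, SCR in μS, PSR in
    tracker area units, HPR in ms of heart-period lengthening.
    """

    seed: int
    n_per_group: int = 39
    sampling_rates: dict = field(default_factory=lambda: dict(
        emg=1000.0, sc=1000.0, pupil=500.0, ecg=1000.0))
    base_amplitude: dict = field(default_factory=lambda: dict(
        sebr=1.0, scr=0.5, psr=50.0, hpr=6.0))
    effect_sizes: dict = field(default_factory=lambda: dict(
        cs_plus_vs_minus=dict(sebr=1.5, scr=2.0, psr=1.6, hpr=3.0),
        drug_modulation=1.5,
        extinction_rate=0.05,
        habituation_rate=0.02,
    ))
    noise: dict = field(default_factory=lambda: dict(
        emg=0.02, sc=0.02, pupil=4.0, ecg=0.05))
    artifact_rates: dict = field(default_factory=lambda: dict(
        pupil_blink_per_min=10.0, sc_artifact_per_min=0.2))
    participant_gain_sd: float = 0.4     # lognormal sigma, EMG only
    mains_amplitude: float = 0.0         # optional 50 Hz component in EMG
    misspecify_kernels: bool = False
    ecg_baseline_hp_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if any(v < 0 for v in self.noise.values()):
            raise ValueError("noise SDs must be >= 0")
        if any(v < 0 for v in self.artifact_rates.values()):
            raise ValueError("artifact rates must be >= 0")
        for m, v in self.effect_sizes["cs_plus_vs_minus"].items():
            if v <= 0:
                raise ValueError(f"multiplier for {m} must be > 0")

    def kernel(self, measure: str):
        if self.misspecify_kernels:
            return {
                "sebr": sebr_kernel(mode_s=0.055, shape_k=3.0),
                "scr": scrf_kernel(rise_s=1.0, decay_s=4.0),
                "psr": psrf_kernel(peak_s=2.5, shape_k=2.5),
                "hpr": hprf_kernel(),
            }[measure]
        return {"sebr": sebr_kernel(), "scr": scrf_kernel(),
                "psr": psrf_kernel(), "hpr": hprf_kernel()}[measure]


# ---------------------------------------------------------------------------
# ground-truth amplitudes

def true_amplitudes(seq: TrialSequence, measure: str, group: str,
                    config: SimConfig) -> np.ndarray:
    """Per-trial true response amplitude for one measure.

    amplitude = base · exp(−hab·(t−1)) · [1 + (m−1)·d·exp(−ext·(t−1))]
    for CS⁺ trials (bracket = 1 for CS⁻), where m is the conditioned
    discrimination multiplier, d the drug modulation (retention phase, drug
    group only), and ext applies in the unreinforced retention phase only.
    """
    es = config.effect_sizes
    base = config.base_amplitude[measure]
    mult = es["cs_plus_vs_minus"][measure]
    hab = es["habituation_rate"]
    ext = es["extinction_rate"] if seq.phase is Phase.RETENTION else 0.0
    drug = (es["drug_modulation"]
            if (seq.phase is Phase.RETENTION and group == "drug") else 1.0)
    out = np.empty(len(seq))
    for i, t in enumerate(seq):
        a = base * np.exp(-hab * i)
        if t.cs.is_plus:
            a *= 1.0 + (mult - 1.0) * drug * np.exp(-ext * i)
        out[i] = a
    return out


# ---------------------------------------------------------------------------
# per-channel forward models

def _merge_intervals(ivs):
    """Sort and merge overlapping/adjacent (start, end) intervals."""
    out = []
    for a, b in sorted(ivs):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _emg_carrier(n: int, rate: float) -> np.ndarray:
    """Deterministic broadband carrier: tones across the EMG passband, off
    the 50 Hz harmonic grid, normalized to unit rectified-smoothed level."""
    tk = np.arange(n) / rate
    c = np.zeros(n)
    for i, f in enumerate((75.0, 175.0, 275.0, 375.0)):
        c += np.sin(2 * np.pi * f * tk + i)
    sos_lp = signal.butter(4, 53.05, btype="lowpass", fs=rate, output="sos")
    rect_dc = signal.sosfiltfilt(sos_lp, np.abs(np.concatenate([c] * 5)))
    return c / float(np.mean(rect_dc[2 * n:3 * n]))


_CHAIN_GAIN_CACHE: dict = {}


def _emg_chain_gain(k: tuple, carrier: tuple, rate: float) -> float:
    """Gain of the EMG scoring chain (band-pass, notches, rectify, smooth)
    on one carrier-modulated burst, measured against the smoothed kernel."""
    key = (hash(k), hash(carrier), rate)
    if key not in _CHAIN_GAIN_CACHE:
        from .sebr import EmgPipelineConfig, preprocess_emg

        ka = np.asarray(k)
        n = len(ka)
        pad = int(rate)  # 1 s of silence either side
        x = np.concatenate([np.zeros(pad), ka * np.asarray(carrier),
                            np.zeros(pad)])
        env = preprocess_emg(ChannelRecording(x, rate)).data
        sos_lp = signal.butter(4, 53.05, btype="lowpass", fs=rate, output="sos")
        ks = signal.sosfiltfilt(sos_lp, np.concatenate([ka, np.zeros(n)]))
        seg = env[pad:pad + len(ks)]
        _CHAIN_GAIN_CACHE[key] = float((seg @ ks) / (ks @ ks))
    return _CHAIN_GAIN_CACHE[key]


def simulate_emg(seq: TrialSequence, amplitudes: np.ndarray, config: SimConfig,
                 rng: np.random.Generator,
                 jitter_s: tuple[float, float] = (0.02, 0.12)) -> ChannelRecording:
    """Raw EMG whose rectified-smoothed envelope is amplitude × blink kernel.

    Each startle probe triggers a burst: the canonical envelope modulating a
    broadband multi-tone carrier (tones spread across the EMG passband, off
    the 50 Hz harmonic grid) normalized so that rectification followed by
    low-pass smoothing recovers the envelope at unit gain.  Onsets are
    jittered uniformly within the fitter's search window.
    """
    rate = config.sampling_rates["emg"]
    n = int(round(seq.duration_s * rate))
    t = np.arange(n) / rate
    x = rng.normal(0.0, config.noise["emg"], n)
    if config.mains_amplitude:
        x += config.mains_amplitude * np.sin(2 * np.pi * 50.0 * t)
    k = config.kernel("sebr").sample(rate)
    carrier = _emg_carrier(len(k), rate)
    # pre-compensate the deterministic envelope-chain gain so the contract
    # "post-chain envelope = amplitude x kernel" holds exactly
    carrier = carrier / _emg_chain_gain(tuple(k), tuple(carrier), rate)
    for trial, amp in zip(seq, amplitudes):
        if trial.probe_onset_s is None:
            continue
        onset = trial.probe_onset_s + rng.uniform(*jitter_s)
        j = int(round(onset * rate))
        if j + len(k) > n:
            continue
        x[j:j + len(k)] += amp * k * carrier
    return ChannelRecording(x, rate, units="au", name="emg")


def simulate_scr(seq: TrialSequence, amplitudes: np.ndarray, config: SimConfig,
                 rng: np.random.Generator, evoked_factor: float = 3.0,
                 dispersion_s: float = 0.3):
    """Skin conductance: tonic drift + anticipatory/evoked responses + artifacts.

    Returns ``(recording, truth_table, artifact_intervals)``.  The
    anticipatory sudomotor input is a fixed-dispersion Gaussian bump whose
    latency is drawn uniformly within the model's [0, 2] s bound (kept 0.1 s
    off the edges); US-evoked inputs (~3× anticipatory, zero dispersion)
    occur on reinforced trials only.  Step artifacts have durations
    straddling the 2 s interpolation threshold.
    """
    rate = config.sampling_rates["sc"]
    n = int(round(seq.duration_s * rate))
    k = config.kernel("scr").sample(rate)
    x = np.zeros(n)
    lat = rng.uniform(0.1, 1.9, len(seq))
    impulses = np.zeros(n)
    idx = np.arange(n)
    sd = dispersion_s * rate
    for i, (trial, amp) in enumerate(zip(seq, amplitudes)):
        center = (trial.cs_onset_s + lat[i]) * rate
        lo, hi = int(max(0, center - 5 * sd)), int(min(n, center + 5 * sd))
        bump = np.exp(-0.5 * ((idx[lo:hi] - center) / sd) ** 2)
        impulses[lo:hi] += amp * bump / bump.sum()
        if trial.reinforced:
            ju = int(round(trial.us_onset_s * rate))
            if 0 <= ju < n:
                impulses[ju] += evoked_factor * amp
    x += signal.fftconvolve(impulses, k)[:n]

    # slow tonic drift: integrated noise, heavily low-passed
    drift = np.cumsum(rng.normal(0, 1, n))
    sos = signal.butter(2, 0.005, btype="lowpass", fs=rate, output="sos")
    drift = signal.sosfiltfilt(sos, drift)
    ptp = np.ptp(drift)
    if ptp > 0:
        drift = drift / ptp * 0.5
    x += drift + rng.normal(0.0, config.noise["sc"], n)

    intervals = []
    n_art = rng.poisson(config.artifact_rates["sc_artifact_per_min"]
                        * seq.duration_s / 60.0)
    for _ in range(n_art):
        start = rng.uniform(0, seq.duration_s - 4.0)
        dur = rng.uniform(0.5, 3.5)
        a, b = int(start * rate), int(min(n, (start + dur) * rate))
        x[a:b] += rng.uniform(1.0, 3.0)
        intervals.append((start, start + dur))
    intervals = _merge_intervals(intervals)

    truth = pd.DataFrame(dict(trial=[t.index for t in seq],
                              amplitude=amplitudes, latency_s=lat))
    return ChannelRecording(x, rate, units="uS", name="sc"), truth, intervals


def simulate_pupil(seq: TrialSequence, amplitudes: np.ndarray, config: SimConfig,
                   rng: np.random.Generator, blink_rate_per_min: float | None = None,
                   baseline: float = 1000.0):
    """Pupil area + gaze for one eye.

    Returns ``(area, gaze, blink_intervals)``.  Blink gaps are NaN runs at
    the configured rate; gaze wanders near center with occasional 1 s
    excursions beyond the 5° box.
    """
    rate = config.sampling_rates["pupil"]
    if blink_rate_per_min is None:
        blink_rate_per_min = config.artifact_rates["pupil_blink_per_min"]
    n = int(round(seq.duration_s * rate))
    k = config.kernel("psr").sample(rate)
    impulses = np.zeros(n)
    for trial, amp in zip(seq, amplitudes):
        j = int(round(trial.cs_onset_s * rate))
        if 0 <= j < n:
            impulses[j] += amp
    area = baseline + signal.fftconvolve(impulses, k)[:n]
    noise = rng.normal(0.0, 1.0, n)
    sos = signal.butter(2, 4.0, btype="lowpass", fs=rate, output="sos")
    noise = signal.sosfiltfilt(sos, noise)
    sd = noise.std()
    if sd > 0:
        area = area + noise / sd * config.noise["pupil"]

    blink_ivs = []
    n_blinks = rng.poisson(blink_rate_per_min * seq.duration_s / 60.0)
    for _ in range(n_blinks):
        start = rng.uniform(0, seq.duration_s - 0.5)
        dur = rng.uniform(0.1, 0.4)
        a, b = int(start * rate), int(min(n, (start + dur) * rate))
        area[a:b] = np.nan
        blink_ivs.append((start, start + dur))
    blink_ivs = _merge_intervals(blink_ivs)

    gaze_xy = np.empty((n, 2))
    for c in range(2):
        w = signal.sosfiltfilt(sos, rng.normal(0, 1, n))
        wsd = w.std()
        gaze_xy[:, c] = w / wsd * 1.0 if wsd > 0 else 0.0
    n_exc = rng.poisson(seq.duration_s / 60.0)      # ~1 excursion per minute
    for _ in range(n_exc):
        start = rng.uniform(0, seq.duration_s - 1.5)
        a, b = int(start * rate), int(min(n, (start + 1.0) * rate))
        gaze_xy[a:b, 0] = 6.0

    area_rec = ChannelRecording(area, rate, units="au", name="pupil")
    gaze_rec = ChannelRecording(gaze_xy, rate, units="deg", name="gaze")
    return area_rec, gaze_rec, blink_ivs


def simulate_ecg(seq: TrialSequence, cond_amplitudes: dict[str, float],
                 config: SimConfig, rng: np.random.Generator):
    """ECG via integrate-and-fire over an instantaneous heart-period trace.

    Heart period (ms) = baseline + per-condition kernel contributions at CS
    onsets + slow variability; R spikes fire when the integrated phase
    crosses 1; a synthetic QRS template is placed at each spike.  Returns
    ``(recording, true_spike_times_s)``.
    """
    rate = config.sampling_rates["ecg"]
    dur = seq.duration_s
    n = int(round(dur * rate))
    k = config.kernel("hpr").sample(rate)
    hp = np.full(n, config.ecg_baseline_hp_ms)
    for trial in seq:
        amp = cond_amplitudes[trial.cs.value]
        j = int(round(trial.cs_onset_s * rate))
        m = min(len(k), n - j)
        if m > 0:
            hp[j:j + m] += amp * k[:m]
    slow = np.cumsum(rng.normal(0, 1, n))
    sos = signal.butter(2, 0.05, btype="lowpass", fs=rate, output="sos")
    slow = signal.sosfiltfilt(sos, slow)
    ptp = np.ptp(slow)
    if ptp > 0:
        hp += slow / ptp * 10.0

    # integrate-and-fire: d(phase)/dt = 1000 / hp_ms
    spikes = []
    phase = 0.99      # first beat shortly after start
    i = 0
    while i < n:
        phase += (1000.0 / hp[i]) / rate
        if phase >= 1.0:
            spikes.append(i / rate)
            phase -= 1.0
        i += 1
    spikes = np.asarray(spikes)

    # synthetic QRS template: small Q dip, tall R, small S dip
    tq = np.arange(-0.05, 0.05, 1 / rate)
    template = (1.0 * np.exp(-0.5 * (tq / 0.008) ** 2)
                - 0.25 * np.exp(-0.5 * ((tq + 0.025) / 0.010) ** 2)
                - 0.3 * np.exp(-0.5 * ((tq - 0.025) / 0.010) ** 2))
    x = rng.normal(0.0, config.noise["ecg"], n)
    half = len(template) // 2
    for s in spikes:
        j = int(round(s * rate))
        a, b = j - half, j - half + len(template)
        ta, tb = max(0, -a), len(template) - max(0, b - n)
        x[max(0, a):min(n, b)] += template[ta:tb]
    return ChannelRecording(x, rate, units="mV", name="ecg"), spikes


# ---------------------------------------------------------------------------
# cohort

#: channels usable per phase (startle probes make non-EMG channels unusable
#: during retention; acquisition/relearning carry the secondary measures)
PHASE_CHANNELS = {
    Phase.ACQUISITION: ("sc", "pupil", "ecg"),
    Phase.RETENTION: ("emg",),
    Phase.RELEARNING: ("sc", "pupil", "ecg"),
    Phase.REMINDER: (),
}


def simulate_participant(participant: str, group: str, gain: float,
                         phase: Phase, seed: int, config: SimConfig,
                         blind_code: str = "?") -> tuple[SessionBundle, pd.DataFrame]:
    """One participant × phase bundle plus its ground-truth table."""
    rng = np.random.default_rng(seed)
    seq = generate_trial_sequence(phase, seed)
    channels: dict[str, ChannelRecording] = {}
    annotations: dict[str, list] = {}
    truth_rows = []

    def add_truth(measure, trials, amps, **extra):
        for tr, a in zip(trials, amps):
            truth_rows.append(dict(participant=participant, phase=phase.value,
                                   trial=tr.index, cs=tr.cs.value,
                                   reinforced=tr.reinforced, measure=measure,
                                   amplitude=a, **extra))

    wanted = PHASE_CHANNELS[phase]
    if "emg" in wanted:
        amps = true_amplitudes(seq, "sebr", group, config) * gain
        channels["emg"] = simulate_emg(seq, amps, config, rng)
        add_truth("sebr", seq, amps)
    if "sc" in wanted:
        amps = true_amplitudes(seq, "scr", group, config)
        rec, truth, ivs = simulate_scr(seq, amps, config, rng)
        channels["sc"] = rec
        annotations["sc_artifact"] = ivs
        add_truth("scr", seq, amps)
    if "pupil" in wanted:
        amps = true_amplitudes(seq, "psr", group, config)
        rate_l = config.artifact_rates["pupil_blink_per_min"]
        for eye, blink_rate in (("left", rate_l), ("right", 0.6 * rate_l)):
            area, gaze, ivs = simulate_pupil(seq, amps, config, rng,
                                             blink_rate_per_min=blink_rate)
            channels[f"pupil_{eye}"] = area
            channels[f"gaze_{eye}"] = gaze
            annotations[f"blink_{eye}"] = ivs
        add_truth("psr", seq, amps)
    if "ecg" in wanted:
        base = config.base_amplitude["hpr"]
        mult = config.effect_sizes["cs_plus_vs_minus"]["hpr"]
        cond = {CS.CS_MINUS.value: base, CS.CSR_PLUS.value: base * mult,
                CS.CSN_PLUS.value: base * mult}
        rec, spikes = simulate_ecg(seq, cond, config, rng)
        channels["ecg"] = rec
        for c in CS:
            truth_rows.append(dict(participant=participant, phase=phase.value,
                                   trial=-1, cs=c.value, reinforced=False,
                                   measure="hpr", amplitude=cond[c.value]))

    bundle = SessionBundle(participant, blind_code, phase, channels,
                           sequence_to_table(seq), annotations)
    return bundle, pd.DataFrame(truth_rows)


def simulate_cohort(config: SimConfig,
                    phases: tuple[Phase, ...] = (Phase.ACQUISITION,
                                                 Phase.RETENTION)):
    """Simulate both groups; returns ``(bundles, truth, participants)``.

    ``bundles`` is a list of :class:`SessionBundle` (one per participant ×
    phase), ``truth`` the concatenated ground-truth table, ``participants``
    a table with group, blind code and EMG gain per participant.  Identical
    seeds yield identical output.
    """
    ss = np.random.SeedSequence(config.seed)
    gain_rng = np.random.default_rng(ss.spawn(1)[0])
    bundles, truths, part_rows = [], [], []
    pid = 0
    for group, code in (("placebo", "A"), ("drug", "B")):
        for _ in range(config.n_per_group):
            pid += 1
            name = f"sub-{pid:03d}"
            gain = float(np.exp(gain_rng.normal(0.0, config.participant_gain_sd)))
            part_rows.append(dict(participant=name, group=group,
                                  group_code=code, gain=gain))
            for phase in phases:
                phase_i = list(Phase).index(phase)
                seed = (config.seed * 1_000_003 + pid * 101 + phase_i) % (2**31)
                bundle, truth = simulate_participant(
                    name, group, gain, phase, seed, config, blind_code=code)
                bundles.append(bundle)
                truths.append(truth)
    truth = pd.concat(truths, ignore_index=True)
    participants = pd.DataFrame(part_rows)
    return bundles, truth, participants
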