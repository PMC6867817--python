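"""Conditioning trial sequences and session timelines.

A session presents three conditioned stimuli — CS⁻ (never reinforced) and
two CS⁺ (each reinforced with an aversive electrical US on half of its
trials).  Sequences are randomized per participant under constraints that
prevent degenerate runs: the first trial of a reinforced phase is a
reinforced CS⁺, the first six trials contain each CS exactly twice, no more
than five identical CS in a row, and no more than four reinforced (or four
unreinforced) CS⁺ trials in a row.

The US is a 500 ms pulse train coterminating with the 4 s CS, so it starts
3.5 s after CS onset.  During the retention phase, an acoustic startle probe
sounds 3.5 s after onset of every CS and no US is ever delivered.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class CS(enum.Enum):
    """Conditioned-stimulus type."""

    CS_MINUS = "CS-"
    CSR_PLUS = "CSr+"   # the CS+ that is later reminded
    CSN_PLUS = "CSn+"   # the non-reminded CS+

    @property
    def is_plus(self) -> bool:
        return self is not CS.CS_MINUS


class Phase(enum.Enum):
    ACQUISITION = "acquisition"
    REMINDER = "reminder"
    RETENTION = "retention"
    RELEARNING = "relearning"


CS_DURATION_S = 4.0
US_DURATION_S = 0.5
PROBE_DELAY_S = 3.5
ITI_CHOICES_S = (7.0, 9.0, 11.0)
LEAD_IN_S = 10.0

#: trials per CS type, whether the phase is reinforced, whether probes sound
PHASE_LAYOUT = {
    Phase.ACQUISITION: dict(per_cs=15, reinforced=True, probes=False),
    Phase.RETENTION: dict(per_cs=15, reinforced=False, probes=True),
    Phase.RELEARNING: dict(per_cs=30, reinforced=True, probes=False),
    Phase.REMINDER: dict(per_cs=None, reinforced=False, probes=False),
}

MAX_CS_RUN = 5
MAX_US_RUN = 4
_MAX_ATTEMPTS = 100_000


@dataclass
class TrialSpec:
    """One trial: stimulus type, reinforcement, and derived event times."""

    index: int                      # 1-based position in the session
    cs: CS
    reinforced: bool = False
    iti_s: float | None = None      # gray-screen interval after CS offset
    cs_onset_s: float | None = None
    cs_duration_s: float = CS_DURATION_S
    us_onset_s: float | None = None
    probe_onset_s: float | None = None


@dataclass
class TrialSequence:
    phase: Phase
    trials: list[TrialSpec]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def cs_labels(self) -> list[str]:
        return [t.cs.value for t in self.trials]

    def nonreinforced(self) -> list[TrialSpec]:
        return [t for t in self.trials if not t.reinforced]

    @property
    def duration_s(self) -> float:
        last = self.trials[-1]
        return last.cs_onset_s + last.cs_duration_s + last.iti_s


# ---------------------------------------------------------------------------
# generation

def generate_trial_sequence(
    phase: Phase,
    seed: int,
    *,
    first_six_balanced: bool = True,
    with_timing: bool = True,
) -> TrialSequence:
    """Generate a randomized trial sequence satisfying all design constraints.

    ``first_six_balanced`` applies the "first six trials contain each CS
    exactly twice" rule; it is applied to all multi-trial phases by default.
    Identical ``seed`` yields an identical sequence.
    """
    if not isinstance(phase, Phase):
        raise ValueError(f"invalid phase: {phase!r}")
    rng = np.random.default_rng(seed)

    if phase is Phase.REMINDER:
        # single unreinforced presentation of the reminded CS+, no draw
        trials = [TrialSpec(index=1, cs=CS.CSR_PLUS, reinforced=False)]
        seq = TrialSequence(phase, trials, seed=seed)
        return assign_timing(seq, seed) if with_timing else seq

    layout = PHASE_LAYOUT[phase]
    per_cs = layout["per_cs"]
    reinforced_phase = layout["reinforced"]

    order = _draw_cs_order(rng, per_cs, reinforced_phase, first_six_balanced)
    trials = [TrialSpec(index=i + 1, cs=c) for i, c in enumerate(order)]

    if reinforced_phase:
        _assign_reinforcement(rng, trials)
    if layout["probes"]:
        pass  # probe times attached by assign_timing

    seq = TrialSequence(phase, trials, seed=seed)
    return assign_timing(seq, seed) if with_timing else seq


def _draw_cs_order(rng, per_cs: int, reinforced_phase: bool,
                   first_six_balanced: bool) -> list[CS]:
    """Rejection-sample a CS order under the first-trial/first-six/run rules."""
    pool = [CS.CS_MINUS, CS.CSR_PLUS, CS.CSN_PLUS]
    for _ in range(_MAX_ATTEMPTS):
        if first_six_balanced:
            head = pool * 2
            rng.shuffle(head)
            if reinforced_phase and not head[0].is_plus:
                # rotate a CS+ to the front; preserves the multiset
                j = int(rng.choice([i for i, c in enumerate(head) if c.is_plus]))
                head[0], head[j] = head[j], head[0]
            tail = [c for c in pool for _ in range(per_cs - 2)]
            rng.shuffle(tail)
            order = head + tail
        else:
            order = [c for c in pool for _ in range(per_cs)]
            rng.shuffle(order)
            if reinforced_phase and not order[0].is_plus:
                j = int(rng.choice([i for i, c in enumerate(order) if c.is_plus]))
                order[0], order[j] = order[j], order[0]
        if _max_run(order) <= MAX_CS_RUN:
            return order
    raise RuntimeError("unsatisfiable constraints: CS order resampling cap hit")


def _assign_reinforcement(rng, trials: list[TrialSpec]) -> None:
    """Reinforce half of each CS⁺'s trials, exact 50% over all CS⁺ trials.

    With an odd per-CS count the CS⁺ shown first gets the extra reinforced
    trial (ceil), the other the floor, so the session-level rate is exact.
    The first trial of the phase is always reinforced, and the CS⁺
    subsequence never contains >4 reinforced or >4 unreinforced in a row.
    """
    plus_idx = {c: [i for i, t in enumerate(trials) if t.cs is c]
                for c in (CS.CSR_PLUS, CS.CSN_PLUS)}
    first_plus_cs = trials[min(i for c in plus_idx for i in plus_idx[c])].cs
    n_reinf = {}
    for c, idx in plus_idx.items():
        n = len(idx)
        n_reinf[c] = math.ceil(n / 2) if c is first_plus_cs else n // 2

    plus_sorted = sorted(i for idx in plus_idx.values() for i in idx)
    for _ in range(_MAX_ATTEMPTS):
        chosen: set[int] = set()
        for c, idx in plus_idx.items():
            pick = rng.choice(len(idx), size=n_reinf[c], replace=False)
            chosen.update(idx[int(k)] for k in pick)
        # first trial of the phase must be a reinforced CS+
        if plus_sorted[0] not in chosen:
            continue
        flags = [i in chosen for i in plus_sorted]
        if _max_bool_run(flags) <= MAX_US_RUN:
            for i, t in enumerate(trials):
                t.reinforced = i in chosen
            return
    raise RuntimeError("unsatisfiable constraints: reinforcement resampling cap hit")


def _max_run(seq) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _max_bool_run(flags: list[bool]) -> int:
    return _max_run(flags) if flags else 0


def assign_timing(seq: TrialSequence, seed: int) -> TrialSequence:
    """Draw ITIs uniformly from {7, 9, 11} s and derive all event onsets.

    CS onsets increase strictly; a reinforced trial's US starts so that the
    500 ms train coterminates with the 4 s CS; retention probes sound 3.5 s
    after CS onset.
    """
    rng = np.random.default_rng(seed + 0x17)
    probes = PHASE_LAYOUT[seq.phase]["probes"]
    trials = []
    t = LEAD_IN_S
    for spec in seq.trials:
        iti = float(rng.choice(ITI_CHOICES_S))
        new = replace(spec, iti_s=iti, cs_onset_s=t)
        new.us_onset_s = (
            t + new.cs_duration_s - US_DURATION_S if new.reinforced else None
        )
        new.probe_onset_s = t + PROBE_DELAY_S if probes else None
        trials.append(new)
        t += spec.cs_duration_s + iti
    return TrialSequence(seq.phase, trials, seed=seq.seed)


# ---------------------------------------------------------------------------
# validation

def validate_sequence(seq: TrialSequence,
                      *, first_six_balanced: bool = True) -> list[str]:
    """Return a named violation per broken design rule (empty list = valid)."""
    v: list[str] = []
    trials = seq.trials
    if not trials:
        return ["empty-sequence"]
    layout = PHASE_LAYOUT[seq.phase]

    if seq.phase is Phase.REMINDER:
        if len(trials) != 1 or trials[0].cs is not CS.CSR_PLUS or trials[0].reinforced:
            v.append("reminder-structure")
        return v

    per_cs = layout["per_cs"]
    if len(trials) != 3 * per_cs:
        v.append("n-trials")
    counts = {c: sum(t.cs is c for t in trials) for c in CS}
    if any(counts[c] != per_cs for c in CS):
        v.append("cs-counts")

    if any(t.reinforced and t.cs is CS.CS_MINUS for t in trials):
        v.append("cs-minus-reinforced")

    if layout["reinforced"]:
        if not (trials[0].cs.is_plus and trials[0].reinforced):
            v.append("first-trial-reinforced-csplus")
        for c in (CS.CSR_PLUS, CS.CSN_PLUS):
            n = counts[c]
            r = sum(t.reinforced for t in trials if t.cs is c)
            if r not in (n // 2, math.ceil(n / 2)):
                v.append("reinforcement-rate")
                break
        total_plus = sum(t.cs.is_plus for t in trials)
        if sum(t.reinforced for t in trials) != round(total_plus / 2):
            v.append("reinforcement-rate-total")
        flags = [t.reinforced for t in trials if t.cs.is_plus]
        runs = _split_bool_runs(flags)
        if any(r > MAX_US_RUN for val, r in runs if val):
            v.append("max-run-us")
        if any(r > MAX_US_RUN for val, r in runs if not val):
            v.append("max-run-us-omission")
    else:
        if any(t.reinforced for t in trials):
            v.append("reinforced-in-unreinforced-phase")

    if first_six_balanced and len(trials) >= 6:
        head = [t.cs for t in trials[:6]]
        if any(head.count(c) != 2 for c in CS):
            v.append("first-six-balance")

    if _max_run([t.cs for t in trials]) > MAX_CS_RUN:
        v.append("max-run-cs")

    v.extend(_validate_timing(seq, layout))
    return v


def _split_bool_runs(flags):
    runs = []
    if not flags:
        return runs
    cur, n = flags[0], 1
    for f in flags[1:]:
        if f == cur:
            n += 1
        else:
            runs.append((cur, n))
            cur, n = f, 1
    runs.append((cur, n))
    return runs


def _validate_timing(seq: TrialSequence, layout) -> list[str]:
    trials = seq.trials
    if trials[0].cs_onset_s is None:
        return []  # timing not yet assigned — not a content violation
    v = []
    onsets = [t.cs_onset_s for t in trials]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        v.append("timing-monotone")
    if any(t.iti_s not in ITI_CHOICES_S for t in trials):
        v.append("iti-values")
    for t in trials:
        if t.reinforced:
            want = t.cs_onset_s + t.cs_duration_s - US_DURATION_S
            if t.us_onset_s is None or abs(t.us_onset_s - want) > 1e-9:
                v.append("us-onset")
                break
        elif t.us_onset_s is not None:
            v.append("us-onset")
            break
    if layout["probes"]:
        for t in trials:
            if t.probe_onset_s is None or abs(
                    t.probe_onset_s - (t.cs_onset_s + PROBE_DELAY_S)) > 1e-9:
                v.append("probe-onset")
                break
    return v


# ---------------------------------------------------------------------------
# serialization

def sequence_to_table(seq: TrialSequence) -> pd.DataFrame:
    """One row per trial: index, cs, reinforced, and event onsets."""
    df = pd.DataFrame(
        {
            "index": [t.index for t in seq],
            "cs": [t.cs.value for t in seq],
            "reinforced": [t.reinforced for t in seq],
            "iti_s": [t.iti_s for t in seq],
            "cs_onset_s": [t.cs_onset_s for t in seq],
            "cs_duration_s": [t.cs_duration_s for t in seq],
            "us_onset_s": [t.us_onset_s for t in seq],
            "probe_onset_s": [t.probe_onset_s for t in seq],
        }
    )
    for col in ("iti_s", "cs_onset_s", "cs_duration_s", "us_onset_s",
                "probe_onset_s"):
        df[col] = df[col].astype(float)   # absent onsets become NaN
    return df


_CS_FROM_LABEL = {c.value: c for c in CS}


def sequence_from_table(df: pd.DataFrame, phase: Phase,
                        seed: int | None = None) -> TrialSequence:
    trials = []
    for _, row in df.iterrows():
        trials.append(
            TrialSpec(
                index=int(row["index"]),
                cs=_CS_FROM_LABEL[row["cs"]],
                reinforced=bool(row["reinforced"]),
                iti_s=_opt(row.get("iti_s")),
                cs_onset_s=_opt(row.get("cs_onset_s")),
                cs_duration_s=float(row.get("cs_duration_s", CS_DURATION_S)),
                us_onset_s=_opt(row.get("us_onset_s")),
                probe_onset_s=_opt(row.get("probe_onset_s")),
            )
        )
    return TrialSequence(phase, trials, seed=seed)


def _opt(x):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)


def sequence_to_bids_events(seq: TrialSequence) -> pd.DataFrame:
    """Long-format events table (onset, duration, trial_type) for interop."""
    rows = []
    for t in seq:
        rows.append((t.cs_onset_s, t.cs_duration_s, f"cs_{t.cs.value}", t.index))
        if t.us_onset_s is not None:
            rows.append((t.us_onset_s, US_DURATION_S, "us", t.index))
        if t.probe_onset_s is not None:
            rows.append((t.probe_onset_s, 0.040, "startle_probe", t.index))
    df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "trial"])
    return df.sort_values(["onset", "trial_type"], kind="stable").reset_index(drop=True)
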