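"""End-to-end pipeline: simulate → quantify → (unblind) → infer.

All quantification stages operate on blinded bundles (they never see the
group mapping); the unblinding table is joined explicitly at the analysis
stage.  Every run can be reproduced from its config: all randomness flows
from named seeds.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import ChannelRecording
from .design import CS, Phase
from .hpr import build_hp_trace, detect_r_spikes, fit_hpr_glm
from .inference import (ModelSpec, RankDeficientDesign, TimeCoding,
                        add_within_cs_trial, effect_tables_both_contrasts,
                        fit_rm_anova)
from .io import SessionBundle, read_bundle, write_bundle, write_unblinding
from .crossval import CVConfig, permutation_test
from .pupil import clean_pupil, exclude_pupil_trials, fit_pupil_glm, select_eye
from .scr import exclude_scr_trials, invert_scr, preprocess_scr, select_scr_trials
from .sebr import fit_sebr_session, normalize_sebr, preprocess_emg
from .synthgen import SimConfig, simulate_cohort


def simulate_to_dir(config: SimConfig, outdir: str | Path,
                    phases=(Phase.ACQUISITION, Phase.RETENTION),
                    fmt: str = "h5") -> Path:
    """Simulate a cohort and write bundles, ground truth and unblinding."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundles, truth, participants = simulate_cohort(config, phases=phases)
    for b in bundles:
        name = f"{b.participant}_{b.phase.value}"
        write_bundle(b, outdir / (name + (".h5" if fmt == "h5" else "")))
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    participants.drop(columns=["group"]).to_csv(
        outdir / "participants.tsv", sep="\t", index=False)
    write_unblinding(dict(zip(participants.group_code, participants.group)),
                     outdir / "unblinding.tsv")
    return outdir


# ---------------------------------------------------------------------------
# per-bundle quantification (blinded)

def fit_bundle(bundle: SessionBundle) -> dict[str, pd.DataFrame]:
    """Run every applicable quantification on one bundle.

    Returns measure -> per-trial (or per-condition) estimate table; all
    tables carry participant/phase columns.
    """
    seq = bundle.sequence()
    out: dict[str, pd.DataFrame] = {}

    if "emg" in bundle.channels:
        env = preprocess_emg(bundle.channels["emg"])
        est = fit_sebr_session(env, seq)
        est = normalize_sebr(est)
        out["sebr"] = est

    if "sc" in bundle.channels:
        artifacts = bundle.annotations.get("sc_artifact", [])
        pre = preprocess_scr(bundle.channels["sc"], artifacts)
        excluded = exclude_scr_trials(seq, artifacts)
        ests = invert_scr(pre, seq, excluded=excluded)
        out["scr"] = select_scr_trials(ests, seq)

    if "pupil_left" in bundle.channels or "pupil" in bundle.channels:
        if "pupil_left" in bundle.channels:
            cleaned = {}
            for eye in ("left", "right"):
                cleaned[eye] = clean_pupil(
                    bundle.channels[f"pupil_{eye}"],
                    bundle.channels[f"gaze_{eye}"],
                    bundle.annotations.get(f"blink_{eye}", []))
            rec = select_eye(cleaned["left"], cleaned["right"])
        else:
            rec = clean_pupil(bundle.channels["pupil"],
                              bundle.channels["gaze"],
                              bundle.annotations.get("blink", []))
        flags = exclude_pupil_trials(rec, seq)
        tab = fit_pupil_glm(rec, seq, trial_flags=flags)
        # only trials without US enter analysis
        out["psr"] = tab[~tab["reinforced"]].reset_index(drop=True)

    if "ecg" in bundle.channels:
        spikes = detect_r_spikes(bundle.channels["ecg"])
        hp = build_hp_trace(spikes, duration_s=seq.duration_s)
        out["hpr"] = fit_hpr_glm(hp, seq,
                                 mean_ibi_s=float(np.mean(np.diff(spikes))))

    for measure, tab in out.items():
        tab.insert(0, "participant", bundle.participant)
        tab.insert(1, "phase", bundle.phase.value)
        tab.insert(2, "group_code", bundle.group_code)
    return out


def fit_bundles(bundles) -> dict[str, pd.DataFrame]:
    """Quantify a list of bundles; concatenated tables per measure."""
    acc: dict[str, list] = {}
    for b in bundles:
        for measure, tab in fit_bundle(b).items():
            acc.setdefault(measure, []).append(tab)
    return {m: pd.concat(ts, ignore_index=True) for m, ts in acc.items()}


# ---------------------------------------------------------------------------
# analysis (explicit unblinding)

def unblind(table: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    out = table.copy()
    out["group"] = out["group_code"].map(mapping)
    if out["group"].isna().any():
        raise ValueError("unblinding map does not cover all group codes")
    return out


def analyze_retention(sebr_table: pd.DataFrame,
                      mapping: dict[str, str]) -> pd.DataFrame:
    """Primary outcome: normalized SEBR over the 45 extinction trials."""
    t = unblind(sebr_table[sebr_table["phase"] == Phase.RETENTION.value],
                mapping)
    spec = ModelSpec(response="normalized_amplitude",
                     time_coding=TimeCoding.ACROSS_CS)
    return _fit_with_time_fallback(t, spec)


def _fit_with_time_fallback(t: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Drop the time terms (with a warning) when the cohort is too small to
    estimate the full drug x cs x time structure."""
    import warnings

    try:
        return effect_tables_both_contrasts(t, spec)
    except RankDeficientDesign:
        if not spec.include_time:
            raise
        warnings.warn("time terms dropped: design rank-deficient at this "
                      "cohort size", RuntimeWarning, stacklevel=2)
        spec2 = ModelSpec(**{**spec.__dict__, "include_time": False})
        return effect_tables_both_contrasts(t, spec2)


def analyze_trialwise(table: pd.DataFrame, mapping: dict[str, str],
                      phase: Phase, response: str = "amplitude") -> pd.DataFrame:
    """Secondary trialwise measures (PSR/SCR) for one phase."""
    t = unblind(table[table["phase"] == phase.value], mapping)
    if phase is Phase.RELEARNING:
        t = add_within_cs_trial(t)
        spec = ModelSpec(response=response, trial_col="trial_within_cs",
                         time_coding=TimeCoding.WITHIN_CS)
    else:
        spec = ModelSpec(response=response, include_time=False)
    return _fit_with_time_fallback(t, spec)


def analyze_hpr(hpr_table: pd.DataFrame, mapping: dict[str, str],
                phase: Phase) -> pd.DataFrame:
    t = unblind(hpr_table[hpr_table["phase"] == phase.value], mapping)
    return fit_rm_anova(t)


def crossval_drug(sebr_table: pd.DataFrame, mapping: dict[str, str],
                  cv_config: CVConfig | None = None):
    """Permutation test: predict each participant's CS⁺/CS⁻ difference of
    normalized SEBR from the drug label."""
    t = unblind(sebr_table[sebr_table["phase"] == Phase.RETENTION.value],
                mapping)
    per = (t.assign(is_plus=t["cs"] != CS.CS_MINUS.value)
           .groupby(["participant", "group", "is_plus"])["normalized_amplitude"]
           .mean().unstack("is_plus"))
    diffs = (per[True] - per[False])
    labels = diffs.index.get_level_values("group").to_numpy()
    return permutation_test(diffs.to_numpy(), labels,
                            cv_config or CVConfig(seed=0))


# ---------------------------------------------------------------------------
# driver

def run_pipeline(sim_config: SimConfig, outdir: str | Path,
                 phases=(Phase.ACQUISITION, Phase.RETENTION),
                 cv_config: CVConfig | None = None) -> dict:
    """Simulate, quantify, unblind, analyze; write all outputs and a log."""
    outdir = Path(outdir)
    data_dir = simulate_to_dir(sim_config, outdir / "data", phases=phases)
    bundles = [read_bundle(p) for p in sorted(data_dir.glob("*.h5"))]
    if not bundles:
        bundles = [read_bundle(p) for p in sorted(data_dir.iterdir())
                   if (p / "manifest.yaml").exists()]
    tables = fit_bundles(bundles)
    res_dir = outdir / "results"
    res_dir.mkdir(parents=True, exist_ok=True)
    for m, tab in tables.items():
        tab.to_csv(res_dir / f"estimates_{m}.tsv", sep="\t", index=False)

    from .io import read_unblinding
    mapping = read_unblinding(data_dir / "unblinding.tsv")

    outputs: dict = {}
    if "sebr" in tables:
        eff = analyze_retention(tables["sebr"], mapping)
        eff.to_csv(res_dir / "effects_sebr_retention.tsv", sep="\t", index=False)
        outputs["sebr_retention"] = eff
        cv = crossval_drug(tables["sebr"], mapping, cv_config)
        outputs["crossval"] = cv
        pd.DataFrame(dict(statistic=[cv.residual_variance_proportion],
                          p=[cv.p_value])).to_csv(
            res_dir / "crossval.tsv", sep="\t", index=False)
    for measure in ("psr", "scr"):
        if measure in tables:
            for phase in phases:
                if phase in (Phase.ACQUISITION, Phase.RELEARNING) and not \
                        tables[measure][tables[measure].phase == phase.value].empty:
                    eff = analyze_trialwise(tables[measure], mapping, phase)
                    eff.to_csv(res_dir / f"effects_{measure}_{phase.value}.tsv",
                               sep="\t", index=False)
                    outputs[f"{measure}_{phase.value}"] = eff
    if "hpr" in tables:
        for phase in phases:
            sub = tables["hpr"][tables["hpr"].phase == phase.value]
            if phase in (Phase.ACQUISITION, Phase.RELEARNING) and not sub.empty:
                eff = analyze_hpr(tables["hpr"], mapping, phase)
                eff.to_csv(res_dir / f"effects_hpr_{phase.value}.tsv",
                           sep="\t", index=False)
                outputs[f"hpr_{phase.value}"] = eff

    log = dict(
        package_version=__version__,
        python=platform.python_version(),
        numpy=np.__version__,
        pandas=pd.__version__,
        seed=sim_config.seed,
        config_hash=config_hash(sim_config),
        phases=[p.value for p in phases],
    )
    (res_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    outputs["log"] = log
    return outputs


def config_hash(config) -> str:
    """Stable hash of a dataclass config (for run logs)."""
    from dataclasses import asdict
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
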