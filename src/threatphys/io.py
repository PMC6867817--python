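"""Session-bundle container and readers/writers.

A :class:`SessionBundle` holds one participant × phase recording: a manifest
(participant id, blinded group code, phase, channel inventory), the named
channel arrays, the trial event table, and annotation intervals (artifact
and blink/saccade marks).  The group *blind code* is an opaque label; the
mapping to placebo/drug lives in a separate unblinding table so that all
fitting stages can run blinded, with unblinding as an explicit final step.

On disk a bundle is either a directory of tab-delimited files plus a YAML
manifest (text interchange), or a single HDF5 file (compact, for large
simulated cohorts).  Round trips are lossless.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import ChannelRecording
from .design import Phase, TrialSequence, sequence_from_table, sequence_to_table

MANIFEST_VERSION = 1
_REQUIRED_MANIFEST = ("participant", "group_code", "phase", "channels", "version")


class SchemaError(ValueError):
    """Bundle on disk does not match the expected schema."""


@dataclass
class SessionBundle:
    participant: str
    group_code: str               # blinded label, e.g. "A"/"B"
    phase: Phase
    channels: dict[str, ChannelRecording] = field(default_factory=dict)
    events: pd.DataFrame | None = None            # one row per trial
    annotations: dict[str, list] = field(default_factory=dict)

    def sequence(self) -> TrialSequence:
        if self.events is None:
            raise ValueError("bundle has no event table")
        return sequence_from_table(self.events, self.phase)

    def manifest(self) -> dict:
        return {
            "version": MANIFEST_VERSION,
            "participant": self.participant,
            "group_code": self.group_code,
            "phase": self.phase.value,
            "channels": {
                name: {"rate_hz": rec.rate_hz, "units": rec.units,
                       "n_samples": rec.n_samples, "t0_s": rec.t0_s}
                for name, rec in self.channels.items()
            },
        }


def _check_manifest(man: dict, where: str) -> None:
    for key in _REQUIRED_MANIFEST:
        if key not in man:
            raise SchemaError(f"{where}: manifest is missing field {key!r}")


# ---------------------------------------------------------------------------
# directory (text) format

def write_bundle(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a bundle; ``.h5``/``.hdf5`` suffix selects the HDF5 container,
    anything else a directory of TSV files with a YAML manifest."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _write_hdf5(bundle, path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "manifest.yaml").write_text(yaml.safe_dump(bundle.manifest()))
    if bundle.events is not None:
        bundle.events.to_csv(path / "events.tsv", sep="\t", index=False)
    for name, rec in bundle.channels.items():
        data = rec.data if rec.data.ndim > 1 else rec.data[:, None]
        cols = {f"v{i}": data[:, i] for i in range(data.shape[1])}
        df = pd.DataFrame(cols)
        if not rec.valid.all():
            df["valid"] = rec.valid.astype(int)
        df.to_csv(path / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.6g")
    if bundle.annotations:
        rows = [(label, float(a), float(b))
                for label, ivs in bundle.annotations.items() for a, b in ivs]
        pd.DataFrame(rows, columns=["label", "start_s", "end_s"]).to_csv(
            path / "annotations.tsv", sep="\t", index=False)
    return path


def read_bundle(path: str | Path) -> SessionBundle:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_hdf5(path)
    man_path = path / "manifest.yaml"
    if not man_path.exists():
        raise SchemaError(f"{path}: no manifest.yaml")
    man = yaml.safe_load(man_path.read_text())
    _check_manifest(man, str(path))
    channels = {}
    for name, meta in man["channels"].items():
        df = pd.read_csv(path / f"{name}.tsv", sep="\t")
        valid = df.pop("valid").to_numpy(bool) if "valid" in df else None
        data = df.to_numpy(float)
        if data.shape[1] == 1:
            data = data[:, 0]
        channels[name] = ChannelRecording(
            data, meta["rate_hz"], units=meta["units"], valid=valid,
            name=name, t0_s=meta.get("t0_s", 0.0))
    events = None
    if (path / "events.tsv").exists():
        events = pd.read_csv(path / "events.tsv", sep="\t")
    annotations: dict[str, list] = {}
    if (path / "annotations.tsv").exists():
        ann = pd.read_csv(path / "annotations.tsv", sep="\t")
        for label, grp in ann.groupby("label"):
            annotations[str(label)] = list(
                zip(grp["start_s"].tolist(), grp["end_s"].tolist()))
    return SessionBundle(man["participant"], man["group_code"],
                         Phase(man["phase"]), channels, events, annotations)


# ---------------------------------------------------------------------------
# HDF5 format

def _write_hdf5(bundle: SessionBundle, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = json.dumps(bundle.manifest())
        for name, rec in bundle.channels.items():
            g = f.create_group(f"channels/{name}")
            g.create_dataset("data", data=rec.data)
            g.create_dataset("valid", data=rec.valid)
        if bundle.events is not None:
            f.attrs["events"] = bundle.events.to_json(orient="split")
        f.attrs["annotations"] = json.dumps(
            {k: [[float(a), float(b)] for a, b in v]
             for k, v in bundle.annotations.items()})
    return path


def _read_hdf5(path: Path) -> SessionBundle:
    with h5py.File(path, "r") as f:
        if "manifest" not in f.attrs:
            raise SchemaError(f"{path}: no manifest attribute")
        man = json.loads(f.attrs["manifest"])
        _check_manifest(man, str(path))
        channels = {}
        for name, meta in man["channels"].items():
            g = f[f"channels/{name}"]
            channels[name] = ChannelRecording(
                g["data"][()], meta["rate_hz"], units=meta["units"],
                valid=g["valid"][()].astype(bool), name=name,
                t0_s=meta.get("t0_s", 0.0))
        events = None
        if "events" in f.attrs:
            events = pd.read_json(_stdio.StringIO(f.attrs["events"]),
                                  orient="split")
        annotations = {k: [tuple(iv) for iv in v]
                       for k, v in json.loads(f.attrs["annotations"]).items()}
    return SessionBundle(man["participant"], man["group_code"],
                         Phase(man["phase"]), channels, events, annotations)


# ---------------------------------------------------------------------------
# unblinding

def write_unblinding(mapping: dict[str, str], path: str | Path) -> Path:
    """Write the blind-code -> group mapping (kept apart from bundles)."""
    path = Path(path)
    pd.DataFrame(sorted(mapping.items()),
                 columns=["group_code", "group"]).to_csv(
        path, sep="\t", index=False)
    return path


def read_unblinding(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["group_code"].astype(str), df["group"].astype(str)))
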