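"""Readers and writers for records, templates, label sequences, features.

Plain-text formats throughout: a record is a CSV potential matrix
(rows = channels, columns = samples) with a JSON sidecar carrying the
sampling rate, channel names, subject id and group; template sets are
JSON; label sequences and run lists are CSV.  EDF reading is supported
through mne when it is installed (``pip install microsem[edf]``).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import STATES, LabelSequence, TemplateSet
from .preprocess import EEGRecord
from .synthetic import SimulatedRecord


# ---------------------------------------------------------------- records

def save_record(record: EEGRecord, path: str | Path) -> None:
    """Write <stem>.csv (channels x samples) and <stem>.json sidecar."""
    path = Path(path)
    stem = path.with_suffix("")
    pd.DataFrame(record.data, index=record.channel_names).to_csv(
        stem.with_suffix(".csv"), header=False)
    sidecar = {
        "fs": record.fs,
        "channel_names": list(record.channel_names),
        "subject_id": record.subject_id,
        "group": record.group,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_record(path: str | Path) -> EEGRecord:
    """Load a CSV + JSON sidecar record written by :func:`save_record`."""
    stem = Path(path).with_suffix("")
    meta = json.loads(stem.with_suffix(".json").read_text())
    df = pd.read_csv(stem.with_suffix(".csv"), header=None, index_col=0)
    return EEGRecord(data=df.to_numpy(float), fs=float(meta["fs"]),
                     channel_names=list(meta["channel_names"]),
                     subject_id=meta.get("subject_id", stem.name),
                     group=meta.get("group", "unknown"))


def read_edf(path: str | Path, group: str = "unknown",
             subject_id: str | None = None) -> EEGRecord:
    """Read an EDF recording through mne (optional dependency)."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover - environment-dependent
        raise ImportError("EDF reading requires mne "
                          "(pip install microsem[edf])") from e
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecord(data=data, fs=float(raw.info["sfreq"]),
                     channel_names=list(raw.ch_names),
                     subject_id=subject_id or Path(path).stem, group=group)


def save_cohort(cohort: list[SimulatedRecord], out_dir: str | Path) -> None:
    """One CSV+JSON record per synthetic subject plus its ground-truth runs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sim in cohort:
        save_record(sim.record, out / f"{sim.record.subject_id}.csv")
        save_runs(sim.runs, out / f"{sim.record.subject_id}_runs.csv")


def load_cohort(in_dir: str | Path) -> list[EEGRecord]:
    out = []
    for f in sorted(Path(in_dir).glob("*.json")):
        if not f.with_suffix(".csv").exists():
            continue
        out.append(load_record(f))
    return out


# ------------------------------------------------- runs / label sequences

def save_runs(runs: list[tuple[int, int]], path: str | Path) -> None:
    """Run-length CSV: state,start_sample,length."""
    starts = np.concatenate(([0], np.cumsum([n for _, n in runs])[:-1]))
    pd.DataFrame({
        "state": [STATES[s] for s, _ in runs],
        "start_sample": starts.astype(int),
        "length": [n for _, n in runs],
    }).to_csv(path, index=False)


def load_runs(path: str | Path) -> list[tuple[int, int]]:
    df = pd.read_csv(path)
    return [(STATES.index(s), int(n))
            for s, n in zip(df["state"], df["length"])]


def save_labels(seq: LabelSequence, path: str | Path) -> None:
    """Per-sample CSV: sample_index,label."""
    pd.DataFrame({
        "sample_index": np.arange(seq.n_samples),
        "label": [STATES[i] for i in seq.labels],
    }).to_csv(path, index=False)


# ------------------------------------------------------------- templates

def save_templates(templates: TemplateSet, path: str | Path,
                   extra: dict | None = None) -> None:
    obj = {
        "group_tag": templates.group_tag,
        "channel_names": list(templates.channel_names),
        "maps": {s: templates.maps[i].tolist() for i, s in enumerate(STATES)},
    }
    if extra:
        obj["provenance"] = extra
    Path(path).write_text(json.dumps(obj, indent=1))


def load_templates(path: str | Path) -> TemplateSet:
    obj = json.loads(Path(path).read_text())
    maps = np.array([obj["maps"][s] for s in STATES], dtype=float)
    return TemplateSet(maps, list(obj["channel_names"]),
                       obj.get("group_tag", "synthetic"))


# -------------------------------------------------------------- features

def save_features(x: np.ndarray, names: list[str],
                  blocks: dict[str, list[int]], y: np.ndarray,
                  subjects: list[str], path: str | Path) -> None:
    """Feature matrix CSV (one row per segment) + JSON schema sidecar."""
    path = Path(path)
    df = pd.DataFrame(x, columns=names)
    df.insert(0, "subject_id", subjects)
    df.insert(1, "group", ["SCZ" if v else "HC" for v in y])
    df.to_csv(path, index=False)
    schema = {"names": names,
              "blocks": {k: list(map(int, v)) for k, v in blocks.items()}}
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=1))


def load_features(path: str | Path,
                  ) -> tuple[np.ndarray, list[str], dict[str, list[int]],
                             np.ndarray, list[str]]:
    path = Path(path)
    df = pd.read_csv(path)
    schema = json.loads(path.with_suffix(".schema.json").read_text())
    names = schema["names"]
    x = df[names].to_numpy(float)
    y = (df["group"] == "SCZ").to_numpy(int)
    return x, names, schema["blocks"], y, df["subject_id"].astype(str).tolist()
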