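"""Disk layout for session bundles: one directory per session.

header.json   — fs, handedness, dtype, shape, layout
signal.f32    — raw little-endian float32, row-major channels × samples
channels.tsv  — name, region_label, hemisphere, artifact_flag
trials.tsv    — trial_id, instruction, perturbed, completed, calibration_speed,
                target_distance, move_onset, hit_target
ground_truth.json — synthetic sessions only

The layout is language-neutral and diff-able; the signal round-trips
bit-exactly and the tables value-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SessionBundle

_TRIAL_COLUMNS = ["trial_id", "instruction", "perturbed", "completed",
                  "calibration_speed", "target_distance", "move_onset",
                  "hit_target"]
_CHANNEL_COLUMNS = ["name", "region_label", "hemisphere", "artifact_flag"]


class SessionFormatError(ValueError):
    """Structured load error naming the offending file or record."""


def write_session(bundle: SessionBundle, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sig = np.ascontiguousarray(bundle.signal, dtype="<f4")
    header = {
        "fs": bundle.fs,
        "handedness": bundle.handedness,
        "dtype": "<f4",
        "shape": list(sig.shape),
        "layout": "row-major channels x samples",
    }
    (path / "header.json").write_text(json.dumps(header, indent=1) + "\n")
    sig.tofile(path / "signal.f32")
    bundle.channel_table[_CHANNEL_COLUMNS].to_csv(path / "channels.tsv",
                                                  sep="\t", index=False)
    bundle.trial_table[_TRIAL_COLUMNS].to_csv(path / "trials.tsv",
                                              sep="\t", index=False)
    if bundle.ground_truth is not None:
        (path / "ground_truth.json").write_text(
            json.dumps(bundle.ground_truth, indent=1) + "\n")


def read_session(path) -> SessionBundle:
    path = Path(path)
    for member in ("header.json", "signal.f32", "channels.tsv", "trials.tsv"):
        if not (path / member).exists():
            raise SessionFormatError(f"missing member file {member} in {path}")
    header = json.loads((path / "header.json").read_text())
    shape = tuple(header["shape"])
    raw = np.fromfile(path / "signal.f32", dtype=header["dtype"])
    expected = shape[0] * shape[1]
    if raw.size != expected:
        raise SessionFormatError(
            f"signal.f32 has {raw.size} samples, header expects {expected} "
            f"({shape[0]} channels x {shape[1]} samples)")
    signal = raw.reshape(shape)

    channels = pd.read_csv(path / "channels.tsv", sep="\t")
    missing = [c for c in _CHANNEL_COLUMNS if c not in channels.columns]
    if missing:
        raise SessionFormatError(f"channels.tsv missing column(s) {missing}")
    if len(channels) != shape[0]:
        raise SessionFormatError(
            f"channels.tsv has {len(channels)} rows, signal has {shape[0]} channels")

    trials = pd.read_csv(path / "trials.tsv", sep="\t")
    missing = [c for c in _TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SessionFormatError(f"trials.tsv missing column(s) {missing}")
    if trials["trial_id"].duplicated().any():
        dup = trials.loc[trials["trial_id"].duplicated(), "trial_id"].iloc[0]
        raise SessionFormatError(f"trials.tsv: duplicate trial_id {dup}")
    bad = trials[trials["hit_target"] <= trials["move_onset"]]
    if len(bad):
        raise SessionFormatError(
            f"trials.tsv: trial_id {bad['trial_id'].iloc[0]} has "
            f"HitTarget <= MoveOnset")
    duration = shape[1] / header["fs"]
    out = trials[(trials["move_onset"] < 0) | (trials["hit_target"] > duration)]
    if len(out):
        raise SessionFormatError(
            f"trials.tsv: trial_id {out['trial_id'].iloc[0]} has event times "
            f"outside the {duration:.3f}s signal")

    gt_path = path / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else None
    return SessionBundle(signal=signal, fs=header["fs"], channel_table=channels,
                         trial_table=trials, handedness=header["handedness"],
                         ground_truth=ground_truth)
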