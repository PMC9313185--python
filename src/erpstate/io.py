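"""Plain-text dataset format: a JSON manifest plus one TSV per trial.

The layout keeps multichannel epoch data diff-able and dependency-light:

    <dir>/manifest.json      fs, t0_ms, channel labels, subjects,
                             conditions, and a file entry per trial
    <dir>/<subject>_<condition>_t<k>.tsv
                             rows = time samples, columns = channels,
                             header = channel labels
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrialDataset", "read_dataset", "write_dataset"]


@dataclass
class TrialDataset:
    """All subjects' epoch stacks for a two-condition study."""

    fs: float
    t0_ms: float
    channels: list[str]
    subjects: list[str]
    conditions: list[str]
    epochs: dict  # (subject, condition) -> EpochSet


def write_dataset(dataset: TrialDataset, out_dir) -> Path:
    """Write the dataset in the manifest + per-trial TSV layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for (subj, cond), ep in dataset.epochs.items():
        for k in range(ep.trials.shape[0]):
            name = f"{subj}_{cond}_t{k:03d}.tsv"
            df = pd.DataFrame(ep.trials[k].T, columns=dataset.channels)
            df.to_csv(out / name, sep="\t", index=False, float_format="%.8g")
            files.append({"subject": subj, "condition": cond, "trial": k, "file": name})
    manifest = {
        "fs": dataset.fs,
        "t0_ms": dataset.t0_ms,
        "channels": dataset.channels,
        "subjects": dataset.subjects,
        "conditions": dataset.conditions,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_dataset(in_dir) -> TrialDataset:
    """Load and validate a dataset written by :func:`write_dataset`."""
    from .erp import EpochSet  # deferred: erp does not depend on io

    d = Path(in_dir)
    mpath = d / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json in {d}")
    manifest = json.loads(mpath.read_text())
    channels = list(manifest["channels"])
    stacks: dict = {}
    for entry in manifest["files"]:
        f = d / entry["file"]
        if not f.exists():
            raise FileNotFoundError(f"manifest lists missing trial file {entry['file']}")
        try:
            df = pd.read_csv(f, sep="\t")
        except ValueError as exc:
            raise ValueError(f"could not parse {entry['file']}: {exc}") from exc
        if list(df.columns) != channels:
            raise ValueError(
                f"{entry['file']}: channel header {list(df.columns)} "
                f"does not match manifest {channels}"
            )
        if not np.issubdtype(df.to_numpy().dtype, np.number):
            raise ValueError(f"{entry['file']}: non-numeric cells")
        key = (entry["subject"], entry["condition"])
        stacks.setdefault(key, []).append((entry["trial"], df.to_numpy().T))
    epochs = {}
    for (subj, cond), lst in stacks.items():
        lst.sort(key=lambda x: x[0])
        trials = np.stack([arr for _, arr in lst], axis=0)
        epochs[(subj, cond)] = EpochSet(
            subject=subj,
            condition=cond,
            trials=trials,
            fs=manifest["fs"],
            t0_ms=manifest["t0_ms"],
            channels=channels,
        )
    return TrialDataset(
        fs=manifest["fs"],
        t0_ms=manifest["t0_ms"],
        channels=channels,
        subjects=list(manifest["subjects"]),
        conditions=list(manifest["conditions"]),
        epochs=epochs,
    )
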