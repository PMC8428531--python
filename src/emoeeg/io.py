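"""Serialisation: epoch containers, configs, optional EDF import.

The epoch container is a directory holding a portable numeric array file
(``data.npy``, epochs x channels x samples) plus a JSON sidecar with the
sampling rate, channel names and per-epoch labels — enough to round-trip a
labelled dataset without any binary metadata format.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .types import LabeledEpoch, Recording


def save_epochs(epochs: list[LabeledEpoch], directory) -> None:
    if not epochs:
        raise ValueError("no epochs to save")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = np.stack([ep.data for ep in epochs])
    np.save(directory / "data.npy", data)
    sidecar = {
        "fs": epochs[0].fs,
        "channel_names": epochs[0].channel_names,
        "labels": [ep.label for ep in epochs],
        "subjects": [ep.subject_id for ep in epochs],
        "clips": [ep.clip_id for ep in epochs],
    }
    (directory / "epochs.json").write_text(json.dumps(sidecar, indent=1))


def load_epochs(directory) -> list[LabeledEpoch]:
    directory = Path(directory)
    data = np.load(directory / "data.npy")
    meta = json.loads((directory / "epochs.json").read_text())
    return [
        LabeledEpoch(
            data=data[i],
            fs=meta["fs"],
            channel_names=list(meta["channel_names"]),
            label=meta["labels"][i],
            subject_id=meta["subjects"][i],
            clip_id=meta["clips"][i],
        )
        for i in range(len(data))
    ]


def read_edf(path, subject_id: str = "", clip_label: str = "positive") -> Recording:
    """Import a continuous EDF recording (requires the optional mne extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "EDF import needs mne; install the package with the [edf] extra"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=subject_id or Path(path).stem,
        clip_label=clip_label,
    )


def write_edf(recording: Recording, path) -> None:
    """EDF export is not provided; save the epoch container instead."""
    raise NotImplementedError(
        "EDF export is not supported; use save_epochs() for a portable "
        "array + JSON container"
    )


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def save_yaml_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
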