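"""Readers and writers for the pipeline's on-disk formats.

EEG comes in as EDF or BrainVision (vhdr/eeg/vmrk) via MNE when that
package is available; volumes as NIfTI via nibabel; neuropsychological
tables as long-format CSV.  Cohort exports write volumes as NIfTI
(intensity float32, labels int16), EEG signals as ``.npy`` arrays with a
JSON sidecar of sampling rate, channel names and event markers, and
ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .neuropsych import DEFAULT_NORMS, NeuropsychTable
from .preprocess import DEFAULT_CHANNELS, EEGRecording, Event

NEUROPSYCH_COLUMNS = [
    "participant_id", "group", "subscale", "session", "raw", "norm_mean", "norm_sd",
]


def read_eeg(path: str | Path, channels: list[str] | None = None) -> EEGRecording:
    """Read an EDF or BrainVision recording into µV, keeping ``channels``."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - depends on install extras
        raise ImportError("reading EDF/BrainVision requires the 'mne' package") from err
    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG format {path.suffix!r}")
    wanted = channels or DEFAULT_CHANNELS
    present = [ch for ch in wanted if ch in raw.ch_names]
    raw.pick(present + [ch for ch in raw.ch_names if ch not in present and ch in ("A1", "A2")])
    events = []
    for ann in raw.annotations:
        events.append(
            Event(
                sample=int(round(ann["onset"] * raw.info["sfreq"])),
                condition=str(ann["description"]),
            )
        )
    return EEGRecording(
        signal=raw.get_data() * 1e6,  # volts -> µV
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        events=events,
    )


def write_eeg(recording: EEGRecording, stem: str | Path) -> tuple[Path, Path]:
    """Write signal as ``<stem>.npy`` plus a ``<stem>.json`` sidecar."""
    stem = Path(stem)
    npy = stem.with_suffix(".npy")
    meta = stem.with_suffix(".json")
    np.save(npy, recording.signal.astype(np.float32))
    meta.write_text(json.dumps({
        "fs": recording.fs,
        "channel_names": recording.channel_names,
        "reference": recording.reference,
        "participant_id": recording.participant_id,
        "events": [
            {"sample": ev.sample, "condition": ev.condition, "session": ev.session}
            for ev in recording.events
        ],
    }, indent=1))
    return npy, meta


def read_eeg_npy(stem: str | Path) -> EEGRecording:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return EEGRecording(
        signal=np.load(stem.with_suffix(".npy")),
        fs=meta["fs"],
        channel_names=meta["channel_names"],
        reference=meta.get("reference", ""),
        events=[Event(ev["sample"], ev["condition"], ev["session"]) for ev in meta["events"]],
        participant_id=meta.get("participant_id", ""),
    )


def read_labeled_volume(
    intensity_path: str | Path, labels_path: str | Path
) -> tuple[np.ndarray, np.ndarray, float]:
    """Load intensity + label NIfTI pair; returns arrays and voxel volume (mm³).

    Features downstream are mask-based, so only the voxel grid matters;
    world orientation is ignored.
    """
    img = nib.load(str(intensity_path))
    lab = nib.load(str(labels_path))
    intensity = np.asarray(img.dataobj, dtype=np.float32)
    labels = np.asarray(lab.dataobj).astype(np.int16)
    if intensity.shape != labels.shape:
        raise ValueError("intensity and label volumes differ in shape")
    voxel_volume = float(np.prod(img.header.get_zooms()[:3]))
    return intensity, labels, voxel_volume


def write_labeled_volume(
    intensity: np.ndarray, labels: np.ndarray, stem: str | Path,
    voxel_size_mm: float = 1.0,
) -> tuple[Path, Path]:
    stem = Path(stem)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    ipath = stem.parent / f"{stem.name}_T1.nii"
    lpath = stem.parent / f"{stem.name}_labels.nii"
    nib.save(nib.Nifti1Image(intensity.astype(np.float32), affine), str(ipath))
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), str(lpath))
    return ipath, lpath


def read_neuropsych_csv(path: str | Path) -> NeuropsychTable:
    """Load a long-format neuropsych CSV with per-row norms."""
    df = pd.read_csv(path)
    missing = set(NEUROPSYCH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"neuropsych CSV missing columns {sorted(missing)}")
    norms = {}
    for sub, grp in df.groupby("subscale"):
        default = DEFAULT_NORMS.get(sub)
        better = default[2] if default else True
        norms[sub] = (float(grp["norm_mean"].iloc[0]), float(grp["norm_sd"].iloc[0]), better)
    return NeuropsychTable(
        df[["participant_id", "group", "session", "subscale", "raw"]].copy(), norms
    )


def write_neuropsych_csv(table: NeuropsychTable, path: str | Path) -> Path:
    df = table.scores.copy()
    df["norm_mean"] = df["subscale"].map({k: v[0] for k, v in table.norms.items()})
    df["norm_sd"] = df["subscale"].map({k: v[1] for k, v in table.norms.items()})
    df[NEUROPSYCH_COLUMNS].to_csv(path, index=False)
    return Path(path)


def write_feature_table(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, index=False)
    return Path(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
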