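"""EEG preprocessing: rereferencing, filtering, amplitude-rule artifact
detection, and condition-locked 1000 ms segmentation.

The preprocessing chain mirrors a standard clinical resting/task EEG
pipeline: linked-earlobe rereference, zero-phase 1 Hz high-pass
(48 dB/oct) plus 50 Hz notch, three amplitude-based artifact rules, and
cutting of one-second segments either event-locked (100 ms pre-stimulus,
900 ms post) or as consecutive windows of the resting block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, minimum_filter1d

logger = logging.getLogger(__name__)

#: Analysis montage: 17 scalp electrodes of the 10-20 system.
DEFAULT_CHANNELS = [
    "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz",
]

CONDITIONS = ("rest", "learning", "recall", "recognition")


@dataclass(frozen=True)
class Event:
    """Stimulus/block marker: sample index, task condition, session number."""

    sample: int
    condition: str
    session: int = 1


@dataclass
class EEGRecording:
    """Multichannel EEG in microvolts.

    signal : (n_channels, n_samples) float array, µV
    fs : sampling rate in Hz
    channel_names : one name per row of ``signal``
    reference : label of the current reference
    events : stimulus/block markers
    artifact_mask : per-sample boolean, True where data are unusable
        (``None`` until :func:`detect_artifacts` has run)
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str]
    reference: str = "FCz"
    events: list[Event] = field(default_factory=list)
    artifact_mask: np.ndarray | None = None
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match signal rows")
        n = self.signal.shape[1]
        for ev in self.events:
            if not 0 <= ev.sample < n:
                raise ValueError(f"event at sample {ev.sample} outside recording")
        if self.artifact_mask is not None and len(self.artifact_mask) != n:
            raise ValueError("artifact mask length must equal sample count")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class Segment:
    """One artifact-free 1000 ms window (channels x round(fs) samples)."""

    data: np.ndarray
    condition: str
    session: int
    participant_id: str
    onset_sample: int


def rereference_average_earlobes(
    recording: EEGRecording, earlobe_channels: tuple[str, str] = ("A1", "A2")
) -> EEGRecording:
    """Rereference to the average of the two earlobe electrodes.

    The mean of the two earlobe signals is subtracted from every channel;
    the earlobe channels themselves are dropped from the analysis set.
    """
    names = recording.channel_names
    for ch in earlobe_channels:
        if ch not in names:
            raise ValueError(f"earlobe channel {ch!r} not present in recording")
    ear_idx = [names.index(ch) for ch in earlobe_channels]
    ref = recording.signal[ear_idx].mean(axis=0)
    keep = [i for i in range(len(names)) if i not in ear_idx]
    return replace(
        recording,
        signal=recording.signal[keep] - ref,
        channel_names=[names[i] for i in keep],
        reference="linked earlobes",
        artifact_mask=None,
    )


def filter_recording(
    recording: EEGRecording,
    highpass_hz: float = 1.0,
    notch_hz: float = 50.0,
    notch_width_hz: float = 2.0,
) -> EEGRecording:
    """Zero-phase 1 Hz high-pass (48 dB/oct) and 50 Hz notch.

    The 48 dB/oct rolloff corresponds to an 8th-order Butterworth; it is
    applied forward-backward (``sosfiltfilt``) for zero phase, which doubles
    the effective order.  The notch is a 2nd-order Butterworth bandstop of
    2 Hz width centred on the mains frequency.
    """
    if recording.fs < 250:
        raise ValueError("sampling rate below 250 Hz not supported")
    hp = sps.butter(8, highpass_hz, btype="highpass", fs=recording.fs, output="sos")
    out = sps.sosfiltfilt(hp, recording.signal, axis=1)
    if notch_hz:
        half = notch_width_hz / 2.0
        bs = sps.butter(
            2, [notch_hz - half, notch_hz + half], btype="bandstop",
            fs=recording.fs, output="sos",
        )
        out = sps.sosfiltfilt(bs, out, axis=1)
    return replace(recording, signal=out, artifact_mask=None)


def _mark_windows(flagged: np.ndarray, width: int) -> np.ndarray:
    """Given per-window-start flags, mark every sample of flagged windows."""
    n = len(flagged) + width - 1
    mask = np.zeros(n, dtype=bool)
    for start in np.flatnonzero(flagged):
        mask[start : start + width] = True
    return mask


def _window_range(x: np.ndarray, width: int) -> np.ndarray:
    """max - min over every sliding window of ``width`` samples (1-sample stride)."""
    mx = maximum_filter1d(x, size=width, mode="nearest")
    mn = minimum_filter1d(x, size=width, mode="nearest")
    # centred filters -> recover window-start alignment
    r = mx - mn
    starts = len(x) - width + 1
    out = np.empty(starts)
    # maximum_filter1d centres the window; index so out[s] covers x[s:s+width]
    offset = width // 2
    out[:] = r[offset : offset + starts]
    return out


def detect_artifacts(
    recording: EEGRecording,
    step_uv: float = 50.0,
    excursion_uv: float = 200.0,
    excursion_window_ms: float = 200.0,
    flat_uv: float = 0.5,
    flat_window_ms: float = 100.0,
) -> np.ndarray:
    """Three amplitude rules, unioned over channels; returns a boolean mask.

    (a) a voltage step of more than 50 µV between consecutive samples marks
        ±100 ms around the jump;
    (b) a peak-to-peak range above 200 µV within any 200 ms window marks
        that window;
    (c) a peak-to-peak range below 0.5 µV over any 100 ms window (a flat,
        disconnected-looking stretch) marks the window plus ±500 ms.

    All windows slide with a 1-sample stride.
    """
    fs = recording.fs
    n = recording.n_samples
    mask = np.zeros(n, dtype=bool)
    pad_step = int(round(0.100 * fs))
    w_exc = int(round(excursion_window_ms / 1000.0 * fs))
    w_flat = int(round(flat_window_ms / 1000.0 * fs))
    pad_flat = int(round(0.500 * fs))

    for x in recording.signal:
        # rule (a): steps
        jumps = np.flatnonzero(np.abs(np.diff(x)) > step_uv)
        for j in jumps:
            mask[max(0, j - pad_step) : j + 1 + pad_step + 1] = True
        # rule (b): high-amplitude excursions
        if n >= w_exc:
            rng = _window_range(x, w_exc)
            mask |= _mark_windows(rng > excursion_uv, w_exc)
        # rule (c): flat stretches, marked with a ±500 ms surround
        if n >= w_flat:
            rng = _window_range(x, w_flat)
            flat = np.flatnonzero(rng < flat_uv)
            for start in flat:
                mask[max(0, start - pad_flat) : start + w_flat + pad_flat] = True
    return mask


def segment(
    recording: EEGRecording,
    mode: str = "rest",
    pre_ms: float = 100.0,
    post_ms: float = 900.0,
) -> list[Segment]:
    """Cut 1000 ms segments; any segment touching the artifact mask is dropped.

    ``event_locked`` mode cuts one window per non-rest event, from 100 ms
    before to 900 ms after stimulus onset.  ``rest`` mode cuts consecutive
    non-overlapping windows starting at each rest-block onset (the whole
    recording when no events are present).  Segments extending past the
    recording edge are skipped and counted.
    """
    if recording.artifact_mask is None:
        raise ValueError("run detect_artifacts before segmentation")
    fs = recording.fs
    nwin = int(round(fs * 1.0))
    mask = recording.artifact_mask
    n = recording.n_samples
    out: list[Segment] = []
    skipped_edge = 0

    def _try_add(onset: int, condition: str, session: int) -> None:
        nonlocal skipped_edge
        if onset < 0 or onset + nwin > n:
            skipped_edge += 1
            return
        if mask[onset : onset + nwin].any():
            return
        out.append(
            Segment(
                data=recording.signal[:, onset : onset + nwin].copy(),
                condition=condition,
                session=session,
                participant_id=recording.participant_id,
                onset_sample=onset,
            )
        )

    if mode == "event_locked":
        pre = int(round(pre_ms / 1000.0 * fs))
        for ev in recording.events:
            if ev.condition == "rest":
                continue
            _try_add(ev.sample - pre, ev.condition, ev.session)
    elif mode == "rest":
        rest_events = [ev for ev in recording.events if ev.condition == "rest"]
        if not rest_events:
            blocks = [(0, n, 1)]
        else:
            starts = sorted(ev.sample for ev in recording.events)
            blocks = []
            for ev in rest_events:
                later = [s for s in starts if s > ev.sample]
                end = later[0] if later else n
                blocks.append((ev.sample, end, ev.session))
        for start, end, session in blocks:
            for onset in range(start, end - nwin + 1, nwin):
                _try_add(onset, "rest", session)
    else:
        raise ValueError(f"unknown segmentation mode {mode!r}")

    if skipped_edge:
        logger.info("skipped %d segment(s) at recording edge", skipped_edge)
    return out
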