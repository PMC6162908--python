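"""Trial data model and I/O.

Epoched motor-imagery EEG is carried as :class:`Trial` / :class:`TrialSet`
(channels x samples in microvolts, one integer class label per trial) and
persisted in a small self-describing HDF5 container.  Continuous recordings
(e.g. imported from GDF files of the BCI Competition IV datasets) are carried
as :class:`RawRecording` and cut into trials with :func:`extract_epoch`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "RawRecording",
    "Trial",
    "TrialSet",
    "FormatError",
    "extract_epoch",
    "read_trialset",
    "write_trialset",
    "import_gdf",
    "drop_eog_channels",
    "epoch_trialset",
]


class FormatError(ValueError):
    """A file exists but does not follow the expected schema/format."""


@dataclass
class RawRecording:
    """Continuous multi-channel recording with event markers.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Voltage traces in microvolts.
    sample_rate_hz : float
        Sampling rate, strictly positive.
    channel_labels : list of str
        One label per channel (e.g. ``"C3"``, ``"EOG-left"``).
    events : list of (int, int)
        ``(onset_sample, class_label)`` pairs; onsets are 0-based sample
        indices into ``signal``.
    """

    signal: np.ndarray
    sample_rate_hz: float
    channel_labels: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("channel label count must match channel count")
        n = self.signal.shape[1]
        for onset, _ in self.events:
            if not 0 <= onset < n:
                raise ValueError(f"event onset {onset} outside recording")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class Trial:
    """One epoched motor-imagery trial (channels x samples, one label)."""

    data: np.ndarray
    label: int
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trial data must be 2-D (channels x samples)")
        if self.data.shape[1] < 1:
            raise ValueError("trial must contain at least one sample")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "Trial":
        """Copy of this trial with new samples, label/metadata preserved."""
        return replace(self, data=data)


@dataclass
class TrialSet:
    """A labelled collection of equally-shaped trials at one sample rate."""

    trials: list[Trial]
    class_set: list[int]
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.class_set = [int(c) for c in self.class_set]
        self.validate()

    def validate(self) -> None:
        if len(self.trials) < 1:
            raise ValueError("TrialSet must contain at least one trial")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        n, t = self.trials[0].data.shape
        for tr in self.trials:
            if tr.data.shape != (n, t):
                raise ValueError(
                    "all trials must share channel and sample counts; "
                    f"got {tr.data.shape} vs {(n, t)}"
                )
            if tr.label not in self.class_set:
                raise ValueError(f"label {tr.label} not in class_set {self.class_set}")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return self.trials[0].n_channels

    @property
    def n_samples(self) -> int:
        return self.trials[0].n_samples

    def labels(self) -> np.ndarray:
        return np.array([tr.label for tr in self.trials], dtype=int)

    def subset(self, indices) -> "TrialSet":
        return TrialSet(
            trials=[self.trials[i] for i in indices],
            class_set=list(self.class_set),
            sample_rate_hz=self.sample_rate_hz,
        )


def extract_epoch(
    recording: RawRecording,
    event: tuple[int, int],
    window_s: tuple[float, float],
    subject_id: str = "",
    session_id: str = "",
) -> Trial:
    """Cut one trial out of a continuous recording, relative to an event.

    The epoch covers the half-open sample interval
    ``[onset + round(start*rate), onset + round(start*rate) + T)`` with
    ``T = round((stop - start) * rate)``; e.g. a [4, 6] s window at 250 Hz
    yields exactly 500 samples.

    Parameters
    ----------
    event : (onset_sample, label)
    window_s : (start, stop)
        Epoch bounds in seconds relative to the event onset; ``stop > start``.
    """
    start, stop = float(window_s[0]), float(window_s[1])
    if stop <= start:
        raise ValueError(f"epoch window must satisfy stop > start, got [{start}, {stop}]")
    onset, label = int(event[0]), int(event[1])
    rate = recording.sample_rate_hz
    first = onset + int(round(start * rate))
    n = int(round((stop - start) * rate))
    if first < 0 or first + n > recording.n_samples:
        raise IndexError(
            f"epoch [{first}, {first + n}) outside recording of "
            f"{recording.n_samples} samples"
        )
    return Trial(
        data=recording.signal[:, first : first + n].copy(),
        label=label,
        subject_id=subject_id,
        session_id=session_id,
    )


def epoch_trialset(ts: TrialSet, window_s: tuple[float, float]) -> TrialSet:
    """Re-epoch every trial of a set relative to its own start.

    Each trial is treated as a recording whose event onset is sample 0 —
    the natural operation on simulated trials that span the full cue
    protocol timeline.
    """
    trials = []
    for tr in ts.trials:
        rec = RawRecording(
            signal=tr.data,
            sample_rate_hz=ts.sample_rate_hz,
            channel_labels=[f"ch{i}" for i in range(tr.n_channels)],
            events=[(0, tr.label)],
        )
        trials.append(
            extract_epoch(rec, (0, tr.label), window_s,
                          subject_id=tr.subject_id, session_id=tr.session_id)
        )
    return TrialSet(trials=trials, class_set=list(ts.class_set),
                    sample_rate_hz=ts.sample_rate_hz)


# HDF5 container schema: root attrs `class_set`, `sample_rate_hz`;
# one dataset /trials/<i>/data per trial with attrs label/subject/session.

def write_trialset(ts: TrialSet, path) -> None:
    """Write a TrialSet to the portable HDF5 trial container."""
    ts.validate()
    with h5py.File(path, "w") as f:
        f.attrs["class_set"] = np.asarray(ts.class_set, dtype=np.int64)
        f.attrs["sample_rate_hz"] = float(ts.sample_rate_hz)
        grp = f.create_group("trials")
        for i, tr in enumerate(ts.trials):
            d = grp.create_group(str(i)).create_dataset("data", data=tr.data)
            d.attrs["label"] = int(tr.label)
            d.attrs["subject"] = tr.subject_id
            d.attrs["session"] = tr.session_id


def read_trialset(path) -> TrialSet:
    """Read a TrialSet written by :func:`write_trialset`."""
    with h5py.File(path, "r") as f:
        if "class_set" not in f.attrs or "sample_rate_hz" not in f.attrs:
            raise FormatError(f"{path}: missing class_set/sample_rate_hz attributes")
        if "trials" not in f:
            raise FormatError(f"{path}: missing /trials group")
        class_set = [int(c) for c in np.asarray(f.attrs["class_set"])]
        rate = float(f.attrs["sample_rate_hz"])
        trials = []
        for key in sorted(f["trials"], key=int):
            node = f["trials"][key]
            if "data" not in node:
                raise FormatError(f"{path}: trial {key} has no data")
            d = node["data"]
            trials.append(
                Trial(
                    data=d[()],
                    label=int(d.attrs["label"]),
                    subject_id=str(d.attrs.get("subject", "")),
                    session_id=str(d.attrs.get("session", "")),
                )
            )
    return TrialSet(trials=trials, class_set=class_set, sample_rate_hz=rate)


_EOG_MARKERS = ("eog",)


def drop_eog_channels(recording: RawRecording) -> RawRecording:
    """Return a recording with EOG-labelled channels removed.

    Channels whose label contains "EOG" (case-insensitive) are dropped;
    ocular channels are never used in the analysis pipeline.
    """
    keep = [
        i
        for i, lab in enumerate(recording.channel_labels)
        if not any(m in lab.lower() for m in _EOG_MARKERS)
    ]
    return RawRecording(
        signal=recording.signal[keep],
        sample_rate_hz=recording.sample_rate_hz,
        channel_labels=[recording.channel_labels[i] for i in keep],
        events=list(recording.events),
    )


def import_gdf(path, eeg_channels_only: bool = True) -> RawRecording:
    """Import a GDF biosignal file (BCI Competition IV format) via MNE.

    Event annotation descriptions that parse as integers become class labels;
    other annotations are skipped. With ``eeg_channels_only`` the three EOG
    channels of the competition montage are dropped.
    """
    import mne

    try:
        raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad files
        raise FormatError(f"could not read GDF file {path}: {exc}") from exc
    signal = raw.get_data() * 1e6  # volts -> microvolts
    rate = float(raw.info["sfreq"])
    events = []
    for ann in raw.annotations:
        try:
            label = int(ann["description"])
        except (TypeError, ValueError):
            continue
        events.append((int(round(ann["onset"] * rate)), label))
    rec = RawRecording(
        signal=signal,
        sample_rate_hz=rate,
        channel_labels=list(raw.ch_names),
        events=events,
    )
    if eeg_channels_only:
        rec = drop_eog_channels(rec)
    return rec
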