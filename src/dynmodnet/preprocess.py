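"""Raw-signal front end: filtering and epoching of continuous recordings.

For users starting from continuous multichannel recordings rather than ROI
time series.  The chain mirrors standard EEG practice: 5th-order Butterworth
band-pass 0.3–50 Hz, 60 Hz notch for line noise, epoching around stimulus
events (−1 s to +2 s by default, with the 2 s post-onset sub-window used for
analysis), and alpha-band (8–13 Hz) selection.

All filters are applied zero-phase (forward–backward), so the effective
order is doubled and phase estimates downstream are unbiased by filter
delay.  Artifact rejection (e.g. ICA) is out of scope; externally cleaned
data can enter the pipeline at any stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
from scipy.signal import butter, iirnotch, filtfilt, sosfiltfilt


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class ContinuousRecording:
    """Channels x samples array with events (sample index, event code)."""

    data: np.ndarray
    fs: float
    ch_names: tuple[str, ...] = ()
    events: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise PreprocessError("data must have shape (n_channels, n_samples)")
        if self.fs <= 0:
            raise PreprocessError("fs must be positive")
        for s, _ in self.events:
            if not 0 <= s < d.shape[1]:
                raise PreprocessError(f"event at sample {s} outside record of {d.shape[1]} samples")
        object.__setattr__(self, "data", d)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class EpochSet:
    """Channels x samples x trials array cut around events."""

    data: np.ndarray
    fs: float
    tmin: float
    tmax: float
    ch_names: tuple[str, ...] = ()
    condition: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise PreprocessError("data must have shape (n_channels, n_samples, n_trials)")
        object.__setattr__(self, "data", d)

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def analysis_window(self, start_s: float = 0.0, duration_s: float = 2.0) -> "EpochSet":
        """Post-onset sub-window used for analysis (default: 0 to +2 s)."""
        i0 = int(round((start_s - self.tmin) * self.fs))
        n = int(round(duration_s * self.fs))
        if i0 < 0 or i0 + n > self.data.shape[1]:
            raise PreprocessError("analysis window outside epoch bounds")
        return replace(self, data=self.data[:, i0 : i0 + n, :], tmin=start_s, tmax=start_s + duration_s)


def bandpass(
    rec: ContinuousRecording, low_hz: float = 0.3, high_hz: float = 50.0, order: int = 5
) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass per channel."""
    if not 0 < low_hz < high_hz:
        raise PreprocessError("need 0 < low < high")
    if high_hz >= rec.fs / 2:
        raise PreprocessError(f"high cutoff {high_hz} Hz at or above Nyquist ({rec.fs / 2} Hz)")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    return replace(rec, data=sosfiltfilt(sos, rec.data, axis=-1))


def notch(rec: ContinuousRecording, freq_hz: float = 60.0, quality: float = 30.0) -> ContinuousRecording:
    """Zero-phase narrow-band rejection (2nd-order IIR notch, Q=30)."""
    if freq_hz >= rec.fs / 2:
        raise PreprocessError(f"notch frequency {freq_hz} Hz at or above Nyquist")
    b, a = iirnotch(freq_hz, quality, fs=rec.fs)
    return replace(rec, data=filtfilt(b, a, rec.data, axis=-1))


def epoch(rec: ContinuousRecording, tmin: float = -1.0, tmax: float = 2.0) -> EpochSet:
    """Cut one epoch per event, spanning [tmin, tmax] seconds around it."""
    n = int(round((tmax - tmin) * rec.fs))
    epochs = []
    for idx, (sample, _code) in enumerate(rec.events):
        i0 = sample + int(round(tmin * rec.fs))
        if i0 < 0 or i0 + n > rec.n_samples:
            raise PreprocessError(
                f"event {idx} at sample {sample}: epoch [{tmin}, {tmax}] s out of record bounds"
            )
        epochs.append(rec.data[:, i0 : i0 + n])
    data = (
        np.stack(epochs, axis=-1)
        if epochs
        else np.empty((rec.n_channels, n, 0))
    )
    return EpochSet(data=data, fs=rec.fs, tmin=tmin, tmax=tmax, ch_names=rec.ch_names)


def band_select(epochs: EpochSet, low_hz: float = 8.0, high_hz: float = 13.0, order: int = 5) -> EpochSet:
    """Zero-phase band-pass per node per epoch (alpha band by default)."""
    if not 0 < low_hz < high_hz:
        raise PreprocessError("need 0 < low < high")
    if high_hz >= epochs.fs / 2:
        raise PreprocessError(f"high cutoff {high_hz} Hz at or above Nyquist")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=epochs.fs, output="sos")
    if epochs.n_trials == 0:
        return epochs
    return replace(epochs, data=sosfiltfilt(sos, epochs.data, axis=1))


def read_events_csv(path: str | Path) -> tuple[tuple[int, int], ...]:
    """Sidecar event list: CSV with header ``sample,code``."""
    events = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            events.append((int(row["sample"]), int(row["code"])))
    return tuple(events)


def read_edf(path: str | Path, events_csv: str | Path | None = None) -> ContinuousRecording:
    """Read an EDF/EDF+ recording (via MNE) into a ContinuousRecording.

    Events come from a sidecar CSV when given, otherwise from EDF+
    annotations (the annotation description must parse as an integer code).
    """
    import mne  # deferred: only needed for EDF ingestion

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    fs = float(raw.info["sfreq"])
    if events_csv is not None:
        events = read_events_csv(events_csv)
    else:
        events = tuple(
            (int(round(onset * fs)), int(float(desc)))
            for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
            if _is_int(desc)
        )
    return ContinuousRecording(data=data, fs=fs, ch_names=tuple(raw.ch_names), events=events)


def _is_int(text: str) -> bool:
    try:
        int(float(text))
        return True
    except ValueError:
        return False


def write_tabular(rec: ContinuousRecording, path: str | Path) -> None:
    """Tabular bundle: wide CSV (`sample` + one column per channel) with a
    `#fs=<Hz>` comment header; events go in a sibling `<stem>_events.csv`."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"#fs={rec.fs}\n")
        names = rec.ch_names or tuple(f"ch{i}" for i in range(rec.n_channels))
        writer = csv.writer(fh)
        writer.writerow(("sample",) + names)
        for s in range(rec.n_samples):
            writer.writerow([s] + [repr(float(v)) for v in rec.data[:, s]])
    if rec.events:
        with open(path.with_name(path.stem + "_events.csv"), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(("sample", "code"))
            writer.writerows(rec.events)


def read_tabular(path: str | Path) -> ContinuousRecording:
    """Read the tabular bundle written by :func:`write_tabular`."""
    path = Path(path)
    with open(path, newline="") as fh:
        header = fh.readline().strip()
        if not header.startswith("#fs="):
            raise PreprocessError("tabular bundle must start with a '#fs=<Hz>' line")
        fs = float(header[4:])
        reader = csv.reader(fh)
        names = next(reader)[1:]
        rows = [[float(v) for v in row[1:]] for row in reader]
    events_path = path.with_name(path.stem + "_events.csv")
    events = read_events_csv(events_path) if events_path.exists() else ()
    return ContinuousRecording(
        data=np.array(rows).T, fs=fs, ch_names=tuple(names), events=events
    )
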