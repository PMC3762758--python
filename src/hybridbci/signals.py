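"""Core EEG containers, filtering, windowing and epoching.

Everything downstream (the ERD, SSVEP and P300 decoders, the protocol
arbiter and the closed-loop simulator) works on the two containers defined
here: :class:`EEGRecording`, a continuous multichannel record with event
markers, and :class:`TrialSet`, a bag of fixed-length labelled windows.

Conventions
-----------
* sample indices are 0-based; window intervals are half-open
  ``[start, start + width)``;
* data matrices are ``channels x samples`` in microvolts;
* the default montage is the 14-channel 10-20 subset of a consumer
  headset sampling at 128 Hz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: 14-channel 10-20 subset used throughout (frontal, frontocentral,
#: temporal, parietal and occipital sites), in acquisition order.
EMOTIV_CHANNELS = (
    "AF3", "AF4", "F3", "F4", "F7", "F8", "FC5", "FC6",
    "P7", "P8", "T7", "T8", "O1", "O2",
)

DEFAULT_RATE = 128.0


@dataclass
class EEGRecording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling rate in Hz (default 128).
    channel_names : sequence of str
        Unique channel labels, one per row of ``data``.
    events : list of (int, object)
        ``(sample_index, event_code)`` markers; indices must lie inside
        the record.
    """

    data: np.ndarray
    rate: float = DEFAULT_RATE
    channel_names: tuple = EMOTIV_CHANNELS
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        for idx, _code in self.events:
            if not 0 <= idx < self.n_samples:
                raise ValueError(f"event sample index {idx} outside record")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.rate

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)

    def pick(self, names) -> "EEGRecording":
        """Return a copy restricted to the given channels, in the given order."""
        idx = [self.channel_index(n) for n in names]
        return EEGRecording(self.data[idx].copy(), self.rate, tuple(names),
                            list(self.events))


@dataclass
class Window:
    """A fixed-length slice of a recording, optionally labelled."""

    data: np.ndarray
    start_time: float
    duration: float
    label: object = None
    rate: float = DEFAULT_RATE
    channel_names: tuple = EMOTIV_CHANNELS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialSet:
    """Labelled fixed-length windows for one protocol (ERD, SSVEP or P300)."""

    windows: list
    protocol: str = ""
    class_labels: list = field(default_factory=list)

    def __post_init__(self):
        if self.windows and not self.class_labels:
            self.class_labels = [w.label for w in self.windows]
        shapes = {w.data.shape for w in self.windows}
        if len(shapes) > 1:
            raise ValueError(f"windows have inconsistent shapes: {shapes}")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def X(self) -> np.ndarray:
        """Stacked data, shape (n_windows, n_channels, n_samples)."""
        return np.stack([w.data for w in self.windows])

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.class_labels)

    def subset(self, indices) -> "TrialSet":
        return TrialSet([self.windows[i] for i in indices], self.protocol,
                        [self.class_labels[i] for i in indices])


def _design_bandpass(low: float, high: float, order: int, rate: float):
    if not 0 < low < high < rate / 2:
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({rate / 2} Hz)"
        )
    return sps.butter(order, [low, high], btype="bandpass", fs=rate,
                      output="sos")


def bandpass(rec: EEGRecording, low: float, high: float, order: int = 5,
             causal: bool = False) -> EEGRecording:
    """Butterworth band-pass filter every channel of a recording.

    Zero-phase (forward-backward) by default, which doubles the effective
    order and removes group delay; set ``causal=True`` for a single forward
    pass as a real-time system would apply.
    """
    sos = _design_bandpass(low, high, order, rec.rate)
    if causal:
        out = sps.sosfilt(sos, rec.data, axis=1)
    else:
        out = sps.sosfiltfilt(sos, rec.data, axis=1)
    logger.debug("bandpass %.3g-%.3g Hz order %d on %s", low, high, order,
                 rec.data.shape)
    return replace(rec, data=out)


def bandpass_window(w: Window, low: float, high: float, order: int = 5) -> Window:
    """Zero-phase band-pass applied to a single short window.

    Uses Gustafsson's initial-condition method, which minimizes the edge
    transients that dominate plain forward-backward filtering on 2 s
    windows.
    """
    if not 0 < low < high < w.rate / 2:
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist)")
    b, a = sps.butter(order, [low, high], btype="bandpass", fs=w.rate)
    return replace(w, data=sps.filtfilt(b, a, w.data, axis=1, method="gust"))


def sliding_windows(rec: EEGRecording, width: float, step: float) -> list:
    """Cut ``rec`` into overlapping windows of ``width`` s every ``step`` s.

    Starts are 0, step, 2*step, ...; only windows fully inside the record
    are returned, so the count is ``floor((T - width) / step) + 1``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if width > rec.duration:
        warnings.warn(
            f"window width {width} s exceeds record duration "
            f"{rec.duration} s; returning no windows"
        )
        return []
    n_win = int(np.floor((rec.duration - width) / step + 1e-9)) + 1
    wlen = int(round(width * rec.rate))
    out = []
    for k in range(n_win):
        start = k * step
        i0 = int(round(start * rec.rate))
        out.append(Window(rec.data[:, i0:i0 + wlen].copy(), start, width,
                          rate=rec.rate, channel_names=rec.channel_names))
    logger.debug("sliding_windows width=%s step=%s -> %d windows", width,
                 step, n_win)
    return out


def extract_epochs(rec: EEGRecording, event_codes, span: float,
                   protocol: str = "P300") -> TrialSet:
    """Extract stimulus-locked epochs of ``span`` seconds.

    One epoch per event whose code is in ``event_codes``, aligned to event
    onset, ``floor(span * rate)`` samples long (76 samples for a 0.6 s
    epoch at 128 Hz).  Events too close to the end of the record for a full
    epoch are skipped with a log message.  Epoch labels are the event codes.
    """
    codes = set(event_codes)
    n = int(np.floor(span * rec.rate))
    windows = []
    for idx, code in rec.events:
        if code not in codes:
            continue
        if idx + n > rec.n_samples:
            logger.info("event %r at sample %d too close to record end; "
                        "epoch skipped", code, idx)
            continue
        windows.append(Window(rec.data[:, idx:idx + n].copy(),
                              idx / rec.rate, span, label=code,
                              rate=rec.rate, channel_names=rec.channel_names))
    return TrialSet(windows, protocol=protocol)


def downsample(ts: TrialSet, from_rate: float, to_rate: float) -> TrialSet:
    """Anti-alias filter then decimate every window by an integer factor.

    128 -> 32 Hz turns a 76-sample epoch into 19 samples.
    """
    factor = from_rate / to_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"decimation factor {from_rate}/{to_rate} is not an integer"
        )
    q = int(round(factor))
    out = []
    for w in ts.windows:
        # polyphase FIR with line-extended edges: clean on short epochs
        data = sps.resample_poly(w.data, 1, q, axis=1, padtype="line")
        out.append(replace(w, data=data, rate=to_rate))
    return TrialSet(out, ts.protocol, list(ts.class_labels))
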