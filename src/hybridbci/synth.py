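"""Synthetic EEG with the statistical structure each decoder assumes.

Three families of records are generated over a common 1/f^alpha background:

* motor-imagery trials, where a mu-band (8-13 Hz) rhythm over
  frontocentral channels is attenuated during imagery (event-related
  desynchronization);
* SSVEP trials, where a sinusoid at the stimulus frequency (12 or 15 Hz)
  rides on the occipital channels O1/O2;
* P300 flash streams, where epochs following flashes of the favourite
  object carry a positive deflection peaking ~300 ms after onset.

``snr`` is a linear amplitude ratio: the RMS of the injected component
over the RMS of the unit-variance background on the channels that carry
it.  All generators are deterministic functions of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signals import (DEFAULT_RATE, EMOTIV_CHANNELS, EEGRecording, TrialSet,
                      Window)

__all__ = [
    "SynthConfig", "ERPTemplate", "gen_background", "gen_erd_trials",
    "gen_ssvep_trials", "gen_p300_stream",
]

#: channels carrying the sensorimotor mu rhythm, with relative gains
ERD_CHANNELS = {"FC5": 1.0, "FC6": 1.0, "F3": 0.7, "F4": 0.7}
SSVEP_CHANNELS = ("O1", "O2")
#: parietal-dominant topography of the simulated P300
P300_CHANNELS = {"P7": 1.0, "P8": 1.0, "T7": 0.4, "T8": 0.4, "O1": 0.3,
                 "O2": 0.3}


def _pattern(weights: dict, channel_names) -> np.ndarray:
    """Unit-norm per-channel gain vector from a {name: gain} dict."""
    v = np.array([weights.get(name, 0.0) for name in channel_names])
    return v / np.linalg.norm(v)


@dataclass
class SynthConfig:
    """Knobs shared by all generators."""

    rate: float = DEFAULT_RATE
    n_channels: int = 14
    noise_exponent: float = 1.0   # spectral slope alpha of 1/f^alpha
    snr: float = 1.0              # linear amplitude SNR of injected signals
    seed: int = 0
    channel_names: tuple = EMOTIV_CHANNELS

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


@dataclass
class ERPTemplate:
    """Half-cosine positive bump standing in for the P300 deflection."""

    peak_latency: float = 0.30    # s after stimulus onset
    width: float = 0.20           # s, full width of the bump
    amplitude: float = 1.0        # peak, in background-SD units
    spatial_pattern: np.ndarray = None

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def pattern(self, channel_names) -> np.ndarray:
        if self.spatial_pattern is not None:
            v = np.asarray(self.spatial_pattern, dtype=float)
            return v / np.linalg.norm(v)
        return _pattern(P300_CHANNELS, channel_names)

    def waveform(self, t: np.ndarray, latency_shift: float = 0.0) -> np.ndarray:
        """Bump amplitude at times ``t`` (s) relative to stimulus onset."""
        centre = self.peak_latency + latency_shift
        phase = (t - centre) / (self.width / 2)
        w = np.where(np.abs(phase) <= 1.0,
                     0.5 * (1 + np.cos(np.pi * phase)), 0.0)
        return self.amplitude * w


def _pink(rng: np.random.Generator, n_channels: int, n_samples: int,
          alpha: float) -> np.ndarray:
    """1/f^alpha noise, zero mean and unit variance per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    if alpha == 0:
        out = white
    else:
        spec = np.fft.rfft(white, axis=1)
        f = np.fft.rfftfreq(n_samples)
        shaping = np.ones_like(f)
        shaping[1:] = f[1:] ** (-alpha / 2)
        shaping[0] = 0.0
        out = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    out -= out.mean(axis=1, keepdims=True)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def gen_background(cfg: SynthConfig, duration: float,
                   salt: int = 0) -> EEGRecording:
    """Pure 1/f^alpha background, unit variance per channel."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * cfg.rate))
    data = _pink(cfg.rng(salt), cfg.n_channels, n, cfg.noise_exponent)
    return EEGRecording(data, cfg.rate, cfg.channel_names)


def _mu_rhythm(rng: np.random.Generator, n_samples: int, rate: float,
               band=(8.0, 13.0)) -> np.ndarray:
    """Band-limited Gaussian rhythm with unit RMS (the simulated mu)."""
    white = rng.standard_normal(n_samples + 256)
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfilt(sos, white)[256:]
    return x / x.std()


def gen_erd_trials(cfg: SynthConfig, n_active: int, n_idle: int,
                   attenuation: float = 0.7,
                   duration: float = 2.0) -> TrialSet:
    """Two-class motor-imagery trials.

    Idle trials carry the mu rhythm on the sensorimotor channels at
    amplitude ``cfg.snr`` (RMS, relative to the unit background); imagery
    ("active") trials carry it attenuated by the given fraction --
    ``attenuation=1`` suppresses it entirely, 0 makes the classes
    indistinguishable.
    """
    if not 0 <= attenuation <= 1:
        raise ValueError("attenuation must lie in [0, 1]")
    n = int(round(duration * cfg.rate))
    pattern = _pattern(ERD_CHANNELS, cfg.channel_names)
    # scale so the per-carrying-channel RMS matches cfg.snr
    gain = pattern / np.max(pattern)
    windows = []
    rng = cfg.rng(salt=1)
    for label, count in (("idle", n_idle), ("active", n_active)):
        amp = cfg.snr * (1.0 if label == "idle" else 1.0 - attenuation)
        for _ in range(count):
            bg = _pink(rng, cfg.n_channels, n, cfg.noise_exponent)
            rhythm = _mu_rhythm(rng, n, cfg.rate)
            data = bg + amp * gain[:, None] * rhythm[None, :]
            windows.append(Window(data, 0.0, duration, label=label,
                                  rate=cfg.rate,
                                  channel_names=cfg.channel_names))
    return TrialSet(windows, protocol="ERD")


def gen_ssvep_trials(cfg: SynthConfig, freq: float, n: int,
                     duration: float = 2.0,
                     harmonic_gain: float = 0.0) -> TrialSet:
    """Occipital sinusoid at the stimulus frequency over background.

    Each trial gets a random phase; ``harmonic_gain`` optionally adds a
    weak second harmonic.  Labelled with the frequency.
    """
    if freq >= cfg.rate / 2:
        raise ValueError("stimulus frequency must be below Nyquist")
    n_samp = int(round(duration * cfg.rate))
    t = np.arange(n_samp) / cfg.rate
    occ = [cfg.channel_names.index(ch) for ch in SSVEP_CHANNELS
           if ch in cfg.channel_names]
    rng = cfg.rng(salt=2)
    amp = cfg.snr * np.sqrt(2.0)  # sine of RMS=snr has peak snr*sqrt(2)
    windows = []
    for _ in range(n):
        bg = _pink(rng, cfg.n_channels, n_samp, cfg.noise_exponent)
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * freq * t + phase)
        if harmonic_gain:
            wave = wave + harmonic_gain * np.sin(
                2 * np.pi * 2 * freq * t + 2 * phase)
        for ch in occ:
            bg[ch] += amp * wave
        windows.append(Window(bg, 0.0, duration, label=freq, rate=cfg.rate,
                              channel_names=cfg.channel_names))
    return TrialSet(windows, protocol="SSVEP")


def gen_p300_stream(cfg: SynthConfig, n_objects: int = 2,
                    n_flashes_per_object: int = 5,
                    favorite_index: int = 0,
                    template: ERPTemplate = None,
                    latency_jitter_sd: float = 0.0,
                    isi: float = 0.25,
                    lead_in: float = 1.0,
                    lead_out: float = 1.0,
                    salt: int = 3):
    """Continuous flash stream for the P300 protocol.

    Flash onsets are spaced ``isi`` seconds apart in a seed-randomized
    order with exactly ``n_flashes_per_object`` flashes per object; each
    event in the returned recording is ``(sample_index, object_id)``.
    Epochs after flashes of object ``favorite_index`` carry the ERP
    template (amplitude scaled by ``cfg.snr``) with Gaussian latency
    jitter.  ``favorite_index=None`` plants no ERP at all.

    Returns ``(recording, schedule)`` where schedule is a list of
    ``(onset_time, object_id)``.
    """
    if n_objects < 2:
        raise ValueError("need at least two objects")
    template = template or ERPTemplate()
    rng = cfg.rng(salt=salt)
    order = np.repeat(np.arange(n_objects), n_flashes_per_object)
    rng.shuffle(order)
    n_flashes = len(order)
    duration = lead_in + (n_flashes - 1) * isi + lead_out + 1.0
    n_samp = int(round(duration * cfg.rate))
    data = _pink(rng, cfg.n_channels, n_samp, cfg.noise_exponent)

    pattern = template.pattern(cfg.channel_names)
    gain = pattern / np.max(pattern) if np.max(pattern) > 0 else pattern
    t_axis = np.arange(n_samp) / cfg.rate
    events, schedule = [], []
    for k, obj in enumerate(order):
        onset = lead_in + k * isi
        idx = int(round(onset * cfg.rate))
        events.append((idx, int(obj)))
        schedule.append((onset, int(obj)))
        if favorite_index is not None and obj == favorite_index:
            shift = rng.normal(0.0, latency_jitter_sd) if latency_jitter_sd else 0.0
            bump = template.waveform(t_axis - onset, latency_shift=shift)
            data += cfg.snr * gain[:, None] * bump[None, :]
    rec = EEGRecording(data, cfg.rate, cfg.channel_names, events)
    return rec, schedule
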