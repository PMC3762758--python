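"""SSVEP decoder: canonical correlation against sinusoidal references.

A window of occipital EEG (channels O1, O2, band-passed 4-50 Hz against
artifacts) is scored against a reference block of sin/cos pairs at each
stimulus frequency (12 and 15 Hz, one harmonic by default).  The first
canonical correlation rho is the decoder's evidence that the window is
phase-locked to that frequency; the pair (rho_12, rho_15) is also the
coordinate system in which the hybrid arbiter separates SSVEP activity
from motor imagery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .signals import DEFAULT_RATE, Window, bandpass_window

__all__ = ["CCAReference", "SSVEPCorrelations", "cca_corr",
           "ssvep_correlation_pair", "SSVEP_BAND", "SSVEP_CHANNELS",
           "STIMULUS_FREQS"]

SSVEP_BAND = (4.0, 50.0)
SSVEP_CHANNELS = ("O1", "O2")
STIMULUS_FREQS = (12.0, 15.0)

_RIDGE = 1e-9  # relative ridge on the autocovariance blocks


@dataclass
class CCAReference:
    """Sin/cos reference block at one stimulus frequency.

    ``n_harmonics`` sin/cos pairs (2*n_harmonics rows), each row
    mean-centred over the window.
    """

    freq: float
    n_harmonics: int = 1
    rate: float = DEFAULT_RATE
    duration: float = 2.0
    start_time: float = 0.0   # phase offset; rho is invariant to it

    def matrix(self, n_samples: int = None) -> np.ndarray:
        n = n_samples or int(round(self.duration * self.rate))
        t = np.arange(n) / self.rate + self.start_time
        rows = []
        for h in range(1, self.n_harmonics + 1):
            rows.append(np.sin(2 * np.pi * h * self.freq * t))
            rows.append(np.cos(2 * np.pi * h * self.freq * t))
        Y = np.asarray(rows)
        return Y - Y.mean(axis=1, keepdims=True)


@dataclass
class SSVEPCorrelations:
    """First canonical correlations against the two stimulus frequencies."""

    rho_f1: float  # at STIMULUS_FREQS[0] (12 Hz)
    rho_f2: float  # at STIMULUS_FREQS[1] (15 Hz)

    def as_array(self) -> np.ndarray:
        return np.array([self.rho_f1, self.rho_f2])


def cca_corr(w: Window, ref: CCAReference) -> float:
    """First canonical correlation between a window and a reference block.

    Solved through the two-block covariance eigenvalue formulation
    ``Cxx^-1 Cxy Cyy^-1 Cyx`` with a small relative ridge on the
    autocovariances for numerical safety.  Deterministic; raises on a
    constant (zero-variance) channel.
    """
    X = np.asarray(w.data, dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    if np.any(X.std(axis=1) < 1e-15):
        raise ValueError("constant channel: canonical correlation undefined")
    Y = ref.matrix(X.shape[1])
    n = X.shape[1]
    Cxx = X @ X.T / n
    Cyy = Y @ Y.T / n
    Cxy = X @ Y.T / n
    Cxx = Cxx + _RIDGE * np.trace(Cxx) / len(Cxx) * np.eye(len(Cxx))
    Cyy = Cyy + _RIDGE * np.trace(Cyy) / len(Cyy) * np.eye(len(Cyy))
    M = linalg.solve(Cxx, Cxy, assume_a="pos") @ linalg.solve(
        Cyy, Cxy.T, assume_a="pos")
    rho2 = np.max(linalg.eigvals(M).real)
    return float(np.clip(np.sqrt(max(rho2, 0.0)), 0.0, 1.0))


def ssvep_correlation_pair(w: Window, freqs=STIMULUS_FREQS,
                           n_harmonics: int = 1,
                           prefilter: bool = True) -> SSVEPCorrelations:
    """(rho_12, rho_15) for one window, identical preprocessing for both.

    The window is restricted to O1/O2 (if those channels are present) and
    band-pass filtered 4-50 Hz before correlation.
    """
    if set(SSVEP_CHANNELS) <= set(w.channel_names):
        idx = [w.channel_names.index(c) for c in SSVEP_CHANNELS]
        w = Window(w.data[idx], w.start_time, w.duration, w.label, w.rate,
                   SSVEP_CHANNELS)
    if prefilter:
        w = bandpass_window(w, *SSVEP_BAND, order=5)
    rhos = [cca_corr(w, CCAReference(f, n_harmonics=n_harmonics,
                                     rate=w.rate, duration=w.duration))
            for f in freqs]
    return SSVEPCorrelations(rho_f1=rhos[0], rho_f2=rhos[1])
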