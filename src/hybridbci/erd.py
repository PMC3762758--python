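"""Motor-imagery (ERD) decoder: CSP spatial filters + linear SVM.

Common Spatial Patterns finds spatial filters w maximizing the variance
ratio ``w' C_active w / w' C_idle w`` between the two classes, solved as
the generalized eigenproblem ``C_active w = lambda (C_active + C_idle) w``.
Features are the normalized log-variances of the filtered signals; a
linear-kernel SVM separates imagery from idle.  Signals are expected
band-passed to 8-30 Hz (mu + beta), which also makes the zero-mean
assumption of the covariance estimates hold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.svm import SVC

from .signals import TrialSet, Window

logger = logging.getLogger(__name__)

__all__ = ["CSPModel", "ERDClassifier", "fit_csp", "csp_features",
           "train_erd", "detect_erd", "ERD_BAND"]

#: analysis band for motor imagery (mu + beta), Hz
ERD_BAND = (8.0, 30.0)


@dataclass
class CSPModel:
    """Fitted CSP filter bank.

    ``filters`` has 2m rows: the m most active-dominant filters first
    (descending eigenvalue), then the m most idle-dominant (ascending).
    ``eigenvalues`` are the whitened variance ratios in the same order;
    ``patterns`` are the corresponding forward activation patterns
    (columns of the inverse of the full filter matrix, i.e. C_total W).
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    patterns: np.ndarray
    m: int
    class_covariances: tuple = None
    trained_band: tuple = ERD_BAND
    channel_names: tuple = ()
    discriminative: bool = True

    def to_dict(self) -> dict:
        return {
            "filters": self.filters.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "patterns": self.patterns.tolist(),
            "m": self.m,
            "class_covariances": [c.tolist() for c in self.class_covariances],
            "trained_band": list(self.trained_band),
            "channel_names": list(self.channel_names),
            "discriminative": self.discriminative,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CSPModel":
        return cls(np.array(d["filters"]), np.array(d["eigenvalues"]),
                   np.array(d["patterns"]), d["m"],
                   tuple(np.array(c) for c in d["class_covariances"]),
                   tuple(d["trained_band"]), tuple(d["channel_names"]),
                   d["discriminative"])


@dataclass
class ERDClassifier:
    """Linear max-margin classifier over the 2m CSP features."""

    svc: SVC
    classes: tuple = ("active", "idle")

    def to_dict(self) -> dict:
        return {
            "weights": self.svc.coef_.ravel().tolist(),
            "bias": float(self.svc.intercept_[0]),
            "classes": list(self.svc.classes_),
        }


def _mean_class_cov(ts_X: np.ndarray) -> np.ndarray:
    """Average of per-trial trace-normalized covariances."""
    covs = []
    for X in ts_X:
        c = X @ X.T
        tr = np.trace(c)
        if tr <= 0:
            raise ValueError("zero-variance trial in covariance estimate")
        covs.append(c / tr)
    return np.mean(covs, axis=0)


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude component of each filter positive."""
    W = W.copy()
    for j in range(W.shape[1]):
        k = np.argmax(np.abs(W[:, j]))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]
    return W


def fit_csp(active: TrialSet, idle: TrialSet, m: int = 2) -> CSPModel:
    """Fit CSP filters from band-passed two-class trials.

    Solves ``C_a w = lambda (C_a + C_i) w`` and keeps the m largest- and m
    smallest-eigenvalue eigenvectors.  Rank-deficient composite
    covariances get a small trace-scaled shrinkage (gamma = 1e-6) with a
    warning.  If the two class covariances are indistinguishable (all
    eigenvalues ~0.5) the model is flagged non-discriminative.
    """
    if len(active) < 2 or len(idle) < 2:
        raise ValueError("need at least 2 trials per class")
    n_ch = active.windows[0].data.shape[0]
    if 2 * m > n_ch:
        raise ValueError(f"2m={2*m} filters exceed {n_ch} channels")
    C_a = _mean_class_cov(active.X)
    C_i = _mean_class_cov(idle.X)
    C_t = C_a + C_i
    if np.linalg.matrix_rank(C_t, tol=1e-10 * np.trace(C_t)) < n_ch:
        gamma = 1e-6 * np.trace(C_t) / n_ch
        C_t = C_t + gamma * np.eye(n_ch)
        warnings.warn("rank-deficient composite covariance; "
                      f"shrinkage {gamma:.3g} applied")
    vals, vecs = linalg.eigh(C_a, C_t)  # ascending
    order = np.concatenate([np.arange(n_ch - 1, n_ch - 1 - m, -1),
                            np.arange(m)])
    W = _fix_signs(vecs[:, order])
    eigenvalues = vals[order]
    discriminative = bool(np.any(np.abs(eigenvalues - 0.5) > 0.05))
    if not discriminative:
        logger.warning("class covariances nearly identical; CSP filters "
                       "carry no discriminative power")
    patterns = C_t @ W
    patterns /= np.linalg.norm(patterns, axis=0, keepdims=True)
    return CSPModel(filters=W.T, eigenvalues=eigenvalues, patterns=patterns,
                    m=m, class_covariances=(C_a, C_i),
                    channel_names=tuple(active.windows[0].channel_names),
                    discriminative=discriminative)


def csp_features(model: CSPModel, w: Window) -> np.ndarray:
    """Normalized log-variance features ``f_i = log(v_i / sum_j v_j)``.

    Scale-invariant by construction; ``sum exp(f_i) = 1``.
    """
    proj = model.filters @ w.data
    v = proj.var(axis=1)
    total = v.sum()
    if total <= 0 or np.any(v <= 0):
        raise ValueError("zero-variance window: CSP features undefined")
    return np.log(v / total)


def train_erd(features: np.ndarray, labels, C: float = 1.0) -> ERDClassifier:
    """Linear-kernel SVM over CSP features."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    svc = SVC(kernel="linear", C=C)
    svc.fit(np.asarray(features), labels)
    return ERDClassifier(svc=svc, classes=tuple(svc.classes_))


def detect_erd(model: CSPModel, clf: ERDClassifier, w: Window):
    """Classify one window; returns ``(label, decision_value)``.

    The raw margin is exposed so the arbitration layer can log confidence.
    """
    f = csp_features(model, w).reshape(1, -1)
    label = clf.svc.predict(f)[0]
    margin = float(clf.svc.decision_function(f)[0])
    return label, margin
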