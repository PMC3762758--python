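"""Protocol arbitration and command confirmation.

Every 250 ms the latest 2 s window is mapped to a point in
(rho_12, rho_15) space -- the canonical correlations against the two
SSVEP stimulus frequencies.  A quadratic max-margin boundary separates
the region of SSVEP activity (S) from the region of motor-imagery/idle
activity (E); inside S a linear boundary separates the 12 Hz (left) from
the 15 Hz (right) response.  Windows landing in E are passed to the ERD
detector, whose "active" decision acts as a state-transition switch.

Raw per-window classifications are noisy, so commands are confirmed by a
dynamic fading feedback rule: a candidate command accumulates one
selection level per consecutive agreeing classification and loses one per
disagreement; only on reaching level four is the command emitted.  At 250
ms per classification the fastest possible confirmation is therefore
1.0 s after the first classification.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from . import erd as erd_mod
from .signals import Window, bandpass_window
from .ssvep import ssvep_correlation_pair

__all__ = ["Command", "SelectorModel", "FadingState", "fit_selector",
           "classify_window", "fading_step", "CONFIRM_LEVEL",
           "CLASSIFICATION_PERIOD"]

CONFIRM_LEVEL = 4
CLASSIFICATION_PERIOD = 0.25  # s between classifications


class Command(enum.Enum):
    """Closed command vocabulary of the navigation/exploration interface."""

    HEAD_LEFT = "HEAD_LEFT"
    HEAD_RIGHT = "HEAD_RIGHT"
    ERD_SWITCH = "ERD_SWITCH"
    NONE = "NONE"


@dataclass
class SelectorModel:
    """Two-stage classifier over (rho_12, rho_15).

    ``quad`` (degree-2 polynomial kernel SVM) separates E from S;
    ``lin`` (linear SVM) separates S_l from S_r inside S.
    """

    quad: SVC
    lin: SVC

    def region(self, rho_pair) -> str:
        """Map one (rho_12, rho_15) point to 'E', 'S_l' or 'S_r'."""
        p = np.asarray(rho_pair, dtype=float).reshape(1, 2)
        if self.quad.predict(p)[0] == "E":
            return "E"
        return self.lin.predict(p)[0]


@dataclass(frozen=True)
class FadingState:
    """Immutable fading-rule state: current candidate and its level."""

    candidate: Command = None
    level: int = 0

    def __post_init__(self):
        if not 0 <= self.level <= CONFIRM_LEVEL:
            raise ValueError("level outside [0, 4]")
        if self.candidate is None and self.level != 0:
            raise ValueError("empty state must have level 0")


def fit_selector(erd_pairs, ssvep_left_pairs, ssvep_right_pairs,
                 C: float = 10.0) -> SelectorModel:
    """Fit the arbitration boundaries from training correlation clouds.

    ``erd_pairs`` holds (rho_12, rho_15) points from motor-imagery *and*
    idle windows (both outcomes of ERD operation live in region E);
    the two SSVEP clouds come from windows recorded under 12 Hz and 15 Hz
    flicker respectively.
    """
    E = np.asarray(erd_pairs, dtype=float)
    L = np.asarray(ssvep_left_pairs, dtype=float)
    R = np.asarray(ssvep_right_pairs, dtype=float)
    for name, arr in (("erd", E), ("ssvep_left", L), ("ssvep_right", R)):
        if len(arr) < 10:
            raise ValueError(f"need >= 10 training pairs per group "
                             f"({name} has {len(arr)})")
    S = np.vstack([L, R])
    if np.allclose(E.mean(axis=0), S.mean(axis=0), atol=1e-9) or \
            np.allclose(L.mean(axis=0), R.mean(axis=0), atol=1e-9):
        raise ValueError("degenerate training clouds: group means coincide")
    quad = SVC(kernel="poly", degree=2, C=C, coef0=1.0, gamma="scale")
    quad.fit(np.vstack([E, S]), ["E"] * len(E) + ["S"] * len(S))
    lin = SVC(kernel="linear", C=C)
    lin.fit(S, ["S_l"] * len(L) + ["S_r"] * len(R))
    return SelectorModel(quad=quad, lin=lin)


def classify_window(selector: SelectorModel, erd_model, erd_clf,
                    w: Window, freq_to_direction=None) -> Command:
    """One 250 ms decision: arbitrate the protocol, then decode.

    Region S_l/S_r maps straight to a head-turn command (12 Hz = left by
    default); region E defers to the ERD detector, whose "active" outcome
    is the state-transition switch and whose "idle" outcome is NONE.
    """
    mapping = freq_to_direction or {"S_l": Command.HEAD_LEFT,
                                    "S_r": Command.HEAD_RIGHT}
    rho = ssvep_correlation_pair(w)
    region = selector.region(rho.as_array())
    if region in mapping:
        return mapping[region]
    wf = bandpass_window(w, *erd_mod.ERD_BAND, order=5)
    label, _margin = erd_mod.detect_erd(erd_model, erd_clf, wf)
    return Command.ERD_SWITCH if label == "active" else Command.NONE


def fading_step(state: FadingState, candidate: Command):
    """One step of the dynamic fading feedback rule.

    * empty state: a non-NONE classification is adopted as the candidate
      at level 0 (NONE leaves the state empty);
    * same candidate again: level + 1; on reaching level 4 the command is
      confirmed and the state resets to empty;
    * different classification: level - 1 if above 0, otherwise the
      candidate is dropped and the *next* classification is adopted anew.

    NONE is treated as a disagreement but is never adopted and never
    confirmed, so idle activity can only delay or cancel a candidate,
    never actuate the robot.  Returns ``(new_state, confirmed)`` where
    ``confirmed`` is the emitted Command or None.
    """
    if state.candidate is None:
        if candidate is None or candidate == Command.NONE:
            return FadingState(), None
        return FadingState(candidate=candidate, level=0), None
    if candidate == state.candidate:
        level = state.level + 1
        if level >= CONFIRM_LEVEL:
            return FadingState(), state.candidate
        return FadingState(candidate=state.candidate, level=level), None
    if state.level > 0:
        return FadingState(candidate=state.candidate,
                           level=state.level - 1), None
    return FadingState(), None  # drop; next classification adopts anew


def run_fading(commands, state: FadingState = None):
    """Feed a command sequence through the rule; returns
    ``(final_state, [(index, confirmed_command), ...])``."""
    state = state or FadingState()
    confirmed = []
    for i, cmd in enumerate(commands):
        state, out = fading_step(state, cmd)
        if out is not None:
            confirmed.append((i, out))
    return state, confirmed
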