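"""Closed-loop simulation: synthetic brain -> decoders -> arbiter -> robot.

The "oracle brain" is a scripted waypoint-following controller that, every
250 ms, picks which mental condition to produce next (look at the 12 Hz
stimulus, look at the 15 Hz stimulus, perform motor imagery, or rest) and
synthesizes a fresh 2 s EEG window of that condition.  The window runs
through the full decoding stack -- correlation-pair arbitration, ERD
detection, the fading feedback rule -- and only *confirmed* commands reach
the simulated surrogate.  This exercises every decision path of the
navigation interface without any recorded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import erd as erd_mod
from .evaluation import accumulate_metrics
from .hybrid import (CLASSIFICATION_PERIOD, FadingState, classify_window,
                     fading_step, fit_selector)
from .signals import bandpass_window
from .ssvep import STIMULUS_FREQS, ssvep_correlation_pair
from .surrogate import Arena, Mode, RobotState, apply_command, tick
from .synth import SynthConfig, gen_erd_trials, gen_ssvep_trials

__all__ = ["TrainedDecoders", "train_decoders", "WindowSource",
           "WaypointController", "run_closed_loop", "ClosedLoopResult"]


@dataclass
class TrainedDecoders:
    csp: object
    erd_clf: object
    selector: object


def _pairs(windows):
    return [ssvep_correlation_pair(w).as_array() for w in windows]


def train_decoders(seed: int = 0, snr: float = 3.0,
                   attenuation: float = 0.9,
                   n_trials: int = 20) -> TrainedDecoders:
    """Train the ERD decoder and the protocol selector on synthetic data.

    Emulates the calibration session: ``n_trials`` imagery + idle windows
    for CSP/SVM, ``n_trials`` windows per SSVEP frequency, and the
    selector fit on the pooled (rho_12, rho_15) clouds (the ERD cloud
    contains both imagery and idle windows).
    """
    cfg = SynthConfig(seed=seed, snr=snr)
    erd_ts = gen_erd_trials(cfg, n_trials, n_trials, attenuation=attenuation)
    filtered = [bandpass_window(w, *erd_mod.ERD_BAND) for w in erd_ts.windows]
    active = [w for w in filtered if w.label == "active"]
    idle = [w for w in filtered if w.label == "idle"]
    from .signals import TrialSet
    csp = erd_mod.fit_csp(TrialSet(active, "ERD"), TrialSet(idle, "ERD"))
    feats = np.stack([erd_mod.csp_features(csp, w) for w in filtered])
    labels = [w.label for w in filtered]
    clf = erd_mod.train_erd(feats, labels)

    left = gen_ssvep_trials(SynthConfig(seed=seed + 1, snr=snr),
                            STIMULUS_FREQS[0], n_trials)
    right = gen_ssvep_trials(SynthConfig(seed=seed + 2, snr=snr),
                             STIMULUS_FREQS[1], n_trials)
    selector = fit_selector(_pairs(erd_ts.windows), _pairs(left.windows),
                            _pairs(right.windows))
    return TrainedDecoders(csp=csp, erd_clf=clf, selector=selector)


class WindowSource:
    """Synthesizes one 2 s window per intent, with a fresh sub-seed each call."""

    INTENTS = ("left", "right", "erd", "idle")

    def __init__(self, seed: int, snr: float = 3.0, attenuation: float = 0.9):
        self.seed = seed
        self.snr = snr
        self.attenuation = attenuation
        self.counter = 0

    def window(self, intent: str):
        self.counter += 1
        cfg = SynthConfig(seed=self.seed, snr=self.snr)
        cfg.seed = int(np.random.SeedSequence(
            [self.seed, self.counter]).generate_state(1)[0] % (2 ** 31))
        if intent == "left":
            return gen_ssvep_trials(cfg, STIMULUS_FREQS[0], 1).windows[0]
        if intent == "right":
            return gen_ssvep_trials(cfg, STIMULUS_FREQS[1], 1).windows[0]
        if intent == "erd":
            return gen_erd_trials(cfg, 1, 0,
                                  attenuation=self.attenuation).windows[0]
        if intent == "idle":
            return gen_erd_trials(cfg, 0, 1,
                                  attenuation=self.attenuation).windows[0]
        raise ValueError(f"unknown intent {intent!r}")


def _wrap_deg(a):
    return (a + 180.0) % 360.0 - 180.0


class WaypointController:
    """Scripted pilot: aims the head at the next waypoint, aligns the
    body, walks, and stops near the waypoint.

    The decision hysteresis accounts for the confirmation latency of the
    fading rule (a stop command takes >= 1.25 s to confirm, during which a
    walking robot covers ~4 cm).
    """

    def __init__(self, waypoints, stop_trigger: float = 12.0,
                 reach_tol: float = 18.0, head_tol: float = 1.6):
        self.waypoints = list(waypoints)
        self.index = 0
        self.stop_trigger = stop_trigger
        self.reach_tol = reach_tol
        self.head_tol = head_tol

    @property
    def done(self) -> bool:
        return self.index >= len(self.waypoints)

    def intent(self, s: RobotState) -> str:
        if self.done:
            return "done"
        if s.mode is Mode.ALIGNING:
            return "idle"
        wx, wy = self.waypoints[self.index]
        dx, dy = wx - s.position[0], wy - s.position[1]
        dist = math.hypot(dx, dy)
        if s.mode is Mode.WALKING:
            if dist < self.stop_trigger:
                return "erd"          # brake for the waypoint
            return "idle"
        if dist < self.reach_tol:
            self.index += 1
            return "done" if self.done else self.intent(s)
        desired = math.degrees(math.atan2(dy, dx))
        head_err = _wrap_deg(desired - s.head_heading)
        if abs(head_err) > self.head_tol:
            return "left" if head_err > 0 else "right"
        return "erd"                  # align body or start walking


@dataclass
class ClosedLoopResult:
    log: list
    reached_goal: bool
    collisions: int
    walking_time: float
    confirmed_commands: list

    @property
    def metrics(self):
        return accumulate_metrics(self.log)


def run_closed_loop(decoders: TrainedDecoders, arena: Arena, waypoints,
                    seed: int = 0, start: RobotState = None,
                    snr: float = 3.0, attenuation: float = 0.9,
                    max_steps: int = 2000) -> ClosedLoopResult:
    """Drive the surrogate through the arena with the scripted brain.

    One classification every 250 ms on a freshly synthesized window; the
    robot is advanced by the same period per step.  Returns the full
    trajectory log (audit format of :mod:`hybridbci.evaluation`) plus the
    live-accumulated walking time for consistency checks against the
    replayed metrics.
    """
    dt = CLASSIFICATION_PERIOD
    source = WindowSource(seed=seed, snr=snr, attenuation=attenuation)
    controller = WaypointController(waypoints)
    state = start or RobotState(position=(40.0, 40.0), body_heading=90.0)
    fstate = FadingState()
    log, confirmed_all, pending = [], [], []
    walking_time = 0.0
    reached = False
    for k in range(max_steps):
        t = k * dt
        intent = controller.intent(state)
        if intent == "done":
            reached = True
            log.append(_row(t, state, pending))
            break
        w = source.window(intent)
        cmd = classify_window(decoders.selector, decoders.csp,
                              decoders.erd_clf, w)
        fstate, confirmed = fading_step(fstate, cmd)
        events = list(pending)
        pending = []
        if confirmed is not None:
            state = apply_command(state, confirmed)
            events.append(f"confirmed:{confirmed.value}")
            confirmed_all.append((t, confirmed))
        log.append(_row(t, state, events))
        if state.mode is Mode.WALKING:
            walking_time += dt
        state, collision = tick(state, dt, arena)
        if collision:
            pending.append("collision")
    else:
        log.append(_row(max_steps * dt, state, pending))
    n_coll = sum(row["event"].split(";").count("collision")
                 for row in log if row["event"])
    return ClosedLoopResult(log=log, reached_goal=reached,
                            collisions=n_coll, walking_time=walking_time,
                            confirmed_commands=confirmed_all)


def _row(t, s: RobotState, events) -> dict:
    return {"t": t, "x": s.position[0], "y": s.position[1],
            "body_heading": s.body_heading, "head_offset": s.head_offset,
            "mode": s.mode.value, "event": ";".join(events)}
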