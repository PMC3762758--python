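"""Evaluation utilities: cross-validation, Wolpaw ITR, navigation metrics.

The information transfer rate follows Wolpaw's definition: with N classes
and accuracy P, each decision carries

    B = log2 N + P log2 P + (1 - P) log2((1 - P) / (N - 1))   bits

(0 log 0 = 0), clipped at zero below chance, and the rate is B times the
number of decisions per minute.  One decision per 2 s window gives the 30
decisions/min used throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .signals import TrialSet

__all__ = ["CVResult", "NavMetrics", "wolpaw_itr", "crossval",
           "accumulate_metrics", "ratio_report", "write_trajectory",
           "read_trajectory", "DECISIONS_PER_MIN"]

#: one decision per 2 s analysis window
DECISIONS_PER_MIN = 30.0


@dataclass
class CVResult:
    """Per-fold accuracies with mean and sample SD."""

    fold_accuracies: list

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


@dataclass
class NavMetrics:
    """Task-level navigation/exploration metrics."""

    total_time: float = 0.0        # s
    distance_travelled: float = 0.0  # cm
    forward_steps: float = 0.0     # nominal steps (1 s of walking each)
    turning_steps: float = 0.0     # nominal steps (1 s of body turn each)
    explored_angle: float = 0.0    # rad, summed head-turn magnitudes
    transitions: float = 0.0       # navigation <-> exploration switches
    collisions: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")


def wolpaw_itr(P: float, N: int, rate: float = DECISIONS_PER_MIN) -> float:
    """Wolpaw information transfer rate in bits/min.

    Monotone increasing in P above chance (1/N) and clipped to 0 below it.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError("accuracy P must lie in [0, 1]")
    if N < 2:
        raise ValueError("need at least two classes")
    if P < 1.0 / N:      # below chance: clip (the N=2 form is symmetric)
        return 0.0
    bits = math.log2(N)
    if P > 0:
        bits += P * math.log2(P)
    if P < 1:
        bits += (1 - P) * math.log2((1 - P) / (N - 1))
    return max(bits, 0.0) * rate


def crossval(trials: TrialSet, fit_and_score, k: int = 10,
             seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation at the trial level.

    ``fit_and_score(train: TrialSet, test: TrialSet) -> accuracy`` does
    the whole fitting pipeline, so no test trial ever leaks into
    training.  Deterministic under ``seed``.  If a shuffle leaves a
    training fold single-class (possible only with tiny minority classes)
    the split is redrawn with a warning.
    """
    y = trials.y
    if len(trials) < k:
        raise ValueError(f"{len(trials)} trials < {k} folds")
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=seed + attempt)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn warns on tiny classes
            splits = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) > 1 for tr, _ in splits):
            if attempt:
                warnings.warn("single-class training fold; refolded")
            break
    accs = [float(fit_and_score(trials.subset(tr), trials.subset(te)))
            for tr, te in splits]
    return CVResult(fold_accuracies=accs)


# ------------------------------------------------------ trajectory logs

_LOG_COLUMNS = ("t", "x", "y", "body_heading", "head_offset", "mode", "event")


def write_trajectory(log, path) -> None:
    """Write a trajectory log (list of dicts) as tab-separated text."""
    with open(path, "w") as fh:
        fh.write("\t".join(_LOG_COLUMNS) + "\n")
        for row in log:
            fh.write("\t".join(str(row.get(c, "")) for c in _LOG_COLUMNS)
                     + "\n")


def read_trajectory(path) -> list:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _LOG_COLUMNS:
            raise ValueError(f"{path}: unexpected trajectory header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_LOG_COLUMNS):
                raise ValueError(f"{path}: line {lineno}: "
                                 f"expected {len(_LOG_COLUMNS)} fields")
            row = dict(zip(_LOG_COLUMNS, parts))
            for key in ("t", "x", "y", "body_heading", "head_offset"):
                row[key] = float(row[key])
            rows.append(row)
    return rows


_EXPLORE_EVENTS = {"confirmed:HEAD_LEFT", "confirmed:HEAD_RIGHT"}
_NAV_EVENTS = {"confirmed:ERD_SWITCH"}


def accumulate_metrics(log, step_duration: float = 1.0) -> NavMetrics:
    """Reduce a trajectory log to :class:`NavMetrics`.

    * distance: summed displacement between consecutive rows;
    * forward/turning steps: time spent WALKING / ALIGNING divided by the
      nominal 1 s step duration;
    * explored angle: 3 degrees per confirmed head-turn event, in radians;
    * transitions: boundaries between runs of exploration (head-turn)
      and navigation (ERD-switch) confirmations;
    * collisions: counted from collision events.
    """
    if not log:
        return NavMetrics()
    dist = 0.0
    walk_time = 0.0
    turn_time = 0.0
    head_turns = 0
    collisions = 0
    cmd_kinds = []
    prev = None
    for row in log:
        if prev is not None:
            dist += math.hypot(row["x"] - prev["x"], row["y"] - prev["y"])
            dt = row["t"] - prev["t"]
            if prev["mode"] == "WALKING":
                walk_time += dt
            elif prev["mode"] == "ALIGNING":
                turn_time += dt
        event = row.get("event", "")
        for ev in event.split(";") if event else []:
            if ev in _EXPLORE_EVENTS:
                head_turns += 1
                cmd_kinds.append("explore")
            elif ev in _NAV_EVENTS:
                cmd_kinds.append("nav")
            elif ev == "collision":
                collisions += 1
        prev = row
    transitions = sum(1 for a, b in zip(cmd_kinds, cmd_kinds[1:]) if a != b)
    return NavMetrics(
        total_time=log[-1]["t"] - log[0]["t"],
        distance_travelled=dist,
        forward_steps=walk_time / step_duration,
        turning_steps=turn_time / step_duration,
        explored_angle=head_turns * math.radians(3.0),
        transitions=transitions,
        collisions=collisions,
    )


def ratio_report(bci, manual) -> dict:
    """Element-wise BCI/manual metric ratios.

    Accepts a single :class:`NavMetrics` per arm or a list per arm (one
    entry per subject), in which case per-subject ratios are averaged.
    A zero manual denominator yields ``nan`` for that metric.
    """
    if isinstance(bci, NavMetrics):
        bci, manual = [bci], [manual]
    if len(bci) != len(manual):
        raise ValueError("BCI and manual lists must have equal length")
    names = [f.name for f in fields(NavMetrics)]
    per_subject = []
    for b, m in zip(bci, manual):
        ratios = {}
        for name in names:
            denom = getattr(m, name)
            num = getattr(b, name)
            ratios[name] = num / denom if denom else math.nan
        per_subject.append(ratios)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # nan means stay nan
        return {name: float(np.mean([r[name] for r in per_subject]))
                for name in names}
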