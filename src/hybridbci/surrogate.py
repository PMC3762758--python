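"""Simulated humanoid surrogate: kinematics, state machine, toy vision.

The surrogate walks at 3.3 cm/s and turns at 0.13 rad/s inside a
150 x 300 cm walled arena.  Head and body are controlled separately:
confirmed head-turn commands rotate the head 3 degrees per decision, and
the ERD switch either toggles walking (head and body aligned within 9
degrees) or triggers an alignment turn of the body toward the head
(misalignment above 9 degrees), during which all commands are ignored.

A toy camera renders coloured object blobs on a white background; a
colour filter finds their bounding boxes, and when the centre of gravity
of the boxes sits in the central fifth of the view the robot freezes and
runs the timed P300 recognition sequence.

Angle convention: degrees, counter-clockwise positive seen from above;
positive head offset = leftward.  Body heading 0 points along +x.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = ["Mode", "RobotState", "Arena", "ViewFrame", "BoundingBox",
           "apply_command", "tick", "render_view", "detect_objects",
           "virtual_center", "in_central_zone", "recognition_sequence",
           "RecognitionPlan", "default_arena",
           "WALK_SPEED", "TURN_SPEED", "HEAD_STEP_DEG", "ALIGN_THRESHOLD_DEG"]

WALK_SPEED = 3.3            # cm/s
TURN_SPEED = 0.13           # rad/s
HEAD_STEP_DEG = 3.0         # per confirmed head-turn command
ALIGN_THRESHOLD_DEG = 9.0   # misalignment beyond which ERD aligns the body
HEAD_LIMIT_DEG = 90.0


class Mode(enum.Enum):
    NAV_IDLE = "NAV_IDLE"
    WALKING = "WALKING"
    ALIGNING = "ALIGNING"
    RECOGNITION = "RECOGNITION"


@dataclass(frozen=True)
class RobotState:
    position: tuple = (0.0, 0.0)     # (x, y) cm
    body_heading: float = 90.0       # degrees CCW from +x
    head_offset: float = 0.0         # degrees relative to body, + = left
    mode: Mode = Mode.NAV_IDLE
    walk_speed: float = WALK_SPEED
    turn_speed: float = TURN_SPEED

    def __post_init__(self):
        if abs(self.head_offset) > HEAD_LIMIT_DEG + 1e-9:
            raise ValueError("head offset beyond limit")

    @property
    def head_heading(self) -> float:
        return self.body_heading + self.head_offset


@dataclass
class Arena:
    """Rectangular maze: wall segments plus coloured objects."""

    width: float = 150.0
    height: float = 300.0
    walls: list = field(default_factory=list)   # [((x1,y1),(x2,y2)), ...]
    objects: list = field(default_factory=list)  # [((x,y), color_id), ...]

    def __post_init__(self):
        if not self.walls:
            w, h = self.width, self.height
            self.walls = [((0, 0), (w, 0)), ((w, 0), (w, h)),
                          ((w, h), (0, h)), ((0, h), (0, 0))]


def default_arena() -> Arena:
    """150 x 300 cm arena with two fruit objects on the far wall."""
    arena = Arena()
    arena.objects = [((60.0, 295.0), 1), ((90.0, 295.0), 2)]
    return arena


@dataclass
class ViewFrame:
    """Synthetic camera frame: integer colour ids, 0 = white background.

    Pixel (0, 0) is the top-left corner.
    """

    pixels: np.ndarray

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class BoundingBox:
    """Normalized box: center in [0,1]^2, width/height fractions."""

    center: tuple
    width: float
    height: float


# ---------------------------------------------------------------- motion

def _wrap_deg(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def apply_command(s: RobotState, cmd) -> RobotState:
    """Apply one confirmed command to the robot state machine.

    Commands are ignored while aligning or in recognition mode.  Head
    turns move the head 3 degrees; the ERD switch aligns the body to the
    head when they differ by more than 9 degrees, and otherwise toggles
    walking.
    """
    from .hybrid import Command  # local import to avoid a cycle

    if s.mode in (Mode.ALIGNING, Mode.RECOGNITION):
        return s
    if cmd in (Command.HEAD_LEFT, Command.HEAD_RIGHT):
        step = HEAD_STEP_DEG if cmd == Command.HEAD_LEFT else -HEAD_STEP_DEG
        off = float(np.clip(s.head_offset + step, -HEAD_LIMIT_DEG,
                            HEAD_LIMIT_DEG))
        return replace(s, head_offset=off)
    if cmd == Command.ERD_SWITCH:
        if abs(s.head_offset) > ALIGN_THRESHOLD_DEG:
            return replace(s, mode=Mode.ALIGNING)
        new_mode = Mode.NAV_IDLE if s.mode == Mode.WALKING else Mode.WALKING
        return replace(s, mode=new_mode)
    return s


def _segment_hit(p0, p1, seg):
    """Earliest parameter t in (0, 1] at which p0->p1 crosses seg, or None."""
    (x1, y1), (x2, y2) = seg
    d = (p1[0] - p0[0], p1[1] - p0[1])
    e = (x2 - x1, y2 - y1)
    denom = d[0] * e[1] - d[1] * e[0]
    if abs(denom) < 1e-12:
        return None
    dx, dy = x1 - p0[0], y1 - p0[1]
    t = (dx * e[1] - dy * e[0]) / denom
    u = (dx * d[1] - dy * d[0]) / denom
    if 1e-9 < t <= 1.0 and -1e-9 <= u <= 1.0 + 1e-9:
        return t
    return None


def tick(s: RobotState, dt: float, arena: Arena):
    """Advance the simulation by dt seconds.

    Returns ``(new_state, collision)``.  Walking moves the robot at
    3.3 cm/s along the body heading and stops it at a wall (collision
    flag set, back to idle).  Aligning rotates the body toward the head
    at 0.13 rad/s, clamped exactly at alignment with no overshoot.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if s.mode == Mode.WALKING:
        theta = math.radians(s.body_heading)
        step = s.walk_speed * dt
        p0 = s.position
        p1 = (p0[0] + step * math.cos(theta), p0[1] + step * math.sin(theta))
        hits = [t for seg in arena.walls
                if (t := _segment_hit(p0, p1, seg)) is not None]
        if hits:
            t = min(hits)
            stop = (p0[0] + (t * step - 1e-6) * math.cos(theta),
                    p0[1] + (t * step - 1e-6) * math.sin(theta))
            return replace(s, position=stop, mode=Mode.NAV_IDLE), True
        return replace(s, position=p1), False
    if s.mode == Mode.ALIGNING:
        remaining = s.head_offset
        delta = math.degrees(s.turn_speed * dt)
        move = math.copysign(min(delta, abs(remaining)), remaining)
        body = _wrap_deg(s.body_heading + move)
        off = remaining - move
        mode = Mode.NAV_IDLE if abs(off) < 1e-9 else Mode.ALIGNING
        if mode is Mode.NAV_IDLE:
            off = 0.0
        return replace(s, body_heading=body, head_offset=off, mode=mode), False
    return s, False


# ---------------------------------------------------------------- vision

def render_view(s: RobotState, arena: Arena, width: int = 160,
                height: int = 120, fov_deg: float = 60.0,
                object_radius_cm: float = 8.0,
                max_range_cm: float = 120.0) -> ViewFrame:
    """Render the head camera's view as coloured disks on white.

    A crude pinhole model: an object's horizontal position comes from its
    bearing relative to the head direction, its apparent radius from its
    distance.  Objects behind the camera, outside the field of view or
    beyond ``max_range_cm`` are not drawn.
    """
    pixels = np.zeros((height, width), dtype=int)
    head = math.radians(s.head_heading)
    half_fov = math.radians(fov_deg) / 2
    yy, xx = np.mgrid[0:height, 0:width]
    for (ox, oy), color in arena.objects:
        dx, dy = ox - s.position[0], oy - s.position[1]
        dist = math.hypot(dx, dy)
        if dist < 1e-6 or dist > max_range_cm:
            continue
        bearing = _wrap_deg(math.degrees(math.atan2(dy, dx)) -
                            math.degrees(head))
        if abs(bearing) > fov_deg / 2:
            continue
        # positive bearing = object to the left = left side of the image
        x_norm = 0.5 - math.radians(bearing) / (2 * half_fov)
        r_norm = object_radius_cm / (2 * dist * math.tan(half_fov))
        cx, cy = x_norm * width, 0.5 * height
        r_px = max(r_norm * width, 1.5)
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px ** 2
        pixels[mask] = color
    return ViewFrame(pixels=pixels)


def detect_objects(frame: ViewFrame, color_table: dict = None,
                   min_area: int = 4) -> list:
    """Colour-filter object detection: per colour, connected pixel runs
    within range become tight normalized bounding boxes; blobs below
    ``min_area`` pixels are discarded."""
    h, w = frame.pixels.shape
    if color_table is None:
        colors = sorted(set(frame.pixels.ravel()) - {0})
        color_table = {c: (c, c) for c in colors}
    boxes = []
    for _color, (lo, hi) in sorted(color_table.items()):
        mask = (frame.pixels >= lo) & (frame.pixels <= hi)
        labeled, n = ndimage.label(mask)
        for sl in ndimage.find_objects(labeled):
            if mask[sl].sum() < min_area:
                continue
            y0, y1 = sl[0].start, sl[0].stop
            x0, x1 = sl[1].start, sl[1].stop
            boxes.append(BoundingBox(
                center=((x0 + x1) / 2 / w, (y0 + y1) / 2 / h),
                width=(x1 - x0) / w, height=(y1 - y0) / h))
    return boxes


def virtual_center(boxes) -> tuple:
    """Unweighted centre of gravity of the box centres."""
    if not boxes:
        raise ValueError("no boxes: virtual centre undefined")
    xs = [b.center[0] for b in boxes]
    ys = [b.center[1] for b in boxes]
    return (sum(xs) / len(xs), sum(ys) / len(ys))


def in_central_zone(pt) -> bool:
    """Middle fifth-by-fifth of the view, half-open: [0.4, 0.6) squared."""
    x, y = pt
    return 0.4 <= x < 0.6 and 0.4 <= y < 0.6


# ----------------------------------------------------- recognition plan

@dataclass
class RecognitionPlan:
    """Timed phases of one recognition episode."""

    n_objects: int
    flashes_per_object: int
    rest: float = 4.0
    isi: float = 0.25
    epoch_span: float = 0.6
    display: float = 2.0

    @property
    def flash_phase(self) -> float:
        """From first flash onset to completion of the last epoch."""
        n = self.n_objects * self.flashes_per_object
        return (n - 1) * self.isi + self.epoch_span

    @property
    def total(self) -> float:
        return self.rest + self.flash_phase + self.display


def recognition_sequence(n_objects: int, flashes_per_object: int = 5,
                         **kwargs) -> RecognitionPlan:
    """Plan one recognition episode: 4 s rest, the flash phase
    ((n_objects * flashes - 1) * 0.25 + 0.6 s), then a 2 s result display
    before returning to navigation."""
    if n_objects < 2:
        raise ValueError("recognition needs at least two objects")
    if flashes_per_object < 1:
        raise ValueError("need at least one flash per object")
    return RecognitionPlan(n_objects=n_objects,
                           flashes_per_object=flashes_per_object, **kwargs)
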