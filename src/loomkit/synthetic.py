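"""Synthetic looming-assay trials with planted ground truth.

This module emulates the recordings of the looming defensive-behavior assay:
a mouse explores the circular open field, enters the central trigger zone,
the overhead looming stimulus fires, the mouse escapes at high speed into the
refuge alley, and — depending on its coping strategy — either freezes there
before re-exploring ("Freezing" animals) or returns directly to exploration
("Non-Freezing" animals).

Every trial is assembled from kinematic motif templates (walking, running,
flight, freezing, rearing, sniffing, turning, ...) chained along a waypoint
path inside the arena, with isotropic Gaussian landmark noise added on top.
The generator records complete ground truth (per-frame motif labels, stimulus
onset, flight onset, refuge entry/exit, freezing bouts, Freezing group), so
every downstream stage of the pipeline can be scored against planted events.

Motif kinematics are package conventions chosen to be field-plausible; the
contract each template honours (centroid speed, signed heading change,
elevated nose for rearing-type motifs, near-zero motion for freezing) is what
the downstream detectors rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ArenaGeometry, StimulusProtocol
from .errors import GeometryError, LabelError, ProtocolKindError, ScheduleError
from .skeleton import BODY_AXIS, LANDMARKS, N_LANDMARKS, SkeletonSeries

# ---------------------------------------------------------------------------
# looming profile
# ---------------------------------------------------------------------------


def make_looming_profile(protocol: StimulusProtocol, dt_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample the looming-disc angular-size profile.

    Each repeat is a linear ramp ``start_deg -> end_deg`` over ``expand_ms``,
    a hold at ``end_deg`` for ``hold_ms``, then 0° (disc absent) during the
    inter-stimulus interval; the last repeat has no trailing interval.

    Parameters
    ----------
    protocol
        Must have ``kind == "looming"``.
    dt_ms
        Sampling step in ms; must be positive and divide ``expand_ms``.

    Returns
    -------
    (times_ms, degrees)
        Sample times ``0, dt, ..., total`` (inclusive) and angular sizes.
    """
    if protocol.kind != "looming":
        raise ProtocolKindError(f"expected a looming protocol, got kind={protocol.kind!r}")
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    if abs(protocol.expand_ms / dt_ms - round(protocol.expand_ms / dt_ms)) > 1e-9:
        raise ValueError("dt_ms must divide expand_ms")

    period = protocol.expand_ms + protocol.hold_ms + protocol.isi_ms
    total = protocol.total_ms
    n = int(round(total / dt_ms))
    t = np.arange(n + 1) * dt_ms
    local = np.mod(t, period)
    # the final sample t == total falls at local == expand+hold of the last repeat
    local[t >= total] = protocol.expand_ms + protocol.hold_ms
    deg = np.zeros_like(t)
    ramp = local <= protocol.expand_ms
    deg[ramp] = protocol.start_deg + (protocol.end_deg - protocol.start_deg) * (
        local[ramp] / protocol.expand_ms
    )
    hold = (local > protocol.expand_ms) & (local <= protocol.expand_ms + protocol.hold_ms)
    deg[hold] = protocol.end_deg
    return t, deg


# ---------------------------------------------------------------------------
# base pose and motif kinematics
# ---------------------------------------------------------------------------

# canonical pose: heading +x, body-axis centroid at the origin, z = height (cm)
_BASE_POSE = np.array(
    [
        [4.5, 0.0, 1.8],  # nose
        [3.4, 0.8, 2.0],  # left_ear
        [3.4, -0.8, 2.0],  # right_ear
        [3.0, 0.0, 1.7],  # neck
        [1.5, 0.0, 2.0],  # spine1
        [0.0, 0.0, 2.1],  # spine2
        [-1.5, 0.0, 2.0],  # spine3
        [-3.0, 0.0, 1.4],  # tail_base
        [2.2, 1.0, 1.0],  # left_front_limb
        [2.2, -1.0, 1.0],  # right_front_limb
        [-1.8, 1.2, 1.0],  # left_hind_limb
        [-1.8, -1.2, 1.0],  # right_hind_limb
        [2.5, 1.1, 0.1],  # left_front_paw
        [2.5, -1.1, 0.1],  # right_front_paw
        [-2.1, 1.4, 0.1],  # left_hind_paw
        [-2.1, -1.4, 0.1],  # right_hind_paw
    ]
)

_HEAD = [0, 1, 2]  # nose, ears
_PAWS = [12, 13, 14, 15]
_LIMBS = [8, 9, 10, 11]


@dataclass(frozen=True)
class MotifKinematics:
    """Kinematic parameters of one movement motif (package defaults).

    Posture offsets are centimetres in the egocentric frame (x forward,
    y left, z up); they are what makes motifs distinguishable after heading
    and translation are removed, mirroring how real movements differ in
    body configuration, not just speed.
    """

    speed: float  # centroid speed, cm/s
    turn_dps: float = 0.0  # signed heading change, degrees/s (+ = left/CCW)
    gait_hz: float = 0.0  # limb/paw oscillation frequency
    gait_amp: float = 0.0  # limb/paw swing amplitude, cm
    head_hz: float = 0.0  # head-bob frequency
    head_amp: float = 0.0  # head-bob amplitude, cm
    nose_dz: float = 0.0  # static nose/head elevation, cm
    nose_dx: float = 0.0  # static nose protraction (+) / retraction (-), cm
    nose_dy: float = 0.0  # static lateral head deflection (grooming), cm
    body_dz: float = 0.0  # static trunk elevation (rearing posture), cm
    pitch: float = 0.0  # static body pitch surrogate: fore-body raised, cm
    bend: float = 0.0  # lateral spine flexion, + = C-shape to the left, cm


MOTIF_KINEMATICS: dict[str, MotifKinematics] = {
    "walking": MotifKinematics(speed=8.0, gait_hz=3.0, gait_amp=1.2, head_hz=1.0, head_amp=0.3),
    "trotting": MotifKinematics(speed=18.0, gait_hz=5.0, gait_amp=1.4, head_hz=1.5, head_amp=0.3),
    "running": MotifKinematics(speed=35.0, gait_hz=8.0, gait_amp=1.6, nose_dx=0.8, head_hz=2.0, head_amp=0.3),
    "flight": MotifKinematics(speed=45.0, gait_hz=10.0, gait_amp=1.8, nose_dx=1.2, head_hz=2.0, head_amp=0.3),
    "stepping": MotifKinematics(speed=4.0, gait_hz=2.0, gait_amp=0.8, head_hz=1.0, head_amp=0.3),
    "left turning": MotifKinematics(speed=3.0, turn_dps=120.0, gait_hz=3.0, gait_amp=0.5, bend=2.5),
    "right turning": MotifKinematics(speed=3.0, turn_dps=-120.0, gait_hz=3.0, gait_amp=0.5, bend=-2.5),
    "looking up": MotifKinematics(speed=1.5, nose_dz=2.5, pitch=0.8, head_hz=1.0, head_amp=0.3),
    "stretching up": MotifKinematics(speed=1.5, nose_dz=4.5, body_dz=1.2, pitch=1.5, head_hz=1.0, head_amp=0.3),
    "rearing": MotifKinematics(speed=1.5, nose_dz=5.5, body_dz=2.5, pitch=2.0, head_hz=1.0, head_amp=0.4),
    "hunching": MotifKinematics(speed=1.5, nose_dz=-0.8, nose_dx=-1.5, body_dz=1.0, head_hz=1.0, head_amp=0.2),
    "sniffing": MotifKinematics(speed=2.5, nose_dx=0.5, head_hz=7.0, head_amp=1.2, gait_hz=2.0, gait_amp=0.3),
    "grooming": MotifKinematics(speed=1.5, nose_dx=-2.5, nose_dy=1.5, body_dz=0.8, head_hz=4.0, head_amp=1.2),
    "freezing": MotifKinematics(speed=0.0),
}

MOTIF_LABELS = tuple(MOTIF_KINEMATICS)


def _pose_frames(
    label: str,
    n: int,
    frame_rate: float,
    kin: MotifKinematics,
    rng: np.random.Generator,
) -> np.ndarray:
    """Egocentric pose (n, 16, 3) for a motif: base pose + motif deformation.

    Only head/limb/paw points are modulated; the body-axis landmarks carry no
    oscillation, so the centroid speed of a leg equals its path speed exactly.
    """
    t = np.arange(n) / frame_rate
    pose = np.broadcast_to(_BASE_POSE, (n, N_LANDMARKS, 3)).copy()
    if label == "freezing":
        return pose

    # static posture offsets
    pose[:, _HEAD, 2] += kin.nose_dz
    pose[:, _HEAD, 0] += kin.nose_dx
    pose[:, 0, 1] += kin.nose_dy
    pose[:, [1, 2], 1] += 0.6 * kin.nose_dy
    pose[:, [4], 2] += kin.body_dz + kin.pitch * 0.5
    pose[:, [3], 2] += kin.body_dz * 0.5 + kin.pitch
    pose[:, _LIMBS[:2], 2] += kin.pitch * 0.6
    pose[:, _PAWS[:2], 2] += kin.pitch * 0.8
    # lateral spine flexion: C-shape toward the turn direction
    if kin.bend != 0.0:
        pose[:, 0, 1] += kin.bend  # nose
        pose[:, [1, 2], 1] += 0.8 * kin.bend  # ears
        pose[:, 3, 1] += 0.5 * kin.bend  # neck
        pose[:, 4, 1] += 0.2 * kin.bend  # spine1
        pose[:, 6, 1] -= 0.2 * kin.bend  # spine3
        pose[:, 7, 1] -= 0.5 * kin.bend  # tail_base

    # limb gait: alternating diagonal pairs, random phase per leg
    if kin.gait_hz > 0:
        phase = rng.uniform(0, 2 * math.pi)
        osc = np.sin(2 * math.pi * kin.gait_hz * t + phase)
        for i, lm in enumerate(_PAWS):
            sign = 1.0 if i in (0, 3) else -1.0  # diagonal gait pattern
            pose[:, lm, 0] += sign * kin.gait_amp * osc
            pose[:, lm, 2] += 0.4 * kin.gait_amp * np.clip(sign * osc, 0, None)
        for i, lm in enumerate(_LIMBS):
            sign = 1.0 if i in (0, 3) else -1.0
            pose[:, lm, 0] += 0.5 * sign * kin.gait_amp * osc

    # head bob (sniffing/grooming nose oscillation)
    if kin.head_hz > 0:
        phase = rng.uniform(0, 2 * math.pi)
        bob = np.sin(2 * math.pi * kin.head_hz * t + phase)
        pose[:, 0, 2] += kin.head_amp * bob
        pose[:, 0, 0] += 0.5 * kin.head_amp * bob
        pose[:, [1, 2], 2] += 0.5 * kin.head_amp * bob[:, None]
    return pose


def _place(pose: np.ndarray, positions: np.ndarray, headings: np.ndarray) -> np.ndarray:
    """Rotate egocentric pose frames by heading and translate to positions."""
    c, s = np.cos(headings), np.sin(headings)
    out = np.empty_like(pose)
    x, y = pose[..., 0], pose[..., 1]
    out[..., 0] = c[:, None] * x - s[:, None] * y + positions[:, None, 0]
    out[..., 1] = s[:, None] * x + c[:, None] * y + positions[:, None, 1]
    out[..., 2] = pose[..., 2]
    return out


def motif_template(
    label: str,
    duration: float,
    frame_rate: float = 30.0,
    params: dict | None = None,
    seed: int = 0,
) -> SkeletonSeries:
    """Generate a skeleton snippet performing one movement motif.

    The snippet starts at the origin heading along +x and is deterministic
    given ``seed``.  ``params`` may override any :class:`MotifKinematics`
    field (e.g. ``{"speed": 40.0}``).

    Raises
    ------
    LabelError
        For a label outside the motif vocabulary.
    ValueError
        If the duration spans fewer than 2 frames.
    """
    if label not in MOTIF_KINEMATICS:
        raise LabelError(f"unknown motif label {label!r}; known: {sorted(MOTIF_KINEMATICS)}")
    n = int(round(duration * frame_rate))
    if n < 2:
        raise ValueError("duration must span at least 2 frames")
    kin = MOTIF_KINEMATICS[label]
    if params:
        from dataclasses import replace

        kin = replace(kin, **params)
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    headings = np.deg2rad(kin.turn_dps) * dt * np.arange(n)
    # integrate positions (frame 0 at the origin)
    step = kin.speed * dt
    dx = np.cos(headings[:-1]) * step
    dy = np.sin(headings[:-1]) * step
    positions = np.zeros((n, 2))
    positions[1:, 0] = np.cumsum(dx)
    positions[1:, 1] = np.cumsum(dy)
    pose = _pose_frames(label, n, frame_rate, kin, rng)
    coords = _place(pose, positions, headings)
    return SkeletonSeries(coords=coords, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# scenarios and trials
# ---------------------------------------------------------------------------


@dataclass
class ScenarioLeg:
    """One scheduled motif bout.

    A leg either moves toward ``target`` at the motif speed (duration then
    follows from the distance) or runs in place / drifts for ``duration``
    seconds.  ``start_s`` is optional; when given for all legs, the schedule
    is validated for overlap/gaps.
    """

    motif: str
    duration: float | None = None
    target: tuple[float, float] | None = None
    speed: float | None = None
    start_s: float | None = None


@dataclass
class Scenario:
    """A full trial schedule: acclimation → center entry → escape → refuge."""

    legs: list[ScenarioLeg]
    freezing: bool = False
    acclimation_s: float = 60.0
    escape: bool = True
    extra: dict = field(default_factory=dict)


@dataclass
class TrialGroundTruth:
    """Planted events and per-frame labels for one simulated trial."""

    labels: np.ndarray  # per-frame motif label (str)
    frame_rate: float
    stimulus_onset: float | None
    flight_onset: float | None
    refuge_entry: float | None
    refuge_exit: float | None
    freezing_bouts: list[tuple[float, float]]
    group: str  # "Freezing" | "Non-Freezing"

    def __post_init__(self) -> None:
        events = [self.stimulus_onset, self.flight_onset, self.refuge_entry, self.refuge_exit]
        present = [e for e in events if e is not None]
        if any(b > a + 1e-9 for a, b in zip(present[1:], present[:-1])):
            raise ValueError(f"ground-truth events out of order: {events}")


@dataclass
class Trial:
    """One simulated animal: noisy skeleton, clean tracking path, ground truth."""

    skeleton: SkeletonSeries | None
    trajectory: pd.DataFrame  # columns t_s, x_cm, y_cm
    ground_truth: TrialGroundTruth
    animal_id: str = ""
    sex: str = "unspecified"


def default_scenario(
    arena: ArenaGeometry,
    freeze: bool,
    rng: np.random.Generator,
    acclimation_s: float = 60.0,
    freeze_duration: float = 2.5,
    escape: bool = True,
) -> Scenario:
    """Build the canonical assay schedule.

    Acclimation wanders the field periphery (outside the trigger circle, so
    the first trigger-circle entry is unambiguous), then the animal walks to
    the centre, pauses briefly (threat detection), flees to the refuge, and —
    for Freezing animals — freezes there before sniffing and leaving.
    Non-escape scenarios skip the flight and keep exploring the field.
    """
    cx, cy = arena.field_center
    legs: list[ScenarioLeg] = []

    # acclimation: waypoints in the annulus between trigger circle and wall;
    # successive waypoint bearings change by <= 50 degrees so connecting
    # chords never cut through the trigger circle
    r_lo = arena.trigger_radius + 5.0
    r_hi = arena.field_radius - 3.0
    t_used = 0.0
    wander = ("walking", "sniffing", "stepping", "looking up", "rearing", "walking")
    ang = -math.pi / 2  # start near the bottom of the field
    prev = np.array([cx + r_lo * math.cos(ang), cy + r_lo * math.sin(ang)])
    i = 0
    while t_used < acclimation_s - 1.0:
        motif = wander[i % len(wander)]
        kin = MOTIF_KINEMATICS[motif]
        if kin.speed >= 3.0:  # locomotor legs head to a waypoint
            ang += rng.uniform(-0.87, 0.87)
            rad = rng.uniform(r_lo, r_hi)
            wp = np.array([cx + rad * math.cos(ang), cy + rad * math.sin(ang)])
            legs.append(ScenarioLeg(motif, target=(wp[0], wp[1])))
            t_used += float(np.linalg.norm(wp - prev)) / kin.speed
            prev = wp
        else:
            # postural legs drift tangentially at their (slow) motif speed so
            # the path neither idles in place nor strays toward the trigger
            # circle; the animal is never truly stationary outside freezing
            d = float(rng.uniform(0.8, 1.6))
            angp = math.atan2(prev[1] - cy, prev[0] - cx)
            rad = max(float(np.linalg.norm(prev - (cx, cy))), r_lo)
            dtheta = kin.speed * d / rad
            wp = np.array([cx + rad * math.cos(angp + dtheta), cy + rad * math.sin(angp + dtheta)])
            legs.append(ScenarioLeg(motif, duration=d, target=(wp[0], wp[1])))
            prev = wp
            t_used += d
        i += 1

    # approach: walk into the trigger circle -> stimulus onset
    legs.append(ScenarioLeg("walking", target=(cx, cy + 3.0)))
    # threat detection pause (short, below the freezing minimum duration)
    legs.append(ScenarioLeg("looking up", duration=0.3))
    if escape:
        ex, ey = arena.entrance_mid
        xmin, xmax, ymin, ymax = arena.refuge_rect
        depth = ymin + 0.6 * (ymax - ymin)
        legs.append(ScenarioLeg("flight", target=(ex, ey)))
        legs.append(ScenarioLeg("flight", target=(ex, depth)))
        if freeze:
            legs.append(ScenarioLeg("freezing", duration=freeze_duration))
        sniff_d = 2.0
        sniff_reach = MOTIF_KINEMATICS["sniffing"].speed * sniff_d
        legs.append(ScenarioLeg("sniffing", duration=sniff_d, target=(ex + sniff_reach, depth)))
        legs.append(ScenarioLeg("walking", target=(ex, ey - 0.5)))  # refuge exit
        legs.append(ScenarioLeg("walking", target=(cx + 5.0, cy + 5.0)))
    else:
        # non-escapers stay in the field; a Freezing animal freezes in place
        if freeze:
            legs.append(ScenarioLeg("freezing", duration=freeze_duration))
        legs.append(ScenarioLeg("walking", target=(cx + 10.0, cy - 8.0)))
        legs.append(ScenarioLeg("sniffing", duration=2.0))
        legs.append(ScenarioLeg("walking", target=(cx - 12.0, cy)))
    return Scenario(legs=legs, freezing=freeze, acclimation_s=acclimation_s, escape=escape)


def _validate_schedule(legs: list[ScenarioLeg], frame_rate: float) -> None:
    starts = [leg.start_s for leg in legs]
    if all(s is None for s in starts):
        return
    if any(s is None for s in starts):
        raise ScheduleError("either all or no legs may carry explicit start times")
    tol = 0.5 / frame_rate
    t = starts[0]
    for leg in legs:
        if leg.duration is None:
            raise ScheduleError("explicitly timed legs need explicit durations")
        if leg.start_s < t - tol:
            raise ScheduleError(f"leg {leg.motif!r} at {leg.start_s} s overlaps the previous leg")
        if leg.start_s > t + tol:
            raise ScheduleError(f"gap before leg {leg.motif!r} at {leg.start_s} s")
        t = leg.start_s + leg.duration


def simulate_trial(
    arena: ArenaGeometry,
    protocol: StimulusProtocol,
    scenario: Scenario,
    frame_rate: float = 30.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    include_skeleton: bool = True,
) -> Trial:
    """Assemble one trial from a scenario schedule.

    Returns the noisy 16-landmark skeleton series, the clean centroid
    trajectory (the tracking modality, as from the touchscreen frame), and
    the planted ground truth.  Stimulus onset is the first entry of the
    generated centroid into the trigger circle at or after the acclimation
    phase; a path point outside arena ∪ refuge raises :class:`GeometryError`.
    """
    _validate_schedule(scenario.legs, frame_rate)
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate

    pos = np.array([arena.field_center[0], arena.field_center[1] - arena.field_radius + 5.0])
    heading = math.pi / 2
    positions: list[np.ndarray] = []
    headings: list[np.ndarray] = []
    labels: list[str] = []
    leg_spans: list[tuple[str, int, int]] = []  # (motif, start_frame, end_frame)
    flight_onset_frame: int | None = None
    frame = 0

    for leg in scenario.legs:
        if leg.motif not in MOTIF_KINEMATICS:
            raise LabelError(f"unknown motif label {leg.motif!r}")
        kin = MOTIF_KINEMATICS[leg.motif]
        speed = leg.speed if leg.speed is not None else kin.speed
        turn = math.radians(kin.turn_dps)
        if leg.target is not None:
            target = np.asarray(leg.target, dtype=float)
            dist = float(np.linalg.norm(target - pos))
            n = max(int(round(dist / max(speed, 1e-9) / dt)), 2)
            if leg.duration is not None:
                n = max(int(round(leg.duration * frame_rate)), 2)
            P = np.empty((n, 2))
            H = np.empty(n)
            p = pos.copy()
            h = heading
            for k in range(n):
                P[k] = p
                to_target = target - p
                d = float(np.linalg.norm(to_target))
                if d > 1e-9:
                    h = math.atan2(to_target[1], to_target[0])
                H[k] = h
                step = min(speed * dt, d)
                if d > 1e-9:
                    p = p + to_target / d * step
        else:
            n = max(int(round((leg.duration or 1.0) * frame_rate)), 2)
            P = np.empty((n, 2))
            H = np.empty(n)
            p = pos.copy()
            h = heading
            for k in range(n):
                P[k] = p
                H[k] = h
                h += turn * dt
                p = p + speed * dt * np.array([math.cos(h), math.sin(h)])
        if leg.motif == "flight" and flight_onset_frame is None:
            flight_onset_frame = frame
        positions.append(P)
        headings.append(H)
        labels.extend([leg.motif] * n)
        leg_spans.append((leg.motif, frame, frame + n))
        frame += n
        pos = P[-1]
        heading = H[-1]

    positions_arr = np.concatenate(positions, axis=0)
    headings_arr = np.concatenate(headings, axis=0)
    labels_arr = np.asarray(labels)
    n_frames = positions_arr.shape[0]
    t_s = np.arange(n_frames) * dt

    if not bool(np.all(arena.in_domain(positions_arr))):
        bad = int(np.flatnonzero(~arena.in_domain(positions_arr))[0])
        raise GeometryError(
            f"scenario path leaves arena ∪ refuge at frame {bad} "
            f"(position {positions_arr[bad].round(2)})"
        )

    # ground-truth events from the generated centroid; stimulus onset is the
    # first entry into the trigger circle (acclimation paths stay clear of it)
    in_trig = arena.in_trigger(positions_arr)
    trig_idx = np.flatnonzero(in_trig)
    stimulus_onset = float(trig_idx[0] * dt) if trig_idx.size else None

    flight_onset = None
    if flight_onset_frame is not None:
        flight_onset = float(flight_onset_frame * dt)

    refuge_entry = refuge_exit = None
    if stimulus_onset is not None:
        in_ref = arena.in_refuge(positions_arr)
        after = np.arange(n_frames) >= int(round(stimulus_onset * frame_rate))
        entry_idx = np.flatnonzero(in_ref & after)
        if entry_idx.size:
            e0 = int(entry_idx[0])
            refuge_entry = float(e0 * dt)
            exit_idx = np.flatnonzero(~in_ref & (np.arange(n_frames) > e0))
            if exit_idx.size:
                refuge_exit = float(int(exit_idx[0]) * dt)

    freezing_bouts = [
        (s * dt, e * dt) for (m, s, e) in leg_spans if m == "freezing"
    ]
    post_stim = [
        b for b in freezing_bouts if stimulus_onset is not None and b[0] >= stimulus_onset
    ]
    group = "Freezing" if post_stim else "Non-Freezing"

    gt = TrialGroundTruth(
        labels=labels_arr,
        frame_rate=frame_rate,
        stimulus_onset=stimulus_onset,
        flight_onset=flight_onset,
        refuge_entry=refuge_entry,
        refuge_exit=refuge_exit,
        freezing_bouts=freezing_bouts,
        group=group,
    )
    traj = pd.DataFrame({"t_s": t_s, "x_cm": positions_arr[:, 0], "y_cm": positions_arr[:, 1]})

    skeleton = None
    if include_skeleton:
        coords = np.empty((n_frames, N_LANDMARKS, 3))
        for motif, s, e in leg_spans:
            kin = MOTIF_KINEMATICS[motif]
            pose = _pose_frames(motif, e - s, frame_rate, kin, rng)
            coords[s:e] = _place(pose, positions_arr[s:e], headings_arr[s:e])
        # body-axis centroid of the placed pose coincides with the path by
        # construction (base pose has zero body-axis mean)
        coords += rng.normal(0.0, noise_sd, size=coords.shape)
        skeleton = SkeletonSeries(coords=coords, frame_rate=frame_rate)
    return Trial(skeleton=skeleton, trajectory=traj, ground_truth=gt)


def simulate_cohort(
    n_male: int,
    n_female: int,
    p_freeze_male: float,
    p_freeze_female: float,
    params: dict | None = None,
    seed: int = 0,
) -> tuple[list[Trial], pd.DataFrame]:
    """Simulate a cohort of looming trials with sex-specific freezing odds.

    Each animal's Freezing status is an independent Bernoulli draw with its
    sex's probability; whether the animal escapes at all is a further draw
    with probability ``p_escape`` (default 0.9, the assay's typical escape
    rate).  ``params`` may override ``arena``, ``frame_rate``, ``noise_sd``,
    ``acclimation_s``, ``freeze_duration``, ``p_escape`` and
    ``include_skeletons``.

    Returns the trial list and a design table (animal_id, sex, planted
    freezing/escape flags).  Reproducible bit-for-bit given ``seed``.
    """
    for p in (p_freeze_male, p_freeze_female):
        if not 0.0 <= p <= 1.0:
            raise ValueError("freezing probabilities must lie in [0, 1]")
    if n_male < 1 or n_female < 1:
        raise ValueError("need at least one animal per sex")
    params = dict(params or {})
    arena = params.pop("arena", ArenaGeometry())
    protocol = params.pop("protocol", StimulusProtocol())
    frame_rate = params.pop("frame_rate", 30.0)
    noise_sd = params.pop("noise_sd", 0.2)
    acclimation_s = params.pop("acclimation_s", 60.0)
    freeze_duration = params.pop("freeze_duration", 2.5)
    p_escape = params.pop("p_escape", 0.9)
    include_skeletons = params.pop("include_skeletons", True)
    if params:
        raise ValueError(f"unknown cohort params: {sorted(params)}")

    root = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(root.spawn(1)[0])
    trial_seeds = root.generate_state(2 * (n_male + n_female)) % (2**31)

    trials: list[Trial] = []
    rows = []
    idx = 0
    for sex, count, p_freeze in (("male", n_male, p_freeze_male), ("female", n_female, p_freeze_female)):
        for j in range(count):
            freeze = bool(draw_rng.random() < p_freeze)
            escape = bool(draw_rng.random() < p_escape)
            animal_id = f"{sex[0].upper()}{j:04d}"
            scen_rng = np.random.default_rng(int(trial_seeds[idx]))
            scenario = default_scenario(
                arena,
                freeze=freeze,
                rng=scen_rng,
                acclimation_s=acclimation_s,
                freeze_duration=freeze_duration,
                escape=escape,
            )
            trial = simulate_trial(
                arena,
                protocol,
                scenario,
                frame_rate=frame_rate,
                noise_sd=noise_sd,
                seed=int(trial_seeds[idx + 1]),
                include_skeleton=include_skeletons,
            )
            trial.animal_id = animal_id
            trial.sex = sex
            if trial.skeleton is not None:
                trial.skeleton.animal_id = animal_id
                trial.skeleton.sex = sex
            trials.append(trial)
            rows.append(
                {
                    "animal_id": animal_id,
                    "sex": sex,
                    "freezing": freeze,
                    "escape": escape,
                    "group": trial.ground_truth.group,
                }
            )
            idx += 2
    design = pd.DataFrame(rows)
    return trials, design
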