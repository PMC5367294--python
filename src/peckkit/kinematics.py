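"""Per-peck event detection and kinematic parameters.

A peck is a movement sequence from the *head fixation* (a rapid standstill of
the head in front of the target) to the *grasping offset* (the minimal bill
aperture after the aperture maximum). Between those anchors the analysis
extracts four parameters per peck:

* grasping onset time — seconds from fixation to the frame where the bill
  aperture has opened 20% of the way from its fixation baseline to its
  maximum;
* movement distance — total head path length of the peck (fixation→offset by
  default; the fixation→onset window is available as a config option);
* mean velocity — mean of per-step instantaneous speeds, fixation→onset;
* mean acceleration — mean of per-step speed differences, fixation→onset.

Movement distance deliberately spans the whole peck: it enters the grasping
onset model as a covariate, and a distance that itself terminated at onset
would be shortened mechanically by any advanced onset, masking exactly the
adjustment effects the model is meant to expose.

Marker tracks are low-pass filtered (zero-phase 4th-order Butterworth, 5 Hz
cutoff by default) before any event detection, so event timing is not biased
by filter lag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .io import MARKER_ROLES, MarkerTrack, PeckTrial


class KinematicsError(ValueError):
    """Base class for event-detection / extraction failures."""


class TrackTooShortError(KinematicsError):
    pass


class TrackGapError(KinematicsError):
    pass


class NoFixationError(KinematicsError):
    """No qualifying pre-reach standstill was found."""


class NoOpeningError(KinematicsError):
    """The bill aperture never rises above its fixation baseline."""


class TruncatedApertureError(KinematicsError):
    """The aperture series ends at or before its maximum."""


@dataclass
class KinematicsConfig:
    """Tunable parameters of the event extraction.

    The 20% opening rule can be applied relative to the fixation-frame
    baseline aperture (``onset_rule="baseline"``, default — a closed bill has
    nonzero marker separation) or as an absolute fraction of the maximum
    (``"absolute"``). ``distance_endpoint`` selects whether movement distance
    terminates at grasping onset (default) or at grasping offset.
    """

    cutoff_hz: float = 5.0
    filter_order: int = 4
    speed_threshold_cm_s: float = 2.0
    min_still_frames: int = 10
    onset_fraction: float = 0.20
    onset_rule: str = "baseline"  # or "absolute"
    distance_endpoint: str = "offset"  # or "onset"


@dataclass
class PeckEvents:
    """Frame-indexed event landmarks of one peck."""

    fixation_frame: int
    onset_frame: int
    max_aperture_frame: int
    max_aperture: float
    offset_frame: int
    offset_aperture: float

    def __post_init__(self) -> None:
        if not (self.fixation_frame <= self.onset_frame
                <= self.max_aperture_frame <= self.offset_frame):
            raise ValueError(
                "event ordering violated: fixation <= onset <= max <= offset "
                f"({self.fixation_frame}, {self.onset_frame}, "
                f"{self.max_aperture_frame}, {self.offset_frame})"
            )
        if not (self.max_aperture >= self.offset_aperture >= 0):
            raise ValueError("apertures must satisfy max >= offset >= 0")


@dataclass
class KinematicRecord:
    """The per-peck parameters entering the mixed models.

    When ``retained`` is False the parameter fields are None and
    ``exclusion_reason`` says why the peck was discarded (e.g. a marker gap
    inside the fixation→offset window, mirroring the exclusion of pecks whose
    markers left the video frame).
    """

    trial_id: str
    species: str
    individual: str
    phase: str
    session: int
    peck_order: int
    target_position: Optional[int]
    outcome: str
    onset_s: Optional[float] = None
    distance_cm: Optional[float] = None
    velocity_cm_s: Optional[float] = None
    accel_cm_s2: Optional[float] = None
    retained: bool = False
    exclusion_reason: str = ""


# ---------------------------------------------------------------------------
# smoothing and primitive series


def smooth_track(track: MarkerTrack, cutoff: float = 5.0, order: int = 4) -> MarkerTrack:
    """Zero-phase Butterworth low-pass filter of x and y, frames unchanged.

    Forward–backward application doubles the effective order's attenuation
    and cancels phase lag, so event timing downstream is unbiased. Edges are
    handled by scipy's odd-reflection padding.
    """
    n = len(track)
    if track.has_gaps:
        raise TrackGapError(
            f"marker {track.marker_name!r} has missing frames inside its span; "
            "split the track at the gap or discard the peck before smoothing"
        )
    if n < 3 * order:
        raise TrackTooShortError(
            f"track of length {n} too short for stable order-{order} filtering"
        )
    nyq = track.frame_rate / 2.0
    b, a = signal.butter(order, cutoff / nyq, btype="low")
    padlen = min(3 * (max(len(a), len(b)) - 1), n - 1)
    xs = signal.filtfilt(b, a, track.x, padlen=padlen)
    ys = signal.filtfilt(b, a, track.y, padlen=padlen)
    return replace(track, x=xs, y=ys)


def aperture_series(upper: MarkerTrack, lower: MarkerTrack) -> np.ndarray:
    """Per-frame bill aperture: Euclidean distance between the tip markers."""
    if len(upper) != len(lower) or np.any(upper.frames != lower.frames):
        raise KinematicsError("upper and lower tip tracks are not frame-aligned")
    return np.hypot(upper.x - lower.x, upper.y - lower.y)


def step_speeds(track: MarkerTrack) -> np.ndarray:
    """Instantaneous speeds from consecutive frames (cm/s), length n-1.

    Speed i is the displacement between frames i and i+1 divided by the frame
    interval; it is attributed to frame i.
    """
    if track.has_gaps:
        raise TrackGapError(f"marker {track.marker_name!r} has gaps")
    d = np.hypot(np.diff(track.x), np.diff(track.y))
    return d * track.frame_rate


# ---------------------------------------------------------------------------
# event detection (positional frame indices; caller maps to absolute frames)


def detect_fixation(
    head: MarkerTrack,
    speed_threshold: float = 2.0,
    min_still_frames: int = 10,
) -> int:
    """First frame of the last pre-reach standstill of the head.

    A standstill is >= ``min_still_frames`` consecutive frames with
    instantaneous speed below ``speed_threshold``; only intervals before the
    global speed peak of the reach qualify. The head track should already be
    smoothed. Returns a positional index into the track.
    """
    v = step_speeds(head)
    if len(v) < min_still_frames:
        raise NoFixationError("track too short to contain a standstill")
    peak = int(np.argmax(v))
    if v[peak] < speed_threshold:
        # no reach-scale movement at all: the whole series is a standstill
        region_end = len(v)
    else:
        region_end = peak
    still = v[:region_end] < speed_threshold
    # runs of consecutive True
    best_start = None
    run_start = None
    for i, s in enumerate(still):
        if s and run_start is None:
            run_start = i
        elif not s and run_start is not None:
            if i - run_start >= min_still_frames:
                best_start = run_start
            run_start = None
    if run_start is not None and len(still) - run_start >= min_still_frames:
        best_start = run_start
    if best_start is None:
        raise NoFixationError(
            f"no standstill of >= {min_still_frames} frames below "
            f"{speed_threshold} cm/s before the speed peak"
        )
    return best_start


def detect_grasp_events(
    aperture: np.ndarray,
    fixation_frame: int,
    onset_fraction: float = 0.20,
    onset_rule: str = "baseline",
    tol: float = 1e-9,
) -> PeckEvents:
    """Grasping onset / maximum / offset from a per-frame aperture series.

    The maximum aperture is taken over [fixation, end] (earliest frame on
    ties). Onset is the first frame at or after fixation where the aperture
    has opened ``onset_fraction`` of the way from the fixation baseline to the
    maximum (or of the absolute maximum under ``onset_rule="absolute"``).
    Offset is the frame of minimal aperture after the maximum; its aperture
    may exceed zero when food is held between the tips.
    """
    aperture = np.asarray(aperture, dtype=float)
    n = len(aperture)
    if not 0 <= fixation_frame < n:
        raise KinematicsError("fixation_frame outside aperture series")
    seg = aperture[fixation_frame:]
    a0 = seg[0]
    imax = int(np.argmax(seg))
    amax = seg[imax]
    if amax - a0 <= tol:
        raise NoOpeningError("aperture never rises above its fixation baseline")
    if onset_rule == "baseline":
        threshold = a0 + onset_fraction * (amax - a0)
    elif onset_rule == "absolute":
        threshold = onset_fraction * amax
    else:
        raise ValueError(f"unknown onset_rule {onset_rule!r}")
    above = np.nonzero(seg[: imax + 1] >= threshold - tol)[0]
    above = above[above >= 0]
    # first crossing at or after fixation, never after the maximum
    onset_rel = int(above[0]) if len(above) else imax
    if imax == len(seg) - 1:
        raise TruncatedApertureError(
            "aperture series ends at its maximum; grasping offset unresolved"
        )
    closing = seg[imax:]
    off_rel = imax + int(np.argmin(closing))
    return PeckEvents(
        fixation_frame=fixation_frame,
        onset_frame=fixation_frame + onset_rel,
        max_aperture_frame=fixation_frame + imax,
        max_aperture=float(amax),
        offset_frame=fixation_frame + off_rel,
        offset_aperture=float(seg[off_rel]),
    )


# ---------------------------------------------------------------------------
# window statistics


def _window_positions(head: MarkerTrack, start_frame: int, end_frame: int) -> np.ndarray:
    if start_frame > end_frame:
        raise KinematicsError("start_frame must not exceed end_frame")
    m = (head.frames >= start_frame) & (head.frames <= end_frame)
    frames = head.frames[m]
    expected = end_frame - start_frame + 1
    if len(frames) != expected:
        raise TrackGapError(
            f"marker {head.marker_name!r}: gap inside window "
            f"[{start_frame}, {end_frame}]"
        )
    return head.positions[m]


def movement_distance(head: MarkerTrack, start_frame: int, end_frame: int) -> float:
    """Total head path length (cm) over the window: sum of per-frame steps."""
    pos = _window_positions(head, start_frame, end_frame)
    return float(np.sum(np.hypot(*np.diff(pos, axis=0).T))) if len(pos) > 1 else 0.0


def mean_velocity(head: MarkerTrack, start_frame: int, end_frame: int) -> float:
    """Mean of per-step instantaneous speeds (cm/s) over the window.

    With a uniform frame interval this equals movement distance divided by
    window duration, exactly.
    """
    pos = _window_positions(head, start_frame, end_frame)
    if len(pos) < 2:
        raise KinematicsError("window must span at least 2 frames")
    steps = np.hypot(*np.diff(pos, axis=0).T)
    return float(np.mean(steps) * head.frame_rate)


def mean_acceleration(head: MarkerTrack, start_frame: int, end_frame: int) -> float:
    """Mean of per-step speed differences over the window (cm/s^2).

    The mean telescopes to (v_last - v_first) / (duration between them).
    """
    pos = _window_positions(head, start_frame, end_frame)
    if len(pos) < 3:
        raise KinematicsError("window must span at least 3 frames")
    v = np.hypot(*np.diff(pos, axis=0).T) * head.frame_rate
    dt = 1.0 / head.frame_rate
    return float(np.mean(np.diff(v) / dt))


# ---------------------------------------------------------------------------
# full extraction


def _common_contiguous_run(trial: PeckTrial) -> tuple[int, int]:
    """Longest run of consecutive frames present in all three tracks.

    Returns (first_frame, last_frame) of the run.
    """
    common = trial.tracks["head"].frames
    for role in ("upper_tip", "lower_tip"):
        common = np.intersect1d(common, trial.tracks[role].frames)
    if len(common) == 0:
        raise TrackGapError("tracks share no frames")
    breaks = np.nonzero(np.diff(common) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(common) - 1]])
    lengths = ends - starts
    k = int(np.argmax(lengths))
    return int(common[starts[k]]), int(common[ends[k]])


def extract_kinematics(trial: PeckTrial, config: KinematicsConfig = KinematicsConfig()) -> KinematicRecord:
    """Run the full per-peck analysis; failures become retained=False records.

    smooth -> aperture -> fixation -> grasp events -> the four parameters
    (velocity/acceleration on the fixation-to-onset window, distance to the
    configured endpoint). A marker gap inside [fixation, offset], or any
    detector failure attributable to one, excludes the peck with reason
    ``"gap"``; other detector failures carry their own reason.
    """
    rec = KinematicRecord(
        trial_id=trial.trial_id,
        species=trial.species,
        individual=trial.individual,
        phase=trial.phase,
        session=trial.session,
        peck_order=trial.peck_order,
        target_position=trial.target_position,
        outcome=trial.outcome,
    )
    any_gap = any(trial.tracks[r].has_gaps for r in MARKER_ROLES)
    try:
        lo, hi = _common_contiguous_run(trial)
        win = {r: trial.tracks[r].window(lo, hi) for r in MARKER_ROLES}
        sm = {r: smooth_track(win[r], config.cutoff_hz, config.filter_order)
              for r in MARKER_ROLES}
        ap = aperture_series(sm["upper_tip"], sm["lower_tip"])
        fix_idx = detect_fixation(
            sm["head"], config.speed_threshold_cm_s, config.min_still_frames
        )
        ev = detect_grasp_events(
            ap, fix_idx, config.onset_fraction, config.onset_rule
        )
        # map positional indices to absolute frame numbers
        ev = PeckEvents(
            fixation_frame=lo + ev.fixation_frame,
            onset_frame=lo + ev.onset_frame,
            max_aperture_frame=lo + ev.max_aperture_frame,
            max_aperture=ev.max_aperture,
            offset_frame=lo + ev.offset_frame,
            offset_aperture=ev.offset_aperture,
        )
        # exclusion rule: any marker gap inside the peck window
        for role in MARKER_ROLES:
            gf = trial.tracks[role].gap_frames()
            if len(gf) and np.any((gf >= ev.fixation_frame) & (gf <= ev.offset_frame)):
                rec.exclusion_reason = "gap"
                return rec
        end = ev.onset_frame if config.distance_endpoint == "onset" else ev.offset_frame
        head = sm["head"]
        fps = trial.frame_rate
        rec.onset_s = (ev.onset_frame - ev.fixation_frame) / fps
        rec.distance_cm = movement_distance(head, ev.fixation_frame, end)
        if ev.onset_frame - ev.fixation_frame >= 2:
            rec.velocity_cm_s = mean_velocity(head, ev.fixation_frame, ev.onset_frame)
            rec.accel_cm_s2 = mean_acceleration(head, ev.fixation_frame, ev.onset_frame)
        else:
            rec.exclusion_reason = "window_too_short"
            rec.onset_s = rec.distance_cm = None
            return rec
        rec.retained = True
        rec.events = ev  # type: ignore[attr-defined]  # not serialized
        return rec
    except (TrackGapError,):
        rec.exclusion_reason = "gap"
    except NoFixationError:
        rec.exclusion_reason = "gap" if any_gap else "no_fixation"
    except NoOpeningError:
        rec.exclusion_reason = "gap" if any_gap else "no_opening"
    except TruncatedApertureError:
        rec.exclusion_reason = "gap" if any_gap else "truncated"
    except TrackTooShortError:
        rec.exclusion_reason = "gap" if any_gap else "too_short"
    return rec


def extract_batch(trials: Sequence[PeckTrial], config: KinematicsConfig = KinematicsConfig()) -> list[KinematicRecord]:
    return [extract_kinematics(t, config) for t in trials]


def records_to_frame(records: Sequence[KinematicRecord]):
    """Tidy DataFrame in the kinematics.csv schema."""
    import pandas as pd

    from .io import KINEMATICS_COLUMNS

    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in KINEMATICS_COLUMNS})
    return pd.DataFrame(rows, columns=KINEMATICS_COLUMNS)


# ---------------------------------------------------------------------------
# trajectory summaries


def _resample_path(pos: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to n_points by normalized path-length parameter."""
    steps = np.hypot(*np.diff(pos, axis=0).T)
    c = np.concatenate([[0.0], np.cumsum(steps)])
    if c[-1] <= 0:
        return np.repeat(pos[:1], n_points, axis=0)
    c = c / c[-1]
    # break exact ties so np.interp sees an increasing abscissa
    c = c + np.arange(len(c)) * 1e-12
    t = np.linspace(0.0, c[-1], n_points)
    return np.column_stack([np.interp(t, c, pos[:, 0]), np.interp(t, c, pos[:, 1])])


def mean_trajectory(
    trials: Sequence[PeckTrial],
    marker: str = "upper_tip",
    n_points: int = 50,
    config: KinematicsConfig = KinematicsConfig(),
):
    """Mean and s.d. curves of a marker's fixation-to-offset path.

    Each retained peck's path is resampled to ``n_points`` by normalized
    path-length parameterization; the pointwise mean and standard deviation of
    x and y are returned as arrays of shape (n_points, 2). Coordinates stay
    target-relative (food at the origin).
    """
    paths = []
    for trial in trials:
        rec = extract_kinematics(trial, config)
        if not rec.retained:
            continue
        ev = rec.events  # type: ignore[attr-defined]
        sm = smooth_track(
            trial.tracks[marker].window(ev.fixation_frame, ev.offset_frame),
            config.cutoff_hz, config.filter_order,
        )
        paths.append(_resample_path(sm.positions, n_points))
    if len(paths) < 2:
        raise KinematicsError("need at least 2 retained pecks for a mean trajectory")
    stack = np.stack(paths)
    return stack.mean(axis=0), stack.std(axis=0, ddof=1)
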