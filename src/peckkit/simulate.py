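"""Synthetic pecking trials with known ground truth.

The generator emulates a sagittal 2-D peck toward a target food at the
origin. The head performs a minimum-jerk reach, s(tau) = L (10 tau^3 -
15 tau^4 + 6 tau^5), along a gently curved arc from a fixation point toward
the target; a pre-reach approach and standstill are prepended so the head
fixation is a detectable event. Bill tips sit one effective bill length
(original bill plus any artificial extension) ahead of the head along the
heading, rotated symmetrically apart so the tip-to-tip distance follows a
raised-cosine open-close aperture pulse: rest aperture -> peak aperture ->
offset aperture (the nonzero floor set by the held food). Opening is
triggered when the remaining head path drops below a species-typical
distance, so grasping onset covaries with movement distance as in real
pecking. Success is Bernoulli on a logit scale with a per-individual random
intercept; i.i.d. Gaussian noise is added per marker per frame.

Ground-truth events are obtained by applying the operational definitions to
the *noiseless, unfiltered* sampled kinematics with a minimal independent
run-finder, so the truth is consistent with the emitted tracks by
construction but independent of the extraction code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io import PHASES, MarkerTrack, PeckTrial


class SimulationError(ValueError):
    pass


@dataclass
class SpeciesParams:
    """Morphometric and kinematic parameters of the simulated species.

    Lengths in cm, durations in seconds, frame_rate in frames/s. The bill
    extension is only applied in phases whose :class:`PhaseEffects` say the
    artificial bill is attached.
    """

    name: str
    bill_length: float
    extension_length: float
    fixation_distance_mean: float
    fixation_distance_sd: float
    reach_duration: float
    peak_aperture: float
    offset_aperture: float
    rest_aperture: float
    open_trigger_cm: float
    open_duration: float
    close_duration: float
    approach_distance: float
    approach_duration: float
    start_angle_deg: float
    end_angle_deg: float
    arc_bulge: float
    base_success_logit: float
    food_size_cm: float
    frame_rate: float = 300.0
    marker_noise_sd: float = 0.05
    still_frames_range: tuple[int, int] = (58, 63)
    tail_s: float = 0.10

    def __post_init__(self) -> None:
        if min(self.bill_length, self.fixation_distance_mean, self.reach_duration,
               self.peak_aperture, self.frame_rate) <= 0:
            raise SimulationError("lengths, durations and frame rate must be positive")
        if self.extension_length < 0 or self.marker_noise_sd < 0:
            raise SimulationError("extension_length and noise sd must be >= 0")


def pigeon_params(**overrides) -> SpeciesParams:
    """Pigeon defaults: 2.3 cm bill + 1 cm artificial extension (43%)."""
    p = SpeciesParams(
        name="pigeon", bill_length=2.3, extension_length=1.0,
        fixation_distance_mean=8.0, fixation_distance_sd=0.7,
        reach_duration=0.50, peak_aperture=1.2, offset_aperture=0.35,
        rest_aperture=0.15, open_trigger_cm=3.0, open_duration=0.25,
        close_duration=0.13, approach_distance=3.0, approach_duration=0.70,
        start_angle_deg=25.0, end_angle_deg=40.0, arc_bulge=0.12,
        base_success_logit=2.2, food_size_cm=0.35,
    )
    return replace(p, **overrides) if overrides else p


def crow_params(**overrides) -> SpeciesParams:
    """Crow defaults: 6.5 cm bill + 2 cm artificial extension (31%)."""
    p = SpeciesParams(
        name="crow", bill_length=6.5, extension_length=2.0,
        fixation_distance_mean=15.0, fixation_distance_sd=1.2,
        reach_duration=0.55, peak_aperture=2.4, offset_aperture=0.8,
        rest_aperture=0.30, open_trigger_cm=3.0, open_duration=0.25,
        close_duration=0.15, approach_distance=4.0, approach_duration=0.70,
        start_angle_deg=25.0, end_angle_deg=40.0, arc_bulge=0.12,
        base_success_logit=2.2, food_size_cm=0.8,
    )
    return replace(p, **overrides) if overrides else p


@dataclass
class PhaseEffects:
    """Phase-dependent perturbations applied to the generated pecks.

    ``onset_shift`` delays (positive) or advances (negative) the opening of
    the bill in seconds; ``after_effect`` is the motor after-effect applied on
    extension removal (an advanced onset, so usually negative);
    ``distance_shift`` moves the mean fixation distance (negative = reach
    initiated closer to the target); ``success_logit_shift`` moves the success
    probability on the logit scale; ``bill_extended`` attaches the artificial
    bill extension.
    """

    onset_shift: float = 0.0
    distance_shift: float = 0.0
    success_logit_shift: float = 0.0
    after_effect: float = 0.0
    bill_extended: bool = False


@dataclass
class GroundTruth:
    """Per-peck generative truth, consistent with the emitted tracks."""

    trial_id: str
    individual: str
    phase: str
    fixation_frame: int
    onset_frame: int
    offset_frame: int
    onset_s: float
    path_length_cm: float
    mean_velocity_cm_s: float
    mean_accel_cm_s2: float
    success_prob: float
    individual_intercept: float
    bill_eff_cm: float
    fixation_distance_cm: float


def _minjerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _bezier_arc(S: np.ndarray, E: np.ndarray, bulge: float, m: int = 2001):
    """Quadratic Bezier from S to E bulging upward; returns dense samples,
    cumulative arc length and tangents."""
    chord = E - S
    nhat = np.array([-chord[1], chord[0]])
    nhat = nhat / np.linalg.norm(nhat)
    if nhat[1] < 0:
        nhat = -nhat
    C = (S + E) / 2 + bulge * np.linalg.norm(chord) * nhat
    t = np.linspace(0.0, 1.0, m)[:, None]
    pts = (1 - t) ** 2 * S + 2 * (1 - t) * t * C + t**2 * E
    dp = 2 * (1 - t) * (C - S) + 2 * t * (E - C)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    tang = dp / np.linalg.norm(dp, axis=1, keepdims=True)
    return pts, cum, tang


def _run_start(v: np.ndarray, threshold: float, min_len: int) -> int:
    """Independent re-statement of the fixation rule for ground truth."""
    peak = int(np.argmax(v))
    end = len(v) if v[peak] < threshold else peak
    best = None
    start = None
    for i in range(end + 1):
        below = i < end and v[i] < threshold
        if below and start is None:
            start = i
        elif not below and start is not None:
            if i - start >= min_len:
                best = start
            start = None
    if best is None:
        raise SimulationError("generated peck has no detectable standstill")
    return best


def simulate_peck(
    sp: SpeciesParams,
    fx: PhaseEffects = PhaseEffects(),
    individual_intercept: float = 0.0,
    rng_seed: int | np.random.SeedSequence | None = 0,
    trial_id: str = "sim-0",
    individual: str = "bird1",
    phase: str = "control",
    session: int = 0,
    peck_order: int = 1,
    target_position: Optional[int] = None,
) -> tuple[PeckTrial, GroundTruth]:
    """Generate one peck and its ground truth."""
    rng = np.random.default_rng(rng_seed)
    fps = sp.frame_rate
    dt = 1.0 / fps
    bill_eff = sp.bill_length + (sp.extension_length if fx.bill_extended else 0.0)

    d_mean = sp.fixation_distance_mean + fx.distance_shift
    d_min = bill_eff + sp.open_trigger_cm + 0.5
    D = 0.0
    for _ in range(200):
        D = rng.normal(d_mean, sp.fixation_distance_sd)
        if D > d_min:
            break
    else:
        raise SimulationError(
            f"cannot draw a fixation distance > {d_min:.2f} cm "
            f"(mean {d_mean:.2f}); onset would fall outside the reach"
        )

    phi0 = math.radians(sp.start_angle_deg)
    phi1 = math.radians(sp.end_angle_deg)
    S = np.array([-D * math.cos(phi0), D * math.sin(phi0)])
    E = np.array([-bill_eff * math.cos(phi1), bill_eff * math.sin(phi1)])
    pts, cum, tang = _bezier_arc(S, E, sp.arc_bulge)
    L = cum[-1]
    if L <= sp.open_trigger_cm:
        raise SimulationError("reach path shorter than the opening trigger distance")

    # opening start: remaining path-to-go == trigger distance, plus shifts
    s_trig = L - sp.open_trigger_cm
    tau_grid = np.linspace(0, 1, 4001)
    tau_trig = float(np.interp(s_trig / L, _minjerk(tau_grid), tau_grid))
    t_open = tau_trig * sp.reach_duration + fx.onset_shift + fx.after_effect
    # Snap the analytic 20% crossing to the centre of a frame interval
    # (< half-frame shift) so the discrete onset landmark is insensitive to
    # sub-frame measurement bias from filtering.
    u20 = math.acos(1.0 - 2 * 0.20) / math.pi
    t_cross_frames = (t_open + u20 * sp.open_duration) * fps
    t_open += (math.floor(t_cross_frames) + 0.5 - t_cross_frames) * dt
    t_peak = t_open + sp.open_duration
    t_close_end = t_peak + sp.close_duration
    if t_open < 0.02:
        raise SimulationError("grasping onset would precede the reach")

    n_app = int(round(sp.approach_duration * fps))
    n_still = int(rng.integers(*sp.still_frames_range))
    n_reach = int(round(sp.reach_duration * fps))
    n_tail = int(round((max(0.0, t_close_end - sp.reach_duration) + sp.tail_s) * fps))
    if t_close_end > sp.reach_duration + n_tail * dt:
        raise SimulationError("grasping would not finish within the recording")
    n_total = n_app + n_still + n_reach + n_tail

    t = np.arange(n_total) * dt
    reach_start = n_app + n_still

    # head path -----------------------------------------------------------
    head = np.empty((n_total, 2))
    app_dir = S / np.linalg.norm(S)  # approach from farther out, same radial
    A = S + sp.approach_distance * app_dir
    tau_a = np.clip(np.arange(n_app) / (sp.approach_duration * fps), 0, 1)
    head[:n_app] = A + (_minjerk(tau_a)[:, None]) * (S - A)
    head[n_app:reach_start] = S
    tau_r = np.clip((np.arange(n_reach + n_tail)) / (sp.reach_duration * fps), 0, 1)
    s_r = _minjerk(tau_r) * L
    idx = np.searchsorted(cum, s_r).clip(1, len(cum) - 1)
    w = (s_r - cum[idx - 1]) / np.maximum(cum[idx] - cum[idx - 1], 1e-12)
    head[reach_start:] = pts[idx - 1] + w[:, None] * (pts[idx] - pts[idx - 1])
    heading = np.empty((n_total, 2))
    heading[:reach_start] = tang[0]
    heading[reach_start:] = tang[idx.clip(0, len(tang) - 1)]

    # aperture profile ----------------------------------------------------
    tr = t - reach_start * dt  # time from reach start
    ap = np.full(n_total, sp.rest_aperture)
    rise = (tr >= t_open) & (tr < t_peak)
    u = (tr[rise] - t_open) / sp.open_duration
    ap[rise] = sp.rest_aperture + (sp.peak_aperture - sp.rest_aperture) * (1 - np.cos(np.pi * u)) / 2
    fall = (tr >= t_peak) & (tr < t_close_end)
    u = (tr[fall] - t_peak) / sp.close_duration
    ap[fall] = sp.offset_aperture + (sp.peak_aperture - sp.offset_aperture) * (1 + np.cos(np.pi * u)) / 2
    ap[tr >= t_close_end] = sp.offset_aperture

    # bill tips: rotate +-half-aperture-angle so tip-to-head == bill_eff
    half = np.arcsin(np.clip(ap / (2 * bill_eff), -1, 1))
    cos_h, sin_h = np.cos(half), np.sin(half)
    hx, hy = heading[:, 0], heading[:, 1]
    upper = head + bill_eff * np.column_stack([hx * cos_h - hy * sin_h,
                                               hx * sin_h + hy * cos_h])
    lower = head + bill_eff * np.column_stack([hx * cos_h + hy * sin_h,
                                               -hx * sin_h + hy * cos_h])

    # ground truth from the noiseless sampled kinematics ------------------
    v = np.hypot(*np.diff(head, axis=0).T) * fps
    fix = _run_start(v, 2.0, 10)
    a0 = ap[fix]
    amax = ap.max()
    if amax - a0 <= 1e-9:
        raise SimulationError("generated aperture never opens")
    thr = a0 + 0.20 * (amax - a0)
    onset = fix + int(np.argmax(ap[fix:] >= thr))
    imax = fix + int(np.argmax(ap[fix:]))
    offset = imax + int(np.argmin(ap[imax:]))
    path_on = float(np.hypot(*np.diff(head[fix:onset + 1], axis=0).T).sum())
    path = float(np.hypot(*np.diff(head[fix:offset + 1], axis=0).T).sum())
    onset_s = (onset - fix) / fps
    vel = path_on / onset_s if onset > fix else 0.0
    acc = float((v[onset - 1] - v[fix]) / ((onset - 1 - fix) * dt)) if onset - fix >= 2 else 0.0

    logit = sp.base_success_logit + fx.success_logit_shift + individual_intercept
    p_succ = 1.0 / (1.0 + math.exp(-logit))
    success = bool(rng.random() < p_succ)

    noise = rng.normal(size=(3, n_total, 2)) * sp.marker_noise_sd
    frames = np.arange(n_total)
    tracks = {
        "head": MarkerTrack("head", frames, *(head + noise[0]).T, frame_rate=fps),
        "upper_tip": MarkerTrack("upper_tip", frames, *(upper + noise[1]).T, frame_rate=fps),
        "lower_tip": MarkerTrack("lower_tip", frames, *(lower + noise[2]).T, frame_rate=fps),
    }
    trial = PeckTrial(
        trial_id=trial_id, species=sp.name, individual=individual, phase=phase,
        session=session, peck_order=peck_order, target_position=target_position,
        food_size_cm=sp.food_size_cm, outcome="success" if success else "failure",
        tracks=tracks,
    )
    truth = GroundTruth(
        trial_id=trial_id, individual=individual, phase=phase,
        fixation_frame=int(fix), onset_frame=int(onset), offset_frame=int(offset),
        onset_s=onset_s,
        path_length_cm=path, mean_velocity_cm_s=vel, mean_accel_cm_s2=acc,
        success_prob=p_succ, individual_intercept=individual_intercept,
        bill_eff_cm=bill_eff, fixation_distance_cm=float(D),
    )
    return trial, truth


# ---------------------------------------------------------------------------
# whole experiments


#: Per-phase peck totals (all individuals pooled) matching the study design:
#: 974 pecks from three pigeons, 378 from three crows.
PIGEON_PHASE_COUNTS = {
    "control": 118, "S1": 49, "S2-4": 221, "S5-7": 218, "S8-10": 231,
    "removal": 84, "follow-up": 53,
}
CROW_PHASE_COUNTS = {
    "control": 80, "S1": 23, "S2-4": 61, "S5-7": 65, "S8-10": 88,
    "removal": 30, "follow-up": 31,
}

_PHASE_SESSIONS = {
    "control": 0, "S1": 1, "S2-4": 3, "S5-7": 6, "S8-10": 9,
    "removal": 11, "follow-up": 12,
}


@dataclass
class ExperimentConfig:
    """Design of a simulated experiment."""

    params: SpeciesParams
    n_individuals: int = 3
    pecks_per_phase: dict = field(default_factory=lambda: {p: 20 for p in PHASES})
    phase_effects: dict = field(default_factory=dict)
    sigma_u: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or not self.pecks_per_phase:
            raise SimulationError("need >= 1 individual and >= 1 phase")
        bad = set(self.pecks_per_phase) - set(PHASES)
        if bad:
            raise SimulationError(f"unknown phase(s) {sorted(bad)}")


def pigeon_like_config(seed: int = 0, scale: float = 1.0) -> ExperimentConfig:
    """Pigeon-style experiment: a persistent success deficit and delayed
    grasping onset across all bill-extension phases, and a motor after-effect
    (advanced onset, continued poor success) immediately after removal."""
    counts = {p: max(6, int(round(c * scale))) for p, c in PIGEON_PHASE_COUNTS.items()}
    ext = dict(bill_extended=True, success_logit_shift=-2.9, onset_shift=0.03)
    effects = {
        "control": PhaseEffects(),
        "S1": PhaseEffects(**ext),
        "S2-4": PhaseEffects(**ext),
        "S5-7": PhaseEffects(**ext),
        "S8-10": PhaseEffects(**ext),
        "removal": PhaseEffects(success_logit_shift=-2.5, after_effect=-0.04),
        "follow-up": PhaseEffects(),
    }
    return ExperimentConfig(params=pigeon_params(), pecks_per_phase=counts,
                            phase_effects=effects, sigma_u=0.4, seed=seed)


def crow_like_config(seed: int = 0, scale: float = 1.0) -> ExperimentConfig:
    """Crow-style experiment: a transient success deficit in S1 only, pecking
    initiated from closer distances in S1 to S5-7, and no after-effect."""
    counts = {p: max(6, int(round(c * scale))) for p, c in CROW_PHASE_COUNTS.items()}
    effects = {
        "control": PhaseEffects(),
        "S1": PhaseEffects(bill_extended=True, success_logit_shift=-2.5,
                           onset_shift=0.02, distance_shift=-1.0),
        "S2-4": PhaseEffects(bill_extended=True, distance_shift=-1.0),
        "S5-7": PhaseEffects(bill_extended=True, distance_shift=-1.0),
        "S8-10": PhaseEffects(bill_extended=True, distance_shift=2.0),
        "removal": PhaseEffects(),
        "follow-up": PhaseEffects(),
    }
    return ExperimentConfig(params=crow_params(), pecks_per_phase=counts,
                            phase_effects=effects, sigma_u=0.4, seed=seed)


def simulate_experiment(config: ExperimentConfig) -> tuple[list[PeckTrial], pd.DataFrame]:
    """Generate a full trial collection plus its ground-truth table.

    Pecks are distributed round-robin across individuals within each phase;
    per-individual random intercepts are N(0, sigma_u) on the success logit.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sp = config.params
    individuals = [f"{sp.name[0]}{i + 1}" for i in range(config.n_individuals)]
    intercepts = rng.normal(0.0, config.sigma_u, size=config.n_individuals)
    trials: list[PeckTrial] = []
    truths: list[GroundTruth] = []
    phase_list = [p for p in PHASES if p in config.pecks_per_phase]
    child_seeds = ss.spawn(sum(config.pecks_per_phase[p] for p in phase_list))
    k = 0
    for phase in phase_list:
        fx = config.phase_effects.get(phase, PhaseEffects())
        n = config.pecks_per_phase[phase]
        for j in range(n):
            i_ind = j % config.n_individuals
            tid = f"{sp.name[:2]}-{phase}-{j:04d}"
            is_pigeon = sp.name == "pigeon"
            trial, truth = simulate_peck(
                sp, fx, float(intercepts[i_ind]), rng_seed=child_seeds[k],
                trial_id=tid, individual=individuals[i_ind], phase=phase,
                session=_PHASE_SESSIONS[phase],
                peck_order=(j % 10) + 1 if is_pigeon else 1,
                target_position=((j * 7) % 10) + 1 if is_pigeon else None,
            )
            trials.append(trial)
            truths.append(truth)
            k += 1
    import dataclasses

    truth_df = pd.DataFrame([dataclasses.asdict(t) for t in truths])
    return trials, truth_df
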