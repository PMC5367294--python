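"""Trial I/O: marker-track files, trial metadata and tidy result tables.

Coordinate conventions used throughout the package: the target food sits at
the origin, x is positive from the bird toward the target, y is positive
upward, all lengths are in cm, times in seconds and frame indices 0-based.
Tracks are stored long ("tidy"): one row per (trial, frame, marker). Missing
frames are represented by absent rows, never by sentinel values; downstream
code decides whether a gap invalidates a peck.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: The seven experimental phases, in design order. ``control`` is the
#: reference level everywhere a phase factor enters a model.
PHASES: tuple[str, ...] = (
    "control", "S1", "S2-4", "S5-7", "S8-10", "removal", "follow-up",
)

MARKER_ROLES: tuple[str, ...] = ("head", "upper_tip", "lower_tip")

TRACK_COLUMNS = ["trial_id", "frame", "marker", "x_cm", "y_cm"]
TRIAL_COLUMNS = [
    "trial_id", "species", "individual", "phase", "session",
    "peck_order", "target_position", "food_size_cm", "outcome",
]

#: Schema of kinematics.csv (one row per peck entering/failing the analysis).
KINEMATICS_COLUMNS = [
    "trial_id", "species", "individual", "phase", "session", "peck_order",
    "target_position", "outcome", "onset_s", "distance_cm", "velocity_cm_s",
    "accel_cm_s2", "retained", "exclusion_reason",
]


class FormatError(ValueError):
    """A delimited input file does not conform to the expected schema."""


@dataclass
class MarkerTrack:
    """One marker's (x, y) series at a fixed frame rate.

    ``frames`` are strictly increasing integer frame indices; gaps (missing
    frames) are allowed and appear as jumps larger than one.
    """

    marker_name: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float = 300.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x and y must have equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError(
                f"frame indices must be strictly increasing (marker "
                f"{self.marker_name!r})"
            )
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"non-finite coordinates in marker {self.marker_name!r}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of xy positions in cm."""
        return np.column_stack([self.x, self.y])

    @property
    def has_gaps(self) -> bool:
        return len(self.frames) > 1 and bool(np.any(np.diff(self.frames) > 1))

    def gap_frames(self) -> np.ndarray:
        """Frame indices that are missing inside the track's span."""
        if len(self.frames) == 0:
            return np.empty(0, dtype=np.int64)
        full = np.arange(self.frames[0], self.frames[-1] + 1)
        return np.setdiff1d(full, self.frames)

    def window(self, start_frame: int, end_frame: int) -> "MarkerTrack":
        """Sub-track with start_frame <= frame <= end_frame (rows only)."""
        m = (self.frames >= start_frame) & (self.frames <= end_frame)
        return replace(self, frames=self.frames[m], x=self.x[m], y=self.y[m])


@dataclass
class PeckTrial:
    """A single peck: three marker tracks plus metadata and outcome."""

    trial_id: str
    species: str
    individual: str
    phase: str
    session: int
    peck_order: int
    target_position: Optional[int]
    food_size_cm: float
    outcome: str
    tracks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in ("pigeon", "crow"):
            raise ValueError(f"unknown species {self.species!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if self.outcome not in ("success", "failure"):
            raise ValueError(f"outcome must be success/failure, got {self.outcome!r}")
        missing = [r for r in MARKER_ROLES if r not in self.tracks]
        if missing:
            raise ValueError(f"trial {self.trial_id!r} missing marker role(s) {missing}")
        rates = {self.tracks[r].frame_rate for r in MARKER_ROLES}
        if len(rates) != 1:
            raise ValueError(f"trial {self.trial_id!r}: tracks disagree on frame_rate")

    @property
    def frame_rate(self) -> float:
        return self.tracks["head"].frame_rate

    @property
    def success(self) -> int:
        return int(self.outcome == "success")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_trials(track_path, metadata_path, frame_rate: float = 300.0) -> list[PeckTrial]:
    """Read tracks.csv + trials.csv into a list of :class:`PeckTrial`.

    Gaps in the frame series are preserved as missing rows and never
    interpolated here.
    """
    tracks = pd.read_csv(track_path, float_precision="round_trip")
    meta = pd.read_csv(metadata_path, float_precision="round_trip")
    _require_columns(tracks, TRACK_COLUMNS, track_path)
    _require_columns(meta, TRIAL_COLUMNS, metadata_path)

    if len(tracks):
        dup = tracks.duplicated(subset=["trial_id", "marker", "frame"])
        if dup.any():
            rows = tracks.loc[dup, ["trial_id", "marker", "frame"]].head(5)
            raise FormatError(
                f"{track_path}: duplicate (trial_id, marker, frame) rows, e.g.\n{rows}"
            )
        bad = set(tracks["marker"]) - set(MARKER_ROLES)
        if bad:
            raise FormatError(f"{track_path}: unknown marker role(s) {sorted(bad)}")

    grouped = {k: g for k, g in tracks.groupby(["trial_id", "marker"], sort=False)}
    missing_ids = [
        tid for tid in meta["trial_id"]
        if not any((tid, role) in grouped for role in MARKER_ROLES)
    ]
    if missing_ids:
        raise FormatError(
            f"{metadata_path}: trial(s) with no track rows: {missing_ids}"
        )

    trials: list[PeckTrial] = []
    for row in meta.itertuples(index=False):
        tid = row.trial_id
        tr = {}
        for role in MARKER_ROLES:
            g = grouped.get((tid, role))
            if g is None:
                raise FormatError(
                    f"{track_path}: trial {tid!r} has no rows for marker {role!r}"
                )
            g = g.sort_values("frame")
            tr[role] = MarkerTrack(
                marker_name=role,
                frames=g["frame"].to_numpy(),
                x=g["x_cm"].to_numpy(),
                y=g["y_cm"].to_numpy(),
                frame_rate=frame_rate,
            )
        tp = row.target_position
        trials.append(
            PeckTrial(
                trial_id=str(tid),
                species=str(row.species),
                individual=str(row.individual),
                phase=str(row.phase),
                session=int(row.session),
                peck_order=int(row.peck_order),
                target_position=None if pd.isna(tp) else int(tp),
                food_size_cm=float(row.food_size_cm),
                outcome=str(row.outcome),
                tracks=tr,
            )
        )
    return trials


def write_trials(trials: Iterable[PeckTrial], track_path, metadata_path) -> None:
    """Write trials back to the tracks.csv / trials.csv long formats."""
    track_rows = []
    meta_rows = []
    for t in trials:
        meta_rows.append(
            {
                "trial_id": t.trial_id,
                "species": t.species,
                "individual": t.individual,
                "phase": t.phase,
                "session": t.session,
                "peck_order": t.peck_order,
                "target_position": t.target_position,
                "food_size_cm": t.food_size_cm,
                "outcome": t.outcome,
            }
        )
        for role in MARKER_ROLES:
            mk = t.tracks[role]
            for f, x, y in zip(mk.frames, mk.x, mk.y):
                track_rows.append(
                    {"trial_id": t.trial_id, "frame": int(f), "marker": role,
                     "x_cm": x, "y_cm": y}
                )
    pd.DataFrame(track_rows, columns=TRACK_COLUMNS).to_csv(
        track_path, index=False, float_format="%.17g")
    meta_df = pd.DataFrame(meta_rows, columns=TRIAL_COLUMNS)
    meta_df["target_position"] = meta_df["target_position"].astype("Int64")
    meta_df.to_csv(metadata_path, index=False, float_format="%.17g")


def write_results(records, path, columns: Optional[Sequence[str]] = None) -> None:
    """Write a tidy delimited table, one row per record, full precision.

    ``records`` may be a DataFrame, a sequence of dataclasses, or a sequence
    of mappings sharing one schema. An empty sequence needs ``columns`` to
    produce a header-only file.
    """
    import dataclasses

    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for r in records:
            rows.append(dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r))
        if rows:
            df = pd.DataFrame(rows, columns=columns or list(rows[0].keys()))
        else:
            df = pd.DataFrame(columns=list(columns or []))
    df.to_csv(path, index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
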