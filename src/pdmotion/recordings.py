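"""Data model and CSV I/O for multi-sensor acceleration sessions.

A recording session consists of up to five tri-axial accelerometers worn on
the wrists, ankles and chest, sampled at 51.2 or 62.5 Hz within a +/-6 g
range, plus a list of labeled activity intervals obtained by video-assisted
tagging.  Sessions are stored as a wide CSV (one row per time instant, one
column per sensor axis) and a labels CSV of ``start_s,end_s,label`` rows.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACCEL_RANGE_G = 6.0
STANDARD_RATES_HZ = (51.2, 62.5)

AXES = ("x", "y", "z")


class SensorPlacement(str, enum.Enum):
    """Body site of an accelerometer; exactly five sites are valid."""

    LEFT_WRIST = "left_wrist"
    RIGHT_WRIST = "right_wrist"
    LEFT_ANKLE = "left_ankle"
    RIGHT_ANKLE = "right_ankle"
    CHEST = "chest"


#: Canonical ordering of sites used for feature-vector layout and CSV columns.
SITE_ORDER = (
    SensorPlacement.LEFT_WRIST,
    SensorPlacement.RIGHT_WRIST,
    SensorPlacement.LEFT_ANKLE,
    SensorPlacement.RIGHT_ANKLE,
    SensorPlacement.CHEST,
)


class ActivityLabel(str, enum.Enum):
    """Closed vocabulary of the recording-protocol activities."""

    WALK = "walk"
    LIFT_OBJECT_LEFT = "lift_object_left"
    LIFT_OBJECT_RIGHT = "lift_object_right"
    LIFT_OBJECT_BOTH = "lift_object_both"
    LIFT_HAND_LEFT = "lift_hand_left"
    LIFT_HAND_RIGHT = "lift_hand_right"
    LIFT_HAND_BOTH = "lift_hand_both"
    SIT_STAND = "sit_stand"
    LIE_RISE = "lie_rise"
    STAND = "stand"
    SIT = "sit"
    LIE = "lie"


#: Gait-task collapse: walking vs everything else.
GAIT_CLASS = "gait"
NO_GAIT_CLASS = "no_gait"

#: Hand-task collapse: which side(s) move, or no hand movement.
HAND_LEFT = "left"
HAND_RIGHT = "right"
HAND_BOTH = "both"
HAND_NONE = "no_movement"

HAND_CLASSES = (HAND_LEFT, HAND_RIGHT, HAND_BOTH, HAND_NONE)
GAIT_CLASSES = (GAIT_CLASS, NO_GAIT_CLASS)

_HAND_MAP = {
    ActivityLabel.LIFT_OBJECT_LEFT: HAND_LEFT,
    ActivityLabel.LIFT_HAND_LEFT: HAND_LEFT,
    ActivityLabel.LIFT_OBJECT_RIGHT: HAND_RIGHT,
    ActivityLabel.LIFT_HAND_RIGHT: HAND_RIGHT,
    ActivityLabel.LIFT_OBJECT_BOTH: HAND_BOTH,
    ActivityLabel.LIFT_HAND_BOTH: HAND_BOTH,
}

#: Activities during which the subject is upright, so the chest x axis
#: (vertical by mounting convention) carries the +1 g gravity component.
UPRIGHT_ACTIVITIES = frozenset(
    a for a in ActivityLabel if a not in (ActivityLabel.LIE,)
)


def gait_class(label: ActivityLabel | None) -> str:
    return GAIT_CLASS if label is ActivityLabel.WALK else NO_GAIT_CLASS


def hand_class(label: ActivityLabel | None) -> str:
    if label is None:
        return HAND_NONE
    return _HAND_MAP.get(label, HAND_NONE)


@dataclass
class TriaxialRecording:
    """One accelerometer's 3xN sample matrix in g, with its rate and site."""

    placement: SensorPlacement
    fs: float
    samples: np.ndarray  # shape (3, N), axes x, y, z

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 3:
            raise ValueError("samples must be a 3xN matrix (axes x, y, z)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not any(np.isclose(self.fs, r) for r in STANDARD_RATES_HZ):
            warnings.warn(
                f"non-standard sampling rate {self.fs} Hz "
                f"(devices record at {STANDARD_RATES_HZ})",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def axis(self, name: str) -> np.ndarray:
        return self.samples[AXES.index(name)]


@dataclass
class LabeledSession:
    """A subject's multi-sensor recording plus activity-interval labels.

    All recordings share a common time origin; intervals are half-open
    ``[start_s, end_s)`` seconds from session start, non-overlapping, sorted.
    """

    subject_id: str
    recordings: dict[SensorPlacement, TriaxialRecording]
    intervals: list[tuple[float, float, ActivityLabel]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[SensorPlacement] = set()
        for site, rec in self.recordings.items():
            if site is not rec.placement:
                raise ValueError(f"recording at key {site} has placement {rec.placement}")
            if site in seen:
                raise ValueError(f"duplicate sensor site {site}")
            seen.add(site)
        self.intervals = sorted(self.intervals, key=lambda iv: iv[0])
        validate_intervals(self.intervals)

    @property
    def sites(self) -> tuple[SensorPlacement, ...]:
        return tuple(s for s in SITE_ORDER if s in self.recordings)

    def label_at(self, t: float) -> ActivityLabel | None:
        for start, end, lab in self.intervals:
            if start <= t < end:
                return lab
        return None

    def duration_s(self) -> float:
        if not self.recordings:
            return 0.0
        return max(r.n_samples / r.fs for r in self.recordings.values())


def validate_intervals(intervals: list[tuple[float, float, ActivityLabel]]) -> None:
    prev_end = -np.inf
    prev = None
    for start, end, lab in intervals:
        if not isinstance(lab, ActivityLabel):
            raise ValueError(f"unknown activity label {lab!r}")
        if start >= end:
            raise ValueError(f"empty or inverted interval ({start}, {end}, {lab.value})")
        if start < prev_end:
            raise ValueError(
                f"overlapping intervals: {prev} and ({start}, {end}, {lab.value})"
            )
        prev_end = end
        prev = (start, end, lab.value)


def _column_name(site: SensorPlacement, axis: str) -> str:
    return f"{site.value}_{axis}"


def write_session(
    session: LabeledSession, session_file: str | Path, labels_file: str | Path
) -> None:
    """Write a session as a wide CSV plus a ``start_s,end_s,label`` CSV."""
    sites = session.sites
    if not sites:
        raise ValueError("session has no recordings")
    lengths = {session.recordings[s].n_samples for s in sites}
    rates = {session.recordings[s].fs for s in sites}
    if len(lengths) != 1 or len(rates) != 1:
        raise ValueError(
            "a session file holds sensors sharing one rate and length; "
            "store other rates in separate files"
        )
    fs = rates.pop()
    n = lengths.pop()
    data = {"time_s": np.arange(n) / fs}
    for site in sites:
        for k, axis in enumerate(AXES):
            data[_column_name(site, axis)] = session.recordings[site].samples[k]
    pd.DataFrame(data).to_csv(session_file, index=False, float_format="%.9g")
    labels = pd.DataFrame(
        [(s, e, lab.value) for s, e, lab in session.intervals],
        columns=["start_s", "end_s", "label"],
    )
    labels.to_csv(labels_file, index=False, float_format="%.9g")


def read_session(
    session_file: str | Path,
    labels_file: str | Path,
    subject_id: str | None = None,
    strict: bool = False,
) -> LabeledSession:
    """Read and validate a session CSV pair.

    Samples outside +/-6 g are clamped with a logged warning (sensor
    saturation); with ``strict=True`` they raise instead.  Unknown columns
    are rejected.
    """
    df = pd.read_csv(session_file)
    if "time_s" not in df.columns:
        raise ValueError("session CSV must have a time_s column")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("session must contain at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time_s must be strictly increasing")
    fs = 1.0 / float(np.median(dt))
    for std_rate in STANDARD_RATES_HZ:
        if abs(fs - std_rate) / std_rate < 5e-3:
            fs = std_rate
            break

    valid_cols = {
        _column_name(site, axis): (site, axis) for site in SITE_ORDER for axis in AXES
    }
    per_site: dict[SensorPlacement, dict[str, np.ndarray]] = {}
    for col in df.columns:
        if col == "time_s":
            continue
        if col not in valid_cols:
            raise ValueError(f"unknown column {col!r} in session CSV")
        site, axis = valid_cols[col]
        per_site.setdefault(site, {})[col.rsplit("_", 1)[-1]] = df[col].to_numpy(float)

    recordings: dict[SensorPlacement, TriaxialRecording] = {}
    for site, axes in per_site.items():
        missing = [a for a in AXES if a not in axes]
        if missing:
            raise ValueError(f"sensor {site.value} missing axes {missing}")
        mat = np.vstack([axes[a] for a in AXES])
        n_oob = int(np.sum(np.abs(mat) > ACCEL_RANGE_G))
        if n_oob:
            if strict:
                raise ValueError(
                    f"{n_oob} samples outside +/-{ACCEL_RANGE_G} g for {site.value}"
                )
            logger.warning(
                "clamping %d out-of-range samples to +/-%.0f g for %s",
                n_oob,
                ACCEL_RANGE_G,
                site.value,
            )
            mat = np.clip(mat, -ACCEL_RANGE_G, ACCEL_RANGE_G)
        recordings[site] = TriaxialRecording(placement=site, fs=fs, samples=mat)

    labels_df = pd.read_csv(labels_file)
    expected = ["start_s", "end_s", "label"]
    if list(labels_df.columns) != expected:
        raise ValueError(f"labels CSV must have columns {expected}")
    intervals = []
    for _, row in labels_df.iterrows():
        try:
            lab = ActivityLabel(row["label"])
        except ValueError as exc:
            raise ValueError(f"unknown activity label {row['label']!r}") from exc
        intervals.append((float(row["start_s"]), float(row["end_s"]), lab))

    if subject_id is None:
        subject_id = Path(session_file).stem
    return LabeledSession(subject_id=subject_id, recordings=recordings, intervals=intervals)
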