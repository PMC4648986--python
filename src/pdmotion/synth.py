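"""Seeded generator of labeled multi-sensor sessions.

Emulates the recording protocol used to train the movement classifiers: a
scripted sequence of everyday activities (walking with a turn, lifting
objects/hands with either or both hands, sit/stand and lie/rise transitions,
static postures), each bracketed by static posture and repeated three times,
recorded by five tri-axial accelerometers at 51.2 or 62.5 Hz.

The signal model is deliberately simple — the goal is a generator whose
statistical structure exercises every downstream assumption, not a
biomechanical gait simulator:

* gravity: +1 g on the chest x axis while the subject is upright (the
  device's vertical mounting axis), moving to z while lying;
* gait: antiphase sinusoids at the subject's step frequency on the ankle
  forward axes plus an in-phase vertical component at twice that frequency
  (both feet strike the ground within one stride), attenuated on the chest;
* hand lifts: half-sine enveloped low-frequency bursts on the named wrist(s);
* parkinsonian tremor: a 4–6 Hz oscillation on both wrists, placed above the
  3 Hz analysis low-pass so filtering demonstrably removes it;
* white Gaussian sensor noise, then clipping to the +/-6 g sensor range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recordings import (
    ACCEL_RANGE_G,
    AXES,
    ActivityLabel,
    LabeledSession,
    SensorPlacement,
    SITE_ORDER,
    TriaxialRecording,
    UPRIGHT_ACTIVITIES,
)

__all__ = ["SubjectProfile", "ProtocolScript", "generate_session", "generate_cohort"]

_HAND_SIDES = {
    ActivityLabel.LIFT_OBJECT_LEFT: (SensorPlacement.LEFT_WRIST,),
    ActivityLabel.LIFT_HAND_LEFT: (SensorPlacement.LEFT_WRIST,),
    ActivityLabel.LIFT_OBJECT_RIGHT: (SensorPlacement.RIGHT_WRIST,),
    ActivityLabel.LIFT_HAND_RIGHT: (SensorPlacement.RIGHT_WRIST,),
    ActivityLabel.LIFT_OBJECT_BOTH: (
        SensorPlacement.LEFT_WRIST,
        SensorPlacement.RIGHT_WRIST,
    ),
    ActivityLabel.LIFT_HAND_BOTH: (
        SensorPlacement.LEFT_WRIST,
        SensorPlacement.RIGHT_WRIST,
    ),
}

_TRANSITIONS = (ActivityLabel.SIT_STAND, ActivityLabel.LIE_RISE)


@dataclass
class SubjectProfile:
    """Per-subject signal parameters; amplitudes in g, frequencies in Hz."""

    gait_freq_hz: float = 1.0  # step frequency; cohort draws U[0.8, 1.2]
    gait_amp_g: dict[SensorPlacement, float] = field(
        default_factory=lambda: {
            SensorPlacement.LEFT_ANKLE: 0.8,
            SensorPlacement.RIGHT_ANKLE: 0.8,
            SensorPlacement.CHEST: 0.25,
            SensorPlacement.LEFT_WRIST: 0.06,
            SensorPlacement.RIGHT_WRIST: 0.06,
        }
    )
    hand_amp_g: float = 0.5
    tremor_freq_hz: float = 5.0  # cohort draws U[4, 6]; must stay above 3 Hz
    tremor_amp_g: float = 0.1
    noise_std_g: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tremor_freq_hz <= 3.0:
            raise ValueError("tremor frequency must exceed the 3 Hz analysis band")
        amps = [self.hand_amp_g, self.tremor_amp_g, self.noise_std_g]
        amps += list(self.gait_amp_g.values())
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be non-negative")


def _default_steps() -> list[tuple[ActivityLabel, float]]:
    A = ActivityLabel
    return [
        (A.STAND, 5.0),
        (A.WALK, 12.0),
        (A.STAND, 3.0),
        (A.LIFT_OBJECT_LEFT, 4.0),
        (A.LIFT_OBJECT_RIGHT, 4.0),
        (A.LIFT_OBJECT_BOTH, 4.0),
        (A.STAND, 3.0),
        (A.LIFT_HAND_LEFT, 4.0),
        (A.LIFT_HAND_RIGHT, 4.0),
        (A.LIFT_HAND_BOTH, 4.0),
        (A.STAND, 3.0),
        (A.SIT_STAND, 4.0),
        (A.SIT, 5.0),
        (A.LIE_RISE, 4.0),
        (A.LIE, 5.0),
        (A.STAND, 2.0),
    ]


@dataclass
class ProtocolScript:
    """Ordered activity steps, executed ``repetitions`` times in sequence."""

    steps: list[tuple[ActivityLabel, float]] = field(default_factory=_default_steps)
    repetitions: int = 3

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if any(d <= 0 for _, d in self.steps):
            raise ValueError("step durations must be positive")

    def expand(self) -> list[tuple[float, float, ActivityLabel]]:
        """Flatten repetitions into absolute half-open intervals."""
        intervals = []
        t = 0.0
        for _ in range(self.repetitions):
            for label, dur in self.steps:
                intervals.append((t, t + dur, label))
                t += dur
        return intervals

    def duration_s(self) -> float:
        return self.repetitions * sum(d for _, d in self.steps)


def generate_session(
    profile: SubjectProfile,
    script: ProtocolScript | None = None,
    fs: float = 51.2,
    subject_id: str = "synthetic",
) -> LabeledSession:
    """Render one subject's session; deterministic given ``profile.seed``."""
    script = script or ProtocolScript()
    if not script.steps:
        raise ValueError("empty protocol script")
    intervals = script.expand()
    n = int(round(script.duration_s() * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(profile.seed)

    sig = {site: np.zeros((3, n)) for site in SITE_ORDER}
    x_i, y_i, z_i = (AXES.index(a) for a in AXES)

    # persistent per-subject phases
    gait_phase = rng.uniform(0, 2 * np.pi)
    tremor_phase = rng.uniform(0, 2 * np.pi, size=2)

    for start, end, label in intervals:
        m = (t >= start) & (t < end)
        ts = t[m]
        dur = end - start
        # gravity on the chest vertical axis
        if label in UPRIGHT_ACTIVITIES:
            sig[SensorPlacement.CHEST][x_i, m] += 1.0
        else:  # lying: gravity along the axis parallel to the chest
            sig[SensorPlacement.CHEST][z_i, m] += 1.0

        if label is ActivityLabel.WALK:
            f = profile.gait_freq_hz
            w = 2 * np.pi * f * ts + gait_phase
            for site, sign in (
                (SensorPlacement.LEFT_ANKLE, 0.0),
                (SensorPlacement.RIGHT_ANKLE, np.pi),
            ):
                a = profile.gait_amp_g.get(site, 0.0)
                # forward swing: antiphase fundamental + small 2nd harmonic
                sig[site][z_i, m] += a * np.sin(w + sign) + 0.25 * a * np.sin(
                    2 * (w + sign)
                )
                # vertical: in-phase heel strikes at 2f + weak antiphase at f
                sig[site][x_i, m] += 0.6 * a * np.sin(2 * w) + 0.25 * a * np.sin(
                    w + sign
                )
                sig[site][y_i, m] += 0.15 * a * np.sin(w + sign)
            a_ch = profile.gait_amp_g.get(SensorPlacement.CHEST, 0.0)
            sig[SensorPlacement.CHEST][x_i, m] += a_ch * np.sin(2 * w)
            sig[SensorPlacement.CHEST][y_i, m] += 0.4 * a_ch * np.sin(w)
            for site, sign in (
                (SensorPlacement.LEFT_WRIST, np.pi),
                (SensorPlacement.RIGHT_WRIST, 0.0),
            ):
                a = profile.gait_amp_g.get(site, 0.0)
                sig[site][z_i, m] += a * np.sin(w + sign)  # arm swing
        elif label in _HAND_SIDES:
            env = np.sin(np.pi * (ts - start) / dur)  # half-sine lift envelope
            carrier = np.sin(2 * np.pi * 1.0 * (ts - start))
            for site in _HAND_SIDES[label]:
                a = profile.hand_amp_g
                sig[site][x_i, m] += 0.6 * a * env
                sig[site][y_i, m] += a * env * carrier
                sig[site][z_i, m] += 0.7 * a * env * np.cos(
                    2 * np.pi * 1.0 * (ts - start)
                )
            if label.value.startswith("lift_object"):
                sig[SensorPlacement.CHEST][y_i, m] += 0.15 * profile.hand_amp_g * env
        elif label in _TRANSITIONS:
            env = np.sin(np.pi * (ts - start) / dur)
            sig[SensorPlacement.CHEST][x_i, m] += 0.4 * env
            sig[SensorPlacement.CHEST][y_i, m] += 0.3 * env * np.sin(
                2 * np.pi * 0.8 * (ts - start)
            )

    # tremor rides on both wrists throughout ("off"-phase severity knob)
    for k, site in enumerate((SensorPlacement.LEFT_WRIST, SensorPlacement.RIGHT_WRIST)):
        tr = profile.tremor_amp_g * np.sin(
            2 * np.pi * profile.tremor_freq_hz * t + tremor_phase[k]
        )
        sig[site][y_i] += tr
        sig[site][z_i] += 0.7 * tr

    recordings = {}
    for site in SITE_ORDER:
        noisy = sig[site] + rng.normal(0.0, profile.noise_std_g, size=(3, n))
        recordings[site] = TriaxialRecording(
            placement=site,
            fs=fs,
            samples=np.clip(noisy, -ACCEL_RANGE_G, ACCEL_RANGE_G),
        )
    return LabeledSession(subject_id=subject_id, recordings=recordings, intervals=intervals)


def draw_profile(rng: np.random.Generator, seed: int) -> SubjectProfile:
    """Draw per-subject parameters from the cohort distributions."""
    return SubjectProfile(
        gait_freq_hz=rng.uniform(0.8, 1.2),
        tremor_freq_hz=rng.uniform(4.0, 6.0),
        tremor_amp_g=rng.uniform(0.05, 0.15),
        noise_std_g=0.05,
        seed=seed,
    )


def generate_cohort(
    n_subjects: int,
    base_seed: int = 0,
    fs: float = 51.2,
    script: ProtocolScript | None = None,
) -> list[LabeledSession]:
    """Generate ``n_subjects`` sessions with per-subject seeds ``base_seed + i``."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects (leave-one-subject-out)")
    sessions = []
    for i in range(n_subjects):
        seed_i = base_seed + i
        rng = np.random.default_rng(seed_i)
        profile = draw_profile(rng, seed=seed_i)
        sessions.append(
            generate_session(profile, script, fs=fs, subject_id=f"S{i:03d}")
        )
    return sessions
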