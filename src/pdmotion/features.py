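"""Time-domain and spectral frame parameters, and feature-vector assembly.

Each analysis frame of each sensor axis is summarised by six parameters —
mean, standard deviation, kurtosis, crest factor, spectral energy and
spectral entropy — plus Pearson correlations between the three axes of one
sensor and between the same axes of different sensors.  For ``s`` sensors
the vector length is ``21 s + 3 * C(s, 2)``: 21/45/72/135 for 1/2/3/5
sensors, of which 30 entries are inter-sensor correlations at s = 5.

Two of the printed formulas are kept in their literal (dimensionally odd)
form behind fidelity options:

* kurtosis divides the fourth central moment by the *squared* standard
  deviation (``krt = m4/std**2 - 3``); the ``standard`` option restores the
  usual excess kurtosis ``m4/std**4 - 3``;
* the correlation formula mixes a 1/N cross-moment with (N-1)-denominator
  standard deviations, so literal self-correlation is (N-1)/N; the default
  ``consistent`` mode is the ordinary Pearson estimator.

Zero-variance or zero-RMS frames make kurtosis/crest/correlation undefined;
those entries are emitted as NaN sentinels and replaced by 0 (with a logged
count) when vectors are assembled, since the classifiers need fixed-length
inputs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recordings import AXES, LabeledSession, SensorPlacement, SITE_ORDER
from .preprocess import FrameSpec, WindowedSession, filter_session, frame_session, label_frames

logger = logging.getLogger(__name__)

__all__ = [
    "FidelityOptions",
    "Spectrum",
    "FeatureVector",
    "Normalizer",
    "time_features",
    "correlation",
    "amplitude_spectrum",
    "spectral_features",
    "vector_layout",
    "vector_length",
    "assemble_vector",
    "featurize_session",
    "featurize_cohort",
    "fit_normalizer",
    "apply_normalizer",
]

#: Per-axis feature names, in canonical order.
AXIS_FEATURES = ("mean", "std", "kurtosis", "crest", "energy", "entropy")
AXIS_PAIRS = tuple(itertools.combinations(AXES, 2))

UNDEFINED = float("nan")


@dataclass(frozen=True)
class FidelityOptions:
    """Select between the literal printed formulas and their standard forms."""

    kurtosis: str = "as_printed"  # "as_printed" | "standard"
    correlation: str = "consistent"  # "consistent" | "as_printed"
    crest: str = "as_printed"  # "as_printed" (max) | "use_abs" (max |x|)
    entropy: str = "spectral"  # "spectral" | "histogram"

    @classmethod
    def as_printed(cls) -> "FidelityOptions":
        return cls(kurtosis="as_printed", correlation="as_printed", crest="as_printed")

    @classmethod
    def standard(cls) -> "FidelityOptions":
        return cls(kurtosis="standard", correlation="consistent", crest="use_abs")


@dataclass
class Spectrum:
    """One-sided amplitude spectrum, DC line excluded; K = floor(N/2) lines."""

    A: np.ndarray
    fs: float

    @property
    def K(self) -> int:
        return len(self.A)


def time_features(
    frame: np.ndarray, fidelity: FidelityOptions | None = None
) -> tuple[float, float, float, float]:
    """Mean, standard deviation (N-1), kurtosis and crest factor of a frame.

    Kurtosis is undefined (NaN) on zero-variance frames, crest on zero-RMS
    frames.
    """
    fidelity = fidelity or FidelityOptions()
    x = np.asarray(frame, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("frame must contain at least 4 samples")
    mean = float(np.mean(x))
    std = float(np.std(x, ddof=1))
    m4 = float(np.mean((x - mean) ** 4))
    if std == 0.0:
        kurt = UNDEFINED
    elif fidelity.kurtosis == "standard":
        kurt = m4 / std**4 - 3.0
    else:
        kurt = m4 / std**2 - 3.0
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0.0:
        crest = UNDEFINED
    else:
        peak = float(np.max(np.abs(x))) if fidelity.crest == "use_abs" else float(np.max(x))
        crest = peak / rms
    return mean, std, kurt, crest


def correlation(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    fidelity: FidelityOptions | None = None,
) -> float:
    """Correlation between two equal-length frames.

    ``consistent`` mode is the Pearson estimator (corr(x, x) = 1);
    ``as_printed`` keeps the literal 1/N-covariance over (N-1)-std form.
    """
    fidelity = fidelity or FidelityOptions()
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have equal length")
    sa = np.std(a, ddof=1)
    sb = np.std(b, ddof=1)
    if sa == 0.0 or sb == 0.0:
        return UNDEFINED
    cov_biased = float(np.mean(a * b) - np.mean(a) * np.mean(b))
    if fidelity.correlation == "as_printed":
        return cov_biased / float(sa * sb)
    n = len(a)
    return cov_biased * n / (n - 1) / float(sa * sb)


def amplitude_spectrum(frame: np.ndarray, fs: float = 1.0) -> Spectrum:
    """Magnitude of the one-sided DFT, DC excluded; K = floor(N/2) lines."""
    x = np.asarray(frame, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("frame must contain at least 4 samples")
    mags = np.abs(np.fft.rfft(x))
    return Spectrum(A=mags[1 : n // 2 + 1], fs=fs)


def spectral_features(
    spec: Spectrum, fidelity: FidelityOptions | None = None
) -> tuple[float, float]:
    """Spectrum energy (mean squared line) and spectral entropy in bits.

    Entropy treats the normalized amplitude spectrum as a probability mass
    function (``histogram`` mode instead bins the amplitude values); an
    all-zero spectrum has energy 0 and entropy 0 by convention.  Low entropy
    indicates a periodic (line-dominated) signal such as gait.
    """
    fidelity = fidelity or FidelityOptions()
    A = np.asarray(spec.A, dtype=float)
    k = len(A)
    if k < 1:
        raise ValueError("spectrum must contain at least one line")
    energy = float(np.sum(A**2) / k)
    total = float(np.sum(A))
    if total == 0.0:
        return energy, 0.0
    if fidelity.entropy == "histogram":
        counts, _ = np.histogram(A, bins=32)
        p = counts[counts > 0] / k
    else:
        p = A[A > 0] / total
    entropy = float(-np.sum(p * np.log2(p)))
    return energy, entropy


# ---------------------------------------------------------------------------
# feature-vector layout and assembly


def vector_layout(config: tuple[SensorPlacement, ...]) -> list[str]:
    """Canonical feature names for a sensor configuration.

    Sensors in fixed site order; per sensor, 6 features per axis then the 3
    intra-sensor axis-pair correlations; then per unordered sensor pair the
    3 same-axis correlations.
    """
    sites = [s for s in SITE_ORDER if s in config]
    if len(sites) != len(config):
        raise ValueError("config must be a subset of the five valid sites")
    names = []
    for site in sites:
        for axis in AXES:
            for feat in AXIS_FEATURES:
                names.append(f"{feat}__{site.value}_{axis}")
        for a1, a2 in AXIS_PAIRS:
            names.append(f"corr__{site.value}_{a1}__{site.value}_{a2}")
    for s1, s2 in itertools.combinations(sites, 2):
        for axis in AXES:
            names.append(f"corr__{s1.value}_{axis}__{s2.value}_{axis}")
    return names


def vector_length(n_sensors: int) -> int:
    """21 s + 3 C(s, 2): 21/45/72/135 for 1/2/3/5 sensors."""
    return 21 * n_sensors + 3 * math.comb(n_sensors, 2)


@dataclass
class FeatureVector:
    """Ordered parameter vector with its canonical layout."""

    values: np.ndarray
    layout: list[str]
    n_undefined: int = 0

    def __len__(self) -> int:
        return len(self.values)


def assemble_vector(
    windowed: WindowedSession,
    config: tuple[SensorPlacement, ...],
    frame_index: int,
    fidelity: FidelityOptions | None = None,
) -> FeatureVector:
    """Assemble one frame's feature vector for a sensor configuration.

    Undefined entries (zero-variance/zero-RMS sentinels) are replaced by 0
    so downstream classifiers receive fixed-length numeric vectors; the
    count of replacements is recorded and logged.
    """
    fidelity = fidelity or FidelityOptions()
    sites = [s for s in SITE_ORDER if s in config]
    if len(sites) != len(config):
        raise ValueError("config must be a subset of the five valid sites")
    missing = [s for s in sites if (s, "x") not in windowed.frames]
    if missing:
        raise ValueError(f"sensors missing from session: {[s.value for s in missing]}")

    frames = {
        (s, a): windowed.frames[(s, a)][frame_index] for s in sites for a in AXES
    }
    values: list[float] = []
    for site in sites:
        for axis in AXES:
            x = frames[(site, axis)]
            mean, std, kurt, crest = time_features(x, fidelity)
            energy, entropy = spectral_features(
                amplitude_spectrum(x, windowed.fs), fidelity
            )
            values.extend([mean, std, kurt, crest, energy, entropy])
        for a1, a2 in AXIS_PAIRS:
            values.append(correlation(frames[(site, a1)], frames[(site, a2)], fidelity))
    for s1, s2 in itertools.combinations(sites, 2):
        for axis in AXES:
            values.append(correlation(frames[(s1, axis)], frames[(s2, axis)], fidelity))

    arr = np.asarray(values, dtype=float)
    n_undef = int(np.sum(np.isnan(arr)))
    if n_undef:
        logger.debug("frame %d: %d undefined features set to 0", frame_index, n_undef)
        arr = np.nan_to_num(arr, nan=0.0)
    return FeatureVector(values=arr, layout=vector_layout(tuple(sites)), n_undefined=n_undef)


def featurize_session(
    session: LabeledSession,
    task: str,
    config: tuple[SensorPlacement, ...],
    fidelity: FidelityOptions | None = None,
    prefiltered: bool = False,
    filter_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Filter, frame, label and featurize one session for one task.

    Returns one row per frame: the canonical feature columns plus
    ``frame_start_s``, ``label`` and ``subject_id``.  The full signal is
    always filtered before framing.
    """
    if not prefiltered:
        session_f = filter_session(session, **(filter_kwargs or {}))
    else:
        session_f = session
    spec = FrameSpec.gait() if task == "gait" else FrameSpec.hand()
    windowed = frame_session(session_f, spec)
    labels = label_frames(session, windowed, task)
    layout = vector_layout(config)
    rows = np.empty((windowed.n_frames, len(layout)))
    n_undef = 0
    for i in range(windowed.n_frames):
        fv = assemble_vector(windowed, config, i, fidelity)
        rows[i] = fv.values
        n_undef += fv.n_undefined
    if n_undef:
        logger.info(
            "session %s/%s: %d undefined feature entries set to 0",
            session.subject_id,
            task,
            n_undef,
        )
    df = pd.DataFrame(rows, columns=layout)
    df["frame_start_s"] = windowed.start_times
    df["label"] = labels
    df["subject_id"] = session.subject_id
    return df


def featurize_cohort(
    sessions: list[LabeledSession],
    task: str,
    config: tuple[SensorPlacement, ...],
    fidelity: FidelityOptions | None = None,
) -> pd.DataFrame:
    """Concatenate per-session feature tables for a cohort."""
    return pd.concat(
        [featurize_session(s, task, config, fidelity) for s in sessions],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# <-1, 1> normalization


@dataclass
class Normalizer:
    """Per-dimension min/max affine map onto [-1, 1], learned on training data.

    Test-time values outside the training range clamp to +/-1; a constant
    training dimension maps everything to 0.
    """

    vmin: np.ndarray
    vmax: np.ndarray
    layout: list[str] = field(default_factory=list)

    def transform(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        span = self.vmax - self.vmin
        out = np.zeros_like(v)
        nz = span > 0
        out[..., nz] = 2.0 * (v[..., nz] - self.vmin[nz]) / span[nz] - 1.0
        return np.clip(out, -1.0, 1.0)


def fit_normalizer(X: np.ndarray, layout: list[str] | None = None) -> Normalizer:
    """Learn per-dimension min/max from the training matrix only."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    return Normalizer(
        vmin=X.min(axis=0), vmax=X.max(axis=0), layout=list(layout or [])
    )


def apply_normalizer(norm: Normalizer, values):
    """Map values onto [-1, 1]; FeatureVector inputs must match the layout."""
    if isinstance(values, FeatureVector):
        if norm.layout and values.layout != norm.layout:
            raise ValueError("feature-vector layout does not match the normalizer")
        return FeatureVector(
            values=norm.transform(values.values),
            layout=values.layout,
            n_undefined=values.n_undefined,
        )
    return norm.transform(values)
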