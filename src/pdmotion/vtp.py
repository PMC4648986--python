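"""Virtual TouchPad: camera-based hand-gesture assessment.

A static downward-looking camera records the hand on a desk.  The pipeline:

1. background model from the first 50 frames — per-pixel mean plus mean
   absolute inter-frame difference;
2. per-frame foreground mask: a pixel is foreground when its intensity
   departs from the model mean by more than ``lambda *`` the modeled
   per-pixel variability;
3. shadow removal (color frames only) by thresholding in YCrCb: shadow
   pixels darken the luma while barely moving the chroma;
4. morphological closing to heal mask defects;
5. hand contour = largest connected component, accepted only at >= 5000 px;
6. radial signature: 180 rays from the mask centroid, rotated 2 degrees
   apart, each counting mask pixels at 1-px steps out to the image border;
7. per-user one-vs-all SVMs over the 180-dim signatures, one classifier per
   UPDRS hand test (23: finger tapping, 24: open/close fist,
   25: pronation-supination), trained from 35 frames per gesture;
8. test report: gesture count, mean gestures per second, per-gesture
   durations, and the label-vs-time series.

A synthetic renderer (parametric palm-plus-fingers silhouettes on a textured
background) stands in for camera input so the pipeline is testable without
recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology

from .classify import ClassifierModel, SvmConfig, train_one_vs_all
from .features import Normalizer, fit_normalizer

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundModel",
    "HandMask",
    "RadialSignature",
    "GestureTestSpec",
    "TestReport",
    "build_background",
    "foreground_mask",
    "shadow_filter",
    "refine_mask",
    "hand_region",
    "radial_signature",
    "train_gestures",
    "run_test",
    "render_gesture",
    "synth_hand_frames",
    "collect_training_signatures",
]

MIN_HAND_AREA = 5000
N_RAYS = 180
DEFAULT_N_INIT = 50


@dataclass
class BackgroundModel:
    """Static scene model: per-pixel mean and mean |inter-frame difference|."""

    mean_image: np.ndarray
    diff_image: np.ndarray
    n_init: int

    def __post_init__(self) -> None:
        if self.mean_image.shape != self.diff_image.shape:
            raise ValueError("mean and diff images must share dimensions")


@dataclass
class HandMask:
    """Binary hand silhouette accepted by the 5000-px area rule."""

    mask: np.ndarray
    area: int
    centroid: tuple[float, float]  # (row, col)


@dataclass
class RadialSignature:
    """180 pixels-on-ray counts, rays 2 degrees apart from the centroid."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != N_RAYS:
            raise ValueError(f"signature must have exactly {N_RAYS} entries")


_TEST_GESTURES = {
    "updrs23": ("fingers_adjoined", "fingers_separated"),
    "updrs24": ("fist_open", "fist_closed"),
    "updrs25": ("pronation", "supination"),
}


@dataclass(frozen=True)
class GestureTestSpec:
    """One of the three automated UPDRS hand tests; two gestures each."""

    test: str

    def __post_init__(self) -> None:
        if self.test not in _TEST_GESTURES:
            raise ValueError(f"unknown test {self.test!r}; expected {list(_TEST_GESTURES)}")

    @property
    def gestures(self) -> tuple[str, str]:
        return _TEST_GESTURES[self.test]


# ---------------------------------------------------------------------------
# segmentation


def _gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        # ITU-R BT.601 luma
        return frame @ np.array([0.299, 0.587, 0.114])
    return frame


def build_background(frames) -> BackgroundModel:
    """Average the initialization frames and their successive differences."""
    grays = [_gray(f) for f in frames]
    if len(grays) < 2:
        raise ValueError("background model needs at least 2 frames")
    shape = grays[0].shape
    if any(g.shape != shape for g in grays):
        raise ValueError("initialization frames must share dimensions")
    stack = np.stack(grays)
    mean = stack.mean(axis=0)
    diff = np.abs(np.diff(stack, axis=0)).mean(axis=0)
    return BackgroundModel(mean_image=mean, diff_image=diff, n_init=len(grays))


def foreground_mask(
    frame: np.ndarray,
    model: BackgroundModel,
    lam: float = 3.0,
    floor: float = 2.0,
) -> np.ndarray:
    """Pixels whose intensity exceeds the modeled range are foreground.

    The per-pixel tolerance is ``lam * max(diff_image, floor)``; the floor
    keeps perfectly static pixels from becoming hypersensitive.
    """
    g = _gray(frame)
    if g.shape != model.mean_image.shape:
        raise ValueError("frame dimensions do not match the background model")
    tol = lam * np.maximum(model.diff_image, floor)
    return np.abs(g - model.mean_image) > tol


def shadow_filter(
    frame: np.ndarray,
    model: BackgroundModel,
    mask: np.ndarray,
    luma_ratio: tuple[float, float] = (0.5, 0.95),
    chroma_tol: float = 12.0,
) -> np.ndarray:
    """Drop foreground pixels that look like shadow in YCrCb.

    A shadow darkens the luma to a fraction of the background value while
    leaving the chroma nearly unchanged.  Grayscale input cannot be chroma
    checked, so the stage is skipped with a logged notice.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3:
        logger.info("shadow filter skipped: grayscale frame has no chroma")
        return mask
    y = _gray(frame)
    cr = 0.713 * (frame[..., 0] - y) + 128.0
    cb = 0.564 * (frame[..., 2] - y) + 128.0
    bg_y = np.maximum(model.mean_image, 1e-9)
    ratio = y / bg_y
    # the model stores only background luma; assume neutral background chroma
    is_shadow = (
        mask
        & (ratio >= luma_ratio[0])
        & (ratio <= luma_ratio[1])
        & (np.abs(cr - 128.0) <= chroma_tol)
        & (np.abs(cb - 128.0) <= chroma_tol)
    )
    return mask & ~is_shadow


def refine_mask(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Morphological closing with an elliptical (disk) structuring element."""
    return morphology.closing(np.asarray(mask, bool), morphology.disk(radius))


def hand_region(mask: np.ndarray, min_area: int = MIN_HAND_AREA) -> HandMask | None:
    """Largest connected component, accepted only at ``min_area`` pixels.

    Area ties break toward the topmost-leftmost bounding box.
    """
    labeled = measure.label(np.asarray(mask, bool))
    props = measure.regionprops(labeled)
    if not props:
        return None
    best = max(props, key=lambda p: (p.area, (-p.bbox[0], -p.bbox[1])))
    if best.area < min_area:
        return None
    hand = labeled == best.label
    return HandMask(mask=hand, area=int(best.area), centroid=tuple(best.centroid))


def radial_signature(hand: HandMask) -> RadialSignature:
    """Count mask pixels along 180 rays, 2 degrees apart, centroid to border.

    Samples at 1-px steps with bilinear interpolation of the mask, so the
    count varies continuously with the (sub-pixel) centroid position —
    nearest-pixel sampling makes rays grazing a finger edge jump by whole
    finger lengths under fractional centroid shifts.
    """
    mask = np.asarray(hand.mask, dtype=float)
    h, w = mask.shape
    r0, c0 = hand.centroid
    counts = np.zeros(N_RAYS)
    angles = np.deg2rad(2.0 * np.arange(N_RAYS))
    max_reach = int(np.ceil(np.hypot(h, w)))
    t = np.arange(max_reach + 1)  # 1-px steps, centroid included
    for i, th in enumerate(angles):
        # counterclockwise in the visual sense (rows grow downward)
        rr = r0 - t * np.sin(th)
        cc = c0 + t * np.cos(th)
        inside = (rr >= 0) & (rr <= h - 1) & (cc >= 0) & (cc <= w - 1)
        rr, cc = rr[inside], cc[inside]
        ri = np.minimum(rr.astype(int), h - 2)
        ci = np.minimum(cc.astype(int), w - 2)
        fr = rr - ri
        fc = cc - ci
        vals = (
            mask[ri, ci] * (1 - fr) * (1 - fc)
            + mask[ri, ci + 1] * (1 - fr) * fc
            + mask[ri + 1, ci] * fr * (1 - fc)
            + mask[ri + 1, ci + 1] * fr * fc
        )
        counts[i] = float(vals.sum())
    return RadialSignature(counts=counts)


# ---------------------------------------------------------------------------
# gesture classification


@dataclass
class GestureModel:
    """Per-user gesture classifier for one UPDRS test."""

    spec: GestureTestSpec
    classifier: ClassifierModel
    normalizer: Normalizer


def train_gestures(
    signatures: dict[str, list[RadialSignature]],
    spec: GestureTestSpec,
    cfg: SvmConfig | None = None,
) -> GestureModel:
    """One-vs-all SVMs over normalized 180-dim signatures (per user).

    The study protocol trains from 35 frames per gesture; any >= 2 per
    gesture is accepted.
    """
    cfg = cfg or SvmConfig()
    missing = [g for g in spec.gestures if not signatures.get(g)]
    if missing:
        raise ValueError(f"missing gesture classes: {missing}")
    X, y = [], []
    for gesture in spec.gestures:
        sigs = signatures[gesture]
        if len(sigs) < 2:
            raise ValueError(f"gesture {gesture!r} needs at least 2 signatures")
        for s in sigs:
            X.append(s.counts)
            y.append(gesture)
    X = np.asarray(X, dtype=float)
    norm = fit_normalizer(X)
    clf = train_one_vs_all(norm.transform(X), np.asarray(y, object), cfg,
                           classes=list(spec.gestures))
    return GestureModel(spec=spec, classifier=clf, normalizer=norm)


@dataclass
class TestReport:
    """Outcome of one automated hand test."""

    gesture_count: int
    gestures_per_second: float
    durations_s: list[float]
    event_labels: list[str]
    frame_labels: list  # str | None per analyzed frame
    frame_times_s: np.ndarray
    unreliable: bool = False
    metadata: dict = field(default_factory=dict)


def _gesture_events(labels: list, min_run: int = 2) -> list[tuple[str, int, int]]:
    """Maximal runs of >= min_run identical non-None labels: (label, i0, i1).

    Runs shorter than ``min_run`` are flickers: they are discarded entirely,
    so a single misread frame neither creates a spurious event nor splits
    the surrounding gesture in two.
    """
    runs = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        runs.append((labels[i], i, j))
        i = j
    kept = [r for r in runs if r[2] - r[1] >= min_run]
    events: list[tuple[str, int, int]] = []
    for lab, i0, i1 in kept:
        if events and events[-1][0] == lab:
            events[-1] = (lab, events[-1][1], i1)  # merge across a flicker
        else:
            events.append((lab, i0, i1))
    return [e for e in events if e[0] is not None]


def run_test(
    frames,
    model: GestureModel,
    background: BackgroundModel | None = None,
    fps: float = 10.0,
    n_init: int = DEFAULT_N_INIT,
    lam: float = 3.0,
) -> TestReport:
    """Classify each frame's hand gesture and extract the gesture timeline.

    If no background model is supplied, the first ``n_init`` frames
    initialize one and the remainder are analyzed.  A gesture event is a
    maximal run of at least two consecutive identical frame labels
    (debouncing single-frame flickers); the report flags itself unreliable
    when more than half of the analyzed frames contain no valid hand.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame sequence")
    if background is None:
        if len(frames) <= n_init:
            raise ValueError(f"need more than {n_init} frames to self-initialize")
        background = build_background(frames[:n_init])
        frames = frames[n_init:]

    labels: list = []
    for frame in frames:
        mask = foreground_mask(frame, background, lam=lam)
        mask = shadow_filter(frame, background, mask)
        mask = refine_mask(mask)
        hand = hand_region(mask)
        if hand is None:
            labels.append(None)
            continue
        sig = radial_signature(hand)
        pred = model.classifier.predict(
            model.normalizer.transform(sig.counts[None, :])
        )
        labels.append(str(pred[0]))

    n_invalid = sum(1 for lab in labels if lab is None)
    unreliable = n_invalid > 0.5 * len(labels)
    events = _gesture_events(labels)
    duration = len(labels) / fps
    durations = [(j - i) / fps for _, i, j in events]
    return TestReport(
        gesture_count=len(events),
        gestures_per_second=len(events) / duration if duration > 0 else 0.0,
        durations_s=durations,
        event_labels=[lab for lab, _, _ in events],
        frame_labels=labels,
        frame_times_s=np.arange(len(labels)) / fps,
        unreliable=unreliable,
        metadata={"n_frames": len(labels), "n_no_hand": n_invalid, "fps": fps},
    )


# ---------------------------------------------------------------------------
# synthetic camera input


_FINGER_ANGLES = {
    # degrees from straight-up, per finger (thumb last); None = no fingers
    "fingers_separated": (-50.0, -25.0, 0.0, 25.0, 50.0),
    "fingers_adjoined": (-8.0, -4.0, 0.0, 4.0, 8.0),
    "fist_open": (-40.0, -20.0, 0.0, 20.0, 40.0),
    "fist_closed": None,
    "pronation": None,
    "supination": None,
}


def _draw_disk(mask: np.ndarray, r: float, c: float, radius: float) -> None:
    h, w = mask.shape
    r_lo, r_hi = max(0, int(r - radius) - 1), min(h, int(r + radius) + 2)
    c_lo, c_hi = max(0, int(c - radius) - 1), min(w, int(c + radius) + 2)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    mask[r_lo:r_hi, c_lo:c_hi] |= (rr - r) ** 2 + (cc - c) ** 2 <= radius**2


def _draw_capsule(mask, r0, c0, angle_deg, length, radius) -> None:
    th = np.deg2rad(angle_deg)
    for t in np.arange(0.0, length, radius / 2.0):
        _draw_disk(mask, r0 - t * np.cos(th), c0 + t * np.sin(th), radius)


def render_gesture(
    gesture: str,
    shape: tuple[int, int] = (240, 320),
    jitter: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Parametric hand silhouette: palm ellipse plus finger/thumb capsules.

    Every render exceeds the 5000-px hand-area rule by construction.
    """
    if gesture not in _FINGER_ANGLES:
        raise ValueError(f"unknown gesture {gesture!r}")
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    pr, pc = h * 0.62 + jitter[0], w * 0.5 + jitter[1]
    rr, cc = np.mgrid[0:h, 0:w]

    if gesture == "fist_closed":
        a, b = 52.0, 46.0
    elif gesture in ("pronation", "supination"):
        a, b = 46.0, 40.0
    else:
        a, b = 44.0, 38.0
    mask |= ((rr - pr) / a) ** 2 + ((cc - pc) / b) ** 2 <= 1.0

    angles = _FINGER_ANGLES[gesture]
    if angles is not None:
        # fingers held together read as one short mitten block; spread
        # fingers are long and thin with clear gaps between the tips
        length = 44.0 if gesture == "fingers_adjoined" else 62.0
        top_r = pr - a * 0.55
        for ang in angles:
            _draw_capsule(mask, top_r, pc + 0.55 * b * np.sin(np.deg2rad(ang)),
                          ang, length=length, radius=8.0)
    if gesture == "pronation":
        _draw_capsule(mask, pr - 10.0, pc - b * 0.8, -80.0, length=42.0, radius=9.0)
    elif gesture == "supination":
        _draw_capsule(mask, pr - 10.0, pc + b * 0.8, 80.0, length=42.0, radius=9.0)
    return mask


def _textured_background(shape, rng: np.random.Generator) -> np.ndarray:
    """Smooth static desk texture around intensity 60."""
    coarse = rng.uniform(-1.0, 1.0, size=(shape[0] // 16 + 2, shape[1] // 16 + 2))
    rows = np.linspace(0, coarse.shape[0] - 1.001, shape[0])
    cols = np.linspace(0, coarse.shape[1] - 1.001, shape[1])
    r0 = rows.astype(int)
    c0 = cols.astype(int)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    tl = coarse[np.ix_(r0, c0)]
    tr = coarse[np.ix_(r0, c0 + 1)]
    bl = coarse[np.ix_(r0 + 1, c0)]
    br = coarse[np.ix_(r0 + 1, c0 + 1)]
    smooth = tl * (1 - fr) * (1 - fc) + tr * (1 - fr) * fc + bl * fr * (1 - fc) + br * fr * fc
    return 60.0 + 15.0 * smooth


def synth_hand_frames(
    script: list[tuple[str, float]],
    spec: GestureTestSpec,
    seed: int = 0,
    fps: float = 10.0,
    shape: tuple[int, int] = (240, 320),
    n_init: int = DEFAULT_N_INIT,
    noise_std: float = 1.5,
    scene_seed: int | None = None,
):
    """Render a scripted gesture sequence preceded by background-only frames.

    Returns ``(frames, truth)`` where the first ``n_init`` truth entries are
    None (scene initialization) and the rest name the scripted gesture.
    ``scene_seed`` fixes the static desk texture; training and test
    sequences of the same user share it, as they would share a physical
    scene.  Deterministic for a fixed (seed, scene_seed).
    """
    for gesture, dur in script:
        if gesture not in spec.gestures:
            raise ValueError(f"gesture {gesture!r} not in test {spec.test}")
        if dur <= 0:
            raise ValueError("durations must be positive")
    rng = np.random.default_rng(seed)
    bg = _textured_background(
        shape, np.random.default_rng(seed if scene_seed is None else scene_seed)
    )
    frames: list[np.ndarray] = []
    truth: list[str | None] = []
    for _ in range(n_init):
        frames.append(bg + rng.normal(0.0, noise_std, size=shape))
        truth.append(None)
    for gesture, dur in script:
        for _ in range(int(round(dur * fps))):
            jitter = rng.uniform(-2.0, 2.0, size=2)
            hand = render_gesture(gesture, shape, jitter=tuple(jitter))
            frame = bg + rng.normal(0.0, noise_std, size=shape)
            frame[hand] = 200.0 + rng.normal(0.0, noise_std)
            frames.append(frame)
            truth.append(gesture)
    return frames, truth


def collect_training_signatures(
    spec: GestureTestSpec,
    n_per_gesture: int = 35,
    seed: int = 0,
    shape: tuple[int, int] = (240, 320),
    scene_seed: int | None = None,
) -> dict[str, list[RadialSignature]]:
    """Run the segmentation pipeline on synthetic renders to get signatures.

    Mirrors the study's training protocol: 35 frames per gesture, collected
    per user in the same scene the test will run in (pass the session's
    ``scene_seed``).
    """
    if scene_seed is None:
        scene_seed = seed
    rng = np.random.default_rng(seed)
    bg = _textured_background(shape, np.random.default_rng(scene_seed))
    bg_frames = [
        bg + np.random.default_rng(seed + 1 + i).normal(0.0, 1.5, size=shape)
        for i in range(10)
    ]
    model = build_background(bg_frames)
    out: dict[str, list[RadialSignature]] = {g: [] for g in spec.gestures}
    for gesture in spec.gestures:
        attempts = 0
        while len(out[gesture]) < n_per_gesture and attempts < 5 * n_per_gesture:
            attempts += 1
            jitter = rng.uniform(-2.0, 2.0, size=2)
            hand = render_gesture(gesture, shape, jitter=tuple(jitter))
            frame = bg + rng.normal(0.0, 1.5, size=shape)
            frame[hand] = 200.0 + rng.normal(0.0, 1.5)
            mask = refine_mask(foreground_mask(frame, model))
            region = hand_region(mask)
            if region is None:
                continue
            out[gesture].append(radial_signature(region))
        if len(out[gesture]) < n_per_gesture:
            raise RuntimeError(f"could not segment enough {gesture!r} renders")
    return out
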