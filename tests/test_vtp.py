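import numpy as np
import pytest

from pdmotion.classify import SvmConfig
from pdmotion.vtp import (
    GestureTestSpec,
    RadialSignature,
    _gesture_events,
    build_background,
    collect_training_signatures,
    foreground_mask,
    hand_region,
    radial_signature,
    refine_mask,
    render_gesture,
    run_test,
    shadow_filter,
    synth_hand_frames,
    train_gestures,
)


def _disk_mask(shape=(200, 200), center=(100, 100), radius=50):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestBackgroundModel:
    def test_identical_frames_mean_equals_frame_and_zero_diff(self):
        f = np.full((10, 12), 33.0)
        model = build_background([f, f, f])
        np.testing.assert_array_equal(model.mean_image, f)
        np.testing.assert_array_equal(model.diff_image, 0.0)

    def test_constant_offset_gives_constant_diff(self):
        a = np.full((8, 8), 50.0)
        model = build_background([a, a + 10.0])
        np.testing.assert_array_equal(model.diff_image, 10.0)
        np.testing.assert_array_equal(model.mean_image, 55.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            build_background([np.zeros((4, 4)), np.zeros((5, 5))])


class TestForegroundMask:
    def test_frame_equal_to_mean_is_all_background(self):
        f = np.full((20, 20), 80.0)
        model = build_background([f, f])
        assert not foreground_mask(f, model).any()

    def test_bright_square_detected(self):
        bg = np.full((120, 120), 60.0)
        model = build_background([bg, bg])
        frame = bg.copy()
        frame[10:110, 10:110] = 200.0
        mask = foreground_mask(frame, model)
        assert mask[12:108, 12:108].all()
        assert not mask[:8, :8].any()

    def test_raising_lambda_never_adds_pixels(self, rng):
        bg = 60.0 + rng.normal(0, 2.0, (50, 50))
        model = build_background([bg + rng.normal(0, 2, bg.shape) for _ in range(6)])
        frame = bg + rng.normal(0, 8.0, bg.shape)
        prev = foreground_mask(frame, model, lam=1.0)
        for lam in (2.0, 3.0, 5.0):
            cur = foreground_mask(frame, model, lam=lam)
            assert not (cur & ~prev).any()
            prev = cur


class TestShadowFilter:
    def _model(self, luma=100.0):
        f = np.full((4, 4), luma)
        return build_background([f, f])

    def _rgb(self, r, g, b):
        frame = np.zeros((4, 4, 3))
        frame[..., 0], frame[..., 1], frame[..., 2] = r, g, b
        return frame

    def test_darkened_pixel_with_stable_chroma_removed(self):
        model = self._model(100.0)
        frame = self._rgb(70.0, 70.0, 70.0)  # 70 % luma, neutral chroma
        mask = np.ones((4, 4), bool)
        assert not shadow_filter(frame, model, mask).any()

    def test_brighter_pixel_retained(self):
        model = self._model(100.0)
        frame = self._rgb(150.0, 150.0, 150.0)
        mask = np.ones((4, 4), bool)
        assert shadow_filter(frame, model, mask).all()

    def test_chroma_shift_beyond_threshold_retained(self):
        model = self._model(100.0)
        frame = self._rgb(120.0, 50.0, 50.0)  # strong Cr shift
        mask = np.ones((4, 4), bool)
        assert shadow_filter(frame, model, mask).all()

    def test_grayscale_input_passes_through(self):
        model = self._model(100.0)
        mask = np.ones((4, 4), bool)
        out = shadow_filter(np.full((4, 4), 70.0), model, mask)
        np.testing.assert_array_equal(out, mask)


class TestRefineAndRegion:
    def test_solid_rectangle_unchanged(self):
        m = np.zeros((40, 40), bool)
        m[5:30, 5:30] = True
        np.testing.assert_array_equal(refine_mask(m), m)

    def test_interior_hole_filled(self):
        m = np.zeros((40, 40), bool)
        m[5:30, 5:30] = True
        m[15, 15] = False
        assert refine_mask(m)[15, 15]

    def test_closing_idempotent(self, rng):
        m = rng.random((60, 60)) > 0.6
        once = refine_mask(m)
        np.testing.assert_array_equal(refine_mask(once), once)

    def test_empty_mask_has_no_hand(self):
        assert hand_region(np.zeros((100, 100), bool)) is None

    def test_largest_component_selected(self):
        m = np.zeros((200, 400), bool)
        m[10:80, 10:110] = True  # 7000 px
        m[100:160, 200:300] = True  # 6000 px
        hand = hand_region(m)
        assert hand.area == 7000
        assert hand.mask[40, 50] and not hand.mask[120, 250]

    @pytest.mark.parametrize("area,accepted", [(4999, False), (5000, True)])
    def test_area_rule_exact_at_boundary(self, area, accepted):
        m = np.zeros((300, 300), bool)
        m[50 : 50 + 100, 50 : 50 + area // 100] = True
        extra = area - 100 * (area // 100)
        m[50 : 50 + extra, 50 + area // 100] = True
        assert int(m.sum()) == area
        assert (hand_region(m) is not None) == accepted


class TestRadialSignature:
    def test_length_is_180(self):
        sig = radial_signature(hand_region(_disk_mask()))
        assert len(sig.counts) == 180

    def test_centered_disk_counts_near_radius(self):
        sig = radial_signature(hand_region(_disk_mask(radius=50)))
        assert sig.counts.min() >= 48 and sig.counts.max() <= 52

    def test_rotating_mask_cyclically_shifts_signature(self):
        base = render_gesture("fingers_separated")
        sig = radial_signature(hand_region(base)).counts
        rotated = np.rot90(base).copy()
        sig_rot = radial_signature(hand_region(rotated)).counts
        # 90 degrees = 45 ray positions; allow +/-1 for rasterization
        best_shift, best_err = min(
            ((s, np.abs(np.roll(sig, s) - sig_rot).max()) for s in range(180)),
            key=lambda p: p[1],
        )
        assert best_shift in (44, 45, 46)
        assert best_err <= 3.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="180"):
            RadialSignature(counts=np.zeros(90))


class TestRenderer:
    def test_every_gesture_exceeds_area_rule(self):
        for spec_name in ("updrs23", "updrs24", "updrs25"):
            for gesture in GestureTestSpec(spec_name).gestures:
                mask = render_gesture(gesture)
                assert int(mask.sum()) >= 5000

    def test_separated_fingers_show_five_protrusions_fist_none(self):
        from scipy.signal import find_peaks

        def protrusions(gesture):
            hand = hand_region(render_gesture(gesture))
            counts = radial_signature(hand).counts
            # a finger = a prominent local maximum among the up-facing rays
            # (the palm's own lower lobe is not a finger)
            wrapped = np.r_[counts[-10:], counts, counts[:10]]
            peaks, _ = find_peaks(wrapped, prominence=10)
            peaks -= 10
            return int(np.sum((peaks >= 0) & (peaks <= 90)))

        assert protrusions("fingers_separated") == 5
        assert protrusions("fist_closed") == 0

    def test_same_seed_reproduces_frames(self):
        spec = GestureTestSpec("updrs24")
        script = [("fist_open", 0.5), ("fist_closed", 0.5)]
        f1, t1 = synth_hand_frames(script, spec, seed=4, n_init=3)
        f2, t2 = synth_hand_frames(script, spec, seed=4, n_init=3)
        assert t1 == t2
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_gesture_outside_test_rejected(self):
        with pytest.raises(ValueError, match="not in test"):
            synth_hand_frames([("pronation", 1.0)], GestureTestSpec("updrs23"))


class TestGestureEvents:
    def test_alternating_pairs(self):
        events = _gesture_events(list("AABBAA"))
        assert [e[0] for e in events] == ["A", "B", "A"]
        assert all(e[2] - e[1] == 2 for e in events)

    def test_single_frame_flicker_ignored(self):
        events = _gesture_events(["A"] * 4 + ["B"] + ["A"] * 4)
        assert events == [("A", 0, 9)]

    def test_none_runs_separate_events(self):
        events = _gesture_events([None, None, "A", "A", None, None, "B", "B"])
        assert [e[0] for e in events] == ["A", "B"]


@pytest.fixture(scope="module")
def updrs24_model():
    spec = GestureTestSpec("updrs24")
    sigs = collect_training_signatures(spec, n_per_gesture=35, seed=21, scene_seed=2)
    return spec, train_gestures(sigs, spec, SvmConfig(seed=0))


class TestGestureClassification:
    def test_training_set_of_35_per_gesture_accepted(self, updrs24_model):
        spec, model = updrs24_model
        assert model.classifier.classes == list(spec.gestures)

    def test_single_gesture_training_rejected(self):
        spec = GestureTestSpec("updrs24")
        sigs = {"fist_open": [RadialSignature(np.zeros(180))] * 3}
        with pytest.raises(ValueError, match="missing gesture"):
            train_gestures(sigs, spec)

    def test_scripted_sequence_recovered_end_to_end(self, updrs24_model):
        spec, model = updrs24_model
        script = [("fist_open", 1.0), ("fist_closed", 1.0)] * 3
        frames, truth = synth_hand_frames(script, spec, seed=33, fps=10,
                                          scene_seed=2)
        report = run_test(frames, model, fps=10.0)
        assert report.gesture_count == 6
        acc = np.mean([p == t for p, t in zip(report.frame_labels, truth[50:])])
        assert acc >= 0.95
        assert not report.unreliable

    def test_constant_gesture_single_event(self, updrs24_model):
        spec, model = updrs24_model
        frames, _ = synth_hand_frames([("fist_open", 2.0)], spec, seed=8, fps=10,
                                      scene_seed=2)
        report = run_test(frames, model, fps=10.0)
        assert report.gesture_count == 1
        assert report.gestures_per_second == pytest.approx(1 / 2.0)

    def test_empty_frame_sequence_rejected(self, updrs24_model):
        _, model = updrs24_model
        with pytest.raises(ValueError, match="empty"):
            run_test([], model)

    def test_background_only_frames_flag_unreliable(self, updrs24_model):
        spec, model = updrs24_model
        frames, _ = synth_hand_frames([("fist_open", 0.5)], spec, seed=8, fps=10,
                                      n_init=50, scene_seed=2)
        # 50 init frames + 5 gesture frames, then 20 empty-scene frames
        empty = [frames[0]] * 20
        report = run_test(frames + empty, model, fps=10.0)
        assert report.unreliable
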