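import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pdmotion.features import (
    AXIS_FEATURES,
    FeatureVector,
    FidelityOptions,
    amplitude_spectrum,
    apply_normalizer,
    assemble_vector,
    correlation,
    featurize_session,
    fit_normalizer,
    spectral_features,
    time_features,
    vector_layout,
    vector_length,
)
from pdmotion.preprocess import FrameSpec, frame_session
from pdmotion.recordings import SITE_ORDER, SensorPlacement

from oracles import (
    corr_printed_oracle,
    crest_oracle,
    dft_amplitudes_oracle,
    energy_oracle,
    entropy_oracle,
    kurtosis_printed_oracle,
    kurtosis_standard_oracle,
    mean_oracle,
    pearson_oracle,
    std_oracle,
)


class TestTimeFeatures:
    def test_worked_example(self):
        mean, std, _, _ = time_features([1.0, 2.0, 3.0, 4.0])
        assert mean == pytest.approx(2.5)
        assert std == pytest.approx(math.sqrt(5 / 3))

    def test_constant_frame_degenerates(self):
        mean, std, kurt, crest = time_features(np.ones(16))
        assert (mean, std, crest) == (1.0, 0.0, 1.0)
        assert math.isnan(kurt)

    def test_sine_crest_factor(self):
        t = np.linspace(0, 1, 8192, endpoint=False)
        crest = time_features(np.sin(2 * np.pi * t))[3]
        assert crest == pytest.approx(math.sqrt(2), rel=0.01)

    def test_printed_vs_standard_kurtosis(self, rng):
        x = rng.normal(size=64)
        assert time_features(x)[2] == pytest.approx(kurtosis_printed_oracle(list(x)))
        std_mode = FidelityOptions(kurtosis="standard")
        assert time_features(x, std_mode)[2] == pytest.approx(
            kurtosis_standard_oracle(list(x))
        )


class TestCorrelation:
    def test_self_and_antisymmetry(self, rng):
        x = rng.normal(size=64)
        assert correlation(x, x) == pytest.approx(1.0)
        assert correlation(x, -x) == pytest.approx(-1.0)

    def test_printed_self_correlation_is_63_64ths(self, rng):
        x = rng.normal(size=64)
        printed = FidelityOptions(correlation="as_printed")
        assert correlation(x, x, printed) == pytest.approx(63 / 64)

    def test_zero_variance_is_undefined(self, rng):
        assert math.isnan(correlation(np.ones(8), rng.normal(size=8)))


class TestSpectrum:
    def test_zero_frame(self):
        spec = amplitude_spectrum(np.zeros(64))
        assert spec.K == 32
        assert np.all(spec.A == 0)
        assert spectral_features(spec) == (0.0, 0.0)

    def test_single_bin_sinusoid(self):
        n = 64
        x = np.sin(2 * np.pi * 5 * np.arange(n) / n)
        A = amplitude_spectrum(x).A
        assert np.argmax(A) == 4  # line k=5 sits at index 4 once DC is dropped
        others = np.delete(A, 4)
        assert others.max() < 0.01 * A[4]

    def test_brute_force_dft_agreement(self, rng):
        x = rng.normal(size=64)
        A = amplitude_spectrum(x).A
        ref = dft_amplitudes_oracle(list(x))
        np.testing.assert_allclose(A, ref, rtol=1e-9, atol=1e-9)

    def test_entropy_edge_cases(self):
        point = amplitude_spectrum(np.zeros(8))
        point.A = np.array([0.0, 3.0, 0.0, 0.0])
        assert spectral_features(point)[1] == pytest.approx(0.0)
        flat = amplitude_spectrum(np.zeros(8))
        flat.A = np.full(4, 2.5)
        assert spectral_features(flat)[1] == pytest.approx(2.0)  # log2(4)


def test_every_feature_matches_naive_oracle(rng):
    """Library features vs loop-based reference on 100 random frames."""
    printed = FidelityOptions()
    for _ in range(100):
        n = int(rng.integers(8, 65))
        x = list(rng.normal(size=n))
        y = list(rng.normal(size=n))
        mean, std, kurt, crest = time_features(x, printed)
        assert mean == pytest.approx(mean_oracle(x), abs=1e-9)
        assert std == pytest.approx(std_oracle(x), abs=1e-9)
        assert kurt == pytest.approx(kurtosis_printed_oracle(x), abs=1e-9)
        assert crest == pytest.approx(crest_oracle(x), abs=1e-9)
        assert correlation(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-9)
        assert correlation(
            x, y, FidelityOptions(correlation="as_printed")
        ) == pytest.approx(corr_printed_oracle(x, y), abs=1e-9)
        A = list(amplitude_spectrum(x).A)
        energy, entropy = spectral_features(amplitude_spectrum(x))
        assert energy == pytest.approx(energy_oracle(A), abs=1e-9)
        assert entropy == pytest.approx(entropy_oracle(A), abs=1e-9)


@settings(deadline=None, max_examples=50)
@given(arrays(float, 32, elements=st.floats(-6, 6, allow_nan=False)))
def test_spectral_feature_bounds(x):
    spec = amplitude_spectrum(x)
    energy, entropy = spectral_features(spec)
    assert energy >= 0.0
    assert 0.0 <= entropy <= math.log2(spec.K) + 1e-9


@settings(deadline=None, max_examples=50)
@given(
    arrays(float, 16, elements=st.floats(-6, 6, allow_nan=False)),
    arrays(float, 16, elements=st.floats(-6, 6, allow_nan=False)),
)
def test_correlation_bounds(x, y):
    c = correlation(x, y)
    assert math.isnan(c) or -1.0 - 1e-9 <= c <= 1.0 + 1e-9


class TestVectorAssembly:
    @pytest.mark.parametrize("n_sensors,expected", [(1, 21), (2, 45), (3, 72), (5, 135)])
    def test_length_per_sensor_count(self, n_sensors, expected):
        assert vector_length(n_sensors) == expected
        assert len(vector_layout(SITE_ORDER[:n_sensors])) == expected

    def test_length_formula_matches_enumeration(self):
        for s in range(1, 6):
            layout = vector_layout(SITE_ORDER[:s])
            brute = s * len(AXIS_FEATURES) * 3 + s * 3 + 3 * s * (s - 1) // 2
            assert len(layout) == brute == 21 * s + 3 * math.comb(s, 2)

    def test_five_sensors_have_30_intersensor_correlations(self):
        layout = vector_layout(SITE_ORDER)
        inter = [
            name
            for name in layout
            if name.startswith("corr__")
            and name.split("__")[1].rsplit("_", 1)[0]
            != name.split("__")[2].rsplit("_", 1)[0]
        ]
        assert len(inter) == 30

    def test_assembled_vector_on_synthetic_session(self, session_a):
        w = frame_session(session_a, FrameSpec.gait())
        fv = assemble_vector(w, SITE_ORDER[:3], frame_index=0)
        assert len(fv) == 72
        assert fv.layout == vector_layout(SITE_ORDER[:3])
        assert np.all(np.isfinite(fv.values))

    def test_missing_sensor_rejected(self, session_a):
        w = frame_session(session_a, FrameSpec.gait())
        del w.frames[(SensorPlacement.CHEST, "x")]
        with pytest.raises(ValueError, match="missing"):
            assemble_vector(w, (SensorPlacement.CHEST,), 0)

    def test_zero_variance_features_become_zero_with_count(self):
        from pdmotion.recordings import LabeledSession, TriaxialRecording

        recs = {
            SensorPlacement.CHEST: TriaxialRecording(
                SensorPlacement.CHEST, 51.2, np.ones((3, 64))
            )
        }
        sess = LabeledSession("s", recs, [])
        w = frame_session(sess, FrameSpec.gait())
        fv = assemble_vector(w, (SensorPlacement.CHEST,), 0)
        assert fv.n_undefined == 6  # 3 kurtoses + 3 axis-pair correlations
        assert np.all(np.isfinite(fv.values))


class TestNormalizer:
    def test_affine_map_and_endpoints(self):
        X = np.array([[0.0, -2.0], [10.0, 4.0], [5.0, 1.0]])
        norm = fit_normalizer(X)
        out = norm.transform(X)
        assert out[0, 0] == -1.0 and out[1, 0] == 1.0
        assert out[2, 0] == pytest.approx(0.0)
        assert np.all(out >= -1.0) and np.all(out <= 1.0)

    def test_constant_dimension_maps_to_zero(self):
        X = np.array([[3.0, 1.0], [3.0, 2.0]])
        out = fit_normalizer(X).transform(np.array([[3.0, 1.5], [99.0, 1.5]]))
        assert out[0, 0] == 0.0 and out[0, 1] == pytest.approx(0.0)

    def test_out_of_range_values_clamp(self):
        X = np.array([[0.0], [10.0]])
        norm = fit_normalizer(X)
        assert norm.transform(np.array([[20.0]]))[0, 0] == 1.0
        assert norm.transform(np.array([[-5.0]]))[0, 0] == -1.0

    def test_clamping_is_idempotent(self, rng):
        # transforming raw data equals transforming data pre-clipped to the
        # training range: the clamp absorbs everything outside it
        X = rng.normal(size=(20, 4))
        norm = fit_normalizer(X)
        T = rng.normal(scale=5.0, size=(10, 4))
        clamped_raw = np.clip(T, norm.vmin, norm.vmax)
        np.testing.assert_allclose(norm.transform(clamped_raw), norm.transform(T),
                                   atol=1e-12)

    def test_layout_mismatch_rejected(self):
        norm = fit_normalizer(np.zeros((2, 3)), layout=["a", "b", "c"])
        fv = FeatureVector(values=np.zeros(3), layout=["a", "b", "x"])
        with pytest.raises(ValueError, match="layout"):
            apply_normalizer(norm, fv)


def test_feature_table_columns_and_entropy_ordering(session_a):
    """Gait frames show lower mean spectral entropy than static frames."""
    df = featurize_session(
        session_a, "gait", (SensorPlacement.LEFT_ANKLE, SensorPlacement.CHEST)
    )
    assert df.shape[1] == 45 + 3
    ent_col = "entropy__left_ankle_z"
    gait_ent = df.loc[df.label == "gait", ent_col].mean()
    rest = df.loc[df.label == "no_gait"]
    static_ent = rest.loc[rest[ent_col] > 0, ent_col].mean()
    assert gait_ent < static_ent
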