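"""Hyperparameters, flatten-width formula, and the classifier contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fbccnn.model import (
    FBCCNNClassifier,
    HyperparamSet,
    ModelSpec,
    build_model,
    channel_based_hyperparams,
    flatten_width,
)


class TestFlattenWidth:
    @pytest.mark.parametrize(
        "hp,nfft,expected",
        [
            (HyperparamSet(nfb=3, nk1=64, nk2=64, k2=64, s2=64), 110, 640),
            (HyperparamSet(nfb=1, nk1=64, nk2=16, k2=64, s2=8), 110, 320),
        ],
    )
    def test_reference_values(self, hp, nfft, expected):
        assert flatten_width(hp, nfft) == expected

    def test_full_width_kernel_single_position(self):
        hp = HyperparamSet(nfb=1, nk1=4, nk2=7, k2=220, s2=128)
        assert flatten_width(hp, 110) == 7

    def test_k2_exceeding_width_rejected(self):
        hp = HyperparamSet(nfb=1, nk1=4, nk2=4, k2=300, s2=10)
        with pytest.raises(ValueError, match="K2"):
            flatten_width(hp, 110)

    def test_s2_exceeding_k2_rejected(self):
        with pytest.raises(ValueError, match="S2"):
            HyperparamSet(nfb=1, nk1=4, nk2=4, k2=8, s2=16)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        s2a=st.integers(1, 32), s2b=st.integers(1, 32),
        k2a=st.integers(32, 64), k2b=st.integers(32, 64),
    )
    def test_monotone_in_stride_and_kernel(self, s2a, s2b, k2a, k2b):
        """Nf is non-increasing in S2 and in K2, other things fixed."""
        s_lo, s_hi = sorted((s2a, s2b))
        k_lo, k_hi = sorted((k2a, k2b))
        base = dict(nfb=1, nk1=8, nk2=8)
        w_slo = flatten_width(HyperparamSet(**base, k2=64, s2=s_lo), 110)
        w_shi = flatten_width(HyperparamSet(**base, k2=64, s2=s_hi), 110)
        assert w_slo >= w_shi
        w_klo = flatten_width(HyperparamSet(**base, k2=k_lo, s2=16), 110)
        w_khi = flatten_width(HyperparamSet(**base, k2=k_hi, s2=16), 110)
        assert w_klo >= w_khi


class TestChannelBasedSets:
    def test_three_band_at_8_channels(self):
        hp = channel_based_hyperparams(8, "three_band")
        assert hp == HyperparamSet(nfb=3, nk1=64, nk2=64, k2=64, s2=64)

    def test_three_band_at_64_channels(self):
        hp = channel_based_hyperparams(64, "three_band")
        assert (hp.nk1, hp.nk2, hp.k2, hp.s2) == (512, 512, 512, 512)

    def test_one_band_single_channel(self):
        hp = channel_based_hyperparams(1, "one_band")
        assert hp == HyperparamSet(nfb=1, nk1=8, nk2=2, k2=8, s2=1)

    def test_clamp_reported_when_k2_exceeds_width(self):
        with pytest.warns(UserWarning, match="clamped"):
            hp = channel_based_hyperparams(64, "three_band", nfft=50)
        assert hp.k2 == 2 * 50 * 3
        assert hp.s2 == hp.k2


class TestBuiltModel:
    def test_forward_shape_contract(self):
        hp = HyperparamSet(nfb=1, nk1=8, nk2=8, k2=32, s2=16)
        spec = ModelSpec(hp=hp, n_channels=4, nfft=55, n_classes=5)
        net = build_model(spec, seed=0)
        x = np.random.default_rng(0).standard_normal((6, 4, 110))
        logits, _ = net.forward(x)
        assert logits.shape == (6, 5)

    def test_optimized_three_band_set_builds(self):
        hp = HyperparamSet(nfb=3, nk1=64, nk2=64, k2=64, s2=64)
        spec = ModelSpec(hp=hp, n_channels=8, nfft=110, n_classes=12)
        net = build_model(spec, seed=0)
        assert net.flat_width == 640

    def test_forward_deterministic_without_dropout(self):
        hp = HyperparamSet(nfb=1, nk1=6, nk2=6, k2=16, s2=8)
        spec = ModelSpec(hp=hp, n_channels=3, nfft=30, n_classes=4, dropout=0.0)
        net = build_model(spec, seed=3)
        x = np.random.default_rng(1).standard_normal((5, 3, 60))
        l1, _ = net.forward(x)
        l2, _ = net.forward(x)
        np.testing.assert_array_equal(l1, l2)

    def test_inference_batchsize_invariance(self):
        """With BN in inference mode, batched and single-sample
        predictions agree."""
        hp = HyperparamSet(nfb=1, nk1=6, nk2=6, k2=16, s2=8)
        spec = ModelSpec(hp=hp, n_channels=3, nfft=30, n_classes=4)
        net = build_model(spec, seed=3)
        x = np.random.default_rng(2).standard_normal((8, 3, 60))
        batched = net.predict_logits(x)
        singles = np.vstack([net.predict_logits(x[i : i + 1]) for i in range(8)])
        np.testing.assert_allclose(batched, singles, rtol=1e-5, atol=1e-6)


class TestClassifierContract:
    def _fit_small(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 3, 40))
        y = rng.integers(0, 3, 60)
        X[np.arange(60), :, y * 5] += 4.0  # separable signature
        clf = FBCCNNClassifier(nfb=1, nk1=4, nk2=4, k2=10, s2=10,
                               epochs=10, random_state=0)
        return clf.fit(X, y), X, y

    def test_fit_predict_api(self):
        clf, X, y = self._fit_small()
        assert set(clf.predict(X)) <= set(clf.classes_)
        assert clf.predict_proba(X).shape == (60, 3)
        np.testing.assert_allclose(clf.predict_proba(X).sum(axis=1), 1.0,
                                   atol=1e-6)
        assert 0.0 <= clf.score(X, y) <= 1.0

    def test_get_set_params_roundtrip(self):
        clf = FBCCNNClassifier()
        params = clf.get_params()
        assert params["nfb"] == 3 and params["batch_size"] == 32
        clf.set_params(k2=32, s2=16)
        assert clf.k2 == 32
        with pytest.raises(ValueError, match="invalid parameter"):
            clf.set_params(bogus=1)

    def test_checkpoint_roundtrip(self, tmp_path):
        clf, X, _ = self._fit_small()
        path = tmp_path / "ckpt.npz"
        clf.save(path)
        clone = FBCCNNClassifier.load(path)
        np.testing.assert_array_equal(clone.predict(X), clf.predict(X))
        np.testing.assert_allclose(clone.decision_function(X),
                                   clf.decision_function(X), atol=1e-6)

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            FBCCNNClassifier().predict(np.zeros((1, 2, 12)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            FBCCNNClassifier(nfb=1, k2=4, s2=4).fit(
                np.zeros((5, 2, 12)), np.zeros(5, dtype=int)
            )
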