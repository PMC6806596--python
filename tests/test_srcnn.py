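import numpy as np
import pytest

from ramanpc.srcnn import (
    SRCNNWeights,
    bicubic_upscale,
    load_weights,
    make_patch_pairs,
    save_weights,
    srcnn_forward,
    srcnn_raw,
    superresolve,
    train_srcnn,
)


@pytest.fixture(scope="module")
def identity_w():
    return SRCNNWeights.identity()


class TestForward:
    def test_bias_only_network(self, rng):
        w = SRCNNWeights(
            w1=np.zeros((64, 1, 9, 9)), b1=np.zeros(64),
            w2=np.zeros((32, 64, 5, 5)), b2=np.zeros(32),
            w3=np.zeros((1, 32, 5, 5)), b3=np.array([0.5]),
        )
        out = srcnn_raw(rng.uniform(0, 1, (12, 12)), w)
        np.testing.assert_allclose(out, np.full((12, 12), 0.5))

    def test_identity_configuration(self, rng, identity_w):
        img01 = rng.uniform(0, 1, (15, 20))
        np.testing.assert_allclose(srcnn_raw(img01, identity_w), img01,
                                   atol=1e-12)

    def test_identity_on_255_scale(self, rng, identity_w):
        img = rng.uniform(0, 255, (20, 20))
        np.testing.assert_allclose(srcnn_forward(img, identity_w), img,
                                   atol=1e-9)

    @pytest.mark.parametrize("size", [20, 33, 64, 160])
    def test_shape_preserved(self, rng, size, identity_w):
        out = srcnn_forward(rng.uniform(0, 255, (size, size)), identity_w)
        assert out.shape == (size, size)

    def test_output_clipped(self, rng):
        w = SRCNNWeights.identity()
        w.b3 = np.array([5.0])  # push everything above 1 pre-clip
        out = srcnn_forward(rng.uniform(0, 255, (12, 12)), w)
        assert out.max() == 255.0

    def test_too_small_input(self, identity_w):
        with pytest.raises(ValueError):
            srcnn_forward(np.zeros((8, 8)), identity_w)

    def test_wrong_weight_shapes(self):
        with pytest.raises(ValueError):
            SRCNNWeights(
                w1=np.zeros((64, 1, 9, 9)), b1=np.zeros(64),
                w2=np.zeros((32, 64, 5, 5)), b2=np.zeros(32),
                w3=np.zeros((1, 32, 3, 3)), b3=np.zeros(1),
            )

    def test_translation_equivariance_on_periodic_pattern(self, rng):
        # an exactly periodic input rolled by (3, 5) is a pure translation,
        # so interior pixels (beyond the receptive-field radius) must follow
        w = SRCNNWeights.identity()
        for name in ("w1", "w2", "w3"):
            arr = getattr(w, name)
            setattr(w, name, 0.05 * rng.standard_normal(arr.shape))
        w.b1 = np.full(64, 0.05)
        w.b2 = np.full(32, 0.05)
        tile = rng.uniform(0, 1, (8, 8))
        img = np.tile(tile, (5, 5))
        out = srcnn_raw(img, w)
        out_shifted = srcnn_raw(np.roll(img, (3, 5), axis=(0, 1)), w)
        back = np.roll(out_shifted, (-3, -5), axis=(0, 1))
        # rolled-back pixels draw on out_shifted rows/cols shifted by (3, 5),
        # so the clean interior shrinks by the shift on the trailing edge
        np.testing.assert_allclose(out[8:-11, 8:-13], back[8:-11, 8:-13],
                                   atol=1e-10)


class TestSuperresolve:
    def test_20_to_320_in_four_doublings(self, rng, identity_w):
        out = superresolve(rng.uniform(0, 255, (20, 20)), identity_w)
        assert out.shape == (320, 320)

    def test_160_single_doubling(self, rng, identity_w):
        out = superresolve(rng.uniform(0, 255, (160, 160)), identity_w)
        assert out.shape == (320, 320)

    def test_already_large_unchanged(self, rng, identity_w):
        img = rng.uniform(0, 255, (320, 330))
        np.testing.assert_array_equal(superresolve(img, identity_w), img)

    def test_identity_equals_iterated_bicubic(self, rng, identity_w):
        img = rng.uniform(0, 255, (20, 20))
        net = superresolve(img, identity_w, target_min=80)
        bic = img
        while min(bic.shape) < 80:
            bic = bicubic_upscale(bic, 2)
        np.testing.assert_allclose(net, np.clip(bic, 0, 255), atol=1e-6)

    def test_rectangular_input(self, rng, identity_w):
        out = superresolve(rng.uniform(0, 255, (20, 30)), identity_w, target_min=40)
        assert out.shape == (40, 60)


@pytest.fixture(scope="module")
def tiny_pairs():
    rng = np.random.default_rng(3)
    imgs = [np.kron(rng.uniform(0, 255, (17, 17)), np.ones((2, 2)))]
    return make_patch_pairs(imgs, patch=34, stride=34)


class TestTraining:
    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            train_srcnn([], seed=0)

    def test_small_patch_rejected(self, rng):
        low = rng.uniform(0, 255, (10, 10))
        high = rng.uniform(0, 255, (20, 20))
        with pytest.raises(ValueError):
            train_srcnn([(low, high)], seed=0)

    def test_loss_decreases(self, tiny_pairs):
        losses = []
        train_srcnn(tiny_pairs, seed=0, epochs=8,
                    callback=lambda s, l: losses.append(l))
        assert losses[-1] < losses[0]

    def test_same_seed_bitwise_identical(self, tiny_pairs):
        runs = []
        for _ in range(2):
            losses = []
            train_srcnn(tiny_pairs, seed=5, epochs=2,
                        callback=lambda s, l: losses.append(l))
            runs.append(losses)
        assert runs[0] == runs[1]


class TestWeightIO:
    @pytest.fixture
    def random_w(self, rng):
        w = SRCNNWeights.identity()
        for name in ("w1", "b1", "w2", "b2", "w3", "b3"):
            arr = getattr(w, name)
            setattr(w, name, rng.standard_normal(arr.shape))
        return w

    @pytest.mark.parametrize("ext", [".json", ".npz"])
    def test_round_trip(self, tmp_path, random_w, ext):
        path = tmp_path / f"w{ext}"
        save_weights(random_w, path)
        back = load_weights(path)
        for name in ("w1", "b1", "w2", "b2", "w3", "b3"):
            np.testing.assert_array_equal(getattr(back, name),
                                          getattr(random_w, name))

    def test_truncated_file_errors(self, tmp_path, random_w):
        path = tmp_path / "w.json"
        save_weights(random_w, path)
        path.write_text(path.read_text()[: len(path.read_text()) // 2])
        with pytest.raises(Exception):
            load_weights(path)

    def test_forward_matches_after_round_trip(self, tmp_path, random_w, rng):
        img = rng.uniform(0, 255, (16, 16))
        before = srcnn_forward(img, random_w)
        path = tmp_path / "w.json"
        save_weights(random_w, path)
        after = srcnn_forward(img, load_weights(path))
        np.testing.assert_array_equal(before, after)
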