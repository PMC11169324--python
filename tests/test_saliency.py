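"""Score-CAM behaviour and saliency binarization."""

import numpy as np
import pytest
from skimage.transform import resize

from camval import nn
from camval.saliency import (SaliencyMap, binarize_original, binarize_otsu,
                             otsu_threshold, score_cam)
from camval.saliency import channel_weights
from camval.errors import ConfigurationError


def _toy(channels, seed=0):
    rng = np.random.default_rng(seed)
    return nn.Sequential([
        ("block1_conv", nn.Conv2D(1, channels, rng=rng, dtype=np.float64)),
        ("block1", nn.ReLU()),
        ("gap", nn.GlobalAvgPool()),
        ("fc", nn.Dense(channels, 2, rng=rng, dtype=np.float64)),
    ])


def _smap(values):
    return SaliencyMap(values=values, model_id="m", target_class=1,
                       layer_name="block1")


class TestScoreCam:
    def test_single_channel_closed_form(self):
        # with one channel the softmax weight is exactly 1, so the map is
        # the min-max normalized ReLU of the upsampled activation
        model = _toy(1, seed=4)
        rng = np.random.default_rng(1)
        img = rng.random((16, 16))
        smap = score_cam(model, img, target_class=1, layer_name="block1")
        _, cap = model.forward(img[None, None], capture=["block1"])
        act = cap["block1"][0, 0]
        up = resize(act, img.shape, order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
        up = np.maximum(up, 0.0)
        expected = up / up.max() if up.max() > 0 else up
        assert np.allclose(smap.values, expected, atol=1e-12)

    def test_alpha_weights_sum_to_one(self):
        model = _toy(6, seed=2)
        img = np.random.default_rng(3).random((16, 16))
        alpha, ups = channel_weights(model, img, 1, "block1")
        assert alpha.shape == (6,)
        assert alpha.sum() == pytest.approx(1.0, abs=1e-6)
        assert ups.shape == (6, 16, 16)

    def test_alpha_ordering_matches_direct_forward_oracle(self):
        # oracle: score the two masked inputs directly; the channel whose
        # masked input raises the class score more must get the larger alpha
        model = _toy(2, seed=7)
        img = np.random.default_rng(5).random((16, 16))
        alpha, ups = channel_weights(model, img, target_class=1,
                                     layer_name="block1")
        scores = []
        for k in range(2):
            u = ups[k]
            u = (u - u.min()) / (u.max() - u.min()) if u.max() > u.min() else u * 0
            masked = (u * img)[None, None]
            scores.append(model.predict_proba(masked)[0, 1])
        assert (alpha[0] > alpha[1]) == (scores[0] > scores[1])

    def test_invariant_to_channel_ordering(self):
        model = _toy(3, seed=9)
        img = np.random.default_rng(8).random((16, 16))
        base = score_cam(model, img, 1, "block1").values
        # permute conv output channels and the matching fc input columns
        perm = [2, 0, 1]
        conv = model.layers[0][1]
        fc = model.layers[3][1]
        conv.params["w"][...] = conv.params["w"][perm]
        conv.params["b"][...] = conv.params["b"][perm]
        fc.params["w"][...] = fc.params["w"][:, perm]
        permuted = score_cam(model, img, 1, "block1").values
        assert np.allclose(base, permuted, atol=1e-10)

    def test_nearest_interpolation_closed_form(self):
        # with nearest-neighbor upsampling the map is exactly blockwise
        model = _toy(1, seed=4)
        img = np.random.default_rng(2).random((16, 16))
        smap = score_cam(model, img, 1, "block1", interpolation="nearest")
        _, cap = model.forward(img[None, None], capture=["block1"])
        act = np.maximum(cap["block1"][0, 0], 0.0)  # conv output is 16x16 here
        expected = act / act.max() if act.max() > 0 else act
        assert np.allclose(smap.values, expected, atol=1e-12)

    def test_rejects_unnormalized_input(self):
        model = _toy(1)
        with pytest.raises(ConfigurationError):
            score_cam(model, np.full((16, 16), 3.0), 1, "block1")

    def test_unknown_layer_raises(self):
        model = _toy(1)
        with pytest.raises(KeyError):
            score_cam(model, np.zeros((16, 16)), 1, "blockX")


class TestBinarizeOriginal:
    def test_zero_map_gives_empty_mask(self):
        b = binarize_original(_smap(np.zeros((8, 8))))
        assert b.variant == "S_o" and not b.mask.any()

    def test_mask_equals_support_at_floor_zero(self):
        rng = np.random.default_rng(0)
        v = rng.random((12, 12))
        v[v < 0.4] = 0.0
        b = binarize_original(_smap(v))
        assert np.array_equal(b.mask, v > 0)

    def test_floor_on_linear_ramp(self):
        v = np.linspace(0, 1, 101)[None, :].repeat(2, axis=0)
        b = binarize_original(_smap(v), activation_floor=0.1)
        assert b.mask.sum() == 2 * int((v[0] > 0.1).sum())


class TestBinarizeOtsu:
    def test_bimodal_split(self):
        v = np.zeros((10, 10))
        v[:5] = 0.1
        v[5:] = 0.9
        b = binarize_otsu(_smap(v))
        assert 0.1 < b.threshold_used < 0.9
        assert np.array_equal(b.mask, v > 0.5)

    def test_threshold_matches_exhaustive_search(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            v = np.clip(rng.beta(0.5, 0.5, size=(20, 20)), 0, 1)
            thr, _ = otsu_threshold(v)
            # independent exhaustive search over every bin split
            hist, edges = np.histogram(v, bins=256, range=(0, 1))
            centers = (edges[:-1] + edges[1:]) / 2
            best, best_t = -1.0, None
            total = hist.sum()
            for t in range(255):
                w0 = hist[: t + 1].sum() / total
                w1 = 1 - w0
                if w0 == 0 or w1 == 0:
                    continue
                mu0 = (hist[: t + 1] * centers[: t + 1]).sum() / hist[: t + 1].sum()
                mu1 = (hist[t + 1:] * centers[t + 1:]).sum() / hist[t + 1:].sum()
                var = w0 * w1 * (mu0 - mu1) ** 2
                if var > best:
                    best, best_t = var, edges[t + 1]
            assert thr == pytest.approx(best_t, abs=1e-12)

    def test_sh_subset_of_so(self):
        rng = np.random.default_rng(6)
        v = rng.random((16, 16))
        v[v < 0.3] = 0
        smap = _smap(v)
        so = binarize_original(smap)
        sh = binarize_otsu(smap)
        assert not (sh.mask & ~so.mask).any()
        assert sh.mask.sum() < so.mask.sum()

    def test_constant_map_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            b = binarize_otsu(_smap(np.full((8, 8), 0.5)))
        assert b.degenerate and not b.mask.any()
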