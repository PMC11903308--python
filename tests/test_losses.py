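"""Loss correctness against brute-force oracles and the frozen-net contract."""

import numpy as np
import pytest

from cellrestore import autograd as ag
from cellrestore.flows import FlowTarget, masks_to_flows
from cellrestore.losses import (
    FrozenSegmenterError,
    LossWeights,
    perceptual_loss,
    reconstruction_loss,
    seg_output_loss,
    segmentation_loss,
    total_loss,
)
from cellrestore.nets import Module, NetConfig, build_net
from cellrestore.simcells import generate_cell_image
from cellrestore.train import AdamW


@pytest.fixture(scope="module")
def frozen_seg():
    return build_net(NetConfig(out_mode="segment", seed=0)).freeze()


@pytest.fixture(scope="module")
def toy_case():
    li = generate_cell_image(3, 12, (64, 64), seed=2)
    from cellrestore.degrade import normalize_percentile

    return normalize_percentile(li.image), masks_to_flows(li.masks)


class TestReconstruction:
    def test_zero_at_equality(self):
        x = np.random.default_rng(0).random((16, 16))
        assert reconstruction_loss(x, x).item() == 0.0

    def test_unit_offset_gives_one(self):
        x = np.random.default_rng(0).random((16, 16))
        assert reconstruction_loss(x + 1.0, x).item() == pytest.approx(1.0, rel=1e-6)

    def test_matches_mean_square_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((2, 16, 16))
        assert reconstruction_loss(a, b).item() == pytest.approx(
            float(np.mean((a - b) ** 2)), abs=1e-8
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((8, 8)), np.zeros((8, 9)))


class _OracleSeg(Module):
    """Stub segmenter returning exactly the ground-truth flows, +/-10 logits."""

    def __init__(self, ft: FlowTarget):
        super().__init__()
        arr = ft.stacked().copy()
        arr[2] = np.where(ft.cellprob, 10.0, -10.0)
        self._out = arr[None]
        self.frozen = True

    def __call__(self, x):
        return ag.Tensor(self._out)


class TestSegmentationLoss:
    def test_unfrozen_net_rejected(self, toy_case):
        img, ft = toy_case
        net = build_net(NetConfig(out_mode="segment", seed=1))
        with pytest.raises(FrozenSegmenterError):
            segmentation_loss(img, ft, net)

    def test_perfect_prediction_floor(self, toy_case):
        img, ft = toy_case
        loss = segmentation_loss(img, ft, _OracleSeg(ft))
        assert loss.item() < 1e-3

    def test_flow_term_scales_by_five(self, toy_case):
        """A constant flow offset delta raises the loss by 5 * delta^2."""
        _, ft = toy_case
        base = seg_output_loss(ag.Tensor(_OracleSeg(ft)._out), ft).item()
        for delta in (0.1, 0.2):
            shifted = _OracleSeg(ft)._out.copy()
            shifted[:, :2] += delta
            pert = seg_output_loss(ag.Tensor(shifted), ft).item()
            assert pert - base == pytest.approx(5 * delta**2, rel=1e-5)

    def test_matches_brute_force_oracle(self, frozen_seg, toy_case):
        img, ft = toy_case
        out = np.asarray(frozen_seg(img[None, None]).data)[0]
        fy, fx, logits = out
        mse = (np.mean((fy - ft.flow_y) ** 2) + np.mean((fx - ft.flow_x) ** 2)) / 2
        p = 1 / (1 + np.exp(-logits))
        t = ft.cellprob.astype(float)
        eps = 0.0
        bce = -np.mean(t * np.log(p) + (1 - t) * np.log(1 - p))
        expected = 5 * mse + bce
        got = segmentation_loss(img, ft, frozen_seg).item()
        assert got == pytest.approx(expected, rel=1e-5)

    def test_frozen_params_untouched_by_optimization(self, frozen_seg, toy_case):
        img, ft = toy_case
        before = frozen_seg.param_hash()
        x = ag.Tensor(img[None, None].astype(np.float32), requires_grad=True)
        opt = AdamW([x], weight_decay=0.0)
        for _ in range(3):
            x.zero_grad()
            loss = segmentation_loss(x, ft, frozen_seg)
            loss.backward()
            opt.step(0.01)
        assert frozen_seg.param_hash() == before
        assert x.grad is not None  # gradients did reach the restored image


class TestPerceptualLoss:
    def test_zero_at_equality(self, frozen_seg, toy_case):
        img, _ = toy_case
        assert perceptual_loss(img, img, frozen_seg).item() == 0.0

    def test_matches_explicit_loop_oracle(self, frozen_seg, toy_case):
        img, _ = toy_case
        rng = np.random.default_rng(3)
        noisy = img + 0.2 * rng.normal(size=img.shape).astype(np.float32)
        feats_p = [np.asarray(f.data) for f in frozen_seg.features(noisy[None, None])]
        feats_t = [np.asarray(f.data) for f in frozen_seg.features(img[None, None])]

        def corr(a):
            c, p = a.shape[1], a.shape[2] * a.shape[3]
            z = a.reshape(1, c, p).astype(np.float64)
            out = np.zeros((c, c))
            zs = np.zeros_like(z[0])
            for i in range(c):
                v = z[0, i]
                zs[i] = (v - v.mean()) / np.sqrt(v.var() + 1e-12)
            for i in range(c):
                for j in range(c):
                    out[i, j] = np.mean(zs[i] * zs[j])
            return out

        blocks = []
        for fp, ft_ in zip(feats_p, feats_t):
            cp, ct = corr(fp), corr(ft_)
            blocks.append(np.mean((cp - ct) ** 2) / (np.std(ct) + 1e-6))
        expected = float(np.mean(blocks))
        got = perceptual_loss(noisy, img, frozen_seg).item()
        assert got == pytest.approx(expected, rel=1e-4)

    def test_target_scale_invariance(self, frozen_seg, toy_case):
        """Correlation matrices ignore per-channel affine scaling of activations."""
        from cellrestore.losses import _correlation_matrices

        rng = np.random.default_rng(4)
        feat = ag.Tensor(rng.normal(size=(1, 6, 10, 10)))
        a = _correlation_matrices(feat).data
        b = _correlation_matrices(ag.Tensor(2.0 * feat.data)).data
        assert a == pytest.approx(b, abs=1e-10)

    def test_unfrozen_net_rejected(self, toy_case):
        img, _ = toy_case
        net = build_net(NetConfig(out_mode="segment", seed=1))
        with pytest.raises(FrozenSegmenterError):
            perceptual_loss(img, img, net)

    def test_blocks_contribute_comparable_magnitude(self, toy_seg_net):
        """With a trained feature extractor and realistic degraded/clean pairs,
        per-block normalized losses stay within one order of magnitude."""
        from cellrestore.degrade import DegradationSpec, apply_degradation, normalize_percentile
        from cellrestore.losses import STD_EPS, _correlation_matrices

        spec = DegradationSpec(mode="denoise", apply_noise=True, poisson_scale=8.0)
        spreads = []
        for i in range(20):
            li = generate_cell_image(6, 18, (64, 64), seed=500 + i)
            clean = normalize_percentile(li.image)
            noisy = apply_degradation(li, spec, np.random.default_rng(i))
            fp = toy_seg_net.features(noisy[None, None].astype(np.float32))
            ft_ = toy_seg_net.features(clean[None, None].astype(np.float32))
            blocks = []
            for a, b in zip(fp, ft_):
                ca, cb = _correlation_matrices(a).data, _correlation_matrices(b).data
                blocks.append(np.mean((ca - cb) ** 2) / (np.std(cb) + STD_EPS))
            blocks = np.asarray(blocks)
            spreads.append(blocks.max() / max(blocks.min(), 1e-12))
        assert np.median(spreads) < 10


class TestTotalLoss:
    def test_reconstruction_only_weights(self, frozen_seg, toy_case):
        img, ft = toy_case
        noisy = img + 0.1
        loss, terms = total_loss(noisy, img, ft, frozen_seg, LossWeights(1.0, 0.0, 0.0))
        assert loss.item() == pytest.approx(reconstruction_loss(noisy, img).item(), rel=1e-6)
        assert set(terms) == {"reconstruction", "total"}

    def test_linearity_in_weights(self, frozen_seg, toy_case):
        img, ft = toy_case
        noisy = (img + 0.05 * np.random.default_rng(6).normal(size=img.shape)).astype(np.float32)
        parts = {}
        for name, w in [
            ("rec", LossWeights(1, 0, 0)),
            ("seg", LossWeights(0, 1, 0)),
            ("per", LossWeights(0, 0, 1)),
        ]:
            parts[name], _ = total_loss(noisy, img, ft, frozen_seg, w)
        for wr, ws, wp in [(1, 1, 1), (2, 0.5, 0), (0, 3, 1)]:
            combined, _ = total_loss(noisy, img, ft, frozen_seg, LossWeights(wr, ws, wp))
            expected = (
                wr * parts["rec"].item() + ws * parts["seg"].item() + wp * parts["per"].item()
            )
            assert combined.item() == pytest.approx(expected, rel=1e-5)

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            LossWeights(0, 0, 0)
        with pytest.raises(ValueError):
            LossWeights(-1, 1, 1)
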