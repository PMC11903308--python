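"""Training objectives for task-driven restoration.

Three terms, combined by :func:`total_loss`:

* reconstruction — pixelwise mean squared error to the clean image;
* segmentation — the restored image is pushed through a *frozen* flow-field
  segmentation network; the loss is 5x the MSE between predicted and
  ground-truth flows plus the binary cross-entropy between predicted
  cell-probability logits and the binary mask.  Gradients reach the
  restorer through the segmentation network, whose own weights never
  update;
* perceptual — for each encoder level of the frozen segmentation network,
  the Pearson channel-channel correlation matrix of the activations is
  computed for the restored and the clean image; the block loss is the MSE
  between the two matrices normalized by the s.d. of the target matrix's
  entries (so every block contributes comparable variance), averaged over
  blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .flows import FlowTarget

STD_EPS = 1e-6  # guards constant activation channels


class FrozenSegmenterError(RuntimeError):
    """The segmentation network must be frozen before it is used as a loss."""


@dataclass
class LossWeights:
    """Relative weights of the three objectives; flow MSE is scaled by 5."""

    w_rec: float = 0.0
    w_seg: float = 1.0
    w_per: float = 1.0
    flow_scale: float = 5.0

    def __post_init__(self):
        if min(self.w_rec, self.w_seg, self.w_per) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.w_rec == self.w_seg == self.w_per == 0:
            raise ValueError("at least one loss weight must be positive")


def _as_batch(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    return Tensor(x)


def _check_frozen(seg_net) -> None:
    if not getattr(seg_net, "frozen", False):
        raise FrozenSegmenterError(
            "segmentation network must be frozen (call seg_net.freeze()) before "
            "being used inside a restoration loss"
        )


def _stack_targets(gt) -> np.ndarray:
    """FlowTarget or list of FlowTargets -> (N, 3, H, W) array."""
    if isinstance(gt, FlowTarget):
        gt = [gt]
    return np.stack([t.stacked() for t in gt]).astype(np.float32)


def reconstruction_loss(pred_image, target_image) -> Tensor:
    """Mean squared error over all pixels and channels."""
    pred = _as_batch(pred_image)
    target = _as_batch(target_image)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return ag.mean((pred - target.detach()) ** 2.0)


def seg_output_loss(seg_out: Tensor, gt, flow_scale: float = 5.0) -> Tensor:
    """Flow-and-probability loss on a raw (N, 3, H, W) segmentation output.

    ``flow_scale`` x MSE over the two unit-norm flow channels plus BCE on
    the cell-probability logits.  Used both for training segmentation
    networks directly and, through a frozen network, for the restoration
    segmentation loss.
    """
    target = _stack_targets(gt)
    pred_flows = ag.mul(seg_out, _flow_selector(seg_out.shape))
    gt_flows = target.copy()
    gt_flows[:, 2] = 0.0
    flow_mse = ag.mean((pred_flows - Tensor(gt_flows)) ** 2.0) * (3.0 / 2.0)
    logits = _channel(seg_out, 2)
    bce = ag.bce_with_logits(logits, target[:, 2])
    return flow_scale * flow_mse + bce


def _flow_selector(shape) -> np.ndarray:
    sel = np.zeros((1, shape[1], 1, 1), dtype=np.float32)
    sel[:, :2] = 1.0
    return sel


def _channel(x: Tensor, c: int) -> Tensor:
    n, _, h, w = x.shape
    sel = np.zeros((1, x.shape[1], 1, 1), dtype=np.float32)
    sel[0, c, 0, 0] = 1.0
    return ag.sum_(ag.mul(x, sel), axis=1)


def segmentation_loss(restored_image, gt, seg_net, flow_scale: float = 5.0) -> Tensor:
    """Task loss: run the restored image through the frozen segmenter.

    ``gt`` is a FlowTarget (or list for a batch) computed from the clean
    ground-truth masks.  Gradients flow back to ``restored_image``; the
    segmentation network's parameters receive none.
    """
    _check_frozen(seg_net)
    seg_out = seg_net(_as_batch(restored_image))
    return seg_output_loss(seg_out, gt, flow_scale=flow_scale)


def _correlation_matrices(feat: Tensor) -> Tensor:
    """Per-sample Pearson channel-channel correlation of (N, C, H, W) features."""
    n, c, h, w = feat.shape
    z = ag.reshape(feat, (n, c, h * w))
    mu = ag.mean(z, axis=2, keepdims=True)
    zc = z - mu
    var = ag.mean(zc**2.0, axis=2, keepdims=True)
    zn = zc * ((var + STD_EPS**2) ** -0.5)
    return ag.bmm(zn, ag.transpose_last2(zn)) * (1.0 / (h * w))


def perceptual_loss(restored_image, target_image, seg_net) -> Tensor:
    """Correlation-matrix discrepancy across the frozen segmenter's encoder.

    Per block: MSE between restored and target correlation matrices,
    divided by the s.d. of the target matrix entries; the total is the
    mean over blocks.  The target branch carries no gradients.
    """
    _check_frozen(seg_net)
    feats_pred = seg_net.features(_as_batch(restored_image))
    feats_tgt = seg_net.features(_as_batch(target_image).detach())
    total = None
    for fp, ft in zip(feats_pred, feats_tgt):
        corr_p = _correlation_matrices(fp)
        corr_t = _correlation_matrices(ft).data  # constant target
        sd = float(np.std(corr_t)) + STD_EPS
        block = ag.mean((corr_p - Tensor(corr_t)) ** 2.0) * (1.0 / sd)
        total = block if total is None else total + block
    return total * (1.0 / len(feats_pred))


def total_loss(
    restored, clean, gt, seg_net, weights: LossWeights
) -> tuple[Tensor, dict[str, float]]:
    """Weighted sum of the three objectives plus a per-term breakdown."""
    terms: dict[str, float] = {}
    total = Tensor(np.float32(0.0))
    if weights.w_rec > 0:
        rec = reconstruction_loss(restored, clean)
        terms["reconstruction"] = rec.item()
        total = total + weights.w_rec * rec
    if weights.w_seg > 0:
        seg = segmentation_loss(restored, gt, seg_net, flow_scale=weights.flow_scale)
        terms["segmentation"] = seg.item()
        total = total + weights.w_seg * seg
    if weights.w_per > 0:
        per = perceptual_loss(restored, clean, seg_net)
        terms["perceptual"] = per.item()
        total = total + weights.w_per * per
    terms["total"] = total.item()
    return total, terms
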