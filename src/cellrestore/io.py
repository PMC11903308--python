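"""Image I/O and the one-call restore/segment entry points.

Images are TIFF or PNG, 8/16-bit integer or 32-bit float, one or two
channels.  Integer data is converted to float without rescaling —
percentile normalization is an explicit downstream step.  Label masks are
written as 16-bit TIFFs with 0 as background.

``restore_image`` and ``segment_image`` handle the full resize contract:
the caller supplies the mean object diameter, the image is resized so
objects match the network's training diameter (30 px for cytoplasm
models, 17 px for nucleus models), reflect-padded to the U-net's
divisibility requirement, run through the network, cropped and resized
back.  Masks are resized with nearest-neighbour interpolation so labels
stay integral.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.transform import resize

from .flows import SegOutput, flows_to_masks, relabel
from .degrade import normalize_percentile
from .nets import UNet, load_checkpoint

SUPPORTED_DTYPES = ("uint8", "uint16", "int16", "float32", "float64")


def read_image(path) -> np.ndarray:
    """Read a TIFF/PNG image as a float32 channel-last array (H, W[, 2])."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.dtype.name not in SUPPORTED_DTYPES:
        raise ValueError(f"unsupported bit depth {arr.dtype} in {path.name}")
    if arr.ndim == 3:
        if arr.shape[0] <= 2 < min(arr.shape[1:]):  # channel-first 2-channel stack
            arr = np.moveaxis(arr, 0, -1)
        if arr.shape[-1] > 2:
            raise ValueError(
                f"{path.name} has {arr.shape[-1]} channels; only 1-2 channel "
                "images are supported (no RGB)"
            )
    elif arr.ndim != 2:
        raise ValueError(f"{path.name} is not a 2D image (ndim={arr.ndim})")
    return arr.astype(np.float32)


def write_image(path, image: np.ndarray) -> None:
    """Write an image; 16-bit TIFF round-trips uint16 data bit-exactly."""
    path = Path(path)
    arr = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_masks(path) -> np.ndarray:
    masks = tifffile.imread(path)
    if not np.issubdtype(masks.dtype, np.integer):
        raise ValueError(f"{Path(path).name} is not an integer label image")
    return masks.astype(np.int32)


def write_masks(path, masks: np.ndarray) -> None:
    if masks.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 instances; cannot write 16-bit labels")
    tifffile.imwrite(path, np.asarray(masks).astype(np.uint16))


# -- padding ---------------------------------------------------------------

def pad_to_multiple(image: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple]:
    """Reflect-pad spatial dims up to the next multiple; returns (padded, crop)."""
    h, w = image.shape[:2]
    ph = (-h) % multiple
    pw = (-w) % multiple
    pad = ((0, ph), (0, pw)) + ((0, 0),) * (image.ndim - 2)
    return np.pad(image, pad, mode="reflect"), (slice(0, h), slice(0, w))


def _as_net(net_or_path) -> UNet:
    if callable(net_or_path) and hasattr(net_or_path, "config"):
        return net_or_path
    return load_checkpoint(net_or_path)


def _resize_factor(diameter: float, target: float) -> float:
    if not diameter > 0:
        raise ValueError("diameter must be positive")
    return target / diameter


def restore_image(image: np.ndarray, net_or_checkpoint, diameter: float,
                  diameter_target: float = 30.0) -> np.ndarray:
    """Normalize, resize to the training diameter, restore, resize back."""
    net = _as_net(net_or_checkpoint)
    if net.config.out_mode != "restore":
        raise ValueError("checkpoint is not a restoration network")
    x = normalize_percentile(np.asarray(image, np.float32))
    factor = _resize_factor(diameter, diameter_target)
    h, w = x.shape[:2]
    if abs(factor - 1.0) > 1e-3:
        x = resize(x, (round(h * factor), round(w * factor)), order=1,
                   preserve_range=True, anti_aliasing=factor < 1).astype(np.float32)
    xp, crop = pad_to_multiple(x, 2 ** net.config.n_blocks)
    out = net(xp[None, None] if xp.ndim == 2 else np.moveaxis(xp, -1, 0)[None])
    r = np.asarray(out.data)[0]
    restored = r[0][crop] if r.shape[0] == 1 else np.moveaxis(r, 0, -1)[crop[0], crop[1], :]
    if abs(factor - 1.0) > 1e-3:
        restored = resize(restored, (h, w), order=1, preserve_range=True,
                          anti_aliasing=factor > 1).astype(np.float32)
    return restored.astype(np.float32)


def segment_image(
    image: np.ndarray,
    net_or_checkpoint,
    diameter: float,
    cellprob_threshold: float = 0.0,
    flow_threshold: float = 0.4,
    niter: int = 200,
    diameter_target: float = 30.0,
) -> np.ndarray:
    """Resize, run the segmentation network, follow flows, resize masks back.

    Defaults follow standard evaluation practice: cell-probability
    threshold 0 and flow-error threshold 0.4.
    """
    net = _as_net(net_or_checkpoint)
    if net.config.out_mode != "segment":
        raise ValueError("checkpoint is not a segmentation network")
    x = normalize_percentile(np.asarray(image, np.float32))
    factor = _resize_factor(diameter, diameter_target)
    h, w = x.shape[:2]
    if abs(factor - 1.0) > 1e-3:
        x = resize(x, (round(h * factor), round(w * factor)), order=1,
                   preserve_range=True, anti_aliasing=factor < 1).astype(np.float32)
    xp, crop = pad_to_multiple(x, 2 ** net.config.n_blocks)
    out = np.asarray(net(xp[None, None] if xp.ndim == 2 else np.moveaxis(xp, -1, 0)[None]).data)[0]
    seg = SegOutput.from_array(out[:, crop[0], crop[1]])
    masks = flows_to_masks(
        seg, cellprob_threshold=cellprob_threshold, flow_threshold=flow_threshold, niter=niter
    )
    if abs(factor - 1.0) > 1e-3:
        masks = resize(masks, (h, w), order=0, preserve_range=True,
                       anti_aliasing=False).astype(np.int32)
    return relabel(masks.astype(np.int32))
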