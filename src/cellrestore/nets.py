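"""Residual U-net backbone for restoration and flow-field segmentation.

One architecture serves two roles.  In ``restore`` mode the head emits a
same-shape image (linear output, no clamp); in ``segment`` mode it emits
three maps: the y flow, the x flow and the cell-probability logit.  The
activations at each downsampling block can be tapped, which is what the
perceptual loss consumes.

The encoder has ``n_blocks`` levels.  Each level contains four 3x3
convolutions arranged as two residual units; levels after the first are
preceded by 2x2 average pooling.  The decoder mirrors the encoder with
nearest-neighbour upsampling and additive skip connections.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    channels_per_block defaults to a desk-scale width (8, 16, 32, 64) that
    trains in minutes on a CPU; the full-scale width used by generalist
    segmentation models is reachable by passing wider channels.
    """

    n_blocks: int = 4
    channels_per_block: tuple = (8, 16, 32, 64)
    in_channels: int = 1
    out_mode: str = "restore"  # "restore" | "segment"
    seed: int = 0

    def __post_init__(self):
        self.channels_per_block = tuple(self.channels_per_block)
        if len(self.channels_per_block) != self.n_blocks:
            raise ValueError("channels_per_block must have n_blocks entries")
        if any(b > a for a, b in zip(self.channels_per_block[1:], self.channels_per_block)):
            raise ValueError("channels_per_block must be nondecreasing")
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")
        if self.out_mode not in ("restore", "segment"):
            raise ValueError("out_mode must be 'restore' or 'segment'")

    @property
    def out_channels(self) -> int:
        return self.in_channels if self.out_mode == "restore" else 3

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


class Module:
    """Tiny module base: parameter registry, freezing, state dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.frozen = False

    def register(self, name: str, tensor: Tensor) -> Tensor:
        self._params[name] = tensor
        return tensor

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, p) for name, p in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def freeze(self) -> "Module":
        for p in self.parameters():
            p.requires_grad = False
        self.frozen = True
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.data.shape)

    def param_hash(self) -> str:
        h = hashlib.sha256()
        for name, p in sorted(self.named_parameters()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 init_scale: float = 1.0):
        super().__init__()
        fan_in = cin * k * k
        w = rng.normal(0.0, init_scale * np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.weight = self.register("weight", Tensor(w.astype(np.float32), requires_grad=True))
        self.bias = self.register("bias", Tensor(np.zeros(cout, np.float32), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias)


class ResUnit(Module):
    """Two 3x3 convolutions with a residual connection.

    A 1x1 projection aligns channels when cin != cout.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, rng)
        # damped residual branch keeps activation variance near the identity
        # path at initialization, regardless of depth
        self.conv2 = Conv2d(cout, cout, 3, rng, init_scale=0.1)
        self.proj = Conv2d(cin, cout, 1, rng) if cin != cout else None

    def __call__(self, x: Tensor) -> Tensor:
        shortcut = self.proj(x) if self.proj is not None else x
        h = ag.relu(self.conv1(x))
        return ag.relu(shortcut + self.conv2(h))


class DownBlock(Module):
    """One encoder level: four convolutions as two residual units."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.unit1 = ResUnit(cin, cout, rng)
        self.unit2 = ResUnit(cout, cout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.unit2(self.unit1(x))


class UpBlock(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv_up = Conv2d(cin, cout, 3, rng)
        self.unit = ResUnit(cout, cout, rng)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        h = ag.relu(self.conv_up(ag.upsample2(x)))
        return self.unit(h + skip)


class UNet(Module):
    """Residual U-net; use :func:`build_net` rather than constructing directly."""

    def __init__(self, config: NetConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        chans = config.channels_per_block
        self.down_blocks: list[DownBlock] = []
        cin = config.in_channels
        for i, c in enumerate(chans):
            block = DownBlock(cin, c, rng)
            setattr(self, f"down{i}", block)
            self.down_blocks.append(block)
            cin = c
        self.up_blocks: list[UpBlock] = []
        for i in range(config.n_blocks - 1, 0, -1):
            block = UpBlock(chans[i], chans[i - 1], rng)
            setattr(self, f"up{i}", block)
            self.up_blocks.append(block)
        self.head = Conv2d(chans[0], config.out_channels, 3, rng, init_scale=0.1)

    # -- forward ----------------------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        h, w = x.shape[-2:]
        div = 2 ** self.config.n_blocks
        if h % div or w % div:
            raise ValueError(
                f"spatial dims ({h}, {w}) must be divisible by {div}; "
                "reflect-pad the input (see cellrestore.io.pad_to_multiple)"
            )

    def _encode(self, x: Tensor) -> list[Tensor]:
        taps = []
        h = x
        for i, block in enumerate(self.down_blocks):
            if i > 0:
                h = ag.avg_pool2(h)
            h = block(h)
            taps.append(h)
        return taps

    def __call__(self, x) -> Tensor:
        x = self._as_input(x)
        self._check_shape(x.data)
        taps = self._encode(x)
        h = taps[-1]
        for block, skip in zip(self.up_blocks, taps[-2::-1]):
            h = block(h, skip)
        return self.head(h)

    def features(self, x) -> list[Tensor]:
        """Downsampling-block activations, highest resolution first."""
        x = self._as_input(x)
        self._check_shape(x.data)
        return self._encode(x)

    def _as_input(self, x) -> Tensor:
        if isinstance(x, Tensor):
            return x
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[None]
        return Tensor(x)


def build_net(config: NetConfig) -> UNet:
    """Build a seeded residual U-net per the given configuration."""
    return UNet(config)


def downsampling_features(net: UNet, image) -> list[Tensor]:
    """Activations at each encoder level, in order of decreasing resolution."""
    return net.features(image)


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(path, net: UNet) -> None:
    """Serialize weights plus a JSON config header into a single .npz file."""
    state = net.state_dict()
    meta = json.dumps({"config": asdict(net.config), "hash": net.config.config_hash()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> UNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = NetConfig(**meta["config"])
        if cfg.config_hash() != meta["hash"]:
            raise ValueError("checkpoint config hash mismatch")
        net = build_net(cfg)
        net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return net
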