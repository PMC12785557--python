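"""U-Net and stacked Double U-Net graphs built from the NumPy layers.

Architecture (per U-Net): ``depth`` encoder levels of
[Conv3x3 -> BN -> ReLU] x 2 followed by 2x2 max-pooling, a double-conv
bottleneck, and mirrored decoder levels of 2x2 transposed convolution,
skip concatenation and a double conv. A 1x1 convolution plus sigmoid
emits the per-pixel foreground probability.

The Double U-Net stacks two such networks: the first produces a coarse
probability map; a bridge combines it with the raw input (elementwise
product by default, channel concatenation as an option) and the second
U-Net refines it. Training supervises only the final map.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm, Conv2D, ConvTranspose2, Layer, MaxPool2, ReLU, sigmoid

__all__ = ["UNet", "DoubleUNet"]

_F32 = np.float32


class _DoubleConv:
    """[Conv -> BN -> ReLU] x 2 block."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.layers: list[Layer] = [
            Conv2D(cin, cout, 3, rng),
            BatchNorm(cout),
            ReLU(),
            Conv2D(cout, cout, 3, rng),
            BatchNorm(cout),
            ReLU(),
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, d: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            d = lay.backward(d)
        return d


class UNet:
    """Single encoder-decoder U-Net with skip connections."""

    def __init__(
        self,
        in_channels: int,
        depth: int = 3,
        base_filters: int = 16,
        rng: np.random.Generator | None = None,
    ):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        if base_filters < 4:
            raise ValueError("base_filters must be >= 4")
        rng = rng if rng is not None else np.random.default_rng()
        self.depth = depth
        self.in_channels = in_channels
        f = base_filters
        self.enc: list[_DoubleConv] = []
        self.pools: list[MaxPool2] = []
        cin = in_channels
        for lvl in range(depth):
            self.enc.append(_DoubleConv(cin, f * 2**lvl, rng))
            self.pools.append(MaxPool2())
            cin = f * 2**lvl
        self.bottleneck = _DoubleConv(cin, f * 2**depth, rng)
        self.ups: list[ConvTranspose2] = []
        self.dec: list[_DoubleConv] = []
        for lvl in reversed(range(depth)):
            cout = f * 2**lvl
            self.ups.append(ConvTranspose2(cout * 2, cout, rng))
            self.dec.append(_DoubleConv(cout * 2, cout, rng))
        self.head = Conv2D(f, 1, 1, rng)

    # -- execution -------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Return the sigmoid probability map (N, H, W, 1)."""
        h, w = x.shape[1:3]
        div = 2**self.depth
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth={div}; "
                "choose a patch size that pools evenly"
            )
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=-1)
            x = dec.forward(x, train)
        logits = self.head.forward(x, train)
        p = sigmoid(logits)
        if train:
            self._p = p
        return p

    def backward(self, dp: np.ndarray) -> np.ndarray:
        """Backprop from d(loss)/d(probability); returns d(loss)/d(input)."""
        d = (dp * self._p * (1.0 - self._p)).astype(_F32)
        d = self.head.backward(d)
        dskips: list[np.ndarray] = []
        for up, dec in zip(reversed(self.ups), reversed(self.dec)):
            d = dec.backward(d)
            nskip = d.shape[-1] // 2
            dskips.append(d[..., :nskip])
            d = up.backward(np.ascontiguousarray(d[..., nskip:]))
        d = self.bottleneck.backward(d)
        # dskips were collected shallow-to-deep; the encoder chain is
        # walked deep-to-shallow
        for enc, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = enc.backward((d + dskip).astype(_F32))
        return d

    # -- parameter access ------------------------------------------------
    def _blocks(self):
        yield from self.enc
        yield self.bottleneck
        yield from self.dec

    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for blk in self._blocks():
            out.extend(blk.layers)
        out.extend(self.ups)
        out.append(self.head)
        return out


class DoubleUNet:
    """Two stacked U-Nets; the second refines the first's segmentation."""

    def __init__(
        self,
        in_channels: int = 3,
        depth: int = 3,
        base_filters: int = 16,
        bridge: str = "multiply",
        seed: int | None = None,
    ):
        if bridge not in ("multiply", "concat"):
            raise ValueError(f"unknown bridge {bridge!r}")
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.depth = depth
        self.base_filters = base_filters
        self.bridge = bridge
        self.unet1 = UNet(in_channels, depth, base_filters, rng)
        c2 = in_channels if bridge == "multiply" else in_channels + 1
        self.unet2 = UNet(c2, depth, base_filters, rng)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=_F32)
        p1 = self.unet1.forward(x, train)
        if self.bridge == "multiply":
            z = x * p1
        else:
            z = np.concatenate([x, p1], axis=-1)
        p2 = self.unet2.forward(z, train)
        if train:
            self._cache = (x, p1)
        return p2

    def backward(self, dp2: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        x, p1 = self._cache
        self._cache = None
        dz = self.unet2.backward(dp2)
        if self.bridge == "multiply":
            dp1 = (dz * x).sum(axis=-1, keepdims=True)
            dx = dz * p1
        else:
            dp1 = dz[..., -1:]
            dx = dz[..., :-1]
        dx = dx + self.unet1.backward(np.ascontiguousarray(dp1))
        return dx

    def layers(self) -> list[Layer]:
        return self.unet1.layers() + self.unet2.layers()

    # -- checkpointing ---------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat dict of every parameter and batch-norm running statistic."""
        out: dict[str, np.ndarray] = {}
        for i, lay in enumerate(self.layers()):
            for k, v in lay.params.items():
                out[f"layer{i:03d}.{k}"] = v
            if isinstance(lay, BatchNorm):
                out[f"layer{i:03d}.running_mean"] = lay.running_mean
                out[f"layer{i:03d}.running_var"] = lay.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, lay in enumerate(self.layers()):
            for k in lay.params:
                lay.params[k] = np.asarray(state[f"layer{i:03d}.{k}"], _F32)
            if isinstance(lay, BatchNorm):
                lay.running_mean = np.asarray(state[f"layer{i:03d}.running_mean"], _F32)
                lay.running_var = np.asarray(state[f"layer{i:03d}.running_var"], _F32)
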