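"""The 3D U-Net segmentation model assembled from the numpy layers.

Nine convolutional blocks — four encoder, one bottleneck, four decoder —
each of two same-padded 3³ convolutions with ReLU.  Encoder blocks are
followed by max pooling (patch schedule 2, 2, 3, 3); decoder blocks are
preceded by nearest-neighbor up-sampling (3, 3, 2, 2) and concatenation
with the final feature map of the mirrored encoder block.  A 1×1×1
convolution with a sigmoid produces the single-channel pocket probability.
On a 36³ input the bottleneck feature maps are 1×1×1.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv3d, MaxPool3d, Upsample3d, sigmoid


class UNet3D:
    def __init__(
        self,
        in_channels: int = 18,
        encoder_filters: tuple[int, ...] = (32, 64, 128, 256),
        bottleneck_filters: int = 512,
        decoder_filters: tuple[int, ...] = (256, 128, 64, 32),
        pool_schedule: tuple[int, ...] = (2, 2, 3, 3),
        upsample_schedule: tuple[int, ...] = (3, 3, 2, 2),
        kernel: int = 3,
        seed: int = 0,
        head_bias_init: float = -4.0,
    ):
        depth = len(encoder_filters)
        if not (len(decoder_filters) == len(pool_schedule) == len(upsample_schedule) == depth):
            raise ValueError("encoder/decoder/pool/upsample schedules must have equal length")
        self.in_channels = in_channels
        self.encoder_filters = tuple(encoder_filters)
        self.bottleneck_filters = bottleneck_filters
        self.decoder_filters = tuple(decoder_filters)
        self.pool_schedule = tuple(pool_schedule)
        self.upsample_schedule = tuple(upsample_schedule)
        self.kernel = kernel
        self.seed = seed
        self.head_bias_init = head_bias_init
        rng = np.random.default_rng(seed)

        self.enc_blocks: list[tuple[Conv3d, Conv3d]] = []
        c_prev = in_channels
        for f in encoder_filters:
            self.enc_blocks.append(
                (Conv3d(c_prev, f, kernel, rng=rng), Conv3d(f, f, kernel, rng=rng))
            )
            c_prev = f
        self.pools = [MaxPool3d(s) for s in pool_schedule]
        self.bottleneck = (
            Conv3d(c_prev, bottleneck_filters, kernel, rng=rng),
            Conv3d(bottleneck_filters, bottleneck_filters, kernel, rng=rng),
        )
        c_prev = bottleneck_filters
        self.upsamples = [Upsample3d(s) for s in upsample_schedule]
        self.dec_blocks: list[tuple[Conv3d, Conv3d]] = []
        for j, f in enumerate(decoder_filters):
            skip_c = encoder_filters[depth - 1 - j]
            self.dec_blocks.append(
                (Conv3d(c_prev + skip_c, f, kernel, rng=rng), Conv3d(f, f, kernel, rng=rng))
            )
            c_prev = f
        self.head = Conv3d(c_prev, 1, kernel=1, relu=False, rng=rng, bias_init=head_bias_init)
        self._cache: dict | None = None

    # -- introspection -----------------------------------------------------

    @property
    def n_blocks(self) -> int:
        """Number of two-convolution blocks (encoder + bottleneck + decoder)."""
        return len(self.enc_blocks) + 1 + len(self.dec_blocks)

    def conv_layers(self) -> list[Conv3d]:
        layers = []
        for c1, c2 in self.enc_blocks:
            layers += [c1, c2]
        layers += list(self.bottleneck)
        for c1, c2 in self.dec_blocks:
            layers += [c1, c2]
        layers.append(self.head)
        return layers

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for layer in self.conv_layers():
            out += layer.params
        return out

    @property
    def grads(self) -> list[np.ndarray]:
        out = []
        for layer in self.conv_layers():
            out += layer.grads
        return out

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def weight_squared_sum(self) -> float:
        """Σ w² over convolution kernels (biases excluded), for L2 regularization."""
        return float(sum(np.sum(layer.w.astype(np.float64) ** 2) for layer in self.conv_layers()))

    def check_input_size(self, size: int) -> None:
        prod = int(np.prod(self.pool_schedule))
        if size % prod:
            raise ValueError(
                f"input spatial size {size} not divisible by pool-schedule product {prod}"
            )

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Predict per-voxel pocket probability.

        ``x``: (batch, D, H, W, in_channels) float32; returns the same
        spatial shape with a single channel, values in (0, 1).
        """
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 5 or x.shape[-1] != self.in_channels:
            raise ValueError(f"expected (n, d, h, w, {self.in_channels}) input, got {x.shape}")
        self.check_input_size(x.shape[1])
        skips = []
        h = x
        for (c1, c2), pool in zip(self.enc_blocks, self.pools):
            h = c2.forward(c1.forward(h, train), train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck[1].forward(self.bottleneck[0].forward(h, train), train)
        self.bottleneck_shape_ = h.shape[1:4]
        for j, ((c1, c2), up) in enumerate(zip(self.dec_blocks, self.upsamples)):
            h = up.forward(h, train)
            skip = skips[len(skips) - 1 - j]
            h = np.concatenate([h, skip], axis=-1)
            h = c2.forward(c1.forward(h, train), train)
        logits = self.head.forward(h, train)
        y = sigmoid(logits)
        if train:
            self._cache = {"y": y}
        return y

    def backward(self, dLdy: np.ndarray) -> None:
        """Accumulate parameter gradients given dL/dy (y = sigmoid output)."""
        assert self._cache is not None, "backward() requires forward(train=True)"
        y = self._cache["y"]
        grad = (dLdy * y * (1.0 - y)).astype(np.float32)
        grad = self.head.backward(grad)
        for j in range(len(self.dec_blocks) - 1, -1, -1):
            c1, c2 = self.dec_blocks[j]
            grad = c1.backward(c2.backward(grad))
            n_up = grad.shape[-1] - self.enc_blocks[len(self.enc_blocks) - 1 - j][1].c_out
            grad, grad_skip = grad[..., :n_up], grad[..., n_up:]
            # stash the skip-connection gradient for the mirrored encoder block
            self._stash_skip(len(self.enc_blocks) - 1 - j, np.ascontiguousarray(grad_skip))
            grad = self.upsamples[j].backward(np.ascontiguousarray(grad))
        grad = self.bottleneck[0].backward(self.bottleneck[1].backward(grad))
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            c1, c2 = self.enc_blocks[i]
            grad = self.pools[i].backward(grad)
            grad = grad + self._pop_skip(i)
            # the first convolution consumes the input grid: no input
            # gradient is needed there, and it is the costliest to compute
            grad = c1.backward(c2.backward(grad), need_input_grad=(i > 0))
        self._cache = None

    def _stash_skip(self, i: int, g: np.ndarray) -> None:
        if not hasattr(self, "_skip_store"):
            self._skip_store = {}
        self._skip_store[i] = g

    def _pop_skip(self, i: int) -> np.ndarray:
        return self._skip_store.pop(i)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        meta = dict(
            in_channels=self.in_channels,
            encoder_filters=self.encoder_filters,
            bottleneck_filters=self.bottleneck_filters,
            decoder_filters=self.decoder_filters,
            pool_schedule=self.pool_schedule,
            upsample_schedule=self.upsample_schedule,
            kernel=self.kernel,
            seed=self.seed,
            head_bias_init=self.head_bias_init,
        )
        np.savez(path, _meta=np.array([repr(meta)], dtype=object), **arrays)

    @classmethod
    def load(cls, path) -> "UNet3D":
        import ast

        with np.load(path, allow_pickle=True) as data:
            meta = ast.literal_eval(str(data["_meta"][0]))
            model = cls(**meta)
            for i, p in enumerate(model.params):
                p[...] = data[f"p{i}"]
        return model
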