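"""Model architecture and objective specifications.

The default architecture: a 3D U-Net with encoder filter counts
(32, 64, 128, 256), a 512-filter bottleneck and a mirrored decoder
(256, 128, 64, 32); all convolutions are same-padded 3³ with ReLU; pooling
patch sizes are (2, 2, 3, 3) down the encoder and up-sampling (3, 3, 2, 2)
up the decoder, so a 36³ input reaches a 1×1×1 bottleneck
(36 → 18 → 9 → 3 → 1) and is restored to 36³ at the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import DEFAULT_EPSILON, UNet3D
from .nn import dice_loss as _dice_loss
from .nn import dice_loss_batch


@dataclass(frozen=True)
class ArchitectureSpec:
    encoder_filters: tuple[int, ...] = (32, 64, 128, 256)
    bottleneck_filters: int = 512
    decoder_filters: tuple[int, ...] = (256, 128, 64, 32)
    kernel: int = 3
    pool_schedule: tuple[int, ...] = (2, 2, 3, 3)
    upsample_schedule: tuple[int, ...] = (3, 3, 2, 2)
    in_channels: int = 18
    out_channels: int = 1

    def __post_init__(self) -> None:
        n = len(self.encoder_filters)
        if not (
            len(self.decoder_filters) == n
            and len(self.pool_schedule) == n
            and len(self.upsample_schedule) == n
        ):
            raise ValueError("filter and pool/upsample schedules must share one length")
        if self.out_channels != 1:
            raise ValueError("single-channel probability output is required")

    @property
    def pool_product(self) -> int:
        return int(np.prod(self.pool_schedule))


@dataclass(frozen=True)
class LossSpec:
    epsilon: float = DEFAULT_EPSILON
    l2_lambda: float = 1e-5

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be non-negative")


def build_model(arch: ArchitectureSpec = ArchitectureSpec(), seed: int = 0) -> UNet3D:
    """Instantiate the segmentation network with freshly initialized weights."""
    return UNet3D(
        in_channels=arch.in_channels,
        encoder_filters=arch.encoder_filters,
        bottleneck_filters=arch.bottleneck_filters,
        decoder_filters=arch.decoder_filters,
        pool_schedule=arch.pool_schedule,
        upsample_schedule=arch.upsample_schedule,
        kernel=arch.kernel,
        seed=seed,
    )


def dice_loss(y: np.ndarray, t: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> float:
    """Negative smoothed Dice coefficient C(y, t) ∈ [-1, 0); lower is better."""
    y = np.asarray(y)
    t = np.asarray(t)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("predicted segmentation values must lie in [0, 1]")
    return _dice_loss(y, t, epsilon)


def regularized_objective(
    model: UNet3D, y: np.ndarray, t: np.ndarray, loss_spec: LossSpec = LossSpec()
) -> float:
    """Dice loss plus λ·Σw² over convolution kernels (biases excluded)."""
    if y.ndim == t.ndim + 1:  # trailing channel axis from the network
        y = y[..., 0]
    base = dice_loss(y, t, loss_spec.epsilon) if y.ndim == 3 else dice_loss_batch(
        y, t, loss_spec.epsilon
    )
    return base + loss_spec.l2_lambda * model.weight_squared_sum()


def parameter_count(arch: ArchitectureSpec = ArchitectureSpec()) -> int:
    """Closed-form trainable parameter count (k³·c_in·c_out + c_out per conv)."""
    k3 = arch.kernel**3
    total = 0
    c_prev = arch.in_channels
    for f in arch.encoder_filters:
        total += k3 * c_prev * f + f + k3 * f * f + f
        c_prev = f
    fb = arch.bottleneck_filters
    total += k3 * c_prev * fb + fb + k3 * fb * fb + fb
    c_prev = fb
    depth = len(arch.encoder_filters)
    for j, f in enumerate(arch.decoder_filters):
        skip = arch.encoder_filters[depth - 1 - j]
        total += k3 * (c_prev + skip) * f + f + k3 * f * f + f
        c_prev = f
    total += 1 * c_prev * 1 + 1  # 1×1×1 sigmoid head
    return total
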