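"""Memory-budgeted resolution selection and dynamic downsampling.

Interactive (rasterized) display pipelines cap volumetric data at
4 GiB = 2**32 bytes per timeframe, counted across all loaded channels after
the float32 resave.  Given a multiscale pyramid this module picks the finest
level that fits the budget; when only a single level exists (a plain TIFF)
or even the coarsest level is too large, it computes the smallest
power-of-two downscale that makes the data fit and performs the pooling.

Intensity channels are mean-pooled (partial windows at the borders use the
mean of the voxels actually present); label-mask channels are downsampled by
stride so integer identities are never averaged.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .volume_io import MultiscaleLevel

#: Default per-timeframe budget: 4 GiB exactly.
DEFAULT_BUDGET_BYTES = 2**32


@dataclass(frozen=True)
class BudgetPolicy:
    """How the per-timeframe footprint is compared against the budget.

    ``inclusive`` decides whether a footprint of exactly ``budget_bytes``
    passes (the default) or fails; ``count_all_channels`` budgets the sum
    over all loaded channels (including label masks) rather than a single
    channel.
    """

    budget_bytes: int = DEFAULT_BUDGET_BYTES
    count_all_channels: bool = True
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.budget_bytes <= 0:
            raise ValidationError("budget must be positive")

    def passes(self, footprint: int) -> bool:
        if self.inclusive:
            return footprint <= self.budget_bytes
        return footprint < self.budget_bytes


@dataclass(frozen=True)
class LevelSelection:
    """Outcome of :func:`select_level`.

    ``extra_downscale`` is (1, 1, 1) when a presaved level fits as-is;
    otherwise it is the uniform power-of-two factor applied on top of the
    coarsest level.
    """

    chosen_level: int
    extra_downscale: tuple[int, int, int]
    resulting_footprint_bytes: int


def parse_budget(text: str | int) -> int:
    """Parse a byte count given as an integer or a '<n>GiB'/'<n>MiB' string."""
    if isinstance(text, int):
        value = text
    else:
        m = re.fullmatch(r"\s*(\d+(?:\.\d+)?)\s*(GiB|MiB|KiB|B)?\s*", str(text))
        if not m:
            raise ValidationError(f"cannot parse budget {text!r}")
        scale = {"GiB": 2**30, "MiB": 2**20, "KiB": 2**10, "B": 1, None: 1}[m.group(2)]
        value = int(float(m.group(1)) * scale)
    if value <= 0:
        raise ValidationError("budget must be positive")
    return value


def footprint_bytes(level: MultiscaleLevel, n_channels: int) -> int:
    """Float32 bytes of one timeframe of this level: Z*Y*X*channels*4.

    Pure integer arithmetic; timeframes are excluded because the budget is
    per timeframe.
    """
    if n_channels <= 0:
        raise ValidationError("channel count must be positive")
    z, y, x = level.shape_zyx
    return z * y * x * n_channels * 4


def select_level(
    levels: list[MultiscaleLevel] | tuple[MultiscaleLevel, ...],
    n_channels: int,
    policy: BudgetPolicy | None = None,
) -> LevelSelection:
    """Pick the finest pyramid level whose footprint passes the policy.

    Levels must be ordered finest first.  If no presaved level passes, the
    coarsest level is taken and the smallest uniform power-of-two extra
    downscale that passes is added.
    """
    policy = policy or BudgetPolicy()
    if not levels:
        raise ValidationError("empty level list")
    channels = n_channels if policy.count_all_channels else 1
    for level in levels:
        fp = footprint_bytes(level, channels)
        if policy.passes(fp):
            return LevelSelection(level.level_index, (1, 1, 1), fp)
    coarsest = levels[-1]
    factor = 2
    while True:
        shape = tuple(-(-s // factor) for s in coarsest.shape_zyx)
        fp = shape[0] * shape[1] * shape[2] * channels * 4
        if policy.passes(fp):
            return LevelSelection(coarsest.level_index, (factor,) * 3, fp)
        factor *= 2


def downsample(volume: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Mean-pool a 3D volume by integer factors per axis.

    The output shape is ``ceil(input / factor)`` per axis; border windows
    that extend past the volume average only the voxels present, so the
    voxel-count-weighted global mean is preserved exactly.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValidationError("downsample expects a 3D (Z, Y, X) volume")
    factors = tuple(int(f) for f in factors)
    if any(f < 1 for f in factors):
        raise ValidationError("downsample factors must be >= 1")
    out = volume.astype(np.float64, copy=False)
    for axis, f in enumerate(factors):
        if f == 1:
            continue
        n = out.shape[axis]
        starts = np.arange(0, n, f)
        sums = np.add.reduceat(out, starts, axis=axis)
        counts = np.minimum(starts + f, n) - starts
        shape = [1, 1, 1]
        shape[axis] = len(starts)
        out = sums / counts.reshape(shape)
    return out.astype(np.float32)


def downsample_labels(labels: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Stride (nearest) downsampling for integer label masks.

    Averaging object identities is meaningless, so labels keep the value of
    the first voxel of each window.  Output shape matches :func:`downsample`.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValidationError("downsample_labels expects a 3D volume")
    if labels.dtype.kind not in "iu":
        raise ValidationError("label volumes must have an integer dtype")
    fz, fy, fx = (int(f) for f in factors)
    if min(fz, fy, fx) < 1:
        raise ValidationError("downsample factors must be >= 1")
    return labels[::fz, ::fy, ::fx]


def isotropy_factor(pixel_size: tuple[float, float, float]) -> float:
    """z/xy pixel-size ratio used to stretch z to isotropy in world space.

    ``pixel_size`` is (x, y, z).  x and y are expected near-square; if they
    differ by more than 1% a warning is emitted and their mean is used.
    """
    x, y, z = (float(v) for v in pixel_size)
    if min(x, y, z) <= 0:
        raise ValidationError("pixel sizes must be positive")
    xy = (x + y) / 2.0
    if abs(x - y) > 0.01 * xy:
        warnings.warn(
            f"x and y pixel sizes differ by more than 1% ({x} vs {y}); "
            "using their mean for the isotropy factor",
            stacklevel=2,
        )
    return z / xy
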