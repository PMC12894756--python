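"""CPU orthographic ray-marching preview with emissive/absorptive media.

The renderer marches every pixel's parallel ray front-to-back through the
scene's world-space bounding box with a fixed step.  At each sample point
the channel transfer functions yield a color and an opacity ``alpha``,
interpreted as opacity per ``reference_step`` of path length; the step
contribution is made step-size consistent through the opacity correction

    alpha_step = 1 - (1 - alpha) ** (step / reference_step)

which makes a homogeneous absorber follow Beer-Lambert exactly,
T = exp(-sigma * L) with sigma = -ln(1 - alpha) / reference_step, for any
step partition.  Emissive channels add radiance ``T * color * alpha_step``
without attenuating anything (fluorescence: every voxel emits light in
proportion to its measured value); absorptive channels add the same term
and multiply the transmittance by ``1 - alpha_step`` (electron densities
scatter/absorb light rather than emit it).  After the march the remaining
transmittance is filled with the background color.

Slice boxes are oriented clipping regions.  A sample excluded by the boxes
applicable to a channel contributes nothing for that channel; channels
without applicable boxes are unsliced, which is how a segmentation can
protrude from a tighter data slice.  A very thin box (:func:`make_slab`)
reproduces a classic orthogonal slice plane.

Images are row-major with the origin at the top-left pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ValidationError
from .scene_space import SceneTransform
from .transfer import LabelPalette, TransferFunction

# ---------------------------------------------------------------------------
# slice boxes


@dataclass(frozen=True)
class SliceBox:
    """Oriented box clipping region.

    A point p is inside iff |R^T (p - center)| <= half_extents componentwise.
    ``applies_to`` lists the channel indices the box clips; an empty set
    means the box applies to every channel.
    """

    center: tuple[float, float, float]
    half_extents: tuple[float, float, float]
    rotation: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    applies_to: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.half_extents):
            raise ValidationError("slice box half extents must be positive")
        R = np.asarray(self.rotation, dtype=np.float64)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValidationError("slice box rotation must be orthonormal (3x3)")
        object.__setattr__(self, "applies_to", frozenset(int(c) for c in self.applies_to))

    def contains(self, points) -> np.ndarray:
        """Vectorized inside test for (..., 3) world points."""
        R = np.asarray(self.rotation, dtype=np.float64)
        local = (np.asarray(points, dtype=np.float64) - np.asarray(self.center)) @ R
        return np.all(np.abs(local) <= np.asarray(self.half_extents), axis=-1)

    def applies_to_channel(self, channel: int) -> bool:
        return not self.applies_to or channel in self.applies_to

    def to_dict(self) -> dict:
        return {
            "center": [float(v) for v in self.center],
            "half_extents": [float(v) for v in self.half_extents],
            "rotation": [[float(v) for v in r] for r in self.rotation],
            "applies_to": sorted(self.applies_to),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SliceBox":
        return cls(
            center=tuple(float(v) for v in d["center"]),
            half_extents=tuple(float(v) for v in d["half_extents"]),
            rotation=tuple(tuple(float(v) for v in r) for r in d["rotation"]),
            applies_to=frozenset(int(c) for c in d.get("applies_to", [])),
        )


def inside_slice(box: SliceBox, p, channel: int) -> bool:
    """True iff p lies inside the box AND the box applies to the channel."""
    if not box.applies_to_channel(channel):
        return False
    return bool(box.contains(np.asarray(p, dtype=np.float64)))


def make_slab(
    axis: str,
    position: float,
    thickness: float,
    volume_bounds: tuple[Sequence[float], Sequence[float]],
    applies_to: Sequence[int] = (),
) -> SliceBox:
    """Axis-aligned slab: thin along ``axis``, spanning the volume otherwise.

    Duplicating thin slabs at different positions reproduces classic
    orthogonal slice planes.
    """
    if thickness <= 0:
        raise ValidationError("slab thickness must be positive")
    try:
        ax = "xyz".index(axis)
    except ValueError:
        raise ValidationError(f"slab axis must be one of x, y, z; got {axis!r}")
    lo = np.asarray(volume_bounds[0], dtype=np.float64)
    hi = np.asarray(volume_bounds[1], dtype=np.float64)
    center = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    center[ax] = float(position)
    half[ax] = thickness / 2.0
    return SliceBox(tuple(center), tuple(half), applies_to=frozenset(applies_to))


# ---------------------------------------------------------------------------
# channels and config


@dataclass
class RenderChannel:
    """A scalar volume with its transfer function, placed in world space.

    ``grid`` is anything with float ``values`` (Z, Y, X) and a
    ``transform``; the emissive/absorptive flag lives on the transfer
    function.
    """

    grid: object
    transfer: TransferFunction
    channel_index: int = 0


@dataclass
class LabelRenderChannel:
    """Integer identities rendered as constant-color semi-transparent
    absorptive media (nearest-neighbor sampling, no identity blending)."""

    labels: np.ndarray  # (Z, Y, X) integer
    transform: SceneTransform
    palette: LabelPalette = field(default_factory=LabelPalette)
    opacity: float = 0.5
    channel_index: int = 0
    overrides: Optional[dict] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.dtype.kind not in "iu":
            raise ValidationError("label channels need integer identities")
        if not (0.0 <= self.opacity <= 1.0):
            raise ValidationError("label opacity must be in [0, 1]")
        if self.opacity == 0.0:
            import warnings

            warnings.warn("label opacity 0 renders nothing", stacklevel=2)


AnyChannel = Union[RenderChannel, LabelRenderChannel]

_AXIS_BASES = {
    # view -> (ray direction, image right, image down), all unit vectors
    "z": ((0.0, 0.0, -1.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
    "y": ((0.0, -1.0, 0.0), (1.0, 0.0, 0.0), (0.0, 0.0, -1.0)),
    "x": ((-1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, -1.0)),
}


@dataclass
class RenderConfig:
    """Orthographic camera and marching parameters.

    ``view`` is 'x', 'y', 'z' (rays travel along the negative axis) or an
    arbitrary direction vector.  ``world_window`` is (u0, u1, v0, v1) in the
    image-plane basis (right, down); by default the scene bounding box is
    framed exactly.  ``step_length`` defaults to half the smallest world
    voxel spacing; ``reference_step`` is the path length over which a
    transfer alpha means 'this much opacity'.
    """

    view: Union[str, Sequence[float]] = "z"
    image_size: tuple[int, int] = (64, 64)  # (width, height)
    world_window: Optional[tuple[float, float, float, float]] = None
    step_length: Optional[float] = None
    reference_step: float = 1.0
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    interpolation: str = "trilinear"  # or "nearest"
    slice_combine: str = "intersect"  # or "union"

    def __post_init__(self) -> None:
        if self.step_length is not None and self.step_length <= 0:
            raise ValidationError("step_length must be positive")
        if self.reference_step <= 0:
            raise ValidationError("reference_step must be positive")
        if self.interpolation not in ("trilinear", "nearest"):
            raise ValidationError("interpolation must be 'trilinear' or 'nearest'")
        if self.slice_combine not in ("intersect", "union"):
            raise ValidationError("slice_combine must be 'intersect' or 'union'")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if isinstance(self.view, str):
            try:
                d, r, dn = _AXIS_BASES[self.view]
            except KeyError:
                raise ValidationError(f"unknown view {self.view!r}")
            return np.asarray(d), np.asarray(r), np.asarray(dn)
        d = np.asarray(self.view, dtype=np.float64)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValidationError("view direction must be nonzero")
        d = d / norm
        up = np.array([0.0, 0.0, 1.0])
        if abs(d @ up) > 0.99:
            up = np.array([0.0, 1.0, 0.0])
        r = np.cross(d, up)
        r /= np.linalg.norm(r)
        dn = np.cross(d, r)
        return d, r, dn


@dataclass
class RenderResult:
    """Radiance image plus the per-pixel remaining transmittance."""

    rgb: np.ndarray  # (height, width, 3) float in [0, inf)
    transmittance: np.ndarray  # (height, width) float in [0, 1]

    def to_png(self, destination: str | Path) -> Path:
        from PIL import Image

        data = (np.clip(self.rgb, 0.0, 1.0) * 255.0).round().astype(np.uint8)
        Image.fromarray(data, mode="RGB").save(str(destination), format="PNG")
        return Path(destination)


# ---------------------------------------------------------------------------
# sampling helpers


def _sample_scalar(grid, points: np.ndarray, interpolation: str) -> tuple[np.ndarray, np.ndarray]:
    """Sample a grid at world points; returns (values, inside_mask)."""
    values = np.asarray(grid.values)
    transform: SceneTransform = grid.transform
    vox = transform.world_to_voxel(points)  # fractional (z, y, x)
    size = np.asarray(values.shape, dtype=np.float64)
    inside = np.all((vox >= -0.5) & (vox <= size - 0.5), axis=-1)
    vox = np.clip(vox, 0.0, size - 1.0)
    if interpolation == "nearest":
        idx = np.round(vox).astype(np.int64)
        out = values[idx[..., 0], idx[..., 1], idx[..., 2]].astype(np.float64)
        return out, inside
    lo = np.floor(vox).astype(np.int64)
    hi = np.minimum(lo + 1, (size - 1).astype(np.int64))
    frac = vox - lo
    out = np.zeros(points.shape[:-1], dtype=np.float64)
    for dz in (0, 1):
        wz = np.where(dz, frac[..., 0], 1.0 - frac[..., 0])
        iz = hi[..., 0] if dz else lo[..., 0]
        for dy in (0, 1):
            wy = np.where(dy, frac[..., 1], 1.0 - frac[..., 1])
            iy = hi[..., 1] if dy else lo[..., 1]
            for dx in (0, 1):
                wx = np.where(dx, frac[..., 2], 1.0 - frac[..., 2])
                ix = hi[..., 2] if dx else lo[..., 2]
                w = wz * wy * wx
                out += w * values[iz, iy, ix]
    return out, inside


def _sample_labels(channel: LabelRenderChannel, points: np.ndarray) -> np.ndarray:
    labels = channel.labels
    vox = channel.transform.world_to_voxel(points)
    size = np.asarray(labels.shape, dtype=np.float64)
    inside = np.all((vox >= -0.5) & (vox <= size - 0.5), axis=-1)
    idx = np.clip(np.round(vox), 0, size - 1).astype(np.int64)
    ids = labels[idx[..., 0], idx[..., 1], idx[..., 2]].astype(np.int64)
    return np.where(inside, ids, 0)


def _slice_mask(
    boxes: Sequence[SliceBox],
    channel_index: int,
    points: np.ndarray,
    combine: str,
) -> np.ndarray:
    """True where a sample survives the slice boxes of this channel."""
    applicable = [b for b in boxes if b.applies_to_channel(channel_index)]
    if not applicable:
        return np.ones(points.shape[:-1], dtype=bool)
    masks = [b.contains(points) for b in applicable]
    if combine == "union":
        return np.logical_or.reduce(masks)
    return np.logical_and.reduce(masks)


def _channel_bounds(channel: AnyChannel) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(channel, LabelRenderChannel):
        return channel.transform.bounds(channel.labels.shape)
    return channel.grid.transform.bounds(np.asarray(channel.grid.values).shape)


def _min_spacing(channel: AnyChannel) -> float:
    tr = (
        channel.transform
        if isinstance(channel, LabelRenderChannel)
        else channel.grid.transform
    )
    return float(min(tr.spacing_world))


# ---------------------------------------------------------------------------
# rendering


def render(
    channels: Sequence[AnyChannel],
    slice_boxes: Sequence[SliceBox] = (),
    config: Optional[RenderConfig] = None,
) -> RenderResult:
    """March all channels together through the scene (see module docstring).

    Channels must share a world space (same unit mode); with no channels
    the image is the background everywhere.
    """
    config = config or RenderConfig()
    width, height = config.image_size
    background = np.asarray(config.background, dtype=np.float64)
    if not channels:
        rgb = np.broadcast_to(background, (height, width, 3)).copy()
        return RenderResult(rgb, np.ones((height, width)))

    unit_modes = set()
    for ch in channels:
        tr = (
            ch.transform
            if isinstance(ch, LabelRenderChannel)
            else ch.grid.transform
        )
        unit_modes.add(tr.unit_mode)
    if len(unit_modes) > 1:
        raise ValidationError(
            f"channels live in different world spaces: {sorted(m.value for m in unit_modes)}"
        )

    los, his = zip(*(_channel_bounds(ch) for ch in channels))
    scene_lo = np.min(np.asarray(los), axis=0)
    scene_hi = np.max(np.asarray(his), axis=0)
    ends = (scene_lo, scene_hi)
    corners = np.array(
        [[ends[i][0], ends[j][1], ends[k][2]] for i, j, k in np.ndindex(2, 2, 2)]
    )
    d, r, dn = config.basis()

    if config.world_window is not None:
        u0, u1, v0, v1 = config.world_window
    else:
        proj_u = corners @ r
        proj_v = corners @ dn
        u0, u1 = float(proj_u.min()), float(proj_u.max())
        v0, v1 = float(proj_v.min()), float(proj_v.max())
    proj_s = corners @ d
    s_start, s_end = float(proj_s.min()), float(proj_s.max())
    path = s_end - s_start
    if path <= 0:
        path = 1e-12

    step = config.step_length
    if step is None:
        step = 0.5 * min(_min_spacing(ch) for ch in channels)
    n_steps = max(1, int(np.ceil(path / step)))

    # pixel-center grid in the (right, down) image basis
    us = u0 + (np.arange(width) + 0.5) * (u1 - u0) / width
    vs = v0 + (np.arange(height) + 0.5) * (v1 - v0) / height
    U, V = np.meshgrid(us, vs)  # (height, width)
    base = U[..., None] * r + V[..., None] * dn  # (h, w, 3)

    radiance = np.zeros((height, width, 3), dtype=np.float64)
    T = np.ones((height, width), dtype=np.float64)

    travelled = 0.0
    for _ in range(n_steps):
        length = min(step, path - travelled)
        if length <= 0:
            break
        s_mid = s_start + travelled + length / 2.0
        travelled += length
        points = base + s_mid * d
        exponent = length / config.reference_step
        for ch in channels:
            keep = _slice_mask(slice_boxes, ch.channel_index, points, config.slice_combine)
            if isinstance(ch, LabelRenderChannel):
                ids = _sample_labels(ch, points)
                ids = np.where(keep, ids, 0)
                if not ids.any():
                    continue
                lut = ch.palette.lut(int(ids.max()), ch.overrides)
                color = lut[ids]
                alpha = np.where(ids > 0, ch.opacity, 0.0)
                absorptive = True
            else:
                values, inside = _sample_scalar(ch.grid, points, config.interpolation)
                color, alpha = ch.transfer(values)
                alpha = np.where(inside & keep, alpha, 0.0)
                absorptive = not ch.transfer.emissive
            alpha_step = 1.0 - np.power(1.0 - np.clip(alpha, 0.0, 1.0), exponent)
            radiance += (T * alpha_step)[..., None] * color
            if absorptive:
                T = T * (1.0 - alpha_step)

    radiance += T[..., None] * background
    return RenderResult(radiance, T)


def render_labels(
    labels: np.ndarray,
    transform: SceneTransform,
    palette: Optional[LabelPalette] = None,
    opacity: float = 0.5,
    slice_boxes: Sequence[SliceBox] = (),
    config: Optional[RenderConfig] = None,
    extra_channels: Sequence[AnyChannel] = (),
    channel_index: int = 0,
    overrides: Optional[dict] = None,
) -> np.ndarray:
    """Render a label volume (plus optional scalar channels) to RGBA.

    Returns a (height, width, 4) array whose alpha is the per-pixel opacity
    accumulated by the march (1 - transmittance).
    """
    channel = LabelRenderChannel(
        labels=labels,
        transform=transform,
        palette=palette or LabelPalette(),
        opacity=opacity,
        channel_index=channel_index,
        overrides=overrides,
    )
    result = render([channel, *extra_channels], slice_boxes, config)
    return np.dstack([result.rgb, 1.0 - result.transmittance])
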