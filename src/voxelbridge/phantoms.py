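"""Synthetic phantoms with known ground truth, and synthetic stores.

Every pipeline stage is testable offline: this module generates small
deterministic volumes (balls, tube networks, nested shells, label cubes)
whose geometry is returned alongside the voxels, and writes them out as
OME-Zarr v0.4 multiscale stores or (ImageJ-)TIFF files that
:func:`voxelbridge.volume_io.read_dataset` can round-trip.

Pyramid levels are built with the same mean pooling as
:func:`voxelbridge.multiscale.downsample` (stride pooling for integer
label volumes), so presaved pyramids and dynamic downsampling can be
cross-validated against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import SourceReadError, ValidationError
from .multiscale import downsample, downsample_labels
from .volume_io import CANONICAL_AXES, validate_axes

_KINDS = ("ball", "tube_network", "nested_shells", "label_cubes")

_NGFF_UNITS = {
    "pixel": None,
    "nanometer": "nanometer",
    "micrometer": "micrometer",
    "angstrom": "angstrom",
    "meter": "meter",
}


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a deterministic synthetic volume.

    Same seed, same output, bit for bit.  ``radius`` applies to balls,
    shells and tubes; ``label_cubes`` instead uses ``cube_size``.  Noise is
    additive Gaussian and never applied to label volumes.
    """

    kind: str = "ball"
    shape_zyx: tuple[int, int, int] = (64, 64, 64)
    n_objects: int = 1
    foreground: float = 200.0
    background: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0
    radius: Optional[float] = None
    cube_size: int = 8
    pixel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (x, y, z)
    pixel_unit: str = "pixel"
    n_timepoints: int = 1
    n_channels: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"phantom kind {self.kind!r} not in {_KINDS}")
        if any(s < 1 for s in self.shape_zyx):
            raise ValidationError("phantom shape must be positive")
        if self.n_objects < 1 or self.n_timepoints < 1 or self.n_channels < 1:
            raise ValidationError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, dict]:
    """Generate a (T, C, Z, Y, X) phantom and its ground truth.

    Intensity phantoms are float32 with the configured foreground /
    background levels plus optional Gaussian noise; ``label_cubes`` is
    uint16 with identities exactly 1..n_objects and no noise.  Objects
    drift by one voxel per timeframe along x so time handling is
    observable; extra channels repeat the structure at intensity scaled by
    (channel index + 1).
    """
    rng = np.random.default_rng(spec.seed)
    builders = {
        "ball": _build_ball,
        "tube_network": _build_tubes,
        "nested_shells": _build_shells,
        "label_cubes": _build_label_cubes,
    }
    base, truth = builders[spec.kind](spec, rng)
    is_labels = spec.kind == "label_cubes"

    T, C = spec.n_timepoints, spec.n_channels
    out = np.empty((T, C) + spec.shape_zyx, dtype=base.dtype)
    for t in range(T):
        frame = np.roll(base, shift=t, axis=2) if t else base
        for c in range(C):
            if is_labels:
                out[t, c] = frame
            else:
                chan = frame.astype(np.float64) * (c + 1)
                if spec.noise_sd > 0:
                    chan = chan + rng.normal(0.0, spec.noise_sd, size=chan.shape)
                out[t, c] = chan.astype(np.float32)
    return out, truth


def _mesh_grid(shape_zyx):
    return np.meshgrid(*(np.arange(s) for s in shape_zyx), indexing="ij")


def _default_radius(spec: PhantomSpec) -> float:
    return min(spec.shape_zyx) / 4.0


def _build_ball(spec: PhantomSpec, rng) -> tuple[np.ndarray, dict]:
    r = float(spec.radius if spec.radius is not None else _default_radius(spec))
    shape = np.asarray(spec.shape_zyx, dtype=float)
    centers = []
    if spec.n_objects == 1:
        centers.append((shape - 1) / 2.0)
    else:
        for _ in range(spec.n_objects):
            centers.append(rng.uniform(r + 1, shape - r - 2))
    for c in centers:
        if np.any(c - r < -0.5) or np.any(c + r > shape - 0.5):
            raise ValidationError(
                f"ball of radius {r} does not fit shape {spec.shape_zyx}"
            )
    zz, yy, xx = _mesh_grid(spec.shape_zyx)
    vol = np.full(spec.shape_zyx, spec.background, dtype=np.float32)
    for c in centers:
        inside = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r**2
        vol[inside] = spec.foreground
    return vol, {"centers_zyx": [tuple(c) for c in centers], "radius": r}


def _build_tubes(spec: PhantomSpec, rng) -> tuple[np.ndarray, dict]:
    r = float(spec.radius if spec.radius is not None else 2.5)
    zz, yy, xx = _mesh_grid(spec.shape_zyx)
    coords = (zz, yy, xx)
    vol = np.full(spec.shape_zyx, spec.background, dtype=np.float32)
    tubes = []
    for _ in range(spec.n_objects):
        axis = int(rng.integers(0, 3))
        others = [a for a in range(3) if a != axis]
        pos = [
            float(rng.uniform(r, spec.shape_zyx[a] - 1 - r)) for a in others
        ]
        dist2 = (coords[others[0]] - pos[0]) ** 2 + (coords[others[1]] - pos[1]) ** 2
        vol[dist2 <= r**2] = spec.foreground
        tubes.append({"axis": "zyx"[axis], "position": pos, "radius": r})
    return vol, {"tubes": tubes}


def _build_shells(spec: PhantomSpec, rng) -> tuple[np.ndarray, dict]:
    r = float(spec.radius if spec.radius is not None else _default_radius(spec))
    center = (np.asarray(spec.shape_zyx, dtype=float) - 1) / 2.0
    if r > min(spec.shape_zyx) / 2.0:
        raise ValidationError("outer shell does not fit the volume")
    zz, yy, xx = _mesh_grid(spec.shape_zyx)
    dist = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    vol = np.full(spec.shape_zyx, spec.background, dtype=np.float32)
    radii = [r * (k + 1) / spec.n_objects for k in range(spec.n_objects)]
    thickness = max(1.5, r / (2 * spec.n_objects))
    for rk in radii:
        vol[np.abs(dist - rk) <= thickness / 2.0] = spec.foreground
    return vol, {"center_zyx": tuple(center), "shell_radii": radii}


def _build_label_cubes(spec: PhantomSpec, rng) -> tuple[np.ndarray, dict]:
    size = int(spec.cube_size)
    gap = max(2, size // 2)
    pitch = size + gap
    slots = [max(0, (s - gap) // pitch) for s in spec.shape_zyx]
    capacity = int(np.prod(slots))
    if size < 1 or capacity < spec.n_objects:
        raise ValidationError(
            f"{spec.n_objects} cubes of size {size} do not fit shape "
            f"{spec.shape_zyx} (capacity {capacity})"
        )
    vol = np.zeros(spec.shape_zyx, dtype=np.uint16)
    placements = {}
    object_id = 1
    for iz in range(slots[0]):
        for iy in range(slots[1]):
            for ix in range(slots[2]):
                if object_id > spec.n_objects:
                    break
                origin = (gap + iz * pitch, gap + iy * pitch, gap + ix * pitch)
                vol[
                    origin[0] : origin[0] + size,
                    origin[1] : origin[1] + size,
                    origin[2] : origin[2] + size,
                ] = object_id
                placements[object_id] = {"origin_zyx": origin, "size": size}
                object_id += 1
    return vol, {"cubes": placements}


# ---------------------------------------------------------------------------
# synthetic stores


def build_pyramid(
    volume: np.ndarray, n_levels: int, is_labels: bool = False
) -> list[np.ndarray]:
    """2x-per-level pyramid over the spatial (last three) axes."""
    if n_levels < 1:
        raise ValidationError("n_levels must be >= 1")
    levels = [volume]
    for _ in range(n_levels - 1):
        prev = levels[-1]
        lead = prev.shape[:-3]
        pooled = np.empty(
            lead + tuple(-(-s // 2) for s in prev.shape[-3:]),
            dtype=prev.dtype if is_labels else np.float32,
        )
        for idx in np.ndindex(*lead) if lead else [()]:
            block = prev[idx] if lead else prev
            if is_labels:
                pooled[idx] = downsample_labels(block, (2, 2, 2))
            else:
                pooled[idx] = downsample(block, (2, 2, 2))
        levels.append(pooled)
    return levels


def write_synthetic_store(
    volume: np.ndarray,
    destination: str | Path,
    format: str = "ome_zarr",
    n_levels: int = 1,
    axes: str = "tczyx",
    pixel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    pixel_unit: str = "pixel",
    channel_names: Optional[list[str]] = None,
    is_labels: bool = False,
    imagej_hyperstack: bool = False,
) -> Path:
    """Write a phantom as an OME-Zarr v0.4 store or a (ImageJ-)TIFF file.

    ``volume`` is (T, C, Z, Y, X); ``axes`` selects which of those axes the
    store keeps (singleton axes not named in ``axes`` are squeezed out).  A
    plain TIFF cannot carry separate T and C axes: data with T or C > 1 is
    an error unless ``imagej_hyperstack`` asks for ImageJ hyperstack
    metadata.  OME-Zarr stores carry full multiscales metadata.
    """
    destination = Path(destination)
    volume = np.asarray(volume)
    if volume.ndim != 5:
        raise ValidationError("write_synthetic_store expects (T, C, Z, Y, X) data")
    axes = validate_axes(axes, len(axes))
    squeezed = _select_axes(volume, axes)
    if format == "ome_zarr":
        return _write_ome_zarr(
            squeezed,
            destination,
            n_levels,
            axes,
            pixel_size,
            pixel_unit,
            channel_names,
            is_labels,
        )
    if format == "tiff":
        if n_levels != 1:
            raise ValidationError("a TIFF store holds exactly one level")
        return _write_tiff(
            squeezed, destination, axes, pixel_size, pixel_unit, imagej_hyperstack
        )
    raise ValidationError(f"unknown store format {format!r}")


def _select_axes(volume: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/squeeze a (T, C, Z, Y, X) array onto the requested axes."""
    for a in CANONICAL_AXES:
        if a not in axes and volume.shape[CANONICAL_AXES.index(a)] != 1:
            raise ValidationError(
                f"axis {a!r} has extent > 1 but is absent from axes {axes!r}"
            )
    order = [CANONICAL_AXES.index(a) for a in axes]
    kept = volume.transpose(order + [i for i in range(5) if i not in order])
    return kept.reshape(kept.shape[: len(axes)])


_AXIS_TYPES = {"t": "time", "c": "channel", "z": "space", "y": "space", "x": "space"}


def _write_ome_zarr(
    data: np.ndarray,
    destination: Path,
    n_levels: int,
    axes: str,
    pixel_size,
    pixel_unit: str,
    channel_names,
    is_labels: bool,
) -> Path:
    import zarr

    spatial = {"x": pixel_size[0], "y": pixel_size[1], "z": pixel_size[2]}
    unit = _NGFF_UNITS.get(pixel_unit, None)

    # lift to 5D for the pyramid builder, then project back per level
    lifted = data.reshape((1,) * (5 - data.ndim) + data.shape)
    pad = 5 - data.ndim
    levels = build_pyramid(lifted, n_levels, is_labels=is_labels)

    try:
        group = zarr.open_group(str(destination), mode="w", zarr_format=2)
    except Exception as exc:  # pragma: no cover - filesystem dependent
        raise SourceReadError(f"cannot create store at {destination}: {exc}") from exc

    datasets = []
    for i, level in enumerate(levels):
        arr = level.reshape(level.shape[pad:])
        za = group.create_array(
            str(i), shape=arr.shape, dtype=arr.dtype, chunks=arr.shape
        )
        za[:] = arr
        scale = []
        for a, full, here in zip(axes, data.shape, arr.shape):
            if a in spatial:
                scale.append(spatial[a] * full / here)
            else:
                scale.append(1.0)
        datasets.append(
            {
                "path": str(i),
                "coordinateTransformations": [{"type": "scale", "scale": scale}],
            }
        )

    axes_meta = []
    for a in axes:
        entry = {"name": a, "type": _AXIS_TYPES[a]}
        if a in "zyx" and unit:
            entry["unit"] = unit
        axes_meta.append(entry)
    group.attrs["multiscales"] = [
        {"version": "0.4", "name": destination.name, "axes": axes_meta, "datasets": datasets}
    ]
    if channel_names:
        group.attrs["omero"] = {
            "channels": [{"label": str(n)} for n in channel_names]
        }
    return destination


def _write_tiff(
    data: np.ndarray,
    destination: Path,
    axes: str,
    pixel_size,
    pixel_unit: str,
    imagej_hyperstack: bool,
) -> Path:
    import tifffile

    # grayscale stacks: never let small trailing axes be guessed as RGB
    kwargs: dict = {"photometric": "minisblack"}
    has_t = "t" in axes and data.shape[axes.index("t")] > 1
    has_c = "c" in axes and data.shape[axes.index("c")] > 1
    if has_t or has_c:
        if not imagej_hyperstack:
            raise ValidationError(
                "a plain TIFF cannot label time/channel axes; pass "
                "imagej_hyperstack=True or write an OME-Zarr store"
            )
        if data.dtype not in (np.uint8, np.uint16, np.float32):
            raise ValidationError(
                "ImageJ hyperstacks support uint8/uint16/float32 only"
            )
        order = [axes.index(a) for a in "tzcyx" if a in axes]
        data = data.transpose(order)
        kwargs["imagej"] = True
        kwargs["metadata"] = {
            "axes": "".join(a.upper() for a in "tzcyx" if a in axes),
            "spacing": pixel_size[2],
            "unit": pixel_unit if pixel_unit != "pixel" else "pixel",
        }
    if pixel_size[0] > 0:
        kwargs["resolution"] = (1.0 / pixel_size[0], 1.0 / pixel_size[1])
    try:
        tifffile.imwrite(str(destination), data, **kwargs)
    except OSError as exc:
        raise SourceReadError(f"cannot write TIFF to {destination}: {exc}") from exc
    return destination
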