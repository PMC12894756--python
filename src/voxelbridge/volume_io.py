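"""Reading microscopy volumes into a canonical lazy 5D (T, C, Z, Y, X) handle.

Microscopy stacks arrive as TIFF files or OME-Zarr stores with anywhere from
2 to 5 dimensions spread over time (t), channel (c) and space (z, y, x) in
arbitrary order.  This module reads the metadata, infers or accepts the axis
order, pixel sizes and channel names, and exposes a :class:`VolumeDataset`
whose voxels are only materialized on demand, one (level, timeframe, channel)
3D block at a time.

Supported sources
-----------------
* OME-Zarr v0.4 groups (``multiscales`` metadata with ``axes`` and
  ``datasets``), local path or URI string accepted by zarr.
* TIFF / ImageJ-TIFF files; multi-page stacks are treated as the Z axis
  unless the series metadata says otherwise.

When a source carries no axis metadata the following fallback applies:
2D -> YX, 3D -> ZYX, 4D -> CZYX if the leading axis has extent <= 8 else
TZYX, 5D -> TCZYX.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .errors import SourceReadError, ValidationError

CANONICAL_AXES = "tczyx"

#: Heuristic when the source has no axis metadata.  4D data with a small
#: leading axis is far more likely to be multi-channel than a 4-frame movie.
_AXIS_FALLBACK_CHANNEL_MAX = 8

_UNIT_ALIASES = {
    "pixel": "pixel",
    "px": "pixel",
    "": "pixel",
    "nanometer": "nanometer",
    "nanometre": "nanometer",
    "nm": "nanometer",
    "micrometer": "micrometer",
    "micrometre": "micrometer",
    "micron": "micrometer",
    "um": "micrometer",
    "µm": "micrometer",
    "μm": "micrometer",
    "angstrom": "angstrom",
    "ångström": "angstrom",
    "Å": "angstrom",
    "a": "angstrom",
    "meter": "meter",
    "metre": "meter",
    "m": "meter",
}

_DTYPE_KINDS = {"u": "unsigned-int", "i": "signed-int", "f": "float"}


def normalize_unit(unit: Optional[str]) -> str:
    """Map the many spellings of physical units onto a canonical name."""
    if unit is None:
        return "pixel"
    key = unit.strip()
    if key in _UNIT_ALIASES:
        return _UNIT_ALIASES[key]
    key = key.lower()
    if key not in _UNIT_ALIASES:
        raise ValidationError(f"unsupported pixel unit {unit!r}")
    return _UNIT_ALIASES[key]


def validate_axes(axes: str, ndim: int) -> str:
    """Check an axis string: 2-5 distinct letters out of 'tczyx'."""
    axes = axes.lower()
    if len(axes) != ndim:
        raise ValidationError(
            f"axis string {axes!r} has {len(axes)} letters for {ndim}-D data"
        )
    if not (2 <= len(axes) <= 5):
        raise ValidationError(f"axis string {axes!r} must have 2-5 letters")
    if len(set(axes)) != len(axes):
        raise ValidationError(f"axis string {axes!r} has repeated letters")
    unknown = set(axes) - set(CANONICAL_AXES)
    if unknown:
        raise ValidationError(
            f"axis string {axes!r} has unknown letters {sorted(unknown)!r}"
        )
    return axes


def guess_axes(shape: Sequence[int]) -> str:
    """Fallback axis order for metadata-free sources (see module docstring)."""
    ndim = len(shape)
    if ndim == 2:
        return "yx"
    if ndim == 3:
        return "zyx"
    if ndim == 4:
        return "czyx" if shape[0] <= _AXIS_FALLBACK_CHANNEL_MAX else "tzyx"
    if ndim == 5:
        return "tczyx"
    raise ValidationError(f"cannot handle {ndim}-D data; 2-5 dimensions supported")


@dataclass(frozen=True)
class MultiscaleLevel:
    """One level of a resolution pyramid, finest at ``level_index`` 0.

    ``footprint_bytes_per_timeframe`` is the float32 size of one timeframe
    across all channels (Z*Y*X*C*4): the quantity budgeted during level
    selection.
    """

    level_index: int
    shape_zyx: tuple[int, int, int]
    downscale_factors: tuple[Fraction, Fraction, Fraction]  # (z, y, x) vs level 0
    footprint_bytes_per_timeframe: int

    def __post_init__(self) -> None:
        if self.level_index < 0:
            raise ValidationError("level_index must be >= 0")
        if any(s <= 0 for s in self.shape_zyx):
            raise ValidationError("level shape must be positive")
        if any(f <= 0 for f in self.downscale_factors):
            raise ValidationError("downscale factors must be positive")

    @classmethod
    def from_shape(
        cls,
        level_index: int,
        shape_zyx: Sequence[int],
        level0_shape_zyx: Sequence[int],
        n_channels: int,
    ) -> "MultiscaleLevel":
        z, y, x = (int(v) for v in shape_zyx)
        factors = tuple(
            Fraction(int(s0), int(s)) for s0, s in zip(level0_shape_zyx, shape_zyx)
        )
        return cls(level_index, (z, y, x), factors, z * y * x * n_channels * 4)


@dataclass(frozen=True)
class ReadOverrides:
    """Manual overrides taking precedence over source metadata."""

    axes: Optional[str] = None
    pixel_size: Optional[tuple[float, float, float]] = None  # (x, y, z)
    pixel_unit: Optional[str] = None
    channel_names: Optional[Sequence[str]] = None


@dataclass(frozen=True)
class VolumeDataset:
    """Canonicalized lazy handle on a 2D-5D microscopy source.

    ``shape_canonical`` is always a 5-tuple ordered (T, C, Z, Y, X); axes
    absent from the source get extent 1.  Voxels are materialized through
    :meth:`read_level`, one channel of one timeframe at one pyramid level,
    cast to float32.
    """

    source: str
    axes_original: str
    shape_canonical: tuple[int, int, int, int, int]
    dtype_bits: int
    dtype_kind: str
    pixel_size: tuple[float, float, float]  # (x, y, z), physical units per voxel
    pixel_unit: str
    channel_names: tuple[str, ...]
    levels: tuple[MultiscaleLevel, ...]
    time_window: tuple[int, int]
    _level_arrays: tuple = field(repr=False, default=(), compare=False)

    def __post_init__(self) -> None:
        if len(self.shape_canonical) != 5:
            raise ValidationError("shape_canonical must have 5 entries")
        validate_axes(self.axes_original, len(self.axes_original))
        t, c = self.shape_canonical[0], self.shape_canonical[1]
        if len(self.channel_names) != c:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        t0, t1 = self.time_window
        if not (0 <= t0 < t1 <= t):
            raise ValidationError(
                f"time window [{t0}, {t1}) invalid for {t} timeframes"
            )
        if any(p <= 0 for p in self.pixel_size):
            raise ValidationError("pixel sizes must be positive")

    # -- derived geometry -------------------------------------------------
    @property
    def n_timeframes(self) -> int:
        t0, t1 = self.time_window
        return t1 - t0

    @property
    def n_channels(self) -> int:
        return self.shape_canonical[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.shape_canonical[2:]

    def timeframes(self) -> range:
        """Absolute timeframe indices inside the active window."""
        return range(*self.time_window)

    # -- data access ------------------------------------------------------
    def read_level(self, level_index: int, t: int = 0, c: int = 0) -> np.ndarray:
        """Materialize one (Z, Y, X) block as float32."""
        return self._read(level_index, t, c).astype(np.float32, copy=False)

    def read_level_native(self, level_index: int, t: int = 0, c: int = 0) -> np.ndarray:
        """Like :meth:`read_level` but keeping the source dtype.

        Needed for label masks, whose integer identities must not pass
        through a float cast.
        """
        return self._read(level_index, t, c)

    def _read(self, level_index: int, t: int, c: int) -> np.ndarray:
        if not (0 <= level_index < len(self.levels)):
            raise ValidationError(
                f"level {level_index} out of range (have {len(self.levels)})"
            )
        t0, t1 = self.time_window
        if not (t0 <= t < t1):
            raise ValidationError(f"timeframe {t} outside window [{t0}, {t1})")
        if not (0 <= c < self.n_channels):
            raise ValidationError(f"channel {c} out of range")
        arr = self._level_arrays[level_index]
        index = []
        spatial_letters = []
        for letter in self.axes_original:
            if letter == "t":
                index.append(t)
            elif letter == "c":
                index.append(c)
            else:
                index.append(slice(None))
                spatial_letters.append(letter)
        block = np.asarray(arr[tuple(index)])
        # reorder surviving spatial axes to (z, y, x), inserting missing ones
        order = [spatial_letters.index(a) for a in "zyx" if a in spatial_letters]
        block = block.transpose(order)
        for pos, a in enumerate("zyx"):
            if a not in spatial_letters:
                block = np.expand_dims(block, pos)
        return block


# ---------------------------------------------------------------------------
# readers


def read_dataset(
    source: str, overrides: Optional[ReadOverrides] = None
) -> VolumeDataset:
    """Open a TIFF file or OME-Zarr store as a canonical :class:`VolumeDataset`.

    Axis order, pixel sizes and channel names come from the source metadata
    when present; ``overrides`` take precedence over metadata; the fallback
    table in the module docstring fills in whatever remains.
    """
    src = str(source)
    if _looks_like_tiff(src):
        raw = _read_tiff(src)
    else:
        raw = _read_zarr(src)
    return _assemble(src, raw, overrides or ReadOverrides())


def clip_time(dataset: VolumeDataset, t0: int, t1: int) -> VolumeDataset:
    """Restrict the dataset to the half-open timeframe window [t0, t1).

    The underlying data is untouched; only iteration and index validation
    change.  An empty or out-of-range window is an error.
    """
    T = dataset.shape_canonical[0]
    if not (0 <= t0 < t1 <= T):
        raise ValidationError(f"time window [{t0}, {t1}) invalid for T={T}")
    return dataclasses.replace(dataset, time_window=(t0, t1))


def read_level(
    dataset: VolumeDataset, level_index: int, t: int = 0, c: int = 0
) -> np.ndarray:
    """Functional alias for :meth:`VolumeDataset.read_level`."""
    return dataset.read_level(level_index, t, c)


# ---------------------------------------------------------------------------
# internals

_TIFF_SUFFIXES = (".tif", ".tiff", ".ome.tif", ".ome.tiff")


def _looks_like_tiff(source: str) -> bool:
    return source.lower().endswith(_TIFF_SUFFIXES)


@dataclass
class _RawSource:
    """What a format-specific reader hands to :func:`_assemble`."""

    arrays: list  # lazy array-likes, finest first, all in the same axis order
    axes: Optional[str]  # metadata axis string or None
    pixel_size: Optional[tuple[float, float, float]]  # (x, y, z)
    pixel_unit: Optional[str]
    channel_names: Optional[list[str]]


class _LazyTiff:
    """Deferred TIFF series: metadata without voxels until first access."""

    def __init__(self, path: str, shape: tuple, dtype: np.dtype) -> None:
        self._path = path
        self.shape = shape
        self.dtype = dtype
        self._data: Optional[np.ndarray] = None

    def __getitem__(self, index):
        if self._data is None:
            import tifffile

            self._data = tifffile.imread(self._path)
        return self._data[index]


def _read_tiff(source: str) -> _RawSource:
    import tifffile

    try:
        tif = tifffile.TiffFile(source)
    except (OSError, ValueError) as exc:
        raise SourceReadError(f"cannot read TIFF source {source!r}: {exc}") from exc
    with tif:
        series = tif.series[0]
        shape = tuple(int(s) for s in series.shape)
        dtype = np.dtype(series.dtype)
        axes = series.axes.lower().replace("s", "c")
        if set(axes) - set(CANONICAL_AXES) or len(set(axes)) != len(axes):
            axes = None  # unlabeled ('q'/'i') axes: fall back to the guess table
        pixel_size = None
        pixel_unit = None
        ij = tif.imagej_metadata or {}
        x = _resolution_to_size(tif.pages[0].tags.get("XResolution"))
        y = _resolution_to_size(tif.pages[0].tags.get("YResolution"))
        z = ij.get("spacing")
        if x or y or z:
            pixel_size = (x or 1.0, y or x or 1.0, float(z) if z else (x or 1.0))
        if ij.get("unit"):
            try:
                pixel_unit = normalize_unit(str(ij["unit"]))
            except ValidationError:
                pixel_unit = None
    return _RawSource(
        arrays=[_LazyTiff(source, shape, dtype)],
        axes=axes,
        pixel_size=pixel_size,
        pixel_unit=pixel_unit,
        channel_names=None,
    )


def _resolution_to_size(tag) -> Optional[float]:
    if tag is None:
        return None
    value = tag.value
    try:
        num, den = value
    except TypeError:
        return None
    if num == 0:
        return None
    return den / num  # tag stores pixels per unit


def _read_zarr(source: str) -> _RawSource:
    import zarr

    try:
        group = zarr.open_group(source, mode="r")
    except Exception:
        group = None
    if group is not None and "multiscales" in group.attrs:
        return _read_ome_zarr_group(group, source)
    try:
        arr = zarr.open_array(source, mode="r")
    except Exception as exc:
        raise SourceReadError(
            f"cannot read source {source!r} as OME-Zarr or zarr array: {exc}"
        ) from exc
    return _RawSource([arr], None, None, None, None)


def _read_ome_zarr_group(group, source: str) -> _RawSource:
    ms = group.attrs["multiscales"][0]
    axes_meta = ms.get("axes", [])
    axes = "".join(a["name"].lower() for a in axes_meta) if axes_meta else None
    arrays = []
    scale0 = None
    for ds in ms["datasets"]:
        arrays.append(group[ds["path"]])
        if scale0 is None:
            for tr in ds.get("coordinateTransformations", []):
                if tr.get("type") == "scale":
                    scale0 = tr["scale"]
    pixel_size = None
    pixel_unit = None
    if axes and scale0 is not None:
        sizes = {}
        units = set()
        for a, s in zip(axes_meta, scale0):
            name = a["name"].lower()
            if name in "zyx":
                sizes[name] = float(s)
                if a.get("unit"):
                    units.add(a["unit"])
        if {"x", "y"} <= sizes.keys():
            pixel_size = (sizes["x"], sizes["y"], sizes.get("z", sizes["x"]))
        if len(units) == 1:
            try:
                pixel_unit = normalize_unit(units.pop())
            except ValidationError:
                pixel_unit = None
    channel_names = None
    omero = group.attrs.get("omero")
    if omero and omero.get("channels"):
        channel_names = [
            str(ch.get("label", f"channel_{i}"))
            for i, ch in enumerate(omero["channels"])
        ]
    return _RawSource(arrays, axes, pixel_size, pixel_unit, channel_names)


def _assemble(
    source: str, raw: _RawSource, overrides: ReadOverrides
) -> VolumeDataset:
    shape = tuple(int(s) for s in raw.arrays[0].shape)
    ndim = len(shape)
    if ndim > 5 or ndim < 2:
        raise ValidationError(
            f"source {source!r} has {ndim} dimensions; 2-5 supported"
        )
    if overrides.axes is not None:
        axes = validate_axes(overrides.axes, ndim)
    elif raw.axes is not None:
        axes = validate_axes(raw.axes, ndim)
    else:
        axes = guess_axes(shape)

    extents = dict(zip(axes, shape))
    shape_canonical = tuple(extents.get(a, 1) for a in CANONICAL_AXES)
    T, C = shape_canonical[0], shape_canonical[1]

    dtype = np.dtype(raw.arrays[0].dtype)
    if dtype.kind not in _DTYPE_KINDS:
        raise ValidationError(f"unsupported voxel dtype {dtype}")
    bits = dtype.itemsize * 8
    if bits not in (8, 16, 32):
        raise ValidationError(f"unsupported voxel bit depth {bits}")

    if overrides.pixel_size is not None:
        if len(overrides.pixel_size) != 3:
            raise ValidationError("pixel_size override must be (x, y, z)")
        pixel_size = tuple(float(v) for v in overrides.pixel_size)
    else:
        pixel_size = raw.pixel_size or (1.0, 1.0, 1.0)
    if overrides.pixel_unit is not None:
        pixel_unit = normalize_unit(overrides.pixel_unit)
    else:
        pixel_unit = raw.pixel_unit or "pixel"

    if overrides.channel_names is not None:
        names = [str(n) for n in overrides.channel_names]
    elif raw.channel_names is not None:
        names = list(raw.channel_names)
    else:
        names = [f"channel_{i}" for i in range(C)]
    if len(names) != C:
        raise ValidationError(f"{len(names)} channel names for {C} channels")

    level0_zyx = tuple(extents.get(a, 1) for a in "zyx")
    levels = []
    for i, arr in enumerate(raw.arrays):
        lvl_extents = dict(zip(axes, (int(s) for s in arr.shape)))
        levels.append(
            MultiscaleLevel.from_shape(
                i, tuple(lvl_extents.get(a, 1) for a in "zyx"), level0_zyx, C
            )
        )
    for fine, coarse in zip(levels, levels[1:]):
        if any(c > f for c, f in zip(coarse.shape_zyx, fine.shape_zyx)):
            raise ValidationError("pyramid levels must be non-increasing in shape")

    return VolumeDataset(
        source=source,
        axes_original=axes,
        shape_canonical=shape_canonical,
        dtype_bits=bits,
        dtype_kind=_DTYPE_KINDS[dtype.kind],
        pixel_size=pixel_size,
        pixel_unit=pixel_unit,
        channel_names=tuple(names),
        levels=tuple(levels),
        time_window=(0, T),
        _level_arrays=tuple(raw.arrays),
    )
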