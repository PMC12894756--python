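"""Renderable asset export: sparse float32 volume grids, meshes, manifest.

Whatever the input bit depth, voxel data is resaved as 32-bit float so a
single grid container serves every channel.  The portable container here is
a bricked sparse grid (``.vxgrid``): the volume is cut into fixed-size
bricks (16^3 by default) and bricks consisting entirely of the background
value are elided, a flat-file analogue of hierarchical sparse voxel formats
such as VDB.  Meshes (threshold isosurfaces and per-identity label
surfaces) are exchanged as OBJ or binary PLY.  A JSON manifest ties the
files of a scene together with the transforms, channel modes, transfer
functions and slice boxes needed to reload or render it.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import FeatureUnavailableError, SourceReadError, ValidationError
from .scene_space import SceneTransform
from .transfer import RGB, LabelPalette, TransferFunction

_GRID_MAGIC = b"VXGRID01"
DEFAULT_BRICK_SIZE = 16


# ---------------------------------------------------------------------------
# volume grids


@dataclass
class VolumeGrid:
    """Dense view of a bricked sparse float32 grid plus its placement.

    ``values`` always reads back the exact float32 cast of the source
    voxels; sparsity only affects storage.
    """

    values: np.ndarray  # (Z, Y, X) float32
    transform: SceneTransform
    background: float = 0.0
    channel_ref: int = 0
    timeframe: int = 0
    brick_size: int = DEFAULT_BRICK_SIZE
    n_stored_bricks: int = 0

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)


def _brick_starts(extent: int, brick: int) -> range:
    return range(0, extent, brick)


def export_volume_grid(
    volume: np.ndarray,
    transform: SceneTransform,
    destination: str | Path,
    background: float = 0.0,
    brick_size: int = DEFAULT_BRICK_SIZE,
    channel_ref: int = 0,
    timeframe: int = 0,
    container: str = "bricked",
) -> VolumeGrid:
    """Write a 3D volume as a bricked sparse float32 grid file.

    All-background bricks occupy no value storage; the round trip through
    :func:`read_volume_grid` is lossless at float32 precision.  ``container
    = "vdb"`` would emit an OpenVDB file but requires a VDB codec
    (pyopenvdb), which this installation does not provide.
    """
    if container == "vdb":
        raise FeatureUnavailableError(
            "VDB export requires a VDB codec (pyopenvdb); "
            "use the default bricked container instead"
        )
    if container != "bricked":
        raise ValidationError(f"unknown grid container {container!r}")
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValidationError("volume grids are 3D (Z, Y, X)")
    if not np.all(np.isfinite(volume)):
        raise ValidationError("volume contains non-finite values")
    if brick_size < 1:
        raise ValidationError("brick size must be >= 1")
    values = volume.astype(np.float32)
    bg = np.float32(background)

    bricks: list[tuple[int, int, int]] = []
    payload: list[bytes] = []
    z_n, y_n, x_n = values.shape
    for bz in _brick_starts(z_n, brick_size):
        for by in _brick_starts(y_n, brick_size):
            for bx in _brick_starts(x_n, brick_size):
                block = values[
                    bz : bz + brick_size, by : by + brick_size, bx : bx + brick_size
                ]
                if np.all(block == bg):
                    continue
                bricks.append((bz, by, bx))
                payload.append(np.ascontiguousarray(block).tobytes())

    header = {
        "shape": [int(s) for s in values.shape],
        "brick_size": int(brick_size),
        "background": float(background),
        "dtype": "float32",
        "bricks": [list(b) for b in bricks],
        "transform": transform.to_dict(),
        "channel_ref": int(channel_ref),
        "timeframe": int(timeframe),
    }
    header_bytes = json.dumps(header, sort_keys=True).encode("utf-8")
    destination = Path(destination)
    try:
        with open(destination, "wb") as fh:
            fh.write(_GRID_MAGIC)
            fh.write(struct.pack("<Q", len(header_bytes)))
            fh.write(header_bytes)
            for chunk in payload:
                fh.write(chunk)
    except OSError as exc:
        raise SourceReadError(f"cannot write grid to {destination}: {exc}") from exc
    return VolumeGrid(
        values=values,
        transform=transform,
        background=float(background),
        channel_ref=int(channel_ref),
        timeframe=int(timeframe),
        brick_size=int(brick_size),
        n_stored_bricks=len(bricks),
    )


def read_volume_grid(path: str | Path) -> VolumeGrid:
    """Read a ``.vxgrid`` file back into a dense :class:`VolumeGrid`."""
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise SourceReadError(f"cannot read grid {path}: {exc}") from exc
    if raw[: len(_GRID_MAGIC)] != _GRID_MAGIC:
        raise ValidationError(f"{path} is not a voxelbridge grid file")
    (header_len,) = struct.unpack_from("<Q", raw, len(_GRID_MAGIC))
    offset = len(_GRID_MAGIC) + 8
    header = json.loads(raw[offset : offset + header_len].decode("utf-8"))
    offset += header_len

    shape = tuple(header["shape"])
    brick = int(header["brick_size"])
    bg = np.float32(header["background"])
    values = np.full(shape, bg, dtype=np.float32)
    for bz, by, bx in header["bricks"]:
        dz = min(brick, shape[0] - bz)
        dy = min(brick, shape[1] - by)
        dx = min(brick, shape[2] - bx)
        count = dz * dy * dx
        block = np.frombuffer(raw, dtype="<f4", count=count, offset=offset)
        offset += count * 4
        values[bz : bz + dz, by : by + dy, bx : bx + dx] = block.reshape(dz, dy, dx)
    return VolumeGrid(
        values=values,
        transform=SceneTransform.from_dict(header["transform"]),
        background=float(header["background"]),
        channel_ref=int(header["channel_ref"]),
        timeframe=int(header["timeframe"]),
        brick_size=brick,
        n_stored_bricks=len(header["bricks"]),
    )


# ---------------------------------------------------------------------------
# meshes


@dataclass
class Mesh:
    """Triangle surface in world space with unit vertex normals."""

    vertices: np.ndarray  # (N, 3) float, world (x, y, z)
    faces: np.ndarray  # (M, 3) int
    normals: np.ndarray  # (N, 3) float, unit

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValidationError("face indices out of range")
        if len(self.normals) != len(self.vertices):
            raise ValidationError("need one normal per vertex")

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    def _trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @property
    def is_watertight(self) -> bool:
        return (not self.is_empty) and bool(self._trimesh().is_watertight)

    def enclosed_volume(self) -> float:
        """Signed-volume (divergence theorem) sum over triangles, absolute."""
        if self.is_empty:
            return 0.0
        return float(abs(self._trimesh().volume))

    @classmethod
    def empty(cls) -> "Mesh":
        return cls(
            np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64), np.zeros((0, 3))
        )


def extract_isosurface(
    volume: np.ndarray,
    threshold: float,
    transform: SceneTransform,
    background: float = 0.0,
) -> Mesh:
    """Marching-cubes surface of {v = threshold}, mapped to world space.

    The volume is padded with one layer of ``background`` first, so
    surfaces that would cross the data boundary are closed (compact
    foreground regions yield watertight meshes).  A threshold outside the
    padded data range yields an empty mesh, not an error.
    """
    from skimage.measure import marching_cubes

    volume = np.asarray(volume, dtype=np.float32)
    if volume.ndim != 3:
        raise ValidationError("isosurface extraction expects a 3D volume")
    if not np.all(np.isfinite(volume)):
        raise ValidationError("volume contains non-finite values")
    padded = np.pad(volume, 1, constant_values=np.float32(background))
    if not (padded.min() < threshold < padded.max()):
        return Mesh.empty()
    verts, faces, _, _ = marching_cubes(padded, level=float(threshold))
    verts = verts - 1.0  # undo the pad offset; coordinates index voxel centers
    world = transform.voxel_to_world(verts)
    # (z,y,x) -> (x,y,z) is an odd permutation: flip winding to keep
    # outward-facing orientation
    faces = faces[:, ::-1].copy()
    normals = _vertex_normals(world, faces)
    return Mesh(world, faces, normals)


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted per-vertex normals, normalized to unit length."""
    normals = np.zeros_like(vertices)
    tri = vertices[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    for k in range(3):
        np.add.at(normals, faces[:, k], fn)
    lengths = np.linalg.norm(normals, axis=1, keepdims=True)
    lengths[lengths == 0] = 1.0
    return normals / lengths


@dataclass
class LabelSurfaceSet:
    """One watertight mesh + color per object identity in a label volume."""

    entries: dict[int, tuple[Mesh, RGB]] = field(default_factory=dict)

    def ids(self) -> list[int]:
        return sorted(self.entries)


def extract_label_surfaces(
    labels: np.ndarray,
    transform: SceneTransform,
    palette: Optional[LabelPalette] = None,
    overrides: Optional[Mapping[int, RGB]] = None,
) -> LabelSurfaceSet:
    """Mesh each object identity of an integer label volume separately.

    Every unique nonzero identity gets the 0.5-isosurface of its binary
    mask, colored by the revolving palette unless overridden.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValidationError("label volumes are 3D (Z, Y, X)")
    if labels.dtype.kind not in "iu":
        raise ValidationError("label volumes must have an integer dtype")
    if labels.size and labels.min() < 0:
        raise ValidationError("label identities must be non-negative")
    palette = palette or LabelPalette()
    out = LabelSurfaceSet()
    for object_id in np.unique(labels):
        object_id = int(object_id)
        if object_id == 0:
            continue
        mask = (labels == object_id).astype(np.float32)
        mesh = extract_isosurface(mask, 0.5, transform, background=0.0)
        out.entries[object_id] = (mesh, palette.color_for(object_id, overrides))
    return out


def write_mesh(mesh: Mesh, destination: str | Path, format: str = "ply") -> Path:
    """Write a mesh as ASCII OBJ or binary little-endian PLY."""
    destination = Path(destination)
    fmt = format.lower()
    if fmt not in ("obj", "ply"):
        raise ValidationError(f"unknown mesh format {format!r}; use 'obj' or 'ply'")
    import trimesh

    if mesh.is_empty and fmt == "obj":
        # trimesh cannot export zero-element OBJ; an empty file is valid OBJ
        destination.write_bytes(b"# empty mesh\n")
        return destination
    tm = trimesh.Trimesh(
        vertices=mesh.vertices,
        faces=mesh.faces,
        vertex_normals=mesh.normals if len(mesh.normals) else None,
        process=False,
    )
    data = tm.export(file_type=fmt)
    if isinstance(data, str):
        data = data.encode("utf-8")
    try:
        destination.write_bytes(data)
    except OSError as exc:
        raise SourceReadError(f"cannot write mesh to {destination}: {exc}") from exc
    return destination


def read_mesh(path: str | Path) -> Mesh:
    """Read an OBJ/PLY file back, preserving vertex order."""
    import trimesh

    try:
        tm = trimesh.load_mesh(str(path), process=False, maintain_order=True)
    except (ValueError, IndexError):
        return Mesh.empty()
    if not hasattr(tm, "faces") or len(getattr(tm, "vertices", ())) == 0:
        return Mesh.empty()
    vertices = np.asarray(tm.vertices, dtype=np.float64).reshape(-1, 3)
    faces = np.asarray(tm.faces, dtype=np.int64).reshape(-1, 3)
    if len(vertices) == 0:
        return Mesh.empty()
    return Mesh(vertices, faces, _vertex_normals(vertices, faces))


# ---------------------------------------------------------------------------
# scene manifest


@dataclass
class ChannelAssets:
    """Asset files and appearance settings of one channel."""

    name: str
    mode: str  # "volumetric" | "isosurface" | "labelmask"
    emissive: bool = True
    color: RGB = (1.0, 1.0, 1.0)
    transfer: Optional[TransferFunction] = None
    threshold: Optional[float] = None  # isosurface mode
    grids: dict[str, str] = field(default_factory=dict)  # timeframe -> relpath
    mesh: Optional[str] = None  # isosurface mode relpath
    labels: dict[str, dict] = field(default_factory=dict)  # id -> {mesh, color}

    _MODES = ("volumetric", "isosurface", "labelmask")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValidationError(
                f"channel mode {self.mode!r} not in {self._MODES}"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mode": self.mode,
            "emissive": bool(self.emissive),
            "color": [float(c) for c in self.color],
            "transfer": self.transfer.to_dict() if self.transfer else None,
            "threshold": None if self.threshold is None else float(self.threshold),
            "grids": dict(sorted(self.grids.items())),
            "mesh": self.mesh,
            "labels": {k: dict(v) for k, v in sorted(self.labels.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelAssets":
        return cls(
            name=d["name"],
            mode=d["mode"],
            emissive=bool(d["emissive"]),
            color=tuple(float(c) for c in d["color"]),
            transfer=(
                TransferFunction.from_dict(d["transfer"]) if d.get("transfer") else None
            ),
            threshold=d.get("threshold"),
            grids=dict(d.get("grids", {})),
            mesh=d.get("mesh"),
            labels={str(k): dict(v) for k, v in d.get("labels", {}).items()},
        )


@dataclass
class Scene:
    """Everything needed to reload or render an exported dataset."""

    channels: list[ChannelAssets]
    base_transform: SceneTransform  # transform of pyramid level 0
    level: int = 0
    extra_downscale: tuple[int, int, int] = (1, 1, 1)
    slice_boxes: list = field(default_factory=list)  # of raymarch.SliceBox
    source: str = ""
    time_window: tuple[int, int] = (0, 1)

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "source": self.source,
            "level": self.level,
            "extra_downscale": list(self.extra_downscale),
            "time_window": list(self.time_window),
            "base_transform": self.base_transform.to_dict(),
            "channels": [c.to_dict() for c in self.channels],
            "slice_boxes": [b.to_dict() for b in self.slice_boxes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scene":
        from .raymarch import SliceBox

        return cls(
            channels=[ChannelAssets.from_dict(c) for c in d["channels"]],
            base_transform=SceneTransform.from_dict(d["base_transform"]),
            level=int(d["level"]),
            extra_downscale=tuple(int(v) for v in d["extra_downscale"]),
            slice_boxes=[SliceBox.from_dict(b) for b in d["slice_boxes"]],
            source=d.get("source", ""),
            time_window=tuple(int(v) for v in d["time_window"]),
        )

    def referenced_files(self) -> list[str]:
        refs: list[str] = []
        for ch in self.channels:
            refs.extend(ch.grids.values())
            if ch.mesh:
                refs.append(ch.mesh)
            for entry in ch.labels.values():
                refs.append(entry["mesh"])
        return refs


def _canonical_json(d: dict) -> bytes:
    return (json.dumps(d, sort_keys=True, indent=2) + "\n").encode("utf-8")


def write_manifest(scene: Scene, destination: str | Path) -> Path:
    """Serialize a scene to canonical JSON next to its asset files.

    All referenced asset paths (relative to the manifest directory) must
    exist; a dangling reference is an error.
    """
    destination = Path(destination)
    base = destination.parent
    for ref in scene.referenced_files():
        if not (base / ref).exists():
            raise ValidationError(f"manifest references missing file {ref!r}")
    destination.write_bytes(_canonical_json(scene.to_dict()))
    return destination


def load_manifest(path: str | Path) -> Scene:
    """Load a scene manifest, validating its file references."""
    path = Path(path)
    try:
        scene = Scene.from_dict(json.loads(path.read_text()))
    except OSError as exc:
        raise SourceReadError(f"cannot read manifest {path}: {exc}") from exc
    for ref in scene.referenced_files():
        if not (path.parent / ref).exists():
            raise ValidationError(f"manifest references missing file {ref!r}")
    return scene
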