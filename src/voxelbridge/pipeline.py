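"""End-to-end orchestration: info, convert (export assets), render.

This is the library backend of the command line interface.  ``convert``
reads a source, picks a pyramid level under the memory budget, builds the
world transform, exports per-channel assets (volume grids, isosurface
meshes, per-identity label surfaces) and writes the scene manifest;
``render`` reloads a manifest and ray-marches a preview image.

A rerun with ``reload_scale`` swaps the grid files for a different pyramid
level while preserving the transfer functions and slice boxes of the
existing manifest — the interactive-coarse / final-fine exchange workflow.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import assets as assets_mod
from .errors import ValidationError
from .multiscale import (
    BudgetPolicy,
    LevelSelection,
    downsample,
    downsample_labels,
    footprint_bytes,
    parse_budget,
    select_level,
)
from .raymarch import (
    LabelRenderChannel,
    RenderChannel,
    RenderConfig,
    RenderResult,
    SliceBox,
    make_slab,
    render,
)
from .scene_space import CenterMode, SceneTransform, UnitMode, build_transform
from .transfer import Colormap, LabelPalette, TransferFunction
from .volume_io import MultiscaleLevel, ReadOverrides, clip_time, read_dataset

logger = logging.getLogger("voxelbridge")

_CONFIG_KEYS = {
    "source",
    "output_dir",
    "channels",
    "emissive",
    "colors",
    "colormaps",
    "unit_mode",
    "center_mode",
    "budget",
    "time_window",
    "level",
    "axes",
    "pixel_size",
    "pixel_unit",
    "channel_names",
    "slabs",
    "label_opacity",
    "log_level",
}


@dataclass
class RunConfig:
    """Flat configuration mirroring the CLI flags.

    ``channels`` holds one mode string per channel: ``volumetric``,
    ``isosurface:<threshold>`` or ``labelmask``; missing entries default to
    volumetric.  Defaults mirror the load defaults of the pipeline:
    px -> cm units, XY centering, 4 GiB budget, volumetric + emissive.
    """

    source: str = ""
    output_dir: str = "voxelbridge_out"
    channels: list[str] = field(default_factory=list)
    emissive: list[bool] = field(default_factory=list)
    colors: list[tuple[float, float, float]] = field(default_factory=list)
    colormaps: list[Optional[str]] = field(default_factory=list)
    unit_mode: str = UnitMode.PX_TO_CM.value
    center_mode: str = CenterMode.XY_CENTERED.value
    budget: str | int = "4GiB"
    time_window: Optional[tuple[int, int]] = None
    level: Optional[int] = None
    axes: Optional[str] = None
    pixel_size: Optional[tuple[float, float, float]] = None
    pixel_unit: Optional[str] = None
    channel_names: Optional[list[str]] = None
    slabs: list[dict] = field(default_factory=list)
    label_opacity: float = 0.5
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        for key, value in d.items():
            setattr(cfg, key, value)
        if cfg.time_window is not None:
            cfg.time_window = tuple(int(v) for v in cfg.time_window)
        if cfg.pixel_size is not None:
            cfg.pixel_size = tuple(float(v) for v in cfg.pixel_size)
        cfg.colors = [tuple(float(v) for v in c) for c in cfg.colors]
        return cfg

    def channel_mode(self, c: int) -> tuple[str, Optional[float]]:
        mode = self.channels[c] if c < len(self.channels) else "volumetric"
        if mode.startswith("isosurface"):
            parts = mode.split(":")
            if len(parts) != 2:
                raise ValidationError(
                    f"isosurface mode needs a threshold: {mode!r}"
                )
            return "isosurface", float(parts[1])
        if mode not in ("volumetric", "labelmask"):
            raise ValidationError(f"unknown channel mode {mode!r}")
        return mode, None

    def channel_emissive(self, c: int) -> bool:
        return self.emissive[c] if c < len(self.emissive) else True

    def channel_color(self, c: int) -> tuple[float, float, float]:
        return self.colors[c] if c < len(self.colors) else (1.0, 1.0, 1.0)

    def channel_colormap(self, c: int) -> Optional[str]:
        return self.colormaps[c] if c < len(self.colormaps) else None


def describe_dataset(source: str, overrides: Optional[ReadOverrides] = None) -> str:
    """Human-readable metadata report: axes, shape, pixel sizes, levels."""
    ds = read_dataset(source, overrides)
    lines = [
        f"source:        {ds.source}",
        f"axes (source): {ds.axes_original}",
        f"shape (TCZYX): {ds.shape_canonical}",
        f"dtype:         {ds.dtype_kind} {ds.dtype_bits}-bit",
        f"pixel size:    x={ds.pixel_size[0]} y={ds.pixel_size[1]} "
        f"z={ds.pixel_size[2]} [{ds.pixel_unit}]",
        f"channels:      {', '.join(ds.channel_names)}",
        f"timeframes:    {ds.shape_canonical[0]}",
        "levels:",
    ]
    for lvl in ds.levels:
        fp = footprint_bytes(lvl, ds.n_channels)
        lines.append(
            f"  level {lvl.level_index}: shape_zyx={lvl.shape_zyx} "
            f"footprint/timeframe={fp} bytes ({fp / 2**30:.3f} GiB)"
        )
    return "\n".join(lines)


def _level_with_extra(
    level: MultiscaleLevel, extra: tuple[int, int, int], n_channels: int
) -> MultiscaleLevel:
    """Virtual level metadata after applying an extra downscale."""
    if extra == (1, 1, 1):
        return level
    shape = tuple(-(-s // f) for s, f in zip(level.shape_zyx, extra))
    factors = tuple(
        f0 * f for f0, f in zip(level.downscale_factors, extra)
    )
    return MultiscaleLevel(
        level.level_index, shape, factors, int(np.prod(shape)) * n_channels * 4
    )


def run_convert(config: RunConfig, reload_scale: Optional[int] = None) -> Path:
    """Export grids, meshes and the manifest for a source dataset.

    Returns the manifest path.  With ``reload_scale`` the existing
    manifest's transfer functions and slice boxes are preserved and only
    the voxel level changes.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"

    previous: Optional[assets_mod.Scene] = None
    if reload_scale is not None:
        previous = assets_mod.load_manifest(manifest_path)
        config = dataclasses.replace(config, level=int(reload_scale))

    overrides = ReadOverrides(
        axes=config.axes,
        pixel_size=config.pixel_size,
        pixel_unit=config.pixel_unit,
        channel_names=config.channel_names,
    )
    ds = read_dataset(config.source, overrides)
    if config.time_window is not None:
        ds = clip_time(ds, *config.time_window)

    budget = parse_budget(config.budget)
    if budget < ds.n_channels * 4:
        raise ValidationError(
            f"budget {budget} bytes cannot hold even a single voxel of "
            f"{ds.n_channels} float32 channels; raise the budget"
        )
    if config.level is not None:
        if not (0 <= config.level < len(ds.levels)):
            raise ValidationError(f"level {config.level} out of range")
        chosen = ds.levels[config.level]
        selection = LevelSelection(
            config.level, (1, 1, 1), footprint_bytes(chosen, ds.n_channels)
        )
    else:
        selection = select_level(
            list(ds.levels), ds.n_channels, BudgetPolicy(budget_bytes=budget)
        )
        chosen = ds.levels[selection.chosen_level]
    logger.info(
        "selected level %d with extra downscale %s (%.3f GiB/timeframe)",
        selection.chosen_level,
        selection.extra_downscale,
        selection.resulting_footprint_bytes / 2**30,
    )

    unit_mode = UnitMode(config.unit_mode)
    center_mode = CenterMode(config.center_mode)
    base_transform = build_transform(ds, ds.levels[0], unit_mode, center_mode)
    effective = _level_with_extra(chosen, selection.extra_downscale, ds.n_channels)
    transform = build_transform(ds, effective, unit_mode, center_mode)

    slice_boxes = [
        make_slab(
            s["axis"],
            float(s["position"]),
            float(s["thickness"]),
            transform.bounds(effective.shape_zyx),
            applies_to=s.get("applies_to", ()),
        )
        for s in config.slabs
    ]
    if previous is not None:
        slice_boxes = previous.slice_boxes

    lvl_tag = f"l{selection.chosen_level}"
    if selection.extra_downscale != (1, 1, 1):
        lvl_tag += f"d{selection.extra_downscale[0]}"
    palette = LabelPalette()
    channels: list[assets_mod.ChannelAssets] = []
    for c in range(ds.n_channels):
        mode, threshold = config.channel_mode(c)
        emissive = config.channel_emissive(c)
        color = config.channel_color(c)
        ch = assets_mod.ChannelAssets(
            name=ds.channel_names[c],
            mode=mode,
            emissive=emissive,
            color=color,
            threshold=threshold,
        )
        prev_ch = previous.channels[c] if previous is not None else None
        if mode == "labelmask":
            for t in ds.timeframes():
                labels = ds.read_level_native(selection.chosen_level, t, c)
                if labels.dtype.kind not in "iu":
                    raise ValidationError(
                        f"channel {c} is marked labelmask but has dtype "
                        f"{labels.dtype}"
                    )
                labels = downsample_labels(labels, selection.extra_downscale)
                grid_name = f"c{c}_t{t}_{lvl_tag}.vxgrid"
                assets_mod.export_volume_grid(
                    labels.astype(np.float32),
                    transform,
                    out_dir / grid_name,
                    channel_ref=c,
                    timeframe=t,
                )
                ch.grids[str(t)] = grid_name
                if t == ds.time_window[0]:
                    surfaces = assets_mod.extract_label_surfaces(
                        labels, transform, palette
                    )
                    for object_id, (mesh, rgb) in surfaces.entries.items():
                        mesh_name = f"c{c}_label{object_id}.ply"
                        assets_mod.write_mesh(mesh, out_dir / mesh_name, "ply")
                        ch.labels[str(object_id)] = {
                            "mesh": mesh_name,
                            "color": list(rgb),
                        }
        else:
            tf: Optional[TransferFunction] = None
            if prev_ch is not None and prev_ch.transfer is not None:
                tf = prev_ch.transfer
            for t in ds.timeframes():
                vol = ds.read_level(selection.chosen_level, t, c)
                vol = downsample(vol, selection.extra_downscale)
                if tf is None:
                    cmap_name = config.channel_colormap(c)
                    cmap = (
                        Colormap.from_name(cmap_name)
                        if cmap_name
                        else Colormap.single_color(color)
                    )
                    default = TransferFunction.default_for(
                        vol, color=color, emissive=emissive
                    )
                    tf = dataclasses.replace(default, colormap=cmap)
                grid_name = f"c{c}_t{t}_{lvl_tag}.vxgrid"
                assets_mod.export_volume_grid(
                    vol, transform, out_dir / grid_name, channel_ref=c, timeframe=t
                )
                ch.grids[str(t)] = grid_name
                if mode == "isosurface" and t == ds.time_window[0]:
                    mesh = assets_mod.extract_isosurface(vol, threshold, transform)
                    mesh_name = f"c{c}_iso.ply"
                    assets_mod.write_mesh(mesh, out_dir / mesh_name, "ply")
                    ch.mesh = mesh_name
            ch.transfer = tf
        channels.append(ch)

    scene = assets_mod.Scene(
        channels=channels,
        base_transform=base_transform,
        level=selection.chosen_level,
        extra_downscale=selection.extra_downscale,
        slice_boxes=list(slice_boxes),
        source=str(config.source),
        time_window=ds.time_window,
    )
    return assets_mod.write_manifest(scene, manifest_path)


def run_render(
    manifest_path: str | Path,
    destination: str | Path,
    view: str | Sequence[float] = "z",
    image_size: tuple[int, int] = (256, 256),
    timeframe: Optional[int] = None,
    step_length: Optional[float] = None,
    background: tuple[float, float, float] = (0.0, 0.0, 0.0),
    label_opacity: float = 0.5,
) -> RenderResult:
    """Ray-march a preview of a converted scene and write a PNG.

    Volumetric and labelmask channels are marched; isosurface channels are
    mesh assets and are skipped by this volume previewer.  Rendering is
    deterministic: identical inputs give identical images.
    """
    manifest_path = Path(manifest_path)
    scene = assets_mod.load_manifest(manifest_path)
    base = manifest_path.parent

    channels = []
    for index, ch in enumerate(scene.channels):
        if not ch.grids:
            if ch.mode == "isosurface":
                logger.info("skipping isosurface channel %r in preview", ch.name)
            continue
        keys = sorted(ch.grids, key=int)
        key = str(timeframe) if timeframe is not None else keys[0]
        if key not in ch.grids:
            raise ValidationError(f"timeframe {key} not present for {ch.name!r}")
        grid = assets_mod.read_volume_grid(base / ch.grids[key])
        if ch.mode == "labelmask":
            overrides = {
                int(object_id): tuple(entry["color"])
                for object_id, entry in ch.labels.items()
            }
            channels.append(
                LabelRenderChannel(
                    labels=np.rint(grid.values).astype(np.int64),
                    transform=grid.transform,
                    opacity=label_opacity,
                    channel_index=index,
                    overrides=overrides,
                )
            )
        elif ch.mode == "volumetric":
            channels.append(RenderChannel(grid, ch.transfer, channel_index=index))
        else:
            logger.info("skipping isosurface channel %r in preview", ch.name)

    config = RenderConfig(
        view=view,
        image_size=tuple(image_size),
        step_length=step_length,
        background=tuple(background),
    )
    result = render(channels, scene.slice_boxes, config)
    result.to_png(destination)
    return result
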