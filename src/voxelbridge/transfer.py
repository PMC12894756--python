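"""Histograms, color lookup tables, alpha transfer functions, label palette.

A channel's appearance is driven by a :class:`TransferFunction`: an
intensity window [lo, hi) set against the channel histogram, a colormap
evaluated on the normalized intensity, and a linear opacity response

    alpha(v) = clamp01(baseline + slope * u),   u = (v - lo) / (hi - lo)

with ``u`` clamped to [0, 1] unless out-of-range clipping is enabled, in
which case intensities outside the window become fully transparent.  For an
emissive channel alpha acts as brightness; for an absorptive one it is the
opacity per unit reference length of the medium.

Label masks are colored by a revolving palette of exactly ten distinct
colors: object identity ``id`` (1-based) receives ``colors[(id-1) % 10]``,
so identities 1 and 11 share a color.  Identity 0 is background and has no
color.  Per-identity overrides supersede the palette.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError

RGB = tuple[float, float, float]


def _clamp01(a):
    return np.clip(a, 0.0, 1.0)


# ---------------------------------------------------------------------------
# colormaps


@dataclass(frozen=True)
class Colormap:
    """Ordered RGB stops in [0, 1], interpolated linearly in RGB."""

    stops: tuple[RGB, ...]
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.stops) < 1:
            raise ValidationError("colormap needs at least one stop")
        arr = np.asarray(self.stops, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.min() < 0 or arr.max() > 1:
            raise ValidationError("colormap stops must be RGB triples in [0, 1]")

    def __call__(self, u) -> np.ndarray:
        """Evaluate at normalized positions u (clamped); returns (..., 3)."""
        u = _clamp01(np.asarray(u, dtype=np.float64))
        stops = np.asarray(self.stops, dtype=np.float64)
        if len(stops) == 1:
            return np.broadcast_to(stops[0], u.shape + (3,)).copy()
        pos = np.linspace(0.0, 1.0, len(stops))
        out = np.empty(u.shape + (3,))
        for k in range(3):
            out[..., k] = np.interp(u, pos, stops[:, k])
        return out

    @classmethod
    def single_color(cls, color: RGB) -> "Colormap":
        """White-to-color ramp: the 'single color' channel mode."""
        return cls(((1.0, 1.0, 1.0), tuple(float(c) for c in color)))

    @classmethod
    def from_name(cls, name: str, n_stops: int = 33) -> "Colormap":
        """Resolve a named colormap from the registry.

        ``gray`` is built in; the nonlinear defaults (viridis, magma,
        inferno, hot) are sampled from matplotlib.
        """
        if name == "gray":
            return cls(((0.0, 0.0, 0.0), (1.0, 1.0, 1.0)), name="gray")
        if name in _NAMED_COLORMAPS:
            import matplotlib

            mpl_map = matplotlib.colormaps[name]
            stops = tuple(
                tuple(float(c) for c in mpl_map(u)[:3])
                for u in np.linspace(0.0, 1.0, n_stops)
            )
            return cls(stops, name=name)
        raise ValidationError(
            f"unknown colormap {name!r}; available: gray, "
            + ", ".join(sorted(_NAMED_COLORMAPS))
        )

    def to_dict(self) -> dict:
        if self.name is not None:
            return {"name": self.name}
        return {"stops": [list(s) for s in self.stops]}

    @classmethod
    def from_dict(cls, d: dict) -> "Colormap":
        if "name" in d:
            return cls.from_name(d["name"])
        return cls(tuple(tuple(float(c) for c in s) for s in d["stops"]))


_NAMED_COLORMAPS = {"viridis", "magma", "inferno", "hot"}


# ---------------------------------------------------------------------------
# histogram


@dataclass(frozen=True)
class HistogramSummary:
    """Equal-width histogram over [data_min, data_max]."""

    bin_edges: np.ndarray  # n_bins + 1 ascending floats
    counts: np.ndarray  # n_bins non-negative integers
    data_min: float
    data_max: float


def compute_histogram(volume: np.ndarray, n_bins: int = 256) -> HistogramSummary:
    """Histogram all voxels of a volume into equal-width bins.

    A constant volume yields a single occupied bin (edges then span a unit
    interval around the constant, the one degenerate case where the edges
    exceed [min, max]).
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    volume = np.asarray(volume)
    if volume.size == 0:
        raise ValidationError("cannot histogram an empty volume")
    vmin = float(volume.min())
    vmax = float(volume.max())
    lo, hi = (vmin, vmax) if vmax > vmin else (vmin - 0.5, vmin + 0.5)
    counts, edges = np.histogram(volume, bins=n_bins, range=(lo, hi))
    return HistogramSummary(edges, counts, vmin, vmax)


# ---------------------------------------------------------------------------
# transfer functions


@dataclass(frozen=True)
class TransferFunction:
    """Intensity window + colormap + linear opacity response (see module doc)."""

    lo: float
    hi: float
    colormap: Colormap = field(default_factory=lambda: Colormap.from_name("gray"))
    alpha_baseline: float = 0.0
    alpha_slope: float = 1.0
    clip_out_of_range: bool = False
    emissive: bool = True

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError(f"need lo < hi, got [{self.lo}, {self.hi}]")
        if self.alpha_baseline < 0:
            raise ValidationError("alpha baseline must be >= 0")

    def normalized(self, v) -> np.ndarray:
        u = (np.asarray(v, dtype=np.float64) - self.lo) / (self.hi - self.lo)
        return _clamp01(u)

    def alpha(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=np.float64)
        a = _clamp01(self.alpha_baseline + self.alpha_slope * self.normalized(v))
        if self.clip_out_of_range:
            a = np.where((v < self.lo) | (v > self.hi), 0.0, a)
        return a

    def color(self, v) -> np.ndarray:
        return self.colormap(self.normalized(v))

    def __call__(self, v) -> tuple[np.ndarray, np.ndarray]:
        return self.color(v), self.alpha(v)

    @classmethod
    def default_for(
        cls,
        volume: np.ndarray,
        color: RGB = (1.0, 1.0, 1.0),
        emissive: bool = True,
    ) -> "TransferFunction":
        """Default per-channel transfer: full data range, b=0, m=1, no clip,
        single-color ramp."""
        vmin = float(np.min(volume))
        vmax = float(np.max(volume))
        if vmax <= vmin:
            vmax = vmin + 1.0
        return cls(vmin, vmax, Colormap.single_color(color), emissive=emissive)

    def to_dict(self) -> dict:
        return {
            "lo": float(self.lo),
            "hi": float(self.hi),
            "colormap": self.colormap.to_dict(),
            "alpha_baseline": float(self.alpha_baseline),
            "alpha_slope": float(self.alpha_slope),
            "clip_out_of_range": self.clip_out_of_range,
            "emissive": self.emissive,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransferFunction":
        return cls(
            lo=float(d["lo"]),
            hi=float(d["hi"]),
            colormap=Colormap.from_dict(d["colormap"]),
            alpha_baseline=float(d["alpha_baseline"]),
            alpha_slope=float(d["alpha_slope"]),
            clip_out_of_range=bool(d["clip_out_of_range"]),
            emissive=bool(d["emissive"]),
        )


def apply_transfer(tf: TransferFunction, v) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a transfer function: returns (rgb, alpha), both in [0, 1]."""
    return tf(v)


def dual_transfer(
    v, tf_a: TransferFunction, tf_b: TransferFunction
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the same scalar through two transfer functions and composite.

    This is the 'evaluate the data twice' trick: e.g. one window picks out
    membranes, a second disjoint window picks out chromatin in a different
    color, without any segmentation.  Alphas combine as
    1 - (1-aa)*(1-ab); colors by alpha-weighted addition.
    """
    ca, aa = tf_a(v)
    cb, ab = tf_b(v)
    alpha = 1.0 - (1.0 - aa) * (1.0 - ab)
    w = aa + ab
    safe_w = np.where(w > 0, w, 1.0)
    rgb = (ca * aa[..., None] + cb * ab[..., None]) / safe_w[..., None]
    rgb = np.where(w[..., None] > 0, rgb, 0.0)
    return rgb, alpha


# ---------------------------------------------------------------------------
# label palette


def _default_palette_colors() -> tuple[RGB, ...]:
    # ten maximally spaced hues at full saturation and value
    return tuple(colorsys.hsv_to_rgb(k / 10.0, 1.0, 1.0) for k in range(10))


@dataclass(frozen=True)
class LabelPalette:
    """Revolving ten-color palette for object identities (1-based)."""

    colors: tuple[RGB, ...] = field(default_factory=_default_palette_colors)

    def __post_init__(self) -> None:
        if len(self.colors) != 10:
            raise ValidationError("label palette must have exactly 10 colors")
        if len({tuple(np.round(c, 12)) for c in self.colors}) != 10:
            raise ValidationError("label palette colors must be distinct")

    def color_for(
        self, object_id: int, overrides: Optional[Mapping[int, RGB]] = None
    ) -> RGB:
        if object_id < 1:
            raise ValidationError("object id 0 is background and has no color")
        if overrides and object_id in overrides:
            return tuple(float(c) for c in overrides[object_id])
        return self.colors[(object_id - 1) % 10]

    def lut(self, max_id: int, overrides: Optional[Mapping[int, RGB]] = None) -> np.ndarray:
        """(max_id+1, 3) lookup table; row 0 (background) is black."""
        table = np.zeros((max_id + 1, 3))
        for i in range(1, max_id + 1):
            table[i] = self.color_for(i, overrides)
        return table

    def to_dict(self) -> dict:
        return {"colors": [list(c) for c in self.colors]}

    @classmethod
    def from_dict(cls, d: dict) -> "LabelPalette":
        return cls(tuple(tuple(float(v) for v in c) for c in d["colors"]))


def label_color(
    palette: LabelPalette,
    object_id: int,
    overrides: Optional[Mapping[int, RGB]] = None,
) -> RGB:
    """Functional alias for :meth:`LabelPalette.color_for`."""
    return palette.color_for(object_id, overrides)
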