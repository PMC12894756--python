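# Methods

This note documents the models, conventions and numerical choices behind
voxelbridge, and what the synthetic phantoms do and do not exercise.

## Canonical 5D datasets

All sources are presented as `(T, C, Z, Y, X)`; axes absent from the
source get extent 1. The axis order comes from OME-Zarr `multiscales`
axes metadata or the TIFF series axes; when a source carries no usable
labels the fallback is: 2D → YX, 3D → ZYX, 4D → CZYX if the leading axis
has extent ≤ 8 else TZYX, 5D → TCZYX. The channel-vs-time split at 4D is
a heuristic — microscopy rarely has more than a handful of channels — and
the threshold of 8 is this package's own convention; explicit overrides
always win. Multi-page TIFF stacks are treated as Z unless metadata says
otherwise. Pixel sizes default to (1, 1, 1) in unit "pixel", which keeps
the px→cm transform path available for unannotated data. Voxel indices
are 0-based and all intervals (time windows, brick ranges) are half-open.

Laziness is per-(level, timeframe, channel): metadata is read eagerly,
voxels are materialized one 3D block at a time through zarr chunk reads
or a deferred TIFF load, and cast to float32 at the API boundary. Label
masks bypass the cast (`read_level_native`) because integer identities
above 2²⁴ would not survive a float32 round trip.

## Memory budget and level selection

The budget models the 4 GiB (2³² bytes) per-timeframe cap of rasterized
interactive display: footprint = `Z·Y·X·C·4` bytes, integer arithmetic
only, timeframes excluded, label channels included ("all loaded channels
combined"). Whether a footprint of exactly 4 GiB passes is not decidable
from the cap's two informal statements ("not more than" vs "under"), so
the comparison is a policy: inclusive (≤) by default, configurable.

Selection walks the pyramid finest-first and returns the first passing
level. If nothing passes (or the source has a single level), the coarsest
level gets the smallest uniform power-of-two extra downscale that passes.
Power-of-two factors mirror pyramid conventions and keep the dynamic path
and presaved pyramids interchangeable.

Dynamic downsampling is mean pooling with partial edge windows: output
shape is `ceil(n/f)` per axis and border windows average only the voxels
present, so the voxel-count-weighted global mean is preserved exactly
(accumulation in float64). Label masks are strided instead — averaging
object identities is meaningless — which preserves the identity set of
every object larger than the stride.

## World space

World coordinates are right-handed, z up, in scene-meters, with the
voxel-center convention `world = spacing · (index + ½) + translation`.
The default `PX_TO_CM` mode maps each xy pixel to 0.01 scene-meters
regardless of the stored pixel size and multiplies the z spacing by the
z/xy pixel-size ratio, so anisotropic confocal stacks appear isotropic
and any dataset lands near the meter scale. x and y pixel sizes differing
by more than 1% trigger a warning and their mean is used. The physical
modes are literal unit relabelings (one µm/nm/Å/m of physical size per
scene-meter), chosen so externally produced meshes with physical
coordinates align without rescaling. `XY_CENTERED` puts the XY
bounding-box center at x = y = 0 with z starting at 0 (volumes sit on a
ground plane; whether z should also be centered is not prescribed
anywhere, sitting-on-the-plane is this package's choice); `CORNER_ORIGIN`
puts the voxel (0,0,0) corner at the origin. Coarser pyramid levels
multiply the spacing by their downscale factors, so every level covers
the same world extent.

## Transfer functions and labels

A channel's window [lo, hi) normalizes intensity to `u`, clamped to
[0, 1] unless out-of-range clipping is on (then α = 0 outside the
window). Opacity is `α = clamp01(b + m·u)` — a baseline plus linear
response. Colormaps are ordered RGB stops interpolated linearly in RGB
(simple and exactly testable; perceptual uniformity is out of scope);
named maps (viridis, magma, inferno, hot, gray) come from matplotlib.
The default per-channel transfer is the full data range, b = 0, m = 1, no
clipping, and a white→channel-color ramp (the "single color" mode). Dual
evaluation combines two transfers on one scalar with
`α = 1 − (1−α_a)(1−α_b)` and alpha-weighted color averaging, so a
transparent partner is exactly neutral.

The label palette is exactly ten distinct colors assigned as
`colors[(id−1) mod 10]` for id ≥ 1; id 0 is background. The default
colors are the ten maximally spaced HSV hues at full saturation and value
— the published material fixes the count, not the RGB values, so the
concrete colors are this package's own and per-identity overrides
supersede them.

## Assets

All channels are resaved as float32 whatever the input depth (8–32 bit
integer or float), so one container serves every channel at the cost of
possibly larger temporaries. The portable container is a bricked sparse
grid: 16³ bricks (VDB-like leaf size), background 0.0, all-background
bricks elided, edge bricks stored cropped, with a JSON header carrying
shape, transform and brick index; round trips are bit-exact. A true
OpenVDB container would need a VDB codec (pyopenvdb) and is exposed only
as an explicit error naming that capability.

Isosurfaces are scikit-image marching cubes on the voxel-center lattice
after padding the volume with one layer of background, which closes
surfaces that cross the data boundary (compact foreground regions become
watertight; a volume entirely above threshold becomes a closed box at the
padded boundary). The boundary treatment of the extraction is not
prescribed by any upstream contract; padding-closure is this package's
documented choice. A threshold outside the padded data range returns an
empty mesh rather than an error, matching interactive threshold sliders.
Vertices map to world space through the channel transform; the axis
reorder (z,y,x) → (x,y,z) is an odd permutation, so face winding is
flipped to keep outward orientation. Normals are area-weighted vertex
normals of the world-space mesh, which stay correct under anisotropic
spacing. Label surfacing is per-identity marching cubes of the binary
mask at 0.5 — separate, individually watertight surfaces per object, not
multi-material contouring. Mesh interchange is ASCII OBJ and binary
little-endian PLY via trimesh; the manifest is canonical JSON (sorted
keys, fixed indentation) so load → save is byte-identical, and it stores
the level-0 transform plus a level field, so a reload at another scale
touches only the level and grid entries.

## Preview renderer

Orthographic, front-to-back, fixed world step Δs (default half the
smallest voxel spacing), trilinear sampling with edge clamping for
intensities and nearest-neighbor for label identities. Transfer alphas
are opacity per `reference_step` of path (default 1 scene-meter); each
step contributes `α_step = 1 − (1−α)^(Δs/Δs_ref)`, the standard opacity
correction. For homogeneous media this makes transmittance exactly
`(1−α)^(L/Δs_ref) = exp(−σL)` with `σ = −ln(1−α)/Δs_ref` for *any* step
partition (the final partial step uses its true length), so the
Beer–Lambert check is limited only by floating point; for inhomogeneous
media the midpoint-rule march converges to the continuous limit as the
step shrinks. Emissive channels add `T·c·α_step` and leave transmittance
untouched (pure additive light — fluorescence); absorptive channels add
the same scattering term and multiply `T` by `1 − α_step`. Consequences
worth knowing: emissive radiance is proportional to path length and can
exceed 1 (it is clipped only at PNG write time), and the per-pixel
radiance bound "≤ channel count" holds in the normalized regime where
each channel's total optical depth `L·(−ln(1−α))/Δs_ref` stays ≤ 1.
Channels are composited in list order within a single march, so the
relative order of absorptive channels matters exactly as physical layering
would.

Slice boxes are oriented boxes (`|Rᵀ(p−c)| ≤ h` componentwise, rotation
orthonormal to 1e-9) with an `applies_to` channel set; a channel with no
applicable boxes is unsliced. When several boxes apply to one channel the
default combine is intersection (a sample survives only inside all of
them); `combine="union"` is available for the duplicated-thin-slab
workflow that shows several orthogonal slice planes at once. A slab one
voxel thick, rendered along its axis with nearest sampling, step = voxel
spacing and `Δs_ref = Δs`, reproduces the transfer-mapped raw slice
pixel-for-pixel — the regression anchor tying the renderer to the data.

Axis views place the image origin top-left: view "z" looks down −z with
image columns along +x and rows along +y; "x" and "y" keep z pointing up
the image. Arbitrary view vectors build a right/down basis from a world
up vector. Images are deterministic functions of their inputs (no
stochastic sampling), so repeated renders are byte-identical.

## Phantoms

The fixture generator produces deterministic volumes with returned ground
truth: centered or randomly placed balls (analytic volume/surface
oracles), axis-aligned tube networks, nested concentric shells, and
non-overlapping label cubes with identities exactly 1..n. Objects drift
one voxel per timeframe and channel intensities scale by channel index,
making time/channel bookkeeping observable. Noise is additive Gaussian
only, and never applied to label volumes. Store pyramids are built with
the same mean pooling (stride for labels) as the dynamic downsampler so
the two paths can be cross-validated.

What the phantoms do not emulate: point-spread functions, shot noise,
intensity inhomogeneity, compressed chunk layouts, or remote stores.
Passing tests therefore demonstrate the correctness of the geometry,
bookkeeping and compositing contracts — not robustness to real-world
acquisition artifacts. Default problem sizes (32³–64³ volumes, 64×64–96×96
previews, ≤ 512 marching steps) are chosen so the full suite exercises
every stage in seconds; all the contracts checked are scale-invariant, and
the budget selector is exercised on metadata alone at realistic
(1024×2048×2048) shapes without allocating voxels.

## Known limitations

Remote URI access is pass-through to zarr and untested against object
stores; OME-TIFF XML pixel metadata is not parsed (ImageJ tags and
resolution tags are); there is no out-of-core brick streaming — one
(level, timeframe, channel) block must fit in memory; perspective
cameras, shadows and multiple scattering are out of scope for the
previewer; alembic and true VDB containers are not written.
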