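"""Load a multiscale store and pick a level under the memory budget.

Generates a small two-channel OME-Zarr pyramid, reads it back with full
metadata, and runs the default 4 GiB-per-timeframe level selection.
"""

import tempfile
from pathlib import Path

import voxelbridge as vb

workdir = Path(tempfile.mkdtemp())
spec = vb.PhantomSpec(kind="ball", shape_zyx=(64, 64, 64), radius=20,
                      n_channels=2, seed=1)
volume, truth = vb.make_phantom(spec)
store = workdir / "ball.zarr"
vb.write_synthetic_store(volume, store, n_levels=3, axes="czyx",
                         pixel_size=(0.1, 0.1, 0.5), pixel_unit="micrometer",
                         channel_names=["membrane", "nucleus"])

print(vb.describe_dataset(str(store)))
# axes/shape/pixel sizes come from the store metadata; each level line shows
# the float32 bytes one timeframe of all channels would occupy.

selection = vb.select_level(list(vb.read_dataset(str(store)).levels), 2)
print(f"\nselected level {selection.chosen_level} "
      f"(extra downscale {selection.extra_downscale}), "
      f"{selection.resulting_footprint_bytes} bytes/timeframe")
# Level 0 already fits the default 4 GiB budget at this desk scale, so the
# finest level is chosen with no extra downscaling.
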