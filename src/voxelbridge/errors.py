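"""Exception hierarchy.

All errors raised deliberately by voxelbridge derive from
:class:`VoxelBridgeError`, so callers (and the CLI) can distinguish
user/input problems from genuine bugs.
"""


class VoxelBridgeError(Exception):
    """Base class for all voxelbridge errors."""


class ValidationError(VoxelBridgeError, ValueError):
    """Invalid argument, metadata or configuration."""


class SourceReadError(VoxelBridgeError, OSError):
    """A data source could not be opened or read."""


class FeatureUnavailableError(VoxelBridgeError, RuntimeError):
    """An optional capability was requested but its backend is missing."""
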