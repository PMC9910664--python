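"""Exception types.

Error messages follow the short phrases used throughout the package's
contracts ("inconsistent stack", "missing voxel size", ...) so callers and
the CLI can map them stably.
"""


class PatsError(Exception):
    """Base class for all package errors."""


class InputError(PatsError):
    """Bad input data or unusable files (CLI exit code 1)."""


class SegmentationError(PatsError):
    """Analysis failed on valid input (CLI exit code 2)."""


class TaskListError(PatsError):
    """Unparsable or unresolvable task list."""
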