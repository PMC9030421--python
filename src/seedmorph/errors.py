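"""Exception hierarchy shared across the pipeline.

Each error class carries the process exit code used by the command-line
interface: 2 validation, 3 I/O, 4 degenerate data, 5 model failure.
"""


class SeedMorphError(Exception):
    """Base class for all seedmorph errors."""

    exit_code = 1


class ValidationError(SeedMorphError):
    """Invalid parameter or inconsistent inputs."""

    exit_code = 2


class InputError(SeedMorphError):
    """Unreadable, corrupt or missing input file."""

    exit_code = 3


class DegenerateShapeError(SeedMorphError):
    """A specimen too small or too flat to be measured."""

    exit_code = 4


class ModelError(SeedMorphError):
    """Discriminant model could not be fitted or applied."""

    exit_code = 5


class EmptyModelError(ModelError):
    """No feature passed the entry threshold at the first step."""


class CollinearityError(ModelError):
    """Selected features are linearly dependent within groups."""


class LayoutError(ValidationError):
    """Synthetic scan layout cannot place all seeds without overlap."""
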