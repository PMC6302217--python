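"""Exception hierarchy shared across the package."""


class ThermavirError(Exception):
    """Base class for all package errors."""


class ParameterError(ThermavirError, ValueError):
    """An input parameter violates its contract; the message names the field."""


class CapacityError(ThermavirError, ValueError):
    """A planted feature does not fit inside the target sequence."""


class ManifestError(ThermavirError, KeyError):
    """A query/contig id is missing from the ground-truth manifest."""


class CompositionError(ThermavirError, ValueError):
    """Sequence composition is undefined (e.g. all-N sequence)."""


class InsufficientSequenceError(ThermavirError, ValueError):
    """Sequence too short / too ambiguous for the requested profile."""


class DegenerateVarianceError(ThermavirError, ValueError):
    """A profile has zero variance and cannot enter a correlation."""


class InsufficientInputError(ThermavirError, ValueError):
    """Fewer usable records than the operation requires."""


class MappingError(ThermavirError, KeyError):
    """A subject id is missing from a user-supplied mapping."""


class InputError(ThermavirError, ValueError):
    """Malformed operation input (mixed queries, empty hit list, ...)."""
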