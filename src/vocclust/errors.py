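"""Exception hierarchy shared by all stages."""


class VocclustError(Exception):
    """Base class for all package errors."""


class InputError(VocclustError):
    """Unreadable, malformed, or inconsistent input data."""


class ParameterError(VocclustError):
    """A parameter value outside its admissible range."""


class DegenerateInputError(InputError):
    """Input that is formally valid but carries no usable signal."""
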