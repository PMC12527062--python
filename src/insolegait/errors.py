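"""Exception hierarchy shared by all insolegait modules."""


class GaitError(Exception):
    """Base class for all insolegait errors."""


class ParameterError(GaitError, ValueError):
    """A function argument violates its documented precondition."""


class InputError(GaitError, ValueError):
    """Input data (sequence shapes, counts, degenerate content) is unusable."""


class ChannelError(GaitError, KeyError):
    """A required sensor channel is absent from a recording."""


class FormatError(GaitError, ValueError):
    """A file does not conform to the documented CSV/YAML schema."""


class DegenerateModelError(GaitError, ValueError):
    """The reference model cannot support the requested operation (e.g. zero stride)."""
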